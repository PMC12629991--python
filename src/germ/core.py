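"""The GeRM (generalized RNA multivalency) score.

For a k-mer starting at position ``p`` the score is the distance-weighted sum
of similarities to every non-overlapping k-mer inside a window of ``n``
consecutive k-mers centred on it:

    g(p) = sum_{i in B} exp(-lambda * d(A_0, A_i)) * weight(i),
    B = {-w, ..., -k, k, ..., w},  w = (n + 1) / 2

where ``d`` is the Hamming distance between the central k-mer ``A_0`` and the
neighbour ``A_i`` starting ``i`` nucleotides away. Neighbour positions beyond
the transcript ends, and k-mers containing ``N``, contribute 0. The weight
decays linearly from 1 at the centre to 0 at ``|i| = w``; the asymmetric form
``|w - i| / w`` is retained behind ``literal_weight=True`` for comparison.

Two scorers are provided: :func:`score_transcript` (vectorized, offset-by-
offset over the whole transcript) and :func:`score_transcript_reference`
(direct term-by-term evaluation of the sum at each position). They agree to
floating-point accuracy and serve as mutual cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import canonicalize, encode, valid_kmer_mask


@dataclass(frozen=True)
class GermParams:
    """Constants of the GeRM score.

    k: k-mer length (nt). n: window size in k-mers (odd, > 2k). lam: decay
    constant of the exponential Hamming similarity. smooth_width: width (nt)
    of the moving-mean smoother. The half-window is w = (n + 1) / 2.
    """

    k: int = 5
    n: int = 123
    lam: float = 1.0
    smooth_width: int = 123

    def __post_init__(self) -> None:
        if self.n % 2 == 0:
            raise ValueError("window size n must be odd")
        if self.n <= 2 * self.k:
            raise ValueError("window size n must exceed 2k")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.smooth_width % 2 == 0:
            raise ValueError("smooth_width must be odd")

    @property
    def w(self) -> int:
        return (self.n + 1) // 2


@dataclass
class NormalizationStats:
    """Affine normalization coefficients: x -> (x - min) / (median - min)."""

    min_raw: float
    median_raw: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.median_raw > self.min_raw:
            raise ValueError("degenerate raw score distribution (median == min)")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.min_raw) / (
            self.median_raw - self.min_raw
        )


@dataclass
class GermTrack:
    """Raw / normalized / smoothed GeRM scores for one transcript.

    Arrays are aligned to k-mer start positions (length L - k + 1).
    """

    transcript_id: str
    raw: np.ndarray
    normalized: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    params: GermParams = field(default_factory=GermParams)


def _weights(params: GermParams, literal_weight: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offsets k..w with weights for +i and -i."""
    w = params.w
    offs = np.arange(params.k, w + 1)
    if literal_weight:
        w_pos = np.abs(w - offs) / w
        w_neg = np.abs(w + offs) / w
    else:
        w_pos = (w - offs) / w
        w_neg = w_pos
    return offs, w_pos, w_neg


def score_transcript(
    sequence: str, params: GermParams = GermParams(), literal_weight: bool = False
) -> np.ndarray:
    """Raw GeRM score per k-mer start position (vectorized scorer).

    Returns an empty array for sequences shorter than k. Invalid characters
    raise ``ValueError``.
    """
    seq = canonicalize(sequence)
    x = encode(seq)
    k = params.k
    nk = len(x) - k + 1
    if nk <= 0:
        return np.zeros(0, dtype=float)
    valid = valid_kmer_mask(x, k)
    g = np.zeros(nk, dtype=float)
    offs, w_pos, w_neg = _weights(params, literal_weight)
    sims = np.exp(-params.lam * np.arange(k + 1))
    for i, wp, wn in zip(offs, w_pos, w_neg):
        if i >= nk:
            break
        # Hamming distance between k-mers p and p+i via a k-wide running sum
        neq = (x[:-i] != x[i:]).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(neq)))
        if len(neq) < k:
            continue
        d = csum[k:] - csum[:-k]  # length nk - i
        sim = sims[d]
        pair_ok = valid[: nk - i] & valid[i:]
        sim = np.where(pair_ok, sim, 0.0)
        g[: nk - i] += sim * wp  # neighbour at +i
        g[i:] += sim * wn  # neighbour at -i
    g[~valid] = 0.0
    return g


def score_transcript_reference(
    sequence: str, params: GermParams = GermParams(), literal_weight: bool = False
) -> np.ndarray:
    """Direct evaluation of the GeRM sum, position by position.

    Independent of the optimized scorer: builds the k-mer matrix and, for each
    central k-mer, evaluates every term exp(-lam*d) * weight(i) over the
    offset set B explicitly.
    """
    seq = canonicalize(sequence)
    x = encode(seq)
    k, w, lam = params.k, params.w, params.lam
    nk = len(x) - k + 1
    if nk <= 0:
        return np.zeros(0, dtype=float)
    kmers = np.lib.stride_tricks.sliding_window_view(x, k)
    valid = valid_kmer_mask(x, k)
    offsets = np.concatenate([np.arange(-w, -k + 1), np.arange(k, w + 1)])
    if literal_weight:
        weights = np.abs(w - offsets) / w
    else:
        weights = (w - np.abs(offsets)) / w
    g = np.zeros(nk, dtype=float)
    for p in range(nk):
        if not valid[p]:
            continue
        q = p + offsets
        in_bounds = (q >= 0) & (q < nk)
        qi = q[in_bounds]
        ok = valid[qi]
        d = (kmers[qi] != kmers[p]).sum(axis=1)
        terms = np.exp(-lam * d) * weights[in_bounds]
        g[p] = float(np.sum(terms[ok]))
    return g


def fit_normalization(
    raw_tracks: dict[str, np.ndarray] | list[np.ndarray], provenance: str = "unspecified"
) -> NormalizationStats:
    """Pool raw scores over a transcript set and fit min/median coefficients."""
    arrays = list(raw_tracks.values()) if isinstance(raw_tracks, dict) else list(raw_tracks)
    pooled = np.concatenate([np.asarray(a, dtype=float) for a in arrays if len(a)])
    if pooled.size < 2:
        raise ValueError("need at least two pooled raw values")
    return NormalizationStats(
        min_raw=float(pooled.min()),
        median_raw=float(np.median(pooled)),
        provenance=provenance,
    )


def smooth_track(values: np.ndarray, smooth_width: int) -> np.ndarray:
    """Centred moving mean; edge windows are truncated to in-bounds values."""
    if smooth_width % 2 == 0:
        raise ValueError("smooth_width must be odd")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    kernel = np.ones(smooth_width)
    sums = np.convolve(v, kernel, mode="same")
    counts = np.convolve(np.ones_like(v), kernel, mode="same")
    return sums / counts


def per_nucleotide_view(values: np.ndarray, length: int, k: int) -> np.ndarray:
    """Expand a k-mer-start track to per-nucleotide length.

    Each nucleotide takes the value of the k-mer starting at it; the trailing
    k - 1 positions carry the last defined k-mer's value.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.zeros(length, dtype=float)
    if v.size != length - k + 1:
        raise ValueError("track length does not match sequence length")
    return np.concatenate([v, np.full(k - 1, v[-1])])


def compute_track(
    transcript_id: str,
    sequence: str,
    params: GermParams = GermParams(),
    stats: NormalizationStats | None = None,
) -> GermTrack:
    """Score one transcript and attach normalized + smoothed arrays.

    Smoothing is applied to the normalized track when ``stats`` is given,
    otherwise to the raw track.
    """
    raw = score_transcript(sequence, params)
    normalized = stats.apply(raw) if stats is not None else None
    base = normalized if normalized is not None else raw
    smoothed = smooth_track(base, params.smooth_width) if len(base) else base
    return GermTrack(transcript_id, raw, normalized, smoothed, params)
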