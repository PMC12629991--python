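"""Calling of high-multivalency (GeRM) regions in coding sequences.

A region is a run of positions whose smoothed GeRM score exceeds a percentile
threshold pooled over all CDS positions of the supplied transcript set. Runs
are extended by half the smoothing window on each side (so a region contains
every k-mer that fell inside the smoothing window of a super-threshold
position), merged when they overlap by at least ``merge_overlap`` nt, and
dropped when at least one third of the extended span lies in an untranslated
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GermParams, GermTrack, per_nucleotide_view
from .io import TranscriptModel


@dataclass
class GermRegion:
    """A contiguous high-multivalency CDS interval (transcript coordinates)."""

    transcript_id: str
    start: int
    end: int
    mean_smoothed: float = 0.0
    total_raw: float = 0.0
    kmer_fractions: dict[str, float] = field(default_factory=dict)
    cluster: str | None = None

    @property
    def region_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_intervals(iv: list[tuple[int, int]], merge_overlap: int) -> list[tuple[int, int]]:
    """Merge intervals overlapping by >= merge_overlap nt, to a fixed point."""
    iv = sorted(iv)
    changed = True
    while changed:
        changed = False
        out: list[tuple[int, int]] = []
        for s, e in iv:
            if out and min(out[-1][1], e) - max(out[-1][0], s) >= merge_overlap:
                out[-1] = (min(out[-1][0], s), max(out[-1][1], e))
                changed = True
            else:
                out.append((s, e))
        iv = out
    return iv


def pooled_cds_threshold(
    tracks: dict[str, GermTrack], models: dict[str, TranscriptModel], percentile: float
) -> float:
    """Percentile (linear interpolation) of smoothed scores over CDS positions."""
    pooled = []
    for tid, track in tracks.items():
        model = models[tid]
        smoothed_nt = per_nucleotide_view(track.smoothed, model.length, track.params.k)
        pooled.append(smoothed_nt[model.cds_start : model.cds_end])
    if not pooled or sum(len(p) for p in pooled) == 0:
        raise ValueError("no CDS positions in the supplied transcript set")
    return float(np.percentile(np.concatenate(pooled), percentile))


def call_regions(
    tracks: dict[str, GermTrack],
    models: dict[str, TranscriptModel],
    percentile: float = 98.0,
    merge_overlap: int = 41,
    threshold: float | None = None,
    utr_fraction: float = 1 / 3,
) -> list[GermRegion]:
    """Call GeRM regions on smoothed tracks sharing normalization stats.

    ``threshold`` overrides the pooled-percentile rule when given (e.g. to
    reuse a threshold fitted on another transcript set).
    """
    if threshold is None:
        threshold = pooled_cds_threshold(tracks, models, percentile)
    regions: list[GermRegion] = []
    for tid in sorted(tracks):
        track, model = tracks[tid], models[tid]
        params: GermParams = track.params
        ext = (params.smooth_width - 1) // 2
        smoothed_nt = per_nucleotide_view(track.smoothed, model.length, params.k)
        raw_nt = per_nucleotide_view(track.raw, model.length, params.k)
        above = smoothed_nt > threshold
        if not above.any():
            continue
        # contiguous super-threshold runs -> extended nt intervals
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        runs = edges.reshape(-1, 2)
        intervals = [
            (max(0, int(s) - ext), min(model.length, int(e) + ext)) for s, e in runs
        ]
        for s, e in _merge_intervals(intervals, merge_overlap):
            in_utr = max(0, model.cds_start - s) + max(0, e - model.cds_end)
            if in_utr / (e - s) >= utr_fraction:
                continue
            regions.append(
                GermRegion(
                    transcript_id=tid,
                    start=s,
                    end=e,
                    mean_smoothed=float(smoothed_nt[s:e].mean()),
                    total_raw=float(raw_nt[s:e].sum()),
                )
            )
    return regions


def kmer_contribution_fractions(
    region: GermRegion, raw: np.ndarray, sequence: str, k: int = 5
) -> dict[str, float]:
    """Fraction of the region's total raw multivalency carried by each k-mer.

    Sums raw scores over the occurrences of each distinct k-mer fully inside
    the region and divides by the region total. Also records the total on the
    region (``total_raw``) and stores the fractions on it.
    """
    seq = sequence.upper().replace("U", "T")
    lo, hi = region.start, region.end - k + 1
    lo = max(lo, 0)
    hi = min(hi, len(raw))
    sums: dict[str, float] = {}
    total = 0.0
    for p in range(lo, hi):
        score = float(raw[p])
        if score == 0.0:
            continue
        kmer = seq[p : p + k]
        sums[kmer] = sums.get(kmer, 0.0) + score
        total += score
    if total <= 0:
        raise ValueError(f"region {region.region_id} has zero total raw score")
    fractions = {m: s / total for m, s in sums.items()}
    region.kmer_fractions = fractions
    region.total_raw = total
    return fractions
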