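"""Synonymous-codon statistics: shuffle nulls, per-position GeRM codon
ratios, conservation normalization, and multivalency-targeted CDS recoding.

All operations preserve the encoded protein exactly. A trailing stop codon in
a CDS, if present, is held fixed; internal stop codons are a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GermParams, score_transcript
from .io import ConservationTrack, TranscriptModel
from .sequence import (
    BASES,
    CODON_TABLE,
    STOP_CODONS,
    canonicalize,
    gc_content,
    split_codons,
)

logger = logging.getLogger(__name__)


@dataclass
class ShuffleConfig:
    """Scope and depth of the synonymous-codon shuffle null.

    Per-position mean tracks use 10 shuffles by default; region-level
    analyses use 5.
    """

    scope: str = "within_transcript"  # or "transcriptome_wide"
    n_shuffles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scope not in ("within_transcript", "transcriptome_wide"):
            raise ValueError(f"unknown shuffle scope {self.scope!r}")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


def _codons_checked(cds: str) -> list[str]:
    codons = split_codons(cds)
    body = codons[:-1] if codons and codons[-1] in STOP_CODONS else codons
    for c in body:
        if c in STOP_CODONS:
            raise ValueError("internal stop codon in CDS")
    return codons


def shuffle_codons(
    cds_set: dict[str, str], config: ShuffleConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Permute synonymous codons, preserving every protein sequence.

    within_transcript: each transcript's per-amino-acid codon multiset is
    preserved and its order permuted. transcriptome_wide: codon multisets are
    pooled per amino acid across the whole set and dealt back in transcript
    order. A trailing stop codon stays in place.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parsed = {tid: _codons_checked(canonicalize(c)) for tid, c in cds_set.items()}
    if config.scope == "within_transcript":
        out = {}
        for tid, codons in parsed.items():
            shuffled = list(codons)
            by_aa: dict[str, list[int]] = {}
            for idx, codon in enumerate(codons):
                if codon in STOP_CODONS:
                    continue
                by_aa.setdefault(CODON_TABLE[codon], []).append(idx)
            for positions in by_aa.values():
                pool = [codons[i] for i in positions]
                rng.shuffle(pool)
                for i, codon in zip(positions, pool):
                    shuffled[i] = codon
            out[tid] = "".join(shuffled)
        return out
    # transcriptome_wide: pool codons per amino acid across all transcripts
    pools: dict[str, list[str]] = {}
    order = sorted(parsed)
    for tid in order:
        for codon in parsed[tid]:
            if codon not in STOP_CODONS:
                pools.setdefault(CODON_TABLE[codon], []).append(codon)
    for pool in pools.values():
        rng.shuffle(pool)
    cursors = {aa: 0 for aa in pools}
    out = {}
    for tid in order:
        shuffled = []
        for codon in parsed[tid]:
            if codon in STOP_CODONS:
                shuffled.append(codon)
            else:
                aa = CODON_TABLE[codon]
                shuffled.append(pools[aa][cursors[aa]])
                cursors[aa] += 1
        out[tid] = "".join(shuffled)
    return out


def mean_shuffled_germ(
    cds_set: dict[str, str],
    config: ShuffleConfig,
    params: GermParams = GermParams(),
) -> dict[str, np.ndarray]:
    """Element-wise mean raw GeRM track over ``n_shuffles`` shuffles."""
    rng = np.random.default_rng(config.seed)
    sums: dict[str, np.ndarray] = {}
    for _ in range(config.n_shuffles):
        shuffled = shuffle_codons(cds_set, config, rng=rng)
        for tid, seq in shuffled.items():
            track = score_transcript(seq, params)
            if tid in sums:
                sums[tid] += track
            else:
                sums[tid] = track
    return {tid: s / config.n_shuffles for tid, s in sums.items()}


# --- mutable positions and GeRM codon ratios --------------------------------


def _synonymous_single_substitutions(codon: str) -> dict[int, list[str]]:
    """offset -> alternative bases that keep the encoded amino acid."""
    aa = CODON_TABLE.get(codon)
    if aa is None:
        return {}
    alts: dict[int, list[str]] = {}
    for offset in range(3):
        for base in BASES:
            if base == codon[offset]:
                continue
            variant = codon[:offset] + base + codon[offset + 1 :]
            if CODON_TABLE.get(variant) == aa:
                alts.setdefault(offset, []).append(base)
    return alts


def enumerate_mutable_positions(cds: str) -> list[tuple[int, int, list[str]]]:
    """All (codon_index, offset, alternative bases) admitting a synonymous
    single-nucleotide substitution under the standard genetic code.

    These are third positions of degenerate codons plus the first positions of
    the leucine (CTA/CTG <-> TTA/TTG) and arginine (CGA/CGG <-> AGA/AGG)
    codons. Stop codons and codons with non-ACGT bases are skipped.
    """
    out = []
    for idx, codon in enumerate(split_codons(cds)):
        if any(b not in BASES for b in codon):
            logger.warning("codon %d (%s) has non-ACGT base; skipped", idx, codon)
            continue
        for offset, alternatives in sorted(_synonymous_single_substitutions(codon).items()):
            out.append((idx, offset, alternatives))
    return out


@dataclass
class CodonRatioRecord:
    """Native-vs-synonymous local GeRM comparison at one mutable position."""

    transcript_id: str
    codon_index: int
    mutable_offset: int
    native_codon: str
    native_max_germ: float
    mutant_mean_max_germ: float

    @property
    def ratio(self) -> float:
        if self.mutant_mean_max_germ == 0.0:
            # degenerate context (no scoreable k-mers): identical for native
            # and variants, hence ratio 1; a native score with zero variant
            # score is unbounded support
            return 1.0 if self.native_max_germ == 0.0 else float("inf")
        return self.native_max_germ / self.mutant_mean_max_germ


def _local_max_germ(sequence: str, position: int, params: GermParams) -> float:
    """Max raw GeRM over the <=k k-mers overlapping ``position``.

    Scores only the window of the transcript that can influence those k-mers
    (the score of an interior k-mer depends on at most w + k - 1 nt on each
    side), clipped at transcript edges so the native edge rule applies.
    """
    k, w = params.k, params.w
    L = len(sequence)
    lo = max(0, position - k + 1 - w)
    hi = min(L, position + w + k)
    local = score_transcript(sequence[lo:hi], params)
    q = position - lo
    starts = np.arange(max(0, q - k + 1), min(len(local), q + 1))
    if len(starts) == 0:
        return 0.0
    return float(local[starts].max())


def germ_codon_ratio(
    sequence: str,
    cds_start: int,
    codon_index: int,
    offset: int,
    params: GermParams = GermParams(),
    transcript_id: str = "",
) -> CodonRatioRecord:
    """Ratio of native to mean-synonymous local maximum GeRM at one position.

    ``sequence`` is the full transcript; the CDS begins at ``cds_start``.
    Raw (unsmoothed, unnormalized) scores are used. Ratio > 1 means the native
    base supports local multivalency more than its synonymous alternatives on
    average.
    """
    seq = canonicalize(sequence)
    codon_pos = cds_start + 3 * codon_index
    codon = seq[codon_pos : codon_pos + 3]
    alts = _synonymous_single_substitutions(codon).get(offset)
    if not alts:
        raise ValueError(
            f"position {codon_index}:{offset} ({codon}) admits no synonymous substitution"
        )
    q = codon_pos + offset
    native_max = _local_max_germ(seq, q, params)
    variant_maxima = []
    for base in alts:
        mutated = seq[:q] + base + seq[q + 1 :]
        variant_maxima.append(_local_max_germ(mutated, q, params))
    return CodonRatioRecord(
        transcript_id=transcript_id,
        codon_index=codon_index,
        mutable_offset=offset,
        native_codon=codon,
        native_max_germ=native_max,
        mutant_mean_max_germ=float(np.mean(variant_maxima)),
    )


def codon_ratio_records(
    model: TranscriptModel, params: GermParams = GermParams()
) -> pd.DataFrame:
    """GeRM codon ratios at every mutable position of one transcript."""
    rows = []
    for codon_index, offset, _ in enumerate_mutable_positions(model.cds_sequence):
        rec = germ_codon_ratio(
            model.spliced_sequence,
            model.cds_start,
            codon_index,
            offset,
            params,
            transcript_id=model.transcript_id,
        )
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "codon_index": rec.codon_index,
                "mutable_offset": rec.mutable_offset,
                "native_codon": rec.native_codon,
                "native_max_germ": rec.native_max_germ,
                "mutant_mean_max_germ": rec.mutant_mean_max_germ,
                "ratio": rec.ratio,
            }
        )
    return pd.DataFrame(rows)


# --- conservation normalization --------------------------------------------


def normalize_conservation(
    records: pd.DataFrame,
    conservation: dict[str, ConservationTrack],
    models: dict[str, TranscriptModel],
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize conservation at mutable positions and bin by codon ratio.

    The mutable-position conservation is centred by the median over all
    instances of the same (codon, offset) type, and the same codon instance's
    middle-position conservation (likewise centred per type) is subtracted, so
    a constant track normalizes to exactly zero. Records lacking conservation
    at either position are dropped (count reported in the log).

    Binning by ratio is performed separately within each codon type and then
    pooled, so every bin holds an equal proportion of each codon. Returns
    (records with ``norm_conservation`` and ``bin``, per-bin summary).
    """
    df = records.copy()
    cons_mut = np.full(len(df), np.nan)
    cons_mid = np.full(len(df), np.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        model = models[row.transcript_id]
        track = conservation[row.transcript_id].values
        q = model.cds_start + 3 * row.codon_index + row.mutable_offset
        mid = model.cds_start + 3 * row.codon_index + 1
        cons_mut[i] = track[q]
        cons_mid[i] = track[mid]
    df["cons_mutable"] = cons_mut
    df["cons_middle"] = cons_mid
    n_before = len(df)
    df = df.dropna(subset=["cons_mutable", "cons_middle"]).reset_index(drop=True)
    if len(df) < n_before:
        logger.info("dropped %d records with missing conservation", n_before - len(df))

    group = df.groupby(["native_codon", "mutable_offset"])
    df["norm_conservation"] = (
        df["cons_mutable"]
        - group["cons_mutable"].transform("median")
        - (df["cons_middle"] - group["cons_middle"].transform("median"))
    )
    # equal-count ratio bins within each codon type, then pooled
    def _bin(sub: pd.Series) -> pd.Series:
        ranks = sub.rank(method="first")
        return np.ceil(ranks / len(sub) * n_bins).astype(int).clip(1, n_bins)

    df["bin"] = group["ratio"].transform(_bin)
    summary = (
        df.groupby("bin")["norm_conservation"]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    return df, summary


# --- CDS recoding -----------------------------------------------------------


def count_ag_only_kmers(seq: str, k: int = 5) -> int:
    """Number of k-length windows composed only of A and G."""
    is_ag = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_ag = (is_ag == ord("A")) | (is_ag == ord("G"))
    if len(seq) < k:
        return 0
    csum = np.concatenate(([0], np.cumsum(is_ag)))
    return int(np.sum((csum[k:] - csum[:-k]) == k))


def _objective(seq: str, objective: str) -> int:
    count = count_ag_only_kmers(seq)
    return -count if objective == "maximize" else count


def recode_cds(
    cds: str,
    objective: str = "minimize",
    gc_tolerance: float = 0.02,
    protected_spans: list[tuple[int, int]] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    max_pair_codons: int = 80,
) -> str:
    """Synonymously recode a CDS to extremize its count of A/G-only 5-mers.

    The protein sequence is always preserved and the GC content stays within
    ``gc_tolerance`` (absolute fraction) of the input. Optimization is greedy
    coordinate descent over codons under a random restart order; when single-
    codon moves stall and the CDS is short enough, GC-compensating pairs of
    codon moves are also tried, so small inputs reach the exhaustive optimum.
    """
    if objective not in ("minimize", "maximize"):
        raise ValueError("objective must be 'minimize' or 'maximize'")
    cds = canonicalize(cds)
    codons = _codons_checked(cds)
    protected = set()
    for s, e in protected_spans or []:
        for idx in range(len(codons)):
            if min(3 * idx + 3, e) - max(3 * idx, s) > 0:
                protected.add(idx)
    choices = []
    for idx, codon in enumerate(codons):
        if idx in protected or codon in STOP_CODONS:
            choices.append([codon])
        else:
            from .sequence import SYNONYMOUS

            choices.append(sorted(SYNONYMOUS[CODON_TABLE[codon]]))
    gc0 = gc_content(cds)
    rng = np.random.default_rng(seed)

    def feasible(seq: str) -> bool:
        return abs(gc_content(seq) - gc0) <= gc_tolerance + 1e-12

    def descend(current: list[str]) -> list[str]:
        improved = True
        while improved:
            improved = False
            order = rng.permutation(len(current))
            for idx in order:
                if len(choices[idx]) == 1:
                    continue
                best = current[idx]
                best_val = _objective("".join(current), objective)
                for alt in choices[idx]:
                    if alt == current[idx]:
                        continue
                    trial = current.copy()
                    trial[idx] = alt
                    seq = "".join(trial)
                    if feasible(seq) and _objective(seq, objective) < best_val:
                        best, best_val = alt, _objective(seq, objective)
                if best != current[idx]:
                    current[idx] = best
                    improved = True
            if not improved and len(current) <= max_pair_codons:
                # GC-compensating pair moves to escape single-move dead ends
                mutable = [i for i in range(len(current)) if len(choices[i]) > 1]
                base_val = _objective("".join(current), objective)
                for a in mutable:
                    for b in mutable:
                        if b <= a:
                            continue
                        for ca in choices[a]:
                            for cb in choices[b]:
                                if ca == current[a] and cb == current[b]:
                                    continue
                                trial = current.copy()
                                trial[a], trial[b] = ca, cb
                                seq = "".join(trial)
                                if feasible(seq) and _objective(seq, objective) < base_val:
                                    current[a], current[b] = ca, cb
                                    base_val = _objective(seq, objective)
                                    improved = True
        return current

    best_codons = list(codons)
    best_val = _objective(cds, objective)
    for _ in range(max(1, n_restarts)):
        result = descend(list(codons))
        val = _objective("".join(result), objective)
        if val < best_val:
            best_codons, best_val = result, val
    out = "".join(best_codons)
    from .sequence import translate

    assert translate(out) == translate(cds), "recoding changed the protein"
    assert abs(gc_content(out) - gc0) <= gc_tolerance + 1e-12
    return out
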