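"""RBP binding-potential scores and CLIP crosslink multivalency statistics.

Binding potential converts per-5-mer in vitro enrichment (RBNS R scores) to
z scores, keeps motifs with an upper-tail P < 0.05, and sums count x z over a
rolling 5-nt window of a sequence.

The CLIP multivalency-preference statistic asks whether a protein crosslinks
its favoured motifs preferentially when those motifs sit in multivalent
contexts: every CDS 5-mer instance gets the percentile of its raw GeRM score
within the transcriptome-wide distribution of that same 5-mer, each crosslink
maps to the (<= 5) 5-mer instances covering it, and the mean percentile of
the 50 most crosslinked 5-mers is divided by the mean over all other
crosslinked 5-mers. Samples with a ratio >= 1.1 are called
multivalency-preferring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CrosslinkTrack, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class MotifTable:
    """Per-5-mer RBNS enrichment with z scores and the significant set."""

    rbp_id: str
    table: pd.DataFrame  # columns: kmer, r_score, z, p, significant

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def motif_zscores(rbp_id: str, r_scores: pd.Series | dict[str, float]) -> MotifTable:
    """z = (R - mean) / sd over the table; one-sided upper-tail normal P.

    The significant set is {P < 0.05}, boundary excluded. Zero variance in
    the R scores is a hard error.
    """
    s = pd.Series(r_scores, dtype=float)
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError("R scores have zero variance")
    z = (s - s.mean()) / sd
    p = sps.norm.sf(z)
    df = pd.DataFrame(
        {"kmer": s.index, "r_score": s.to_numpy(), "z": z.to_numpy(), "p": p}
    ).reset_index(drop=True)
    df["significant"] = df["p"] < 0.05
    return MotifTable(rbp_id, df)


def binding_potential(sequence: str, motifs: MotifTable, k: int = 5) -> float:
    """Sum over significant 5-mers of (rolling-window count) x z."""
    seq = sequence.upper().replace("U", "T")
    if len(seq) < k:
        return 0.0
    counts: dict[str, int] = {}
    for p in range(len(seq) - k + 1):
        m = seq[p : p + k]
        counts[m] = counts.get(m, 0) + 1
    sig = motifs.significant
    return float(sum(counts.get(m, 0) * z for m, z in zip(sig["kmer"], sig["z"])))


# --- CLIP multivalency preference -------------------------------------------


def kmer_percentile_tracks(
    models: dict[str, TranscriptModel], raw_tracks: dict[str, np.ndarray], k: int = 5
) -> dict[str, np.ndarray]:
    """Percentile of each CDS 5-mer instance's raw GeRM score within the
    distribution of that same 5-mer transcriptome-wide.

    Returns per-transcript arrays aligned to k-mer starts (NaN outside the
    CDS). A 5-mer with a single instance gets percentile 50 (uninformative
    prior for a degenerate distribution).
    """
    instances: dict[str, list[tuple[str, int, float]]] = {}
    for tid in sorted(models):
        model, raw = models[tid], raw_tracks[tid]
        seq = model.spliced_sequence
        # a CDS k-mer instance starts in the CDS
        hi = min(model.cds_end, len(raw))
        for p in range(model.cds_start, hi):
            kmer = seq[p : p + k]
            if "N" not in kmer:
                instances.setdefault(kmer, []).append((tid, p, float(raw[p])))
    out = {
        tid: np.full(max(model.length - k + 1, 0), np.nan)
        for tid, model in models.items()
    }
    for kmer, inst in instances.items():
        scores = np.array([v for _, _, v in inst])
        ranks = sps.rankdata(scores, method="average")
        pct = 100.0 * (ranks - 0.5) / len(scores)
        for (tid, p, _), val in zip(inst, pct):
            out[tid][p] = val
    return out


@dataclass
class MultivalencyPreference:
    sample_id: str
    preference_ratio: float
    top_kmers: list[str]
    per_kmer: pd.DataFrame  # kmer, crosslink_weight, mean_percentile

    @property
    def passes(self) -> bool:
        return self.preference_ratio >= 1.1


def qc_filter_samples(
    tracks_by_sample: dict[str, list[CrosslinkTrack]],
    models: dict[str, TranscriptModel],
) -> list[str]:
    """CLIP sample QC: drop the bottom third by CDS-crosslink proportion,
    then the bottom third (of the remainder) by raw CDS crosslink count."""
    rows = []
    for sample, tracks in tracks_by_sample.items():
        total = sum(t.total for t in tracks)
        cds = sum(
            int(t.counts[models[t.transcript_id].cds_start : models[t.transcript_id].cds_end].sum())
            for t in tracks
        )
        if cds == 0:
            logger.info("sample %s has zero CDS crosslinks; excluded", sample)
            continue
        rows.append((sample, cds / total if total else 0.0, cds))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["sample", "cds_proportion", "cds_count"])
    df = df[df["cds_proportion"] > df["cds_proportion"].quantile(1 / 3, interpolation="lower")]
    df = df[df["cds_count"] > df["cds_count"].quantile(1 / 3, interpolation="lower")]
    return sorted(df["sample"])


def crosslink_multivalency_preference(
    tracks: list[CrosslinkTrack],
    models: dict[str, TranscriptModel],
    percentile_tracks: dict[str, np.ndarray],
    top_n: int = 50,
    k: int = 5,
    mapping: str = "overlapping",
) -> MultivalencyPreference:
    """Multivalency-preference ratio for one CLIP sample.

    ``mapping='overlapping'`` assigns each crosslinked nucleotide to all
    (<= 5) 5-mer instances covering it; ``'start'`` uses only the 5-mer
    starting at the crosslink. The top-``top_n`` motif set is the most
    crosslinked 5-mers (ties broken lexicographically).
    """
    if mapping not in ("overlapping", "start"):
        raise ValueError("mapping must be 'overlapping' or 'start'")
    weight: dict[str, float] = {}
    pct_sum: dict[str, float] = {}
    sample_id = tracks[0].sample_id if tracks else "sample"
    for track in tracks:
        model = models[track.transcript_id]
        pct = percentile_tracks[track.transcript_id]
        seq = model.spliced_sequence
        positions = np.nonzero(track.counts)[0]
        for x in positions:
            c = int(track.counts[x])
            if mapping == "start":
                starts = [x] if x < len(pct) else []
            else:
                starts = range(max(0, x - k + 1), min(len(pct), x + 1))
            for p in starts:
                if np.isnan(pct[p]):
                    continue
                m = seq[p : p + k]
                weight[m] = weight.get(m, 0.0) + c
                pct_sum[m] = pct_sum.get(m, 0.0) + c * pct[p]
    if not weight:
        raise ValueError(f"sample {sample_id} has no crosslinks on scored CDS positions")
    per = pd.DataFrame(
        {
            "kmer": list(weight),
            "crosslink_weight": [weight[m] for m in weight],
            "mean_percentile": [pct_sum[m] / weight[m] for m in weight],
        }
    ).sort_values(["crosslink_weight", "kmer"], ascending=[False, True], kind="mergesort")
    top = per.head(top_n)
    rest = per.iloc[len(top) :]
    if rest.empty:
        raise ValueError("fewer distinct crosslinked 5-mers than the top-N cutoff")
    ratio = float(top["mean_percentile"].mean() / rest["mean_percentile"].mean())
    return MultivalencyPreference(
        sample_id=sample_id,
        preference_ratio=ratio,
        top_kmers=list(top["kmer"]),
        per_kmer=per.reset_index(drop=True),
    )


# --- region-level crosslink statistics --------------------------------------


def filter_transcripts_by_density(
    tracks_by_sample: dict[str, list[CrosslinkTrack]],
    models: dict[str, TranscriptModel],
) -> list[str]:
    """Transcripts in the top half of CDS crosslinks per nucleotide, pooled
    across samples."""
    density: dict[str, float] = {}
    for tracks in tracks_by_sample.values():
        for t in tracks:
            model = models[t.transcript_id]
            cds = int(t.counts[model.cds_start : model.cds_end].sum())
            density[t.transcript_id] = density.get(t.transcript_id, 0.0) + cds / max(
                model.cds_length, 1
            )
    if not density:
        return []
    cutoff = float(np.median(list(density.values())))
    return sorted(tid for tid, d in density.items() if d >= cutoff)


def region_crosslink_enrichment(
    tracks: list[CrosslinkTrack],
    regions,
    models: dict[str, TranscriptModel],
    labels: np.ndarray | None = None,
    pseudocount: float = 0.5,
    transcripts: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region crosslink density ratio (inside region vs rest of CDS) and
    its per-cluster mean for one sample.

    ``pseudocount`` (crosslinks per nt floor on the denominator) keeps regions
    on transcripts whose remaining CDS has no crosslinks; set it to 0 to skip
    such regions instead.
    """
    by_tid = {t.transcript_id: t for t in tracks}
    keep = set(transcripts) if transcripts is not None else None
    rows = []
    for i, region in enumerate(regions):
        tid = region.transcript_id
        if keep is not None and tid not in keep:
            continue
        track = by_tid.get(tid)
        if track is None:
            continue
        model = models[tid]
        s = max(region.start, model.cds_start)
        e = min(region.end, model.cds_end)
        if e <= s:
            continue
        inside = int(track.counts[s:e].sum())
        cds_total = int(track.counts[model.cds_start : model.cds_end].sum())
        outside = cds_total - inside
        outside_len = model.cds_length - (e - s)
        if outside_len <= 0:
            continue
        inside_density = inside / (e - s)
        outside_density = outside / outside_len
        if outside_density == 0:
            if pseudocount <= 0:
                logger.info("region %s skipped: no crosslinks in rest of CDS", region.region_id)
                continue
            outside_density = pseudocount / outside_len
        rows.append(
            {
                "region_id": region.region_id,
                "transcript_id": tid,
                "cluster": str(labels[i]) if labels is not None else (region.cluster or "."),
                "sample_id": track.sample_id,
                "ratio": inside_density / outside_density,
            }
        )
    return pd.DataFrame(rows)


def enrichment_matrix(per_region: pd.DataFrame) -> pd.DataFrame:
    """sample x cluster mean density ratios (heatmap-ready)."""
    return per_region.pivot_table(
        index="sample_id", columns="cluster", values="ratio", aggfunc="mean"
    )


def region_metaprofile(
    tracks: list[CrosslinkTrack], regions, halfwidth: int = 500
) -> np.ndarray:
    """Crosslink counts around region midpoints, normalized by the number of
    regions and by millions of crosslinks in the sample.

    Returns an array over relative positions [-halfwidth, +halfwidth].
    """
    by_tid: dict[str, list[CrosslinkTrack]] = {}
    for t in tracks:
        by_tid.setdefault(t.transcript_id, []).append(t)
    total = sum(t.total for t in tracks)
    profile = np.zeros(2 * halfwidth + 1, dtype=float)
    n_regions = 0
    for region in regions:
        for track in by_tid.get(region.transcript_id, ()):
            mid = (region.start + region.end) // 2
            lo = max(0, mid - halfwidth)
            hi = min(len(track.counts), mid + halfwidth + 1)
            profile[lo - (mid - halfwidth) : hi - (mid - halfwidth)] += track.counts[lo:hi]
        n_regions += 1
    if n_regions == 0 or total == 0:
        return profile
    return profile / (n_regions * (total / 1e6))
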