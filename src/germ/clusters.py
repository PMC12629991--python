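"""Multivalency classes: clustering of GeRM regions by k-mer composition,
representative k-mers, and per-transcript class scores.

Regions are embedded with UMAP (4 dimensions, 50 neighbours, min_dist 0.001)
on their per-k-mer contribution fractions and clustered by density: OPTICS
reachability is extracted, a flat cut is made at the knee of the
proportion-below-threshold curve (the threshold where the first derivative
reaches 40% of its maximum, scanning down from the 99th percentile), and the
cut is applied DBSCAN-style. Noise points get label -1 and are excluded from
everything downstream. The number of clusters is an outcome, never a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import OPTICS, cluster_optics_dbscan
from sklearn.preprocessing import StandardScaler

from .core import GermTrack
from .io import TranscriptModel
from .regions import GermRegion
from .sequence import BASES, canonicalize

ALL_5MERS = ["".join(p) for p in product(BASES, repeat=5)]


@dataclass
class ClassModel:
    """Cluster labels with per-class representative k-mers."""

    labels: np.ndarray
    representative_kmers: dict[str, list[str]]
    embedding: np.ndarray | None = None
    eps: float = float("nan")


def regions_to_matrix(regions: list[GermRegion], k: int = 5) -> pd.DataFrame:
    """Region x k-mer fraction matrix (dense, 4^k columns)."""
    kmers = ALL_5MERS if k == 5 else ["".join(p) for p in product(BASES, repeat=k)]
    mat = np.zeros((len(regions), len(kmers)))
    index = {m: j for j, m in enumerate(kmers)}
    for i, r in enumerate(regions):
        for m, f in r.kmer_fractions.items():
            j = index.get(m)
            if j is not None:
                mat[i, j] = f
    return pd.DataFrame(mat, columns=kmers, index=[r.region_id for r in regions])


def knee_threshold(reachability: np.ndarray, fraction_of_max: float = 0.4) -> float:
    """Flat-cut threshold at the knee of the reachability profile.

    Scans thresholds from the 99th percentile of (finite) reachability down to
    0, tracks the proportion of points below each threshold, and returns the
    first threshold at which the first derivative of that curve reaches
    ``fraction_of_max`` of its maximum.
    """
    r = reachability[np.isfinite(reachability)]
    if r.size == 0:
        raise ValueError("no finite reachability values")
    hi = float(np.percentile(r, 99))
    ts = np.linspace(hi, 0.0, 512)
    prop = np.array([(r < t).mean() for t in ts])
    deriv = np.abs(np.gradient(prop, ts))
    target = fraction_of_max * deriv.max()
    for t, d in zip(ts, deriv):
        if d >= target:
            return float(t)
    return float(ts[-1])


def reachability_gap_threshold(reachability: np.ndarray) -> float:
    """Flat-cut threshold at the widest relative gap in reachability.

    Within-cluster and between-cluster reachability live on separate scales;
    the cut is placed at the largest gap in the sorted log-reachability above
    the median (geometric midpoint of the gap). Robust when between-cluster
    points are rare, where the knee of the proportion-below curve sits inside
    the within-cluster bulk and over-fragments.
    """
    r = np.sort(reachability[np.isfinite(reachability)])
    r = r[r > 0]
    if r.size < 4 or r[0] == r[-1]:
        raise ValueError("degenerate reachability profile")
    logs = np.log(r)
    half = r.size // 2
    gaps = np.diff(logs)[half:]
    i = half + int(np.argmax(gaps))
    return float(np.sqrt(r[i] * r[i + 1]))


def cluster_regions(
    fraction_matrix: pd.DataFrame,
    seed: int,
    n_components: int = 4,
    n_neighbors: int = 50,
    min_dist: float = 0.001,
    min_points_fraction: float = 0.01,
    eps_rule: str = "gap",
) -> tuple[np.ndarray, ClassModel]:
    """UMAP embedding + reachability clustering of GeRM regions.

    ``seed`` pins both the embedding and OPTICS ordering; noise is -1.
    ``eps_rule`` selects the flat-cut threshold: ``'gap'`` (default, the
    scale-separation cut of :func:`reachability_gap_threshold`) or ``'knee'``
    (the 40%-of-max-derivative knee of the proportion-below curve).
    Refuses inputs too small for the 1% minimum-points rule to be meaningful.
    """
    import umap  # deferred: slow import

    X = fraction_matrix.to_numpy()
    n = X.shape[0]
    if n < 200:
        raise ValueError(
            "need >= 200 regions for density clustering with the 1% min-points rule"
        )
    min_points = max(5, int(round(min_points_fraction * n)))
    reducer = umap.UMAP(
        n_components=n_components,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    embedding = reducer.fit_transform(X)
    optics = OPTICS(min_samples=min_points)
    optics.fit(embedding)
    if eps_rule == "knee":
        eps = knee_threshold(optics.reachability_)
    elif eps_rule == "gap":
        eps = reachability_gap_threshold(optics.reachability_)
    else:
        raise ValueError("eps_rule must be 'gap' or 'knee'")
    labels = cluster_optics_dbscan(
        reachability=optics.reachability_,
        core_distances=optics.core_distances_,
        ordering=optics.ordering_,
        eps=eps,
    )
    model = ClassModel(labels=labels, representative_kmers={}, embedding=embedding, eps=eps)
    return labels, model


def representative_kmers(
    regions: list[GermRegion],
    labels: np.ndarray,
    coverage: float = 0.5,
    deduplicate: bool = False,
) -> dict[str, list[str]]:
    """Minimal descending-sorted k-mer prefix covering >= 50% of each
    cluster's multivalency.

    K-mer mass is pooled over a cluster's regions as fraction x region total
    raw score; ties in the sort are broken lexicographically. With
    ``deduplicate`` a k-mer selected for several clusters is kept only in the
    cluster where its contribution proportion is highest (feature-table mode).
    """
    mass: dict[str, dict[str, float]] = {}
    for region, label in zip(regions, labels):
        if label == -1:
            continue
        key = str(label)
        bucket = mass.setdefault(key, {})
        weight = region.total_raw if region.total_raw > 0 else 1.0
        for m, f in region.kmer_fractions.items():
            bucket[m] = bucket.get(m, 0.0) + f * weight
    reps: dict[str, list[str]] = {}
    proportions: dict[str, dict[str, float]] = {}
    for key, bucket in mass.items():
        total = sum(bucket.values())
        props = {m: v / total for m, v in bucket.items()}
        proportions[key] = props
        ordered = sorted(props.items(), key=lambda kv: (-kv[1], kv[0]))
        cum, chosen = 0.0, []
        for m, p in ordered:
            chosen.append(m)
            cum += p
            if cum >= coverage:
                break
        reps[key] = chosen
    if deduplicate:
        owner: dict[str, str] = {}
        for key, kmers in reps.items():
            for m in kmers:
                if m not in owner or proportions[key][m] > proportions[owner[m]][m]:
                    owner[m] = key
        reps = {key: [m for m in kmers if owner[m] == key] for key, kmers in reps.items()}
    return reps


def fit_kmer_zscores(
    models: dict[str, TranscriptModel], raw_tracks: dict[str, np.ndarray], k: int = 5
) -> pd.DataFrame:
    """Per-5-mer mean/sd of raw GeRM scores over all CDS instances."""
    values: dict[str, list[float]] = {}
    for tid, model in models.items():
        raw = raw_tracks[tid]
        seq = model.spliced_sequence
        # a CDS k-mer is one whose start lies in the CDS
        hi = min(model.cds_end, len(raw))
        for p in range(model.cds_start, hi):
            kmer = seq[p : p + k]
            if "N" in kmer:
                continue
            values.setdefault(kmer, []).append(float(raw[p]))
    rows = [
        {"kmer": m, "mean": float(np.mean(v)), "sd": float(np.std(v)), "n": len(v)}
        for m, v in values.items()
    ]
    return pd.DataFrame(rows).set_index("kmer")


def transcript_class_scores(
    models: dict[str, TranscriptModel],
    raw_tracks: dict[str, np.ndarray],
    representative: dict[str, list[str]],
    zstats: pd.DataFrame | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Per-transcript, per-class sums of z-scaled GeRM scores.

    Each CDS occurrence of a class's representative 5-mer contributes
    (raw - mean_kmer) / sd_kmer, with the statistics fitted on the supplied
    transcript set; zero-variance 5-mers contribute 0. Transcripts with many
    instances of a class's 5-mers specifically in multivalent (high-scoring)
    contexts are rewarded.
    """
    if zstats is None:
        zstats = fit_kmer_zscores(models, raw_tracks, k)
    mean = zstats["mean"].to_dict()
    sd = zstats["sd"].to_dict()
    kmer_to_classes: dict[str, list[str]] = {}
    for cls, kmers in representative.items():
        for m in kmers:
            kmer_to_classes.setdefault(m, []).append(cls)
    rows = []
    for tid in sorted(models):
        model, raw = models[tid], raw_tracks[tid]
        scores = {cls: 0.0 for cls in representative}
        seq = model.spliced_sequence
        hi = min(model.cds_end, len(raw))
        for p in range(model.cds_start, hi):
            kmer = seq[p : p + k]
            classes = kmer_to_classes.get(kmer)
            if not classes:
                continue
            s = sd.get(kmer, 0.0)
            z = (float(raw[p]) - mean.get(kmer, 0.0)) / s if s > 0 else 0.0
            for cls in classes:
                scores[cls] += z
        rows.append({"transcript_id": tid, **scores})
    return pd.DataFrame(rows).set_index("transcript_id")


def retention_feature_table(
    models: dict[str, TranscriptModel],
    raw_tracks: dict[str, np.ndarray],
    representative: dict[str, list[str]],
    merge_map: dict[str, str] | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Feature matrix for retention classifiers.

    Columns: CDS length (nt), mean exon length (nt), and per-class
    length-normalized multivalency sums, standard-scaled column-wise on the
    supplied set. ``merge_map`` folds correlated classes (e.g. the GC-like
    clusters) into one before scoring; representative k-mer lists are
    deduplicated across the merged classes first.
    """
    if merge_map:
        merged: dict[str, list[str]] = {}
        for cls, kmers in representative.items():
            merged.setdefault(merge_map.get(cls, cls), []).extend(kmers)
        representative = {cls: sorted(set(km)) for cls, km in merged.items()}
    classes = sorted(representative)
    rows = []
    for tid in sorted(models):
        model = models[tid]
        if not model.exon_lengths:
            continue
        raw = raw_tracks[tid]
        seq = model.spliced_sequence
        sums = {cls: 0.0 for cls in classes}
        kmer_to_classes: dict[str, list[str]] = {}
        for cls in classes:
            for m in representative[cls]:
                kmer_to_classes.setdefault(m, []).append(cls)
        hi = min(model.cds_end, len(raw))
        for p in range(model.cds_start, hi):
            for cls in kmer_to_classes.get(seq[p : p + k], ()):
                sums[cls] += float(raw[p])
        row = {
            "transcript_id": tid,
            "cds_length": model.cds_length,
            "mean_exon_length": float(np.mean(model.exon_lengths)),
        }
        for cls in classes:
            row[f"multivalency_{cls}"] = sums[cls] / model.cds_length
        rows.append(row)
    df = pd.DataFrame(rows).set_index("transcript_id")
    mv_cols = [c for c in df.columns if c.startswith("multivalency_")]
    df[mv_cols] = StandardScaler().fit_transform(df[mv_cols])
    return df
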