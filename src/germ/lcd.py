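"""Low-complexity domain (LCD) detection and arginine codon-usage analysis.

Complexity is Shannon entropy (bits) of amino-acid frequencies in a sliding
window; LCDs are windows in the bottom tail of the pooled entropy
distribution, expanded to their full window span and merged when overlapping.
R-LCDs are LCDs with >= 20% arginine; R-MCDs additionally require positive
net charge and > 40% charged residues (D, E, K, R — histidine excluded by
the usual mixed-charge-domain convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .sequence import ARG_CODONS, split_codons

CHARGED = set("DEKR")
POSITIVE = set("KR")
NEGATIVE = set("DE")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class LcdRegion:
    """A low-entropy protein interval (0-based half-open aa coordinates)."""

    protein_id: str
    start: int
    end: int
    min_entropy: float = float("nan")
    arg_fraction: float = float("nan")
    charged_fraction: float = float("nan")
    net_charge: int = 0
    is_r_lcd: bool = False
    is_r_mcd: bool = False

    @property
    def lcd_id(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def window_entropy(protein: str, window: int = 41) -> np.ndarray:
    """Shannon entropy (bits) of aa frequencies per window start.

    Proteins shorter than the window yield an empty array. Residues outside
    the 20 canonical amino acids are counted as a single extra symbol.
    """
    L = len(protein)
    if L < window:
        return np.zeros(0, dtype=float)
    codes = np.array([_AA_INDEX.get(aa, 20) for aa in protein.upper()])
    onehot = np.zeros((L, 21), dtype=np.int32)
    onehot[np.arange(L), codes] = 1
    csum = np.concatenate([np.zeros((1, 21), dtype=np.int64), np.cumsum(onehot, axis=0)])
    counts = csum[window:] - csum[:-window]
    freqs = counts / window
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return -terms.sum(axis=1)


def call_lcds(
    entropy_tracks: dict[str, np.ndarray],
    percentile: float = 2.0,
    window: int = 41,
    threshold: float | None = None,
) -> list[LcdRegion]:
    """LCDs from pooled window entropies.

    The threshold is the stated percentile of all pooled entropies (or an
    explicit override, e.g. to reuse one proteome's threshold on another);
    every sub-threshold window contributes its full span and overlapping
    spans are merged.
    """
    if threshold is None:
        pooled = np.concatenate([v for v in entropy_tracks.values() if len(v)])
        if pooled.size == 0 or pooled.min() == pooled.max():
            raise ValueError("degenerate pooled entropy distribution")
        threshold = float(np.percentile(pooled, percentile))
    out: list[LcdRegion] = []
    for pid in sorted(entropy_tracks):
        ent = entropy_tracks[pid]
        hits = np.flatnonzero(ent <= threshold)
        if hits.size == 0:
            continue
        spans: list[list[int]] = []
        for s in hits:
            if spans and s < spans[-1][1]:
                spans[-1][1] = s + window
            else:
                spans.append([int(s), int(s) + window])
        for s, e in spans:
            out.append(
                LcdRegion(pid, s, e, min_entropy=float(ent[s : e - window + 1].min()))
            )
    return out


def classify_lcd(lcd: LcdRegion, protein: str) -> LcdRegion:
    """Fill composition fields and the R-LCD / R-MCD flags in place."""
    segment = protein[lcd.start : lcd.end].upper()
    n = len(segment)
    n_r = segment.count("R")
    n_charged = sum(segment.count(aa) for aa in CHARGED)
    net = sum(segment.count(aa) for aa in POSITIVE) - sum(
        segment.count(aa) for aa in NEGATIVE
    )
    lcd.arg_fraction = n_r / n
    lcd.charged_fraction = n_charged / n
    lcd.net_charge = net
    lcd.is_r_lcd = lcd.arg_fraction >= 0.20
    lcd.is_r_mcd = lcd.is_r_lcd and net > 0 and lcd.charged_fraction > 0.40
    return lcd


def arginine_codon_proportions(lcd: LcdRegion, cds: str) -> np.ndarray:
    """Proportions of the six arginine codons used inside an LCD.

    The LCD's aa interval maps to CDS nucleotides [3*start, 3*end).
    """
    codons = split_codons(cds)[lcd.start : lcd.end]
    counts = np.array([codons.count(c) for c in ARG_CODONS], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"LCD {lcd.lcd_id} contains no arginine codons")
    return counts / total


@dataclass
class ArgCodonUsage:
    lcd_id: str
    proportions: np.ndarray
    pc1: float = float("nan")
    arg_class: str = "unassigned"  # GA_rich | CG_rich | unassigned


def arginine_codon_analysis(
    lcds: list[LcdRegion], cds_by_protein: dict[str, str]
) -> tuple[list[ArgCodonUsage], pd.DataFrame]:
    """Codon-usage vectors, 6x6 Spearman matrix, and PC1 class split.

    PC1 orientation is fixed so that AGA loads positively; the top third of
    LCDs by PC1 is labelled GA_rich and the bottom third CG_rich.
    """
    if len(lcds) < 3:
        raise ValueError("need at least 3 R-LCDs for correlation/PCA")
    usages = [
        ArgCodonUsage(l.lcd_id, arginine_codon_proportions(l, cds_by_protein[l.protein_id]))
        for l in lcds
    ]
    mat = pd.DataFrame(
        [u.proportions for u in usages], columns=list(ARG_CODONS), index=[u.lcd_id for u in usages]
    )
    spearman = mat.corr(method="spearman")
    pca = PCA(n_components=min(6, len(usages)))
    scores = pca.fit_transform(mat.to_numpy())
    loading = pca.components_[0]
    if loading[ARG_CODONS.index("AGA")] < 0:
        loading = -loading
        scores = -scores
    pc1 = scores[:, 0]
    for u, v in zip(usages, pc1):
        u.pc1 = float(v)
    lo, hi = np.percentile(pc1, [100 / 3, 200 / 3])
    for u in usages:
        if u.pc1 >= hi:
            u.arg_class = "GA_rich"
        elif u.pc1 <= lo:
            u.arg_class = "CG_rich"
    return usages, spearman


def proteome_lcds(
    proteins: dict[str, str],
    window: int = 41,
    percentile: float = 2.0,
    cds_by_protein: dict[str, str] | None = None,
    threshold: float | None = None,
) -> list[LcdRegion]:
    """Entropy tracks -> called, classified LCDs for a whole proteome."""
    tracks = {pid: window_entropy(seq, window) for pid, seq in proteins.items()}
    tracks = {pid: t for pid, t in tracks.items() if len(t)}
    lcds = call_lcds(tracks, percentile=percentile, window=window, threshold=threshold)
    for lcd in lcds:
        classify_lcd(lcd, proteins[lcd.protein_id])
    return lcds
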