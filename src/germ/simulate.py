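"""Synthetic transcriptomes with planted ground truth.

The simulator emulates the statistical structure the toolkit is built to
detect: multi-exon spliced transcripts whose CDSs are codon-frequency-matched
random sequence, a subset carrying planted multivalent repeats that encode
class-appropriate low-complexity domains (GA-rich charged R-MCDs, CAG-repeat
poly-Q, GC-rich R/A/P/G, C-rich P/S), matched conservation tracks elevated at
codon positions whose native choice supports multivalency, and crosslink
tracks for multivalency-preferring and indifferent RNA-binding proteins.
Everything is deterministic under the config seed, and the emitted FASTA/GTF
round-trips through the loaders.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_usage import AA_FREQUENCIES, CODON_FRACTIONS
from .io import ConservationTrack, CrosslinkTrack, TranscriptModel
from .sequence import reverse_complement

#: per-class amino-acid pools (aa -> weight) and class-consistent codons.
#: GA plants charged R-MCD-style domains with AGA/AGG arginine bias; GC
#: plants R/A/P/G with CGG/CGC bias; CAG plants poly-Q; C plants P/S-rich.
CLASS_RECIPES: dict[str, dict] = {
    "GA": {
        "aa_weights": {"R": 0.30, "K": 0.25, "E": 0.25, "G": 0.10, "D": 0.05, "S": 0.05},
        "biased_codons": {
            "R": ("AGA", "AGG"),
            "K": ("AAG", "AAA"),
            "E": ("GAA", "GAG"),
            "G": ("GGA", "GGG"),
            "D": ("GAT",),
            "S": ("AGT",),
        },
    },
    "CAG": {
        "aa_weights": {"Q": 0.9, "H": 0.05, "L": 0.05},
        "biased_codons": {"Q": ("CAG",), "H": ("CAC",), "L": ("CTG",)},
    },
    "GC": {
        "aa_weights": {"R": 0.30, "A": 0.30, "P": 0.20, "G": 0.20},
        "biased_codons": {
            "R": ("CGG", "CGC"),
            "A": ("GCC", "GCG"),
            "P": ("CCG", "CCC"),
            "G": ("GGC", "GGG"),
        },
    },
    "C": {
        "aa_weights": {"P": 0.55, "S": 0.20, "T": 0.15, "H": 0.10},
        "biased_codons": {
            "P": ("CCC", "CCT"),
            "S": ("TCC",),
            "T": ("ACC",),
            "H": ("CAC",),
        },
    },
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic transcriptome."""

    n_genes: int = 200
    planted_fraction: float = 0.1
    planted_classes: tuple[str, ...] = ("GA", "CAG", "GC", "C")
    region_length_range: tuple[int, int] = (250, 400)  # nt, rounded to codons
    codon_bias_strength: float = 0.9
    cds_codons_range: tuple[int, int] = (350, 650)
    n_exons_range: tuple[int, int] = (3, 12)
    exon_length_sigma: float = 0.4
    utr5_range: tuple[int, int] = (50, 200)
    utr3_range: tuple[int, int] = (100, 300)
    intron_range: tuple[int, int] = (80, 400)
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if not 0 <= self.codon_bias_strength <= 1:
            raise ValueError("codon_bias_strength must lie in [0, 1]")
        lo, hi = self.region_length_range
        if lo // 3 < 2:
            raise ValueError("planted regions must span at least two codons")
        if self.cds_codons_range[0] * 3 <= hi:
            raise ValueError("CDS length range cannot accommodate planted regions")


_AA = sorted(AA_FREQUENCIES)
_AA_P = np.array([AA_FREQUENCIES[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()


def _random_codon(aa: str, rng: np.random.Generator) -> str:
    codons = sorted(CODON_FRACTIONS[aa])
    probs = np.array([CODON_FRACTIONS[aa][c] for c in codons])
    return codons[rng.choice(len(codons), p=probs / probs.sum())]


def _background_codons(n: int, rng: np.random.Generator) -> list[str]:
    aas = rng.choice(len(_AA), size=n, p=_AA_P)
    return [_random_codon(_AA[i], rng) for i in aas]


def _planted_codons(cls: str, n: int, bias: float, rng: np.random.Generator) -> list[str]:
    recipe = CLASS_RECIPES[cls]
    aas = sorted(recipe["aa_weights"])
    weights = np.array([recipe["aa_weights"][a] for a in aas])
    weights = weights / weights.sum()
    out = []
    for i in rng.choice(len(aas), size=n, p=weights):
        aa = aas[i]
        if rng.random() < bias:
            biased = recipe["biased_codons"][aa]
            out.append(biased[rng.integers(len(biased))])
        else:
            out.append(_random_codon(aa, rng))
    return out


def _random_utr(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, TranscriptModel], pd.DataFrame]:
    """Generate transcript models plus a truth table of planted regions.

    Truth columns: transcript_id, gene_id, planted (bool), class,
    region_start/region_end (transcript coordinates, nt), bias, strand.
    """
    rng = np.random.default_rng(config.seed)
    n_planted = int(round(config.n_genes * config.planted_fraction))
    models: dict[str, TranscriptModel] = {}
    truth_rows = []
    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        tid = f"tx{g:04d}"
        planted = g < n_planted
        cls = config.planted_classes[g % len(config.planted_classes)] if planted else ""
        n_codons = int(rng.integers(config.cds_codons_range[0], config.cds_codons_range[1] + 1))
        codons = _background_codons(n_codons, rng)
        region_start = region_end = -1
        utr5 = _random_utr(int(rng.integers(*config.utr5_range)), rng)
        if planted:
            lo, hi = config.region_length_range
            m = int(rng.integers(lo // 3, hi // 3 + 1))
            at = int(rng.integers(10, n_codons - m - 10))
            codons[at : at + m] = _planted_codons(cls, m, config.codon_bias_strength, rng)
            region_start = len(utr5) + 3 * at
            region_end = len(utr5) + 3 * (at + m)
        cds = "".join(codons)
        utr3 = _random_utr(int(rng.integers(*config.utr3_range)), rng)
        spliced = utr5 + cds + utr3
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        weights = rng.lognormal(0.0, config.exon_length_sigma, size=n_exons)
        cuts = np.floor(np.cumsum(weights) / weights.sum() * len(spliced)).astype(int)
        cuts[-1] = len(spliced)
        exon_lengths = np.diff(np.concatenate(([0], cuts)))
        exon_lengths = [int(x) for x in exon_lengths if x > 0]
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            spliced_sequence=spliced,
            exon_lengths=exon_lengths,
            cds_start=len(utr5),
            cds_end=len(utr5) + len(cds),
            is_spliced=len(exon_lengths) >= 2,
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gene_id,
                "planted": planted,
                "class": cls,
                "region_start": region_start,
                "region_end": region_end,
                "bias": config.codon_bias_strength if planted else 0.0,
                "strand": strand,
                "intron_lengths": ",".join(
                    str(int(rng.integers(*config.intron_range)))
                    for _ in range(len(exon_lengths) - 1)
                ),
            }
        )
    return models, pd.DataFrame(truth_rows)


def write_transcriptome(
    models: dict[str, TranscriptModel],
    truth: pd.DataFrame,
    fasta_path: str,
    gtf_path: str,
) -> None:
    """Emit one genomic contig per gene (exons + introns) with a GTF.

    Minus-strand transcripts are written reverse-complemented on their contig
    so loading exercises the strand logic; the spliced sequences round-trip
    exactly through ``load_transcript_models``.
    """
    info = truth.set_index("transcript_id")
    fa_records = []
    gtf_lines = []
    for tid in sorted(models):
        model = models[tid]
        row = info.loc[tid]
        introns = [int(x) for x in str(row["intron_lengths"]).split(",") if x != ""]
        rng = np.random.default_rng(zlib.crc32(tid.encode()) % (2**31))
        plus_exons = []  # genomic intervals on the plus-strand construction
        genome_parts = []
        pos = 0
        offset = 0
        for i, ex_len in enumerate(model.exon_lengths):
            exon_seq = model.spliced_sequence[offset : offset + ex_len]
            genome_parts.append(exon_seq)
            plus_exons.append((pos, pos + ex_len))
            pos += ex_len
            offset += ex_len
            if i < len(model.exon_lengths) - 1:
                ilen = introns[i] if i < len(introns) else 120
                genome_parts.append(_random_utr(ilen, rng))
                pos += ilen
        contig = "".join(genome_parts)
        strand = str(row["strand"])
        L = len(contig)
        if strand == "-":
            contig = reverse_complement(contig)
            exons = sorted((L - e, L - s) for s, e in plus_exons)
        else:
            exons = plus_exons
        # CDS genomic intervals from transcript-space CDS bounds
        cds_iv = []
        t_off = 0
        for s, e in plus_exons:
            ex_len = e - s
            lo = max(model.cds_start, t_off)
            hi = min(model.cds_end, t_off + ex_len)
            if hi > lo:
                cds_iv.append((s + (lo - t_off), s + (hi - t_off)))
            t_off += ex_len
        if strand == "-":
            cds_iv = sorted((L - e, L - s) for s, e in cds_iv)
        fa_records.append((model.gene_id, contig))
        attrs = f'gene_id "{model.gene_id}"; transcript_id "{tid}";'
        tx_start = min(s for s, _ in exons)
        tx_end = max(e for _, e in exons)
        gtf_lines.append(
            f"{model.gene_id}\tgerm_sim\ttranscript\t{tx_start + 1}\t{tx_end}\t.\t{strand}\t.\t{attrs}"
        )
        for s, e in exons:
            gtf_lines.append(
                f"{model.gene_id}\tgerm_sim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )
        for s, e in cds_iv:
            gtf_lines.append(
                f"{model.gene_id}\tgerm_sim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t{attrs}"
            )
    with open(fasta_path, "w") as fh:
        for name, seq in fa_records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")


def simulate_conservation(
    models: dict[str, TranscriptModel],
    records: pd.DataFrame,
    delta: float = 0.5,
    noise_sd: float = 0.3,
    baseline: float = 0.5,
    seed: int = 0,
) -> dict[str, ConservationTrack]:
    """Conservation = baseline + noise, plus ``delta`` at mutable positions
    whose native codon supports local multivalency (codon ratio > 1).

    ``records`` is a codon-ratio table (transcript_id, codon_index,
    mutable_offset, ratio) from :func:`germ.codon.codon_ratio_records`.
    """
    rng = np.random.default_rng(seed)
    tracks = {
        tid: ConservationTrack(
            tid, baseline + rng.normal(0.0, noise_sd, size=m.length)
        )
        for tid, m in models.items()
    }
    for row in records.itertuples(index=False):
        if row.ratio > 1:
            model = models[row.transcript_id]
            q = model.cds_start + 3 * row.codon_index + row.mutable_offset
            tracks[row.transcript_id].values[q] += delta
    return tracks


def simulate_crosslinks(
    models: dict[str, TranscriptModel],
    truth: pd.DataFrame,
    sample_id: str,
    total_counts: int = 10_000,
    model: str = "uniform",
    enrichment_factor: float = 5.0,
    enriched_classes: tuple[str, ...] | None = None,
    seed: int = 0,
) -> list[CrosslinkTrack]:
    """Multinomial crosslink placement over CDS positions.

    ``model='uniform'`` weights every CDS nucleotide equally;
    ``'region_enriched'`` multiplies the weight of positions inside planted
    regions (optionally restricted to ``enriched_classes``) by
    ``enrichment_factor``. Total counts are conserved exactly.
    """
    if model not in ("uniform", "region_enriched"):
        raise ValueError("model must be 'uniform' or 'region_enriched'")
    rng = np.random.default_rng(seed)
    tids = sorted(models)
    weights = []
    spans = []
    info = truth.set_index("transcript_id")
    for tid in tids:
        m = models[tid]
        w = np.ones(m.cds_length, dtype=float)
        if model == "region_enriched":
            row = info.loc[tid]
            if bool(row["planted"]) and (
                enriched_classes is None or row["class"] in enriched_classes
            ):
                s = int(row["region_start"]) - m.cds_start
                e = int(row["region_end"]) - m.cds_start
                w[max(0, s) : max(0, e)] *= enrichment_factor
        weights.append(w)
        spans.append(m.cds_length)
    flat = np.concatenate(weights)
    counts = rng.multinomial(total_counts, flat / flat.sum())
    tracks = []
    offset = 0
    for tid, span in zip(tids, spans):
        m = models[tid]
        per_nt = np.zeros(m.length, dtype=np.int64)
        per_nt[m.cds_start : m.cds_end] = counts[offset : offset + span]
        offset += span
        tracks.append(CrosslinkTrack(tid, per_nt, sample_id))
    return tracks
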