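"""Readers/writers for the formats the toolkit touches.

Transcript models are resolved from a genome FASTA plus a GTF/GFF3 annotation
into spliced-transcript space: all internal coordinates are 0-based half-open
on the spliced transcript, and minus-strand transcripts are returned already
reverse-complemented (transcript orientation). Genomic coordinates exist only
at this I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .sequence import canonicalize, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """A spliced transcript with its CDS extent in transcript coordinates."""

    transcript_id: str
    gene_id: str
    spliced_sequence: str
    exon_lengths: list[int]
    cds_start: int
    cds_end: int
    is_spliced: bool = True

    def __post_init__(self) -> None:
        self.spliced_sequence = canonicalize(self.spliced_sequence)
        if sum(self.exon_lengths) != len(self.spliced_sequence):
            raise ValueError(
                f"{self.transcript_id}: exon lengths do not sum to sequence length"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(self.spliced_sequence)):
            raise ValueError(f"{self.transcript_id}: CDS bounds out of range")
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.spliced_sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def cds_sequence(self) -> str:
        return self.spliced_sequence[self.cds_start : self.cds_end]


@dataclass
class ConservationTrack:
    """Per-nucleotide conservation (PhyloP-like); missing values are NaN."""

    transcript_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CrosslinkTrack:
    """Per-nucleotide crosslink counts for one CLIP sample."""

    transcript_id: str
    counts: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("crosslink counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def load_transcript_models(fasta_path: str, annotation_path: str) -> dict[str, TranscriptModel]:
    """Resolve a GTF/GFF3 annotation against a genome FASTA.

    Returns ``{transcript_id: TranscriptModel}``. Transcripts whose CDS length
    is not divisible by 3 are skipped with a warning; an annotated transcript
    whose contig is absent from the FASTA is a hard error.
    """
    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = Fasta(str(fasta_path), sequence_always_upper=True)

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, seqid, strand)
    tx_parent: dict[str, str] = {}  # GFF3: transcript id -> gene id
    for feat in db.features_of_type(("mRNA", "transcript")):
        parents = feat.attributes.get("Parent")
        if parents and feat.id:
            tx_parent[feat.id] = parents[0]
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tids:
            continue
        for tid in tids:
            gene = (feat.attributes.get("gene_id") or [tx_parent.get(tid, tid)])[0]
            meta.setdefault(tid, (gene, feat.seqid, feat.strand))
            target = exons if feat.featuretype == "exon" else cds
            target.setdefault(tid, []).append((feat.start - 1, feat.end))  # to 0-based

    models: dict[str, TranscriptModel] = {}
    for tid, (gene_id, seqid, strand) in meta.items():
        if tid not in exons or tid not in cds:
            continue
        if seqid not in genome:
            raise KeyError(f"sequence {seqid!r} for transcript {tid!r} missing from FASTA")
        ex = sorted(exons[tid])
        cd = sorted(cds[tid])
        cds_len = sum(e - s for s, e in cd)
        if cds_len % 3:
            logger.warning("skipping %s: CDS length %d not divisible by 3", tid, cds_len)
            continue
        chrom = str(genome[seqid][:])
        spliced = "".join(chrom[s:e] for s, e in ex)
        # genomic -> transcript offset of the CDS span
        cds_gstart, cds_gend = cd[0][0], cd[-1][1]
        offset = 0
        t_start = t_end = None
        for s, e in ex:
            if s <= cds_gstart < e:
                t_start = offset + (cds_gstart - s)
            if s < cds_gend <= e:
                t_end = offset + (cds_gend - s)
            offset += e - s
        if t_start is None or t_end is None:
            logger.warning("skipping %s: CDS not contained in exons", tid)
            continue
        exon_lengths = [e - s for s, e in ex]
        if strand == "-":
            spliced = reverse_complement(spliced)
            L = len(spliced)
            t_start, t_end = L - t_end, L - t_start
            exon_lengths = exon_lengths[::-1]
        try:
            models[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                spliced_sequence=spliced,
                exon_lengths=exon_lengths,
                cds_start=t_start,
                cds_end=t_end,
                is_spliced=len(ex) >= 2,
            )
        except ValueError as err:
            logger.warning("skipping %s: %s", tid, err)
    return models


def select_primary_transcripts(models: dict[str, TranscriptModel]) -> dict[str, TranscriptModel]:
    """One transcript per gene: longest CDS, ties broken by total length.

    Unspliced (single-exon) transcripts are excluded before selection; genes
    left with no spliced coding transcript are omitted.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models.values():
        if not m.is_spliced:
            continue
        by_gene.setdefault(m.gene_id, []).append(m)
    out: dict[str, TranscriptModel] = {}
    for gene_id in sorted(by_gene):
        best = max(
            by_gene[gene_id],
            key=lambda m: (m.cds_length, m.length, m.transcript_id),
        )
        out[best.transcript_id] = best
    dropped = {m.gene_id for m in models.values()} - set(by_gene)
    for g in sorted(dropped):
        logger.info("gene %s has no spliced coding transcript; omitted", g)
    return out


# --- region tables ----------------------------------------------------------

REGION_COLUMNS = ["transcript_id", "start", "end", "region_id", "score", "cluster"]


def write_regions(regions, path: str) -> None:
    """BED-like 6-column TSV (0-based half-open transcript coordinates)."""
    rows = []
    seen = set()
    for r in regions:
        rid = getattr(r, "region_id", None) or f"{r.transcript_id}:{r.start}-{r.end}"
        if rid in seen:
            raise ValueError(f"duplicate region id {rid!r}")
        seen.add(rid)
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "start": r.start,
                "end": r.end,
                "region_id": rid,
                "score": getattr(r, "mean_smoothed", 0.0),
                "cluster": getattr(r, "cluster", None) or ".",
            }
        )
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "cluster": str})
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    return df


# --- per-position tracks ----------------------------------------------------


def write_conservation(tracks: dict[str, ConservationTrack], path: str) -> None:
    frames = [
        pd.DataFrame(
            {"transcript_id": t.transcript_id, "pos": np.arange(len(t.values)), "value": t.values}
        )
        for t in tracks.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_conservation(path: str) -> dict[str, ConservationTrack]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for tid, sub in df.groupby("transcript_id", sort=False):
        values = np.full(int(sub["pos"].max()) + 1, np.nan)
        values[sub["pos"].to_numpy()] = sub["value"].to_numpy()
        out[str(tid)] = ConservationTrack(str(tid), values)
    return out


def write_crosslinks(tracks: list[CrosslinkTrack], path: str) -> None:
    frames = []
    for t in tracks:
        pos = np.nonzero(t.counts)[0]
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": t.transcript_id,
                    "pos": pos,
                    "count": t.counts[pos],
                    "sample_id": t.sample_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_crosslinks(path: str, lengths: dict[str, int]) -> list[CrosslinkTrack]:
    """Read crosslink TSV; ``lengths`` gives each transcript's length."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sample, tid), sub in df.groupby(["sample_id", "transcript_id"], sort=False):
        counts = np.zeros(lengths[str(tid)], dtype=np.int64)
        counts[sub["pos"].to_numpy()] = sub["count"].to_numpy()
        out.append(CrosslinkTrack(str(tid), counts, str(sample)))
    return out


def write_score_tracks(tracks, path: str) -> None:
    """Per k-mer-position TSV of raw/normalized/smoothed scores."""
    frames = []
    for t in tracks.values() if isinstance(tracks, dict) else tracks:
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": t.transcript_id,
                    "pos": np.arange(len(t.raw)),
                    "raw": t.raw,
                    "normalized": t.normalized if t.normalized is not None else np.nan,
                    "smoothed": t.smoothed if t.smoothed is not None else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
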