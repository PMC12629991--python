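"""Nucleotide alphabet handling and genetic-code helpers.

All sequences are canonicalized to the DNA alphabet (U -> T) on entry so that
RNA and DNA inputs score identically. ``N`` is the only ambiguity code
accepted; k-mers containing ``N`` receive no multivalency score and contribute
zero similarity as window neighbours.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

# integer encoding; N = 4 is treated as invalid inside k-mers
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _v
    _ENCODE_LUT[ord(_b.lower())] = _v

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

BASES = "ACGT"

#: forward genetic code on the canonical alphabet, stops excluded
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: codons per amino acid (sense codons only)
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    SYNONYMOUS.setdefault(_aa, ())
    SYNONYMOUS[_aa] += (_codon,)

ARG_CODONS = ("AGA", "AGG", "CGA", "CGG", "CGC", "CGT")


def canonicalize(seq: str) -> str:
    """Uppercase and convert RNA to the DNA alphabet."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 (A=0, C=1, G=2, T/U=3, N=4).

    Raises ``ValueError`` on characters outside {A, C, G, T, U, N}.
    """
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(arr == 255)[0][:5]})
        raise ValueError(f"invalid nucleotide characters: {bad}")
    return arr


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame CDS (stops rendered as ``*``)."""
    cds = canonicalize(cds)
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        out.append(CODON_TABLE.get(codon, "*" if codon in STOP_CODONS else "X"))
    return "".join(out)


def split_codons(cds: str) -> list[str]:
    cds = canonicalize(cds)
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def valid_kmer_mask(encoded: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over k-mer start positions: True where the k-mer is N-free."""
    n_ok = encoded != 4
    if len(encoded) < k:
        return np.zeros(0, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(n_ok)))
    return (csum[k:] - csum[:-k]) == k


def gc_content(seq: str) -> float:
    seq = canonicalize(seq)
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
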