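"""Bundled human-like codon usage (static, versioned with the package).

``CODON_FRACTIONS`` gives, for each amino acid, the approximate fraction of
its usage carried by each codon in the human transcriptome; ``AA_FREQUENCIES``
gives average amino-acid frequencies in human proteins. Both are used by the
simulator to draw codon-frequency-matched random coding backgrounds without
any download.
"""

from __future__ import annotations

CODON_FRACTIONS: dict[str, dict[str, float]] = {
    "A": {"GCT": 0.26, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11},
    "R": {"CGT": 0.08, "CGC": 0.19, "CGA": 0.11, "CGG": 0.21, "AGA": 0.20, "AGG": 0.21},
    "N": {"AAT": 0.46, "AAC": 0.54},
    "D": {"GAT": 0.46, "GAC": 0.54},
    "C": {"TGT": 0.45, "TGC": 0.55},
    "Q": {"CAA": 0.25, "CAG": 0.75},
    "E": {"GAA": 0.42, "GAG": 0.58},
    "G": {"GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25},
    "H": {"CAT": 0.41, "CAC": 0.59},
    "I": {"ATT": 0.36, "ATC": 0.48, "ATA": 0.16},
    "L": {
        "TTA": 0.07,
        "TTG": 0.13,
        "CTT": 0.13,
        "CTC": 0.20,
        "CTA": 0.07,
        "CTG": 0.40,
    },
    "K": {"AAA": 0.42, "AAG": 0.58},
    "M": {"ATG": 1.0},
    "F": {"TTT": 0.45, "TTC": 0.55},
    "P": {"CCT": 0.28, "CCC": 0.33, "CCA": 0.27, "CCG": 0.12},
    "S": {
        "TCT": 0.18,
        "TCC": 0.22,
        "TCA": 0.15,
        "TCG": 0.06,
        "AGT": 0.15,
        "AGC": 0.24,
    },
    "T": {"ACT": 0.24, "ACC": 0.36, "ACA": 0.28, "ACG": 0.12},
    "W": {"TGG": 1.0},
    "Y": {"TAT": 0.43, "TAC": 0.57},
    "V": {"GTT": 0.18, "GTC": 0.24, "GTA": 0.11, "GTG": 0.47},
}

AA_FREQUENCIES: dict[str, float] = {
    "A": 0.070,
    "R": 0.056,
    "N": 0.036,
    "D": 0.047,
    "C": 0.023,
    "Q": 0.047,
    "E": 0.071,
    "G": 0.066,
    "H": 0.026,
    "I": 0.043,
    "L": 0.100,
    "K": 0.057,
    "M": 0.021,
    "F": 0.036,
    "P": 0.063,
    "S": 0.083,
    "T": 0.053,
    "W": 0.012,
    "Y": 0.027,
    "V": 0.060,
}
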