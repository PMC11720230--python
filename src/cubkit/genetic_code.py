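"""Standard genetic code tables and codon bookkeeping.

Everything downstream (RSCU, ENC, CAI, the simulator) indexes codons in
lexicographic order over the alphabet A < C < G < T, i.e. codon index
``16*b1 + 4*b2 + b3`` with A=0, C=1, G=2, T=3.  All tables here refer to
translation table 1 (the standard nuclear code).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: all 64 codons in lexicographic order
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")

#: amino acid (1-letter) -> tuple of codons, translation table 1
GENETIC_CODE: dict[str, tuple[str, ...]] = {
    "A": ("GCA", "GCC", "GCG", "GCT"),
    "C": ("TGC", "TGT"),
    "D": ("GAC", "GAT"),
    "E": ("GAA", "GAG"),
    "F": ("TTC", "TTT"),
    "G": ("GGA", "GGC", "GGG", "GGT"),
    "H": ("CAC", "CAT"),
    "I": ("ATA", "ATC", "ATT"),
    "K": ("AAA", "AAG"),
    "L": ("CTA", "CTC", "CTG", "CTT", "TTA", "TTG"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCA", "CCC", "CCG", "CCT"),
    "Q": ("CAA", "CAG"),
    "R": ("AGA", "AGG", "CGA", "CGC", "CGG", "CGT"),
    "S": ("AGC", "AGT", "TCA", "TCC", "TCG", "TCT"),
    "T": ("ACA", "ACC", "ACG", "ACT"),
    "V": ("GTA", "GTC", "GTG", "GTT"),
    "W": ("TGG",),
    "Y": ("TAC", "TAT"),
}

CODON_TO_AA: dict[str, str] = {
    codon: aa for aa, codons in GENETIC_CODE.items() for codon in codons
}
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: the 18 amino acids with >1 synonymous codon (Met and Trp excluded)
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, cs in GENETIC_CODE.items() if len(cs) > 1)
)

#: the 59 degenerate sense codons, lexicographic order (matrix column order)
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS if c not in STOP_CODONS and c not in ("ATG", "TGG")
)

#: ENC degeneracy classes (6-fold families kept whole, Wright's treatment)
ENC_CLASSES: dict[int, tuple[str, ...]] = {
    2: ("C", "D", "E", "F", "H", "K", "N", "Q", "Y"),
    3: ("I",),
    4: ("A", "G", "P", "T", "V"),
    6: ("L", "R", "S"),
}

#: fourfold-degenerate families used by the PR2 parity diagnostic
FOURFOLD_AAS: tuple[str, ...] = ("A", "G", "P", "T", "V")

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_AAS = frozenset("FYW")

# byte-level lookup tables for fast codon counting -------------------------

_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i

_SYN_CODON_IDX = np.array([CODON_INDEX[c] for c in SYNONYMOUS_CODONS])
_STOP_IDX = np.array([CODON_INDEX[c] for c in STOP_CODONS])


def codon_indices(sequence: str) -> np.ndarray:
    """Map a CDS string to the array of its codon indices (0..63).

    Raises ``ValueError`` on a length not divisible by 3 or a non-ACGT
    character.
    """
    if len(sequence) % 3:
        raise ValueError(f"sequence length {len(sequence)} not divisible by 3")
    arr = _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains a character outside ACGT")
    arr = arr.reshape(-1, 3).astype(np.int64)
    return 16 * arr[:, 0] + 4 * arr[:, 1] + arr[:, 2]
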