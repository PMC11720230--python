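"""Per-gene codon composition and usage-bias indices.

This module computes the standard battery of codon-usage statistics:

* positional GC content (GC, GC1, GC2, GC3, GC12) and the synonymous
  third-position composition (GC3s, A3s, T3s, C3s, G3s),
* RSCU — relative synonymous codon usage, ``x_ij / ((1/n_i) Σ_j x_ij)``,
* ENC — Wright's effective number of codons, via per-family codon
  homozygosity ``F = (n Σ p_j² − 1)/(n − 1)`` and
  ``ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆``,
* CAI — Sharp & Li's codon adaptation index against a reference codon
  frequency table,
* CBI and FOP — codon bias index and frequency of optimal codons for a
  supplied optimal-codon set,
* GRAVY and aromaticity of the encoded protein.

Conventions (CodonW-compatible where the choice matters): GC covers all
positions except the terminal stop codon; GC1/GC2/GC3 cover all sense
codons including ATG and TGG; GC3s and A3s..G3s cover synonymous codons
only (ATG, TGG and stops excluded).  A3s here is the plain fraction of
synonymous codons ending in A — CodonW's per-availability normalization is
deliberately not replicated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genetic_code import (
    AROMATIC_AAS,
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    DEGENERATE_AAS,
    ENC_CLASSES,
    GENETIC_CODE,
    KYTE_DOOLITTLE,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    codon_indices,
)
from .sequence_io import CodingSequence

__all__ = [
    "CodonCountTable",
    "CompositionProfile",
    "count_codons",
    "composition_profile",
    "rscu",
    "enc",
    "cai_weights",
    "cai",
    "cbi_fop",
    "gravy_aromo",
    "compute_gene_indices",
    "INDEX_COLUMNS",
]


@dataclass
class CodonCountTable:
    """Counts over the 64 codons for one gene or a pooled set."""

    counts: np.ndarray  # shape (64,), int
    source: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if (self.counts < 0).any():
            raise ValueError("negative codon count")

    @classmethod
    def zeros(cls, source: str = "") -> "CodonCountTable":
        return cls(np.zeros(64, dtype=np.int64), source)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int], source: str = "") -> "CodonCountTable":
        counts = np.zeros(64, dtype=np.int64)
        for codon, n in mapping.items():
            counts[CODON_INDEX[codon.upper().replace("U", "T")]] = n
        return cls(counts, source)

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(self.counts + other.counts, self.source)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self.counts)}

    def family_counts(self, aa: str) -> np.ndarray:
        return self.counts[[CODON_INDEX[c] for c in GENETIC_CODE[aa]]]


def count_codons(cds: CodingSequence | str, source: str | None = None) -> CodonCountTable:
    """Count non-overlapping codons of a CDS, terminal stop included."""
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds
    label = source if source is not None else getattr(cds, "gene_id", "")
    idx = codon_indices(seq)
    return CodonCountTable(np.bincount(idx, minlength=64), label)


def pool_counts(tables: Iterable[CodonCountTable], source: str = "pool") -> CodonCountTable:
    """Elementwise sum of codon count tables (empty pool -> all zeros)."""
    pooled = CodonCountTable.zeros(source)
    for t in tables:
        pooled = pooled + t
    pooled.source = source
    return pooled


# -- composition ------------------------------------------------------------

_GC = frozenset("GC")


@dataclass(frozen=True)
class CompositionProfile:
    """Positional GC content and synonymous third-base composition."""

    GC: float
    GC1: float
    GC2: float
    GC3: float
    GC3s: float
    A3s: float
    T3s: float
    C3s: float
    G3s: float

    @property
    def GC12(self) -> float:
        return (self.GC1 + self.GC2) / 2.0


def composition_profile(cds: CodingSequence | str) -> CompositionProfile:
    """Compute GC/GC1/GC2/GC3/GC3s and A3s..G3s for a filtered CDS."""
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no sense codons")

    body = "".join(codons)
    gc_all = sum(b in _GC for b in body) / len(body)
    gck = [
        sum(c[k] in _GC for c in codons) / len(codons) for k in range(3)
    ]

    syn3 = [c[2] for c in codons if CODON_TO_AA[c] in DEGENERATE_AAS]
    if syn3:
        n = len(syn3)
        a3s = syn3.count("A") / n
        t3s = syn3.count("T") / n
        c3s = syn3.count("C") / n
        g3s = syn3.count("G") / n
        gc3s = c3s + g3s
    else:
        a3s = t3s = c3s = g3s = gc3s = math.nan

    return CompositionProfile(
        GC=gc_all, GC1=gck[0], GC2=gck[1], GC3=gck[2],
        GC3s=gc3s, A3s=a3s, T3s=t3s, C3s=c3s, G3s=g3s,
    )


# -- RSCU -------------------------------------------------------------------

def rscu(table: CodonCountTable, include_stops: bool = False) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    For each degenerate family with codons ``j = 1..n``:
    ``RSCU_j = x_j / ((1/n) Σ x_j)``.  Families with zero total are
    reported as NaN.  ATG and TGG are excluded always; the three stop
    codons are treated as a 3-member family only when ``include_stops``
    (used for pooled stop-usage summaries).
    """
    out: dict[str, float] = {}
    families: list[tuple[str, ...]] = [GENETIC_CODE[aa] for aa in DEGENERATE_AAS]
    if include_stops:
        families.append(STOP_CODONS)
    for codons in families:
        counts = np.array([table[c] for c in codons], dtype=float)
        total = counts.sum()
        if total == 0:
            for c in codons:
                out[c] = math.nan
        else:
            vals = counts * len(codons) / total
            for c, v in zip(codons, vals):
                out[c] = float(v)
    return out


# -- ENC --------------------------------------------------------------------

def _family_homozygosity(counts: np.ndarray) -> float | None:
    """Wright's F for one amino-acid family; None when n <= 1."""
    n = counts.sum()
    if n <= 1:
        return None
    p = counts / n
    return float((n * (p ** 2).sum() - 1.0) / (n - 1.0))


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Families with total count <= 1 are excluded from their degeneracy
    class average.  A missing 3-fold class average is imputed as
    ``(F̄₂ + F̄₄)/2``; any other missing class leaves ENC undefined (NaN).
    A class average of exactly zero (perfectly even usage at tiny counts)
    drives the reciprocal to infinity and thus the cap of 61.
    """
    fbar: dict[int, float] = {}
    for k, aas in ENC_CLASSES.items():
        fs = []
        for aa in aas:
            f = _family_homozygosity(table.family_counts(aa))
            if f is not None:
                fs.append(f)
        if fs:
            fbar[k] = float(np.mean(fs))

    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(k not in fbar for k in (2, 3, 4, 6)):
        return math.nan

    with np.errstate(divide="ignore"):
        terms = [
            9.0 / fbar[2] if fbar[2] > 0 else math.inf,
            1.0 / fbar[3] if fbar[3] > 0 else math.inf,
            5.0 / fbar[4] if fbar[4] > 0 else math.inf,
            3.0 / fbar[6] if fbar[6] > 0 else math.inf,
        ]
    value = 2.0 + sum(terms)
    return float(min(61.0, max(20.0, value)))


# -- CAI --------------------------------------------------------------------

def cai_weights(reference: CodonCountTable) -> dict[str, float]:
    """Relative adaptiveness weights from a reference (high-expression) pool.

    Within each degenerate family ``w_j = x_j / max_j x_j``; zero counts
    receive a 0.5 pseudocount before division (Sharp & Li convention), so
    every weight is in (0, 1].  ATG, TGG and stops carry no weight.
    """
    if reference.total == 0:
        raise ValueError("empty reference codon table")
    weights: dict[str, float] = {}
    for aa in DEGENERATE_AAS:
        codons = GENETIC_CODE[aa]
        counts = np.array([reference[c] for c in codons], dtype=float)
        counts[counts == 0] = 0.5
        w = counts / counts.max()
        for c, v in zip(codons, w):
            weights[c] = float(v)
    return weights


def cai(table: CodonCountTable, weights: Mapping[str, float]) -> float:
    """Geometric mean of adaptiveness weights over the gene's synonymous codons."""
    log_sum = 0.0
    n = 0
    for c in SYNONYMOUS_CODONS:
        x = table[c]
        if x:
            log_sum += x * math.log(weights[c])
            n += x
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


# -- CBI / FOP --------------------------------------------------------------

def cbi_fop(table: CodonCountTable, optimal_set: set[str] | frozenset[str]) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    Both are computed over the families that contain at least one optimal
    codon: ``FOP = N_opt / N_tot`` and
    ``CBI = (N_opt − N_rand)/(N_tot − N_rand)`` where ``N_rand`` is the
    count expected if codons were drawn uniformly within each family.
    """
    if not optimal_set:
        raise ValueError("empty optimal codon set")
    n_opt = 0.0
    n_tot = 0.0
    n_rand = 0.0
    for aa in DEGENERATE_AAS:
        codons = GENETIC_CODE[aa]
        opt_in_family = [c for c in codons if c in optimal_set]
        if not opt_in_family:
            continue
        fam_total = sum(table[c] for c in codons)
        n_tot += fam_total
        n_opt += sum(table[c] for c in opt_in_family)
        n_rand += fam_total * len(opt_in_family) / len(codons)
    if n_tot == 0:
        return math.nan, math.nan
    fop = n_opt / n_tot
    cbi_val = (n_opt - n_rand) / (n_tot - n_rand) if n_tot != n_rand else math.nan
    return cbi_val, fop


# -- protein-level ----------------------------------------------------------

def gravy_aromo(protein: str) -> tuple[float, float]:
    """GRAVY (mean Kyte-Doolittle hydropathy) and aromatic residue fraction."""
    if not protein:
        raise ValueError("empty protein")
    try:
        gravy = sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc}") from exc
    aromo = sum(a in AROMATIC_AAS for a in protein) / len(protein)
    return gravy, aromo


# -- assembly ---------------------------------------------------------------

INDEX_COLUMNS = [
    "gene_id", "L_aa", "L_sym", "GC", "GC1", "GC2", "GC3", "GC12",
    "GC3s", "A3s", "T3s", "C3s", "G3s", "ENC", "CAI", "CBI", "FOP",
    "GRAVY", "Aromo",
]


def compute_gene_indices(
    sequences: list[CodingSequence],
    optimal_set: set[str] | None = None,
    cai_weights_map: Mapping[str, float] | None = None,
    reference_fraction: float = 0.10,
) -> pd.DataFrame:
    """All per-gene indices as one DataFrame (one row per gene).

    CAI needs a reference set and CBI/FOP an optimal-codon set.  When not
    supplied they are derived from the input itself: the reference pool is
    the lowest-ENC decile (a high-expression proxy) and the optimal set
    comes from the ΔRSCU procedure in :mod:`cubkit.optimal_codons`.  With
    fewer than 20 genes and nothing supplied, CAI/CBI/FOP are NaN.
    """
    from .optimal_codons import delta_rscu, split_expression_libraries
    from .sequence_io import translate

    tables = {c.gene_id: count_codons(c) for c in sequences}
    encs = {gid: enc(t) for gid, t in tables.items()}

    defined = [(gid, e) for gid, e in encs.items() if not math.isnan(e)]
    if cai_weights_map is None or optimal_set is None:
        if len(defined) >= 20:
            libs = split_expression_libraries(defined, fraction=reference_fraction)
            high_pool = pool_counts(
                (tables[g] for g in libs.high_expression), "high")
            if cai_weights_map is None:
                cai_weights_map = cai_weights(high_pool)
            if optimal_set is None:
                low_pool = pool_counts(
                    (tables[g] for g in libs.low_expression), "low")
                report = delta_rscu(high_pool, low_pool)
                optimal_set = set(report.index[report["optimal"]])

    rows = []
    for cds in sequences:
        t = tables[cds.gene_id]
        prof = composition_profile(cds)
        protein = translate(cds)
        gravy, aromo = gravy_aromo(protein)
        l_sym = int(sum(t[c] for c in SYNONYMOUS_CODONS))
        cai_val = cai(t, cai_weights_map) if cai_weights_map else math.nan
        if optimal_set:
            cbi_val, fop_val = cbi_fop(t, optimal_set)
        else:
            cbi_val = fop_val = math.nan
        rows.append({
            "gene_id": cds.gene_id,
            "L_aa": len(protein),
            "L_sym": l_sym,
            "GC": prof.GC, "GC1": prof.GC1, "GC2": prof.GC2,
            "GC3": prof.GC3, "GC12": prof.GC12, "GC3s": prof.GC3s,
            "A3s": prof.A3s, "T3s": prof.T3s, "C3s": prof.C3s,
            "G3s": prof.G3s,
            "ENC": encs[cds.gene_id],
            "CAI": cai_val, "CBI": cbi_val, "FOP": fop_val,
            "GRAVY": gravy, "Aromo": aromo,
        })
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)
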