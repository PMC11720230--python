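"""Optimal-codon determination via ENC-decile expression libraries.

Genes are ranked by ENC; the lowest decile (strongest bias) serves as a
high-expression proxy library and the highest decile as the low-expression
library.  Pooled RSCU is computed for each library and a codon is called

* high-frequency when ``RSCU_high > 1``,
* optimal when additionally ``ΔRSCU = RSCU_high − RSCU_low > 0.08``

(strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .codon_metrics import CodonCountTable, rscu
from .genetic_code import CODON_TO_AA, SYNONYMOUS_CODONS

__all__ = [
    "ExpressionLibraries",
    "split_expression_libraries",
    "delta_rscu",
    "high_frequency_codons",
]


@dataclass(frozen=True)
class ExpressionLibraries:
    """Gene-ID deciles used as expression proxies."""

    high_expression: tuple[str, ...]  # lowest-ENC genes
    low_expression: tuple[str, ...]   # highest-ENC genes
    fraction: float


def split_expression_libraries(
    gene_enc: list[tuple[str, float]], fraction: float = 0.10
) -> ExpressionLibraries:
    """Split genes into lowest/highest-ENC libraries of size ⌊fraction·N⌋.

    Ties in ENC are broken by gene ID (lexicographic) so the split is
    deterministic.  Genes with undefined ENC are ignored; fewer than 20
    usable genes is an error.
    """
    usable = [(gid, e) for gid, e in gene_enc if not math.isnan(e)]
    n = len(usable)
    if n < 20:
        raise ValueError(f"need >= 20 genes with defined ENC, got {n}")
    k = max(1, int(fraction * n))
    ordered = sorted(usable, key=lambda t: (t[1], t[0]))
    high = tuple(gid for gid, _ in ordered[:k])
    low = tuple(gid for gid, _ in ordered[-k:])
    return ExpressionLibraries(high, low, fraction)


def delta_rscu(
    high_pool: CodonCountTable,
    low_pool: CodonCountTable,
    threshold: float = 0.08,
) -> pd.DataFrame:
    """Per-codon ΔRSCU report over the 59 degenerate sense codons.

    Columns: amino_acid, rscu_high, rscu_low, delta_rscu,
    high_frequency (RSCU_high > 1), optimal (ΔRSCU > threshold and
    RSCU_high > 1).  Codons of a family absent from either pool have NaN
    ΔRSCU and are never flagged.
    """
    rscu_h = rscu(high_pool)
    rscu_l = rscu(low_pool)
    rows = []
    for codon in SYNONYMOUS_CODONS:
        rh, rl = rscu_h[codon], rscu_l[codon]
        delta = rh - rl if not (math.isnan(rh) or math.isnan(rl)) else math.nan
        high_freq = (not math.isnan(rh)) and rh > 1.0
        optimal = (not math.isnan(delta)) and delta > threshold and rh > 1.0
        rows.append({
            "codon": codon,
            "amino_acid": CODON_TO_AA[codon],
            "rscu_high": rh,
            "rscu_low": rl,
            "delta_rscu": delta,
            "high_frequency": high_freq,
            "optimal": optimal,
        })
    return pd.DataFrame(rows).set_index("codon")


def high_frequency_codons(species_rscu: dict[str, float]) -> list[tuple[str, float]]:
    """Codons with RSCU > 1, ranked by descending RSCU (ties by codon)."""
    hits = [
        (c, v) for c, v in species_rscu.items()
        if c in SYNONYMOUS_CODONS and not math.isnan(v) and v > 1.0
    ]
    return sorted(hits, key=lambda t: (-t[1], t[0]))
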