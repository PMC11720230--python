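"""Mutation-vs-selection diagnostics.

Three classic plots discriminate mutational pressure from selection as the
driver of codon usage bias:

* the ENC-GC3s plot, comparing observed ENC with the value expected when
  composition alone sets usage, ``ENC_exp = 2 + s + 29/(s² + (1−s)²)``,
  plus the binned distribution of ``(ENC_exp − ENC_obs)/ENC_exp``;
* the PR2 (parity rule 2) plot of ``A3/(A3+T3)`` against ``G3/(G3+C3)``
  at third positions of fourfold-degenerate families, where (0.5, 0.5)
  means no strand/selection asymmetry;
* the neutrality plot regressing GC12 on GC3 — a slope near 1 indicates
  mutation-driven usage, near 0 selection-constrained usage.

An index-correlation matrix (Pearson by default) across all per-gene
indices rounds out the diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable
from .genetic_code import CODON_INDEX, DEGENERATE_AAS, FOURFOLD_AAS, GENETIC_CODE

__all__ = [
    "RegressionResult",
    "DeviationBinTable",
    "expected_enc",
    "enc_deviation",
    "bin_enc_deviations",
    "pr2_coordinates",
    "neutrality_regression",
    "index_correlation_matrix",
    "CORRELATION_PANEL",
]


def expected_enc(gc3s: float) -> float:
    """Expected ENC under pure compositional (mutational) determination."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def enc_deviation(enc_obs: float, gc3s: float) -> float:
    """(ENC_exp − ENC_obs)/ENC_exp; positive when observed usage is more biased."""
    if math.isnan(enc_obs) or math.isnan(gc3s):
        return math.nan
    exp = expected_enc(gc3s)
    return (exp - enc_obs) / exp


#: Table-2 style bins, highest first; half-open [lo, hi) except the top bin
DEVIATION_BINS: tuple[tuple[float, float, str], ...] = (
    (0.3, 0.4, "0.3~0.4"),
    (0.2, 0.3, "0.2~0.3"),
    (0.1, 0.2, "0.1~0.2"),
    (0.0, 0.1, "0~0.1"),
    (-0.1, 0.0, "-0.1~0"),
    (-0.2, -0.1, "-0.2~-0.1"),
)


@dataclass
class DeviationBinTable:
    """Percentage of genes per ENC-deviation bin (2 decimals)."""

    percentages: dict[str, float]
    out_of_range: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        data = dict(self.percentages)
        data["out_of_range"] = self.out_of_range
        return pd.DataFrame([data])


def bin_enc_deviations(ratios: list[float] | np.ndarray) -> DeviationBinTable:
    """Bin (ENC_exp − ENC_obs)/ENC_exp ratios into the six standard intervals."""
    arr = np.asarray([r for r in np.ravel(ratios) if not math.isnan(r)], dtype=float)
    if arr.size == 0:
        raise ValueError("no defined deviation ratios to bin")
    pct: dict[str, float] = {}
    binned = 0
    for lo, hi, label in DEVIATION_BINS:
        if (lo, hi) == (0.3, 0.4):  # topmost bin closed on the right
            mask = (arr >= lo) & (arr <= hi)
        else:
            mask = (arr >= lo) & (arr < hi)
        count = int(mask.sum())
        binned += count
        pct[label] = round(100.0 * count / arr.size, 2)
    out = round(100.0 * (arr.size - binned) / arr.size, 2)
    return DeviationBinTable(percentages=pct, out_of_range=out, n=int(arr.size))


# -- PR2 --------------------------------------------------------------------

def pr2_coordinates(
    table: CodonCountTable, fourfold_only: bool = True
) -> tuple[float, float]:
    """AT bias ``A3/(A3+T3)`` and GC bias ``G3/(G3+C3)`` at third positions.

    By default the four bases are tallied over the fourfold-degenerate
    families only (Sueoka's parity convention); with ``fourfold_only=False``
    all synonymous codons contribute.
    """
    aas = FOURFOLD_AAS if fourfold_only else DEGENERATE_AAS
    tally = {b: 0 for b in "ACGT"}
    for aa in aas:
        for codon in GENETIC_CODE[aa]:
            tally[codon[2]] += table[codon]
    at = tally["A"] + tally["T"]
    gc = tally["G"] + tally["C"]
    at_bias = tally["A"] / at if at else math.nan
    gc_bias = tally["G"] / gc if gc else math.nan
    return at_bias, gc_bias


# -- neutrality plot --------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def neutrality_regression(points: list[tuple[float, float]] | np.ndarray) -> RegressionResult:
    """OLS of GC12 on GC3 over (GC12, GC3) pairs."""
    arr = np.asarray(points, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 points for the neutrality regression")
    gc12, gc3 = arr[:, 0], arr[:, 1]
    if np.var(gc3) == 0:
        raise ValueError("zero variance in GC3")
    fit = stats.linregress(gc3, gc12)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        n_points=int(arr.shape[0]),
    )


# -- index correlations -----------------------------------------------------

CORRELATION_PANEL = [
    "A3s", "T3s", "C3s", "G3s", "CAI", "CBI", "FOP", "ENC",
    "GC3s", "GC", "L_sym", "L_aa", "GRAVY", "Aromo",
]


def index_correlation_matrix(
    gene_indices: pd.DataFrame,
    method: str = "pearson",
    panel: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation (r, p) across the per-gene index panel.

    Missing values are pairwise-deleted; a constant column yields NaN for
    its correlations.  Returns ``(r_matrix, p_matrix)``.
    """
    panel = panel or [c for c in CORRELATION_PANEL if c in gene_indices.columns]
    if len(gene_indices) < 10:
        raise ValueError("need at least 10 genes for the correlation matrix")
    corr_fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    k = len(panel)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    cols = [gene_indices[c].to_numpy(dtype=float) for c in panel]
    for i in range(k):
        for j in range(i, k):
            x, y = cols[i], cols[j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.var(x[ok]) == 0 or np.var(y[ok]) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = corr_fn(x[ok], y[ok])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return (
        pd.DataFrame(r, index=panel, columns=panel),
        pd.DataFrame(p, index=panel, columns=panel),
    )
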