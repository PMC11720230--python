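"""Correspondence analysis of the gene × 59-codon RSCU matrix.

Standard chi-square-metric CA: with ``P`` the matrix scaled to sum 1,
row/column margins ``r`` and ``c``, the standardized residuals
``s_ij = (p_ij − r_i c_j) / sqrt(r_i c_j)`` are decomposed by SVD; the
squared singular values partition the total inertia.  Rows are genes,
columns the 59 degenerate sense codons, values RSCU (the convention of
CodonW-style codon-usage ordinations — usage profiles, not raw counts).

Axis signs from an SVD are arbitrary; they are canonicalized so the
largest-magnitude column loading on each axis is positive, making results
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_metrics import CodonCountTable, rscu
from .genetic_code import CODON_TO_AA, DEGENERATE_AAS, GENETIC_CODE, SYNONYMOUS_CODONS

logger = logging.getLogger(__name__)

__all__ = ["CoaResult", "rscu_matrix", "correspondence_analysis", "gc_class_labels"]


def rscu_matrix(
    genes: list[CodonCountTable],
    max_missing_families: int | None = None,
) -> pd.DataFrame:
    """Genes × 59 RSCU matrix (fixed lexicographic codon order).

    RSCU undefined because a family is absent from a gene is imputed as 0.
    Genes missing more than ``max_missing_families`` of the 18 degenerate
    families can be excluded (extreme zero-imputation distorts the
    chi-square residuals).
    """
    rows = []
    labels = []
    for table in genes:
        values = rscu(table)
        if max_missing_families is not None:
            missing = sum(
                1 for aa in DEGENERATE_AAS
                if math.isnan(values[GENETIC_CODE[aa][0]])
            )
            if missing > max_missing_families:
                logger.warning(
                    "excluding %s from CA: %d absent families", table.source, missing)
                continue
        rows.append([0.0 if math.isnan(values[c]) else values[c]
                     for c in SYNONYMOUS_CODONS])
        labels.append(table.source)
    return pd.DataFrame(rows, index=labels, columns=list(SYNONYMOUS_CODONS))


@dataclass
class CoaResult:
    row_coordinates: pd.DataFrame
    column_coordinates: pd.DataFrame
    inertia_fraction: np.ndarray
    total_inertia: float

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.inertia_fraction)


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int | None = None) -> CoaResult:
    """Run CA on a non-negative matrix; returns principal coordinates.

    All-zero columns are dropped with a warning; an all-zero row or a
    zero-total matrix is an error.  A matrix with (near-)zero total
    inertia — rank-one association — yields zero coordinates and zero
    inertia fractions.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("CA requires a non-negative matrix")
    col_ok = X.sum(axis=0) > 0
    if not col_ok.all():
        logger.warning("dropping %d all-zero columns", int((~col_ok).sum()))
        matrix = matrix.loc[:, col_ok]
        X = X[:, col_ok]
    if X.size == 0 or X.sum() == 0:
        raise ValueError("degenerate matrix: zero total")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero row in CA input")

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)

    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    max_axes = min(X.shape) - 1
    total_inertia = float((sigma ** 2).sum())

    if total_inertia < 1e-12:
        k = max(1, max_axes)
        zeros_r = pd.DataFrame(
            np.zeros((X.shape[0], k)), index=matrix.index,
            columns=[f"axis{i+1}" for i in range(k)])
        zeros_c = pd.DataFrame(
            np.zeros((X.shape[1], k)), index=matrix.columns,
            columns=zeros_r.columns)
        return CoaResult(zeros_r, zeros_c, np.zeros(k), 0.0)

    keep = min(max_axes, int((sigma > 1e-12 * sigma[0]).sum()))
    if n_axes is not None:
        keep = min(keep, n_axes)
    U, sigma, Vt = U[:, :keep], sigma[:keep], Vt[:keep, :]

    # principal coordinates
    row_coord = (U * sigma) / np.sqrt(r)[:, None]
    col_coord = (Vt.T * sigma) / np.sqrt(c)[:, None]

    # canonical signs: largest-|loading| column coordinate positive per axis
    for k_ax in range(keep):
        j = int(np.argmax(np.abs(col_coord[:, k_ax])))
        if col_coord[j, k_ax] < 0:
            col_coord[:, k_ax] *= -1
            row_coord[:, k_ax] *= -1

    axes = [f"axis{i+1}" for i in range(keep)]
    return CoaResult(
        row_coordinates=pd.DataFrame(row_coord, index=matrix.index, columns=axes),
        column_coordinates=pd.DataFrame(col_coord, index=matrix.columns, columns=axes),
        inertia_fraction=sigma ** 2 / total_inertia,
        total_inertia=total_inertia,
    )


GC_CLASS_LABELS = ("<45%", "45-60%", ">60%")


def gc_class_labels(gc_values: list[float] | np.ndarray) -> list[str]:
    """GC-content class per gene: [0, 0.45), [0.45, 0.60], (0.60, 1]."""
    out = []
    for gc in np.ravel(gc_values):
        if gc < 0.45:
            out.append(GC_CLASS_LABELS[0])
        elif gc <= 0.60:
            out.append(GC_CLASS_LABELS[1])
        else:
            out.append(GC_CLASS_LABELS[2])
    return out
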