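"""Multivariate and rank statistics used across the analysis.

PCA operates on matrices whose rows are genomes or genes and whose
columns are the 59 RSCU values or the 20 amino-acid frequencies.
Columns are mean-centred but not variance-scaled (RSCU values already
share a scale); the decomposition is by singular values with a
deterministic sign convention.  Spearman correlation and one-way ANOVA
wrap the standard estimators with the significance-star conventions
used in the field (* p<0.05, ** p<0.01, *** p<0.001, two-sided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PcaResult",
    "CorrelationResult",
    "AnovaResult",
    "pca",
    "spearman",
    "one_way_anova",
    "significance_stars",
]


@dataclass
class PcaResult:
    labels: list[str]
    coords: np.ndarray  # rows x components
    explained_fraction: np.ndarray
    loadings: np.ndarray  # components x columns


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class AnovaResult:
    f: float
    p: float
    stars: str


def pca(matrix, labels: Sequence[str] | None = None) -> PcaResult:
    """Principal component analysis by SVD of the mean-centred matrix.

    ``explained_fraction`` is each singular value's share of total
    variance, non-increasing and summing to 1 over all components.  The
    sign of each component is fixed by making its largest-magnitude
    loading positive.  A constant matrix has zero total variance: all
    fractions are defined as 0 and a warning is issued.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    centred = x - x.mean(axis=0)
    if np.allclose(centred, 0.0):
        warnings.warn("constant matrix: zero total variance", stacklevel=2)
        k = min(x.shape)
        return PcaResult(
            labels=list(labels),
            coords=np.zeros((x.shape[0], k)),
            explained_fraction=np.zeros(k),
            loadings=np.zeros((k, x.shape[1])),
        )
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    lam = s**2
    return PcaResult(
        labels=list(labels),
        coords=u * s,
        explained_fraction=lam / lam.sum(),
        loadings=vt,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided p from the t approximation.

    Ties receive average ranks; rho is the Pearson correlation of the
    rank vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(r=float(rho), p=float(p), n=len(x))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def one_way_anova(*groups) -> AnovaResult:
    """One-way ANOVA over two or more groups of values."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input F=0 case
        f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    return AnovaResult(f=float(f), p=float(p), stars=significance_stars(float(p)))
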