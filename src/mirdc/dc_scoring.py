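"""Condition-specific miRNA-mRNA co-expression and the DC score.

Co-expression of gene g_i and miRNA m_j within a condition is the Spearman
coefficient: the Pearson correlation of the two rank vectors (average ranks
on ties), which captures any monotone association and makes the result
invariant to monotone transforms of either profile — so whether expression
was logged upstream is irrelevant here.

The differential co-expression score for a pair is

    s_ij = | T(rho_ij) - T(rho~_ij) |,     T(x) = sqrt((N-3)/1.06) * atanh(x)

the absolute difference of variance-stabilized Fisher z values (the 1.06
factor is the Fieller inflation of the Fisher-z variance for Spearman
coefficients, making Var(T) ~ 1 under independence, so s_ij behaves like
the absolute difference of two standard normals when nothing changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import PairedExpressionStudy

RHO_CLIP = 1.0 - 1e-7        # keeps atanh finite at |rho| = 1
SPEARMAN_VAR_FACTOR = 1.06   # Fieller variance inflation for Spearman z


@dataclass(frozen=True)
class DCScoreMatrix:
    """Per-condition Spearman matrices and the G x M DC score matrix.

    Entries are NaN where a feature was constant within a condition (the
    correlation is undefined there); downstream enrichment means exclude
    them and reduce K accordingly.
    """

    rho_normal: np.ndarray
    rho_diseased: np.ndarray
    s: np.ndarray
    N: int

    @property
    def n_flagged(self) -> int:
        return int(np.isnan(self.s).sum())


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit population sd.

    Rows with zero rank variance (constant features) become NaN rows.
    """
    R = stats.rankdata(X, axis=1, method="average")
    R = R - R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = R / sd[:, None]
    Z[sd == 0.0] = np.nan
    return Z


def spearman_matrix(genes: np.ndarray, mirnas: np.ndarray) -> np.ndarray:
    """All gene-by-miRNA Spearman coefficients within one condition.

    Computed as Pearson correlations of standardized rank vectors via one
    matrix product.  Constant features yield NaN entries (flagged, not 0).
    """
    genes = np.asarray(genes, dtype=float)
    mirnas = np.asarray(mirnas, dtype=float)
    N = genes.shape[1]
    if mirnas.shape[1] != N:
        raise ValueError("gene and miRNA matrices have different sample counts")
    if N < 4:
        raise ValueError("N >= 4 required for correlation estimates")
    Zg = _rank_standardize(genes)
    Zm = _rank_standardize(mirnas)
    rho = Zg @ Zm.T / N
    return np.clip(rho, -1.0, 1.0)


def fisher_transform(x, N: int):
    """Variance-stabilized Fisher z for Spearman correlations.

    T(x) = sqrt((N-3)/1.06) * atanh(x); approximately N(0,1) under the null
    of no correlation.  |x| is clipped just below 1 so T stays finite.
    """
    if N <= 3:
        raise ValueError("Fisher transform requires N > 3")
    x = np.clip(np.asarray(x, dtype=float), -RHO_CLIP, RHO_CLIP)
    out = np.sqrt((N - 3) / SPEARMAN_VAR_FACTOR) * np.arctanh(x)
    return out if out.ndim else float(out)


def dc_scores(rho_normal: np.ndarray, rho_diseased: np.ndarray, N: int) -> np.ndarray:
    """Elementwise |T(rho) - T(rho~)|; symmetric in the two conditions."""
    rho_normal = np.asarray(rho_normal, dtype=float)
    rho_diseased = np.asarray(rho_diseased, dtype=float)
    if rho_normal.shape != rho_diseased.shape:
        raise ValueError("correlation matrices are not conformable")
    return np.abs(fisher_transform(rho_normal, N) - fisher_transform(rho_diseased, N))


def dc_score_matrix(study: PairedExpressionStudy) -> DCScoreMatrix:
    """Full DC scoring of a study: both Spearman matrices plus scores."""
    N = study.N
    rho_n = spearman_matrix(study.genes.normal, study.mirnas.normal)
    rho_d = spearman_matrix(study.genes.diseased, study.mirnas.diseased)
    return DCScoreMatrix(rho_normal=rho_n, rho_diseased=rho_d,
                         s=dc_scores(rho_n, rho_d, N), N=N)
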