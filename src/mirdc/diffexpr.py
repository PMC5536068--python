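"""Paired differential expression with BH FDR and signed fold changes.

The test is a two-tailed paired Student's t on within-pair differences
(diseased minus normal, log2 units) with N-1 degrees of freedom.  The fold
change is reported on the signed-linear convention: 2**d for a mean log2
difference d >= 0, -(2**-d) for d < 0, so |fc| >= 1 always and the sign
tracks the direction of deregulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import PairedExpressionStudy


@dataclass(frozen=True)
class PairedTResult:
    t: np.ndarray
    p: np.ndarray
    mean_diff: np.ndarray
    zero_variance: np.ndarray  # bool mask: p undefined for these features
    df: int


def paired_t(normal: np.ndarray, diseased: np.ndarray) -> PairedTResult:
    """Two-tailed paired t per feature on aligned per-condition matrices.

    Features whose within-pair differences have zero variance are flagged
    (t and p set to NaN) rather than silently assigned 0 or 1.
    """
    normal = np.asarray(normal, dtype=float)
    diseased = np.asarray(diseased, dtype=float)
    if normal.shape != diseased.shape:
        raise ValueError("condition matrices are not conformable")
    N = normal.shape[1]
    if N < 2:
        raise ValueError("paired t needs at least 2 pairs")
    d = diseased - normal
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    zero_var = sd_d == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(N))
    df = N - 1
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, np.nan, p)
    return PairedTResult(t=t, p=p, mean_diff=mean_d, zero_variance=zero_var, df=df)


def fold_change(mean_diff) -> np.ndarray:
    """Signed linear fold change from a mean log2 difference."""
    d = np.asarray(mean_diff, dtype=float)
    fc = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return fc if fc.ndim else float(fc)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def de_table(
    study: PairedExpressionStudy,
    which: str = "genes",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature DE table sorted by p, with BH q and signed fold change.

    The returned frame carries ``.attrs`` with the counts of significant
    features at ``alpha`` (unadjusted p) and the up/down split among them.
    """
    if which not in ("genes", "mirnas"):
        raise ValueError("which must be 'genes' or 'mirnas'")
    table = study.genes if which == "genes" else study.mirnas
    res = paired_t(table.normal, table.diseased)
    q = bh_fdr(res.p)
    fc = fold_change(res.mean_diff)
    df = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "t": res.t,
            "p": res.p,
            "q": q,
            "fc": fc,
            "mean_diff": res.mean_diff,
            "direction": np.where(res.mean_diff >= 0, "up", "down"),
            "zero_variance": res.zero_variance,
        }
    ).sort_values("p", kind="mergesort").reset_index(drop=True)
    sig = df["p"] < alpha
    df.attrs["alpha"] = alpha
    df.attrs["n_significant"] = int(sig.sum())
    df.attrs["n_up"] = int((sig & (df["direction"] == "up")).sum())
    df.attrs["n_down"] = int((sig & (df["direction"] == "down")).sum())
    return df
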