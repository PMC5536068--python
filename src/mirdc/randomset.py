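"""Random-set restandardized gene-set enrichment for differential expression.

Each gene's paired t statistic t_i is mapped to a non-negative score
s_i = |Phi^-1(F_df(t_i))| (F_df the t CDF, Phi the standard normal CDF), so
under the null the scores look like |N(0,1)| draws regardless of df.  A set
of K genes is scored by the restandardized statistic

    Z = sqrt(K (G-1) / (G-K)) * (S_bar - mu) / sigma

with S_bar the mean member score and mu, sigma the mean and population
standard deviation of the full score vector; under random set membership
Z has mean 0 and variance 1 exactly, so large Z signals deregulation.

Significance combines two nulls: the sample-label null is addressed by
within-pair condition swaps (2^N relabelings of the paired design), and the
gene-identity null by recomputing mu and sigma inside every permutation
(restandardization).  The permutation p is one-sided: only large Z counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    DegenerateScoreError,
    GeneSet,
    GeneSetCollection,
    PairedExpressionStudy,
    member_indices,
)
from .diffexpr import bh_fdr

SCORE_CLIP_EPS = 1e-16  # keeps Phi^-1 finite at |t| -> inf
TIE_EPS = 1e-9          # relabelings matching Z_obs up to float noise are ties
DEFAULT_B = 1000


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    K: int
    Z: float
    S_bar: float
    mu: float
    sigma: float
    p_perm: float
    q: float = float("nan")


def gene_scores(t, df: int) -> np.ndarray:
    """Map t statistics to |Phi^-1(F_df(t))| scores, clipped to stay finite.

    NaN t values (zero-variance features with zero mean difference) carry no
    evidence and are scored 0.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.nan_to_num(np.asarray(t, dtype=float), nan=0.0)
    u = stats.t.cdf(t, df=df)
    u = np.clip(u, SCORE_CLIP_EPS, 1.0 - SCORE_CLIP_EPS)
    return np.abs(stats.norm.ppf(u))


def restandardized_z(scores: np.ndarray, member_index) -> tuple[float, float, float, float]:
    """The restandardized set statistic (Z, S_bar, mu, sigma).

    sigma is the population (divide-by-G) standard deviation of the full
    score vector.  Raises DegenerateScoreError when all scores are equal.
    """
    s = np.asarray(scores, dtype=float)
    idx = np.asarray(member_index, dtype=int)
    G = s.size
    K = idx.size
    if not 1 <= K < G:
        raise ValueError(f"need 1 <= K < G, got K={K}, G={G}")
    mu = float(s.mean())
    sigma = float(s.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateScoreError("all gene scores identical; Z undefined")
    S_bar = float(s[idx].mean())
    Z = np.sqrt(K * (G - 1) / (G - K)) * (S_bar - mu) / sigma
    return float(Z), S_bar, mu, sigma


def pair_swap_signs(
    N: int, B: int | None = None, seed: int | None = None, exhaustive: bool = False
) -> np.ndarray:
    """Within-pair relabeling signs: rows of +-1, one entry per subject.

    A -1 swaps the subject's condition labels (negating its paired
    difference).  Exhaustive mode enumerates all 2^N sign vectors, identity
    first; random mode draws B vectors uniformly from the non-identity
    relabelings — the add-one term of the (1+count)/(B+1) estimator already
    stands for the identity, so drawing it again would double-count the
    observed statistic.
    """
    if exhaustive:
        if N > 20:
            raise ValueError("exhaustive enumeration limited to N <= 20")
        codes = np.arange(2**N, dtype=np.uint32)
        bits = (codes[:, None] >> np.arange(N)) & 1
        return 1 - 2 * bits.astype(np.int8)
    if B is None or B < 1:
        raise ValueError("B >= 1 required for random relabelings")
    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([1, -1], dtype=np.int8), size=(B, N))
    identity = (signs == 1).all(axis=1)
    while identity.any():
        signs[identity] = rng.choice(
            np.array([1, -1], dtype=np.int8), size=(int(identity.sum()), N)
        )
        identity = (signs == 1).all(axis=1)
    return signs


def _perm_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t for every sign-flip relabeling at once.

    Sign flips leave sum(d^2) untouched, so the per-relabeling variance is
    (sum(d^2) - N*mean^2)/(N-1) with only the mean recomputed: one matmul.
    Returns a G x B matrix.
    """
    G, N = diffs.shape
    means = diffs @ signs.T.astype(float) / N            # G x B
    sumsq = (diffs**2).sum(axis=1, keepdims=True)        # G x 1
    var = np.maximum(sumsq - N * means**2, 0.0) / (N - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / N)
    # var == 0: all-equal differences; t is +-inf for nonzero mean (score
    # clipping keeps it finite downstream) and 0 for a mean of zero
    t = np.where((var == 0.0) & (means == 0.0), 0.0, t)
    return t


def enrich_collection_de(
    study: PairedExpressionStudy,
    collection: GeneSetCollection,
    B: int = DEFAULT_B,
    seed: int | None = None,
    exhaustive: bool = False,
    df_mode: str = "paired",
) -> pd.DataFrame:
    """DE enrichment of every set in a collection with shared permutations.

    The same relabelings are applied to every set so set-level results are
    comparable.  p is the one-sided permutation estimate (add-one form
    (1+count)/(B+1) for sampled relabelings, the exact enumeration fraction
    in exhaustive mode); q is BH across the collection.

    df_mode selects the score-transform degrees of freedom: "paired" (N-1,
    matching the paired t actually computed) or "two-sample" (2N-2).
    """
    genes = study.genes
    diffs = genes.diseased - genes.normal
    G, N = diffs.shape
    df = (N - 1) if df_mode == "paired" else (2 * N - 2)
    if df_mode not in ("paired", "two-sample"):
        raise ValueError("df_mode must be 'paired' or 'two-sample'")

    t_obs = _perm_t(diffs, np.ones((1, N), dtype=np.int8))[:, 0]
    s_obs = gene_scores(t_obs, df)
    members = {s.name: member_indices(s, genes.feature_ids) for s in collection}
    observed = {name: restandardized_z(s_obs, idx) for name, idx in members.items()}

    signs = pair_swap_signs(N, B=B, seed=seed, exhaustive=exhaustive)
    t_b = _perm_t(diffs, signs)
    s_b = gene_scores(t_b, df)                         # G x B
    mu_b = s_b.mean(axis=0)
    sigma_b = s_b.std(axis=0, ddof=0)
    if (sigma_b == 0.0).any():
        raise DegenerateScoreError("degenerate permutation score vector")

    rows = []
    for gene_set in collection:
        name = gene_set.name
        idx = members[name]
        K = idx.size
        Z, S_bar, mu, sigma = observed[name]
        pref = np.sqrt(K * (G - 1) / (G - K))
        Z_b = pref * (s_b[idx].mean(axis=0) - mu_b) / sigma_b
        count = int((Z_b >= Z - TIE_EPS).sum())
        if exhaustive:
            p = count / signs.shape[0]
        else:
            p = (1 + count) / (signs.shape[0] + 1)
        rows.append(
            EnrichmentResult(set_name=name, K=K, Z=Z, S_bar=S_bar, mu=mu,
                             sigma=sigma, p_perm=p)
        )
    out = pd.DataFrame([vars(r) for r in rows])
    if len(out):
        out["q"] = bh_fdr(out["p_perm"].to_numpy())
    return out


def permutation_p(
    study: PairedExpressionStudy,
    gene_set: GeneSet,
    B: int = DEFAULT_B,
    seed: int | None = None,
    exhaustive: bool = False,
    df_mode: str = "paired",
) -> EnrichmentResult:
    """Restandardized permutation p for a single gene set."""
    collection = GeneSetCollection(sets=(gene_set,))
    df = enrich_collection_de(study, collection, B=B, seed=seed,
                              exhaustive=exhaustive, df_mode=df_mode)
    row = df.iloc[0]
    return EnrichmentResult(
        set_name=row["set_name"], K=int(row["K"]), Z=float(row["Z"]),
        S_bar=float(row["S_bar"]), mu=float(row["mu"]), sigma=float(row["sigma"]),
        p_perm=float(row["p_perm"]), q=float(row["q"]),
    )
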