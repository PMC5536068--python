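"""Pathway enrichment for differential co-expression.

Two statistics share the random-set form.  For a pathway Gamma of K genes
and a single miRNA j,

    Z_j(Gamma) = sqrt(K (G-1) / (G-K)) * (S_bar_j - mu_j) / sigma_j

with S_bar_j the mean DC score of the member genes against miRNA j and
mu_j, sigma_j the column moments over all G genes.  Aggregating over the
whole miRNome of M miRNAs,

    Z(Gamma) = sqrt(K M (G M - 1) / (M (G - K))) * (S_bar - mu) / sigma

with S_bar the mean over the K x M member block and mu, sigma the moments
of the full G x M score matrix.  Since M (G - K) = GM - KM, the miRNome
prefactor is exactly the per-miRNA one with K -> KM and G -> GM, and at
M = 1 the two statistics coincide.

DC scores are used raw: under the no-correlation null T(rho) is already
approximately standard normal, so no quantile re-mapping of s is needed.
Significance comes from within-pair condition swaps with full recomputation
of correlations, scores and moments per relabeling (restandardization); the
same relabelings are shared by every set and miRNA in a run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import (
    DegenerateScoreError,
    GeneSetCollection,
    PairedExpressionStudy,
    member_indices,
)
from .dc_scoring import dc_scores, spearman_matrix
from .diffexpr import bh_fdr
from .randomset import TIE_EPS, pair_swap_signs

DEFAULT_B = 1000
MODE_MIRNA = "mirna"
MODE_MIRNOME = "mirnome"


def _set_stats(s: np.ndarray, idx: np.ndarray):
    """(member means per miRNA, effective K per miRNA) with NaN exclusion."""
    block = s[idx]
    if np.isnan(block).any() or np.isnan(s).any():
        means = np.nanmean(block, axis=0)
        k_eff = (~np.isnan(block)).sum(axis=0)
    else:
        means = block.mean(axis=0)
        k_eff = np.full(s.shape[1], idx.size)
    return means, k_eff


def mirna_pathway_z(s: np.ndarray, idx: np.ndarray, j: int) -> float:
    """Per-miRNA DC enrichment statistic Z_j for one pathway."""
    return float(_mirna_z_all(s, idx)[j])


def _mirna_z_all(s: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Z_j for every miRNA column at once."""
    G = s.shape[0]
    K = idx.size
    if not 1 <= K < G:
        raise ValueError(f"need 1 <= K < G, got K={K}, G={G}")
    mu = np.nanmean(s, axis=0)
    sigma = np.nanstd(s, axis=0, ddof=0)
    if (sigma == 0.0).any():
        raise DegenerateScoreError("constant DC score column; Z undefined")
    means, k_eff = _set_stats(s, idx)
    pref = np.sqrt(k_eff * (G - 1) / (G - k_eff))
    return pref * (means - mu) / sigma


def mirnome_pathway_z(s: np.ndarray, idx: np.ndarray) -> float:
    """miRNome-wide DC enrichment statistic Z for one pathway."""
    G, M = s.shape
    K = idx.size
    if not 1 <= K < G:
        raise ValueError(f"need 1 <= K < G, got K={K}, G={G}")
    mu = np.nanmean(s)
    sigma = np.nanstd(s, ddof=0)
    if sigma == 0.0:
        raise DegenerateScoreError("constant DC score matrix; Z undefined")
    block = s[idx]
    km_eff = int((~np.isnan(block)).sum()) if np.isnan(block).any() else K * M
    S_bar = np.nanmean(block)
    pref = np.sqrt(km_eff * (G * M - 1) / (G * M - km_eff))
    return float(pref * (S_bar - mu) / sigma)


def _score_matrix_for_relabeling(
    gene_n, gene_d, mirna_n, mirna_d, swap: np.ndarray, N: int
) -> np.ndarray:
    """DC score matrix after swapping conditions for the flagged subjects."""
    w = swap[None, :]
    gn = np.where(w, gene_d, gene_n)
    gd = np.where(w, gene_n, gene_d)
    mn = np.where(w, mirna_d, mirna_n)
    md = np.where(w, mirna_n, mirna_d)
    rho_n = spearman_matrix(gn, mn)
    rho_d = spearman_matrix(gd, md)
    return dc_scores(rho_n, rho_d, N)


def enrich_collection_dc(
    study: PairedExpressionStudy,
    collection: GeneSetCollection,
    mode: str = MODE_MIRNOME,
    B: int = DEFAULT_B,
    seed: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """DC enrichment of a collection in per-miRNA or miRNome mode.

    Every relabeling recomputes both condition-specific Spearman matrices,
    the DC scores and the score moments from scratch; the identical set of
    relabelings is applied to every (set, miRNA) pair.  p is one-sided
    (large Z); BH corrects across sets (miRNome mode) or across all
    set x miRNA pairs (per-miRNA mode).
    """
    if mode not in (MODE_MIRNA, MODE_MIRNOME):
        raise ValueError(f"mode must be '{MODE_MIRNA}' or '{MODE_MIRNOME}'")
    genes, mirnas = study.genes, study.mirnas
    N = study.N
    members = {gs.name: member_indices(gs, genes.feature_ids) for gs in collection}

    s_obs = _score_matrix_for_relabeling(
        genes.normal, genes.diseased, mirnas.normal, mirnas.diseased,
        np.zeros(N, dtype=bool), N,
    )
    if mode == MODE_MIRNA:
        Z_obs = {name: _mirna_z_all(s_obs, idx) for name, idx in members.items()}
    else:
        Z_obs = {name: mirnome_pathway_z(s_obs, idx) for name, idx in members.items()}

    signs = pair_swap_signs(N, B=B, seed=seed, exhaustive=exhaustive)
    swaps = signs == -1
    counts = {name: np.zeros_like(np.asarray(z, dtype=float)) for name, z in Z_obs.items()}
    for b in range(swaps.shape[0]):
        s_b = _score_matrix_for_relabeling(
            genes.normal, genes.diseased, mirnas.normal, mirnas.diseased,
            swaps[b], N,
        )
        if mode == MODE_MIRNA:
            for name, idx in members.items():
                counts[name] += _mirna_z_all(s_b, idx) >= Z_obs[name] - TIE_EPS
        else:
            for name, idx in members.items():
                counts[name] += mirnome_pathway_z(s_b, idx) >= Z_obs[name] - TIE_EPS

    n_perm = swaps.shape[0]

    def pval(count):
        return count / n_perm if exhaustive else (1 + count) / (n_perm + 1)

    rows = []
    if mode == MODE_MIRNA:
        for gene_set in collection:
            name = gene_set.name
            for j, mirna_id in enumerate(mirnas.feature_ids):
                rows.append({
                    "set_name": name,
                    "mirna_id": mirna_id,
                    "K": int(members[name].size),
                    "Z": float(Z_obs[name][j]),
                    "p_perm": pval(counts[name][j]),
                })
    else:
        for gene_set in collection:
            name = gene_set.name
            rows.append({
                "set_name": name,
                "mirna_id": "ALL",
                "K": int(members[name].size),
                "Z": float(Z_obs[name]),
                "p_perm": pval(float(counts[name])),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p_perm"].to_numpy())
    out.attrs["mode"] = mode
    out.attrs["n_perm"] = n_perm
    out.attrs["bh_family"] = (
        "set x miRNA pairs" if mode == MODE_MIRNA else "sets"
    )
    return out


def attach_dc_mirnas(
    mirnome_results: pd.DataFrame,
    per_mirna_results: pd.DataFrame,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Annotate set-level records with the miRNAs DC with each set.

    A miRNA counts as DC with a pathway when its per-miRNA enrichment p is
    below ``threshold``.
    """
    sig = per_mirna_results[per_mirna_results["p_perm"] < threshold]
    by_set = sig.groupby("set_name")["mirna_id"].apply(
        lambda ids: ";".join(sorted(ids))
    )
    out = mirnome_results.copy()
    out["dc_mirnas"] = out["set_name"].map(by_set).fillna("")
    return out
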