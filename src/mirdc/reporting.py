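"""Integrative reporting: DE/DC overlap, miRNA ranking and validation.

Given the pathway-level DE enrichment and the DC enrichment results, this
module quantifies how strongly the two views agree (Fisher's exact overlap
test against the expected-by-chance count), ranks miRNAs by the number of
deregulated pathways they are differentially co-expressed with, and checks
whether a user-supplied list of disease-associated miRNAs is enriched among
the top-ranked ones (rank-sum test) or among the DE miRNAs (Fisher).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapTable:
    universe: int
    n_de: int
    n_dc: int
    n_both: int
    odds_ratio: float
    p_fisher: float

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.n_both, self.n_de - self.n_both],
            [self.n_dc - self.n_both,
             self.universe - self.n_de - self.n_dc + self.n_both],
        ]


def expected_significant(n_sets: int, alpha: float) -> int:
    """Sets expected significant by chance under a global null: round(n*alpha)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return int(round(n_sets * alpha))


def overlap_fisher(universe: int, n_de: int, n_dc: int, n_both: int) -> OverlapTable:
    """One-sided (enrichment) Fisher's exact test for DE/DC list overlap."""
    if n_both > min(n_de, n_dc) or max(n_de, n_dc, n_both) > universe:
        raise ValueError("inconsistent overlap counts")
    if universe - n_de - n_dc + n_both < 0:
        raise ValueError("inconsistent overlap counts")
    table = [
        [n_both, n_de - n_both],
        [n_dc - n_both, universe - n_de - n_dc + n_both],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return OverlapTable(universe=universe, n_de=n_de, n_dc=n_dc, n_both=n_both,
                        odds_ratio=float(odds), p_fisher=float(p))


def rank_mirnas_by_de_pathways(
    dc_results: pd.DataFrame,
    de_results: pd.DataFrame,
    alpha_dc: float = 0.01,
    alpha_de: float = 0.01,
) -> pd.DataFrame:
    """Rank miRNAs by how many DE pathways they are DC with.

    For each miRNA the count is over pathways with DE enrichment
    p < alpha_de whose per-miRNA DC enrichment p < alpha_dc.  Sorted by
    count descending, ties broken by miRNA id.  Both result frames must
    come from the same collection.
    """
    dc_sets = set(dc_results["set_name"])
    de_sets = set(de_results["set_name"])
    if dc_sets != de_sets:
        raise ValueError(
            "DC and DE results cover different collections: "
            f"{sorted(dc_sets ^ de_sets)[:5]} ..."
        )
    de_sig = set(de_results.loc[de_results["p_perm"] < alpha_de, "set_name"])
    hits = dc_results[
        (dc_results["p_perm"] < alpha_dc) & dc_results["set_name"].isin(de_sig)
    ]
    counts = hits.groupby("mirna_id").size()
    all_mirnas = sorted(dc_results["mirna_id"].unique())
    out = pd.DataFrame({
        "mirna_id": all_mirnas,
        "n_de_pathways": [int(counts.get(m, 0)) for m in all_mirnas],
    })
    out = out.sort_values(
        ["n_de_pathways", "mirna_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def validate_known_mirnas(
    ranked_counts: pd.DataFrame,
    known: list[str],
    de_mirnas: set[str] | None = None,
    n_resamples: int = 0,
    seed: int | None = None,
) -> dict:
    """Test whether known disease miRNAs rank high and/or are DE.

    The primary test is a one-sided Wilcoxon rank-sum comparing the
    DE-pathway counts of the known miRNAs against all remaining miRNAs
    (the deterministic limit of comparing against random miRNA lists of the
    same size; set ``n_resamples`` > 0 for the explicit Monte-Carlo
    variant).  If ``de_mirnas`` is given, a one-sided Fisher's exact test of
    the known-list/DE-list overlap is also reported.
    """
    counts = ranked_counts.set_index("mirna_id")["n_de_pathways"]
    matched = [m for m in known if m in counts.index]
    unmatched = sorted(set(known) - set(matched))
    if not matched:
        raise ValueError("no known miRNAs match the assayed miRNA ids")
    rest = counts.index.difference(matched)
    result: dict = {"n_known_matched": len(matched), "unmatched": unmatched}
    if len(rest) == 0:
        result["wilcoxon_p"] = float("nan")
        result["degenerate"] = "known list covers all assayed miRNAs"
        return result
    x = counts.loc[matched].to_numpy(dtype=float)
    y = counts.loc[rest].to_numpy(dtype=float)
    result["wilcoxon_p"] = float(
        stats.mannwhitneyu(x, y, alternative="greater").pvalue
    )
    if n_resamples > 0:
        rng = np.random.default_rng(seed)
        obs = x.mean()
        pool = counts.to_numpy(dtype=float)
        hits = sum(
            rng.choice(pool, size=len(matched), replace=False).mean() >= obs
            for _ in range(n_resamples)
        )
        result["resampling_p"] = (1 + hits) / (n_resamples + 1)
    if de_mirnas is not None:
        universe = len(counts)
        k = len(set(matched) & de_mirnas)
        table = [
            [k, len(matched) - k],
            [len(de_mirnas & set(counts.index)) - k,
             universe - len(matched) - len(de_mirnas & set(counts.index)) + k],
        ]
        result["fisher_de_p"] = float(
            stats.fisher_exact(table, alternative="greater")[1]
        )
    return result


def plot_pvalue_histograms(de_results: pd.DataFrame, dc_results: pd.DataFrame,
                           path) -> None:
    """Side-by-side histograms of DE and DC enrichment p-values.

    A pileup near 0 relative to the flat null profile is the visual
    counterpart of the expected-by-chance comparison.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, res, label in ((axes[0], de_results, "DE enrichment"),
                           (axes[1], dc_results, "DC enrichment")):
        ax.hist(res["p_perm"], bins=20, range=(0, 1), color="steelblue",
                edgecolor="white")
        ax.axhline(len(res) / 20, color="grey", linestyle="--", linewidth=1)
        ax.set_xlabel("permutation p-value")
        ax.set_title(label)
    axes[0].set_ylabel("gene sets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mirna_ranking(ranking: pd.DataFrame, path, top: int = 20) -> None:
    """Horizontal bar chart of the miRNAs linked to most DE pathways."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    head = ranking.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(head) + 1.2))
    ax.barh(head["mirna_id"], head["n_de_pathways"], color="firebrick")
    ax.set_xlabel("DE pathways linked by differential co-expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
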