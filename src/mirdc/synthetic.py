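"""Synthetic paired two-condition studies with planted signal.

Emulates the structure of a paired inflamed/non-inflamed expression study:
N subjects each contribute one sample per condition, expression is on a log
scale, and pairing is mimicked with a per-subject random intercept shared by
the two conditions.  On top of that null backbone the generator can plant

* differential expression: an additive condition shift on chosen features;
* differential co-expression: for a (pathway, miRNA) pair, the pathway's
  member genes are generated as ``c * z_m + sqrt(1 - c^2) * eps`` on the
  latent Gaussian scale, where ``z_m`` is the miRNA's standardized value and
  ``c`` the condition-specific coupling — so the within-condition
  correlation changes between conditions while the marginal variance stays
  constant.  Spearman's rho of a bivariate Gaussian with latent correlation
  r is (6/pi)*asin(r/2) (``latent_to_spearman``), which recovery tests use
  to translate planted couplings into expected rank correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    GeneSet,
    GeneSetCollection,
    PairedExpressionStudy,
    study_from_arrays,
)

DEFAULT_NOISE_SD = 1.0
# intercept sd as a fraction of noise_sd; 0.5 gives within-subject
# correlation 0.2, a mild paired-design dependence
DEFAULT_INTERCEPT_RATIO = 0.5
BASELINE_MEAN = 8.0   # typical log2 microarray intensity
BASELINE_SD = 1.0


@dataclass(frozen=True)
class DCPair:
    """A planted differential-co-expression pair."""

    pathway: str
    mirna: str
    coupling_normal: float
    coupling_diseased: float

    def __post_init__(self) -> None:
        for c in (self.coupling_normal, self.coupling_diseased):
            if not -1.0 < c < 1.0:
                raise ValueError(f"coupling must be in (-1, 1), got {c}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted signal: DE features with signed log-unit effects and DC pairs."""

    de_genes: dict[str, float] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    dc_pairs: tuple[DCPair, ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def latent_to_spearman(r: float) -> float:
    """Population Spearman rho of a bivariate Gaussian with correlation r."""
    return (6.0 / math.pi) * math.asin(r / 2.0)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _null_block(rng, n_features, N, noise_sd, intercept_sd, baseline=None):
    """Paired-condition pair of matrices sharing a subject intercept."""
    if baseline is None:
        baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=(n_features, 1))
    intercept = rng.normal(0.0, intercept_sd, size=(n_features, N))
    normal = baseline + intercept + rng.normal(0.0, noise_sd, size=(n_features, N))
    diseased = baseline + intercept + rng.normal(0.0, noise_sd, size=(n_features, N))
    return normal, diseased


def generate_null_study(
    G: int,
    M: int,
    N: int,
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    intercept_sd: float | None = None,
) -> PairedExpressionStudy:
    """A study with no condition effect and no miRNA-gene coupling.

    Entries are Gaussian noise around a per-feature baseline plus a
    per-subject random intercept shared by the two conditions (so the paired
    design's within-subject correlation is present but within-pair
    differences are pure noise).  Deterministic given ``seed``.
    """
    if G < 2 or M < 2:
        raise ValueError("G and M must be >= 2")
    if N < 4:
        raise ValueError("N must be >= 4")
    if intercept_sd is None:
        intercept_sd = DEFAULT_INTERCEPT_RATIO * noise_sd
    rng = np.random.default_rng(seed)
    gn, gd = _null_block(rng, G, N, noise_sd, intercept_sd)
    mn, md = _null_block(rng, M, N, noise_sd, intercept_sd)
    return study_from_arrays(gn, gd, mn, md, _ids("g", G), _ids("mir-", M))


def generate_planted_study(
    G: int,
    M: int,
    N: int,
    truth: SyntheticTruth,
    collection: GeneSetCollection,
    intercept_sd: float | None = None,
) -> tuple[PairedExpressionStudy, SyntheticTruth]:
    """A null backbone with the truth's DE shifts and DC couplings planted.

    DC-planted member genes are regenerated from the coupled miRNA's
    standardized per-condition values, scaled so their marginal standard
    deviation equals sqrt(intercept_sd^2 + noise_sd^2) like every other
    feature; their pairing correlation is inherited through the miRNA's
    subject intercept instead of an intercept of their own.  Planted
    pathways must be disjoint so recovery is unambiguous.
    """
    noise_sd = truth.noise_sd
    if intercept_sd is None:
        intercept_sd = DEFAULT_INTERCEPT_RATIO * noise_sd
    total_sd = math.hypot(noise_sd, intercept_sd)
    rng = np.random.default_rng(truth.seed)

    gene_ids = _ids("g", G)
    mirna_ids = _ids("mir-", M)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    mirna_index = {m: j for j, m in enumerate(mirna_ids)}

    gn, gd = _null_block(rng, G, N, noise_sd, intercept_sd)
    mn, md = _null_block(rng, M, N, noise_sd, intercept_sd)

    # DE shifts (diseased minus normal, log units)
    for fid, effect in truth.de_genes.items():
        gd[gene_index[fid]] += effect
    for fid, effect in truth.de_mirnas.items():
        md[mirna_index[fid]] += effect

    claimed: set[str] = set()
    for pair in truth.dc_pairs:
        try:
            gene_set = collection[pair.pathway]
        except KeyError:
            raise ValueError(f"planted pathway {pair.pathway!r} absent from collection")
        members = sorted(m for m in gene_set.members if m in gene_index)
        overlap = claimed.intersection(members)
        if overlap:
            raise ValueError(
                f"planted pathways overlap on genes {sorted(overlap)[:5]}; "
                "disjoint pathways are required for unambiguous recovery"
            )
        claimed.update(members)
        j = mirna_index[pair.mirna]
        for cond_mat, gene_mat, c in (
            (mn, gn, pair.coupling_normal),
            (md, gd, pair.coupling_diseased),
        ):
            m = cond_mat[j]
            z = (m - m.mean()) / m.std()
            for gid in members:
                i = gene_index[gid]
                baseline = gene_mat[i].mean()
                eps = rng.normal(0.0, 1.0, size=N)
                latent = c * z + math.sqrt(1.0 - c * c) * eps
                shift = truth.de_genes.get(gid, 0.0) if cond_mat is md else 0.0
                gene_mat[i] = baseline + shift + total_sd * latent

    study = study_from_arrays(gn, gd, mn, md, gene_ids, mirna_ids)
    return study, truth


def generate_collection(
    n_sets: int,
    sizes: range | tuple[int, int],
    universe: list[str],
    seed: int,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene sets sampled without replacement within each set."""
    if isinstance(sizes, tuple):
        sizes = range(sizes[0], sizes[1] + 1)
    if len(sizes) and max(sizes) > len(universe) - 1:
        raise ValueError("max set size must be <= |universe| - 1")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(sizes.start, sizes.stop))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(
            GeneSet(name=f"{prefix}{k:03d}", description="synthetic",
                    members=frozenset(members.tolist()))
        )
    return GeneSetCollection(sets=tuple(sets), source=f"synthetic(seed={seed})")


def write_study(study: PairedExpressionStudy, out_dir, prefix: str = "") -> dict:
    """Write gene/miRNA TSVs and metadata TSV; returns the paths written."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, table in (("genes", study.genes), ("mirnas", study.mirnas)):
        cols = table.sample_ids_normal + table.sample_ids_diseased
        df = pd.DataFrame(
            np.hstack([table.normal, table.diseased]),
            index=pd.Index(table.feature_ids, name="feature_id"),
            columns=cols,
        )
        path = out / f"{prefix}{tag}.tsv"
        df.to_csv(path, sep="\t")
        paths[tag] = path
    meta_rows = []
    for table_tag, table in (("g", study.genes),):
        for cond, ids in (("normal", table.sample_ids_normal),
                          ("diseased", table.sample_ids_diseased)):
            for pid, sid in zip(table.pair_ids, ids):
                meta_rows.append({"sample_id": sid, "condition": cond, "pair_id": pid})
    # miRNA table has its own sample ids; append them with the same pairing
    for cond, ids in (("normal", study.mirnas.sample_ids_normal),
                      ("diseased", study.mirnas.sample_ids_diseased)):
        for pid, sid in zip(study.mirnas.pair_ids, ids):
            meta_rows.append({"sample_id": sid, "condition": cond, "pair_id": pid})
    meta = pd.DataFrame(meta_rows).drop_duplicates()
    meta_path = out / f"{prefix}metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    return paths
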