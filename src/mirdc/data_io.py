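"""Data model and readers for paired two-condition expression studies.

The pipeline operates on a *paired* design: each of N subjects contributes
one sample per phenotypic condition (``diseased`` and ``normal``), giving 2N
samples.  Expression matrices are features x samples on a log scale and are
assumed already normalized; missing values are rejected at ingestion because
every downstream statistic (paired t, rank correlation) is ill-defined with
holes in the data and silent imputation would change every result.

Gene sets are read from GMT (one set per line: name, description, members,
tab-separated), the dialect used by MSigDB collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITION_DISEASED = "diseased"
CONDITION_NORMAL = "normal"
CONDITIONS = (CONDITION_NORMAL, CONDITION_DISEASED)


class ValidationError(ValueError):
    """Base class for ingestion/validation failures."""


class UnpairedSampleError(ValidationError):
    """A subject does not have exactly one sample per condition."""


class DuplicateFeatureError(ValidationError):
    """A feature identifier occurs more than once in an expression table."""


class MissingValueError(ValidationError):
    """A non-numeric or missing cell was found in an expression table."""


class UnknownSampleError(ValidationError):
    """A sample column is absent from the metadata (or vice versa)."""


class GMTFormatError(ValidationError):
    """A GMT line does not have the required name/description/members fields."""


class DuplicateSetNameError(ValidationError):
    """Two gene sets in one collection share a name."""


class DegenerateScoreError(ValueError):
    """All scores identical: the restandardized statistic is undefined."""


@dataclass(frozen=True)
class ExpressionTable:
    """A validated single-omic matrix in canonical sample order.

    Columns are ordered by (pair_id, condition) with the normal sample of
    each pair first, so ``values[:, :N]`` would interleave pairs; instead the
    two per-condition views are exposed directly, aligned pair-by-pair.
    """

    feature_ids: list[str]
    pair_ids: list[str]          # length N, sorted
    normal: np.ndarray           # features x N
    diseased: np.ndarray         # features x N
    sample_ids_normal: list[str]
    sample_ids_diseased: list[str]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


@dataclass(frozen=True)
class PairedExpressionStudy:
    """Paired gene and miRNA expression matrices with aligned subjects.

    Invariants enforced at construction: both omics cover the same subjects,
    every pair_id occurs exactly once per condition, feature ids are unique,
    and no value is missing.  N >= 4 is required by correlation-based stages
    (the Fisher transform needs N > 3) but smaller N is allowed here so the
    differential-expression stage can run on minimal designs.
    """

    genes: ExpressionTable
    mirnas: ExpressionTable

    def __post_init__(self) -> None:
        if self.genes.pair_ids != self.mirnas.pair_ids:
            raise UnpairedSampleError(
                "gene and miRNA tables cover different subjects: "
                f"{self.genes.pair_ids} vs {self.mirnas.pair_ids}"
            )

    @property
    def G(self) -> int:
        return self.genes.n_features

    @property
    def M(self) -> int:
        return self.mirnas.n_features

    @property
    def N(self) -> int:
        return self.genes.n_pairs

    @property
    def gene_ids(self) -> list[str]:
        return self.genes.feature_ids

    @property
    def mirna_ids(self) -> list[str]:
        return self.mirnas.feature_ids

    def swap_conditions(self) -> "PairedExpressionStudy":
        """Relabel diseased as normal and vice versa (for symmetry checks)."""
        return PairedExpressionStudy(
            genes=replace(
                self.genes,
                normal=self.genes.diseased,
                diseased=self.genes.normal,
                sample_ids_normal=self.genes.sample_ids_diseased,
                sample_ids_diseased=self.genes.sample_ids_normal,
            ),
            mirnas=replace(
                self.mirnas,
                normal=self.mirnas.diseased,
                diseased=self.mirnas.normal,
                sample_ids_normal=self.mirnas.sample_ids_diseased,
                sample_ids_diseased=self.mirnas.sample_ids_normal,
            ),
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    @property
    def K(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateSetNameError(f"duplicate gene-set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample_id, condition, pair_id."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "condition", "pair_id"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    return meta


def validate_metadata(meta: pd.DataFrame, check_pairing: bool = True) -> pd.DataFrame:
    """Normalize and validate sample annotations.

    Pairing (exactly one sample per condition per subject) is checked only
    when ``check_pairing`` is set: a metadata file may legitimately annotate
    the gene and miRNA matrices' samples together, in which case pairing is
    validated per matrix after subsetting to its columns.
    """
    meta = meta.copy()
    for col in ("sample_id", "condition", "pair_id"):
        meta[col] = meta[col].astype(str).str.strip()
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(
            f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
        )
    if check_pairing:
        counts = meta.groupby("pair_id")["condition"].agg(list)
        for pid, conds in counts.items():
            if sorted(conds) != sorted(CONDITIONS):
                raise UnpairedSampleError(
                    f"subject {pid!r} has conditions {conds}; "
                    "each pair_id needs exactly one sample per condition"
                )
    return meta


def _table_from_frame(df: pd.DataFrame, meta: pd.DataFrame) -> ExpressionTable:
    meta = validate_metadata(meta, check_pairing=False)
    feature_ids = [str(f).strip() for f in df.index]
    if len(feature_ids) != len(set(feature_ids)):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise DuplicateFeatureError(f"duplicate feature ids: {dupes}")

    sample_ids = [str(c).strip() for c in df.columns]
    known = set(meta["sample_id"])
    extra = [s for s in sample_ids if s not in known]
    if extra:
        raise UnknownSampleError(f"samples in matrix absent from metadata: {extra}")
    meta = meta[meta["sample_id"].isin(sample_ids)]
    validate_metadata(meta)  # re-check pairing on the retained samples

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        values = pd.DataFrame(df).apply(pd.to_numeric, errors="coerce").to_numpy()
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise MissingValueError(
            f"{n_bad} missing/non-numeric cells; ingestion rejects missing "
            "values (impute upstream if needed)"
        )

    col_of = {s: i for i, s in enumerate(sample_ids)}
    pair_ids = sorted(meta["pair_id"].unique())
    by_cond = {
        cond: meta[meta["condition"] == cond].set_index("pair_id")["sample_id"]
        for cond in CONDITIONS
    }
    ids_n = [by_cond[CONDITION_NORMAL][p] for p in pair_ids]
    ids_d = [by_cond[CONDITION_DISEASED][p] for p in pair_ids]
    normal = values[:, [col_of[s] for s in ids_n]]
    diseased = values[:, [col_of[s] for s in ids_d]]
    return ExpressionTable(
        feature_ids=feature_ids,
        pair_ids=pair_ids,
        normal=normal,
        diseased=diseased,
        sample_ids_normal=ids_n,
        sample_ids_diseased=ids_d,
    )


def read_expression_table(path, metadata: pd.DataFrame) -> ExpressionTable:
    """Read a features-x-samples TSV and return a validated, pair-aligned table.

    The first column holds feature ids, the header row sample ids.  Columns
    are reordered canonically (pairs sorted by pair_id, normal/diseased
    aligned), so the result is invariant to the column order on disk.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    return _table_from_frame(df, metadata)


def load_study(gene_path, mirna_path, metadata_path) -> PairedExpressionStudy:
    """Read gene and miRNA TSVs plus metadata into a PairedExpressionStudy."""
    meta = read_metadata(metadata_path)
    genes = read_expression_table(gene_path, meta)
    mirnas = read_expression_table(mirna_path, meta)
    return PairedExpressionStudy(genes=genes, mirnas=mirnas)


def study_from_arrays(
    gene_normal, gene_diseased, mirna_normal, mirna_diseased,
    gene_ids=None, mirna_ids=None, pair_ids=None,
) -> PairedExpressionStudy:
    """Build a study directly from per-condition arrays (testing/simulation)."""
    gene_normal = np.asarray(gene_normal, dtype=float)
    gene_diseased = np.asarray(gene_diseased, dtype=float)
    mirna_normal = np.asarray(mirna_normal, dtype=float)
    mirna_diseased = np.asarray(mirna_diseased, dtype=float)
    G, N = gene_normal.shape
    M = mirna_normal.shape[0]
    if gene_diseased.shape != (G, N) or mirna_diseased.shape != (M, N):
        raise ValidationError("per-condition arrays are not conformable")
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i:04d}" for i in range(G)]
    mirna_ids = list(mirna_ids) if mirna_ids is not None else [f"mir-{j:03d}" for j in range(M)]
    pair_ids = list(pair_ids) if pair_ids is not None else [f"subj{k:02d}" for k in range(N)]
    for arr, ids in ((gene_normal, gene_ids), (mirna_normal, mirna_ids)):
        if len(ids) != arr.shape[0] or len(ids) != len(set(ids)):
            raise DuplicateFeatureError("feature ids must be unique and match rows")

    def table(normal, diseased, ids, tag):
        return ExpressionTable(
            feature_ids=ids,
            pair_ids=pair_ids,
            normal=normal,
            diseased=diseased,
            sample_ids_normal=[f"{p}_{tag}_n" for p in pair_ids],
            sample_ids_diseased=[f"{p}_{tag}_d" for p in pair_ids],
        )

    return PairedExpressionStudy(
        genes=table(gene_normal, gene_diseased, gene_ids, "g"),
        mirnas=table(mirna_normal, mirna_diseased, mirna_ids, "m"),
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member ids, tab-separated.

    Duplicate members within one line are collapsed; duplicate set names
    across lines are an error.  Empty files yield an empty collection.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise GMTFormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name.strip(), description=desc,
                                members=frozenset(members)))
    return GeneSetCollection(sets=tuple(sets), source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def map_collection_to_study(
    collection: GeneSetCollection,
    study: PairedExpressionStudy,
    min_size: int = 5,
    max_size: int | None = None,
) -> GeneSetCollection:
    """Intersect each set with the assayed genes and drop unusable sets.

    Sets with K < min_size, K > max_size, or K = G are dropped: tiny sets
    make the random-set moments unstable and a set equal to the whole gene
    universe has a zero G-K denominator in the restandardized statistic.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    assayed = set(study.gene_ids)
    G = study.G
    if max_size is None:
        max_size = G - 1
    kept, dropped = [], []
    for s in collection:
        members = frozenset(m for m in s.members if m in assayed)
        K = len(members)
        if K < min_size or K > max_size or K == G:
            dropped.append((s.name, K))
            continue
        kept.append(GeneSet(name=s.name, description=s.description, members=members))
    if dropped:
        logger.info(
            "map_collection_to_study: dropped %d/%d sets (size out of [%d, %d]): %s",
            len(dropped), len(collection), min_size, max_size,
            ", ".join(f"{n}(K={k})" for n, k in dropped[:10]),
        )
    return GeneSetCollection(sets=tuple(kept), source=collection.source)


def member_indices(gene_set: GeneSet, gene_ids: list[str]) -> np.ndarray:
    """Row indices of a set's members in the study's gene order."""
    index = {g: i for i, g in enumerate(gene_ids)}
    return np.array(sorted(index[m] for m in gene_set.members if m in index), dtype=int)


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a TSV with an optional '#'-prefixed provenance comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
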