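import numpy as np
import pandas as pd
import pytest

from mirdc import (
    GeneSet,
    GeneSetCollection,
    generate_null_study,
    study_from_arrays,
)


@pytest.fixture
def tiny_study():
    """A deterministic 6-gene, 3-miRNA, 5-pair study with mild structure."""
    rng = np.random.default_rng(42)
    gn = rng.normal(8, 1, size=(6, 5))
    gd = gn + rng.normal(0.0, 1, size=(6, 5))
    mn = rng.normal(8, 1, size=(3, 5))
    md = mn + rng.normal(0.0, 1, size=(3, 5))
    return study_from_arrays(gn, gd, mn, md)


@pytest.fixture
def null_study():
    return generate_null_study(G=60, M=8, N=8, seed=7)


@pytest.fixture
def small_collection(null_study):
    members = null_study.gene_ids
    return GeneSetCollection(
        sets=(
            GeneSet("SA", "", frozenset(members[:10])),
            GeneSet("SB", "", frozenset(members[10:25])),
            GeneSet("SC", "", frozenset(members[25:33])),
        )
    )


def write_expression_tsv(path, feature_ids, sample_ids, values):
    df = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                      columns=sample_ids)
    df.to_csv(path, sep="\t")
    return path


def write_metadata_tsv(path, rows):
    pd.DataFrame(rows, columns=["sample_id", "condition", "pair_id"]).to_csv(
        path, sep="\t", index=False
    )
    return path
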