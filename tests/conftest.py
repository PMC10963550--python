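import numpy as np
import pandas as pd
import pytest

import tmehot as th


@pytest.fixture(scope="session")
def small_atlas():
    """3 generic clusters, 50 cells each, 200 genes, fold-4 markers."""
    return th.simulate_cell_atlas(3, 50, 200, 10, 4.0, seed=1)


@pytest.fixture(scope="session")
def default_atlas():
    """The full cluster grid the scoring module expects (smaller cells/genes)."""
    return th.simulate_cell_atlas(
        th.DEFAULT_CLUSTER_LINEAGE, 40, 800, 10, 4.0, seed=0
    )


@pytest.fixture(scope="session")
def default_atlas_markers(default_atlas):
    expr, ann, truth = default_atlas
    lognorm = th.lognormalize(expr)
    mt = th.find_markers(lognorm, ann)
    return lognorm, ann, truth, mt


@pytest.fixture(scope="session")
def planted_signatures(default_atlas):
    """Signatures taken directly from the planted ground truth."""
    _, _, truth = default_atlas
    sets = dict(truth.planted_markers)
    sets["NK"] = (
        truth.planted_markers["NK_GNLY"] + truth.planted_markers["NK_FCGR3A"]
    )
    return th.SignatureSet(sets)


@pytest.fixture
def toy_survival():
    """6 subjects, all events, two clearly separated groups."""
    surv = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
        },
        index=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(
        ["A", "A", "A", "B", "B", "B"], index=surv.index, name="group"
    )
    return surv, groups


def make_enrichment(rows: dict[str, list[float]], samples=None) -> th.EnrichmentMatrix:
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    return th.EnrichmentMatrix(df, alpha=0.25, normalized=True)
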