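import numpy as np
import pandas as pd
import pytest

import iggsca as ig
from iggsca.model_spec import ConstructDef, PathModel


@pytest.fixture(scope="session")
def gene_map():
    return ig.load_gene_map()


@pytest.fixture(scope="session")
def roi_map():
    return ig.load_roi_map()


@pytest.fixture(scope="session")
def study_model(gene_map, roi_map):
    return ig.build_study_model(gene_map, roi_map)


@pytest.fixture(scope="session")
def small_roi_map(roi_map):
    """Five-ROI reduction of the study ROI map for fast simulations; keeps
    the three mediating ROIs of the default planted-path set."""
    return roi_map.subset(["ACgG", "CO", "OFuG", "FRP", "SFG"])


@pytest.fixture(scope="session")
def small_model(gene_map, small_roi_map):
    return ig.build_study_model(gene_map, small_roi_map)


def chain_model(names=("X", "M", "Y")):
    """Single-indicator chain X -> M -> Y."""
    constructs = tuple(
        ConstructDef(n, "outcome" if i == len(names) - 1 else "observed", (n.lower(),))
        for i, n in enumerate(names)
    )
    edges = tuple(zip(names[:-1], names[1:]))
    return PathModel(constructs=constructs, edges=edges)


def multi_predictor_model(n_pred=2):
    """Single-indicator model X1..Xk -> Y."""
    preds = [f"X{i}" for i in range(1, n_pred + 1)]
    constructs = tuple(
        [ConstructDef(p, "observed", (p.lower(),)) for p in preds]
        + [ConstructDef("Y", "outcome", ("y",))]
    )
    edges = tuple((p, "Y") for p in preds)
    return PathModel(constructs=constructs, edges=edges)


def gaussian_table(model, corr, n, seed):
    """Raw data for a single-indicator model with a given correlation matrix."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.asarray(corr))
    X = rng.standard_normal((n, L.shape[0])) @ L.T
    return pd.DataFrame(X, columns=model.indicator_names)
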