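"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk except
files the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snr.io import DataDictionary, Dimension, Experiment
from snr.synthgen import SynthConfig, generate_collection, generate_go_annotation

STANDARD_DIMS = (
    Dimension("EnsemblID", "identifier", "Ensembl gene identifier"),
    Dimension("geneName", "categorical", "gene symbol"),
    Dimension("baseMean", "numeric", "mean normalized expression"),
    Dimension("foldChange", "numeric", "log2 fold change"),
    Dimension("pValue", "numeric", "DE test p-value"),
)


def make_dictionary(dims=STANDARD_DIMS) -> DataDictionary:
    return DataDictionary(tuple(dims))


def make_experiment(
    eid: str,
    genes,
    foldChange=None,
    pValue=None,
    baseMean=None,
    geneName=None,
    visibility: str = "private",
    title: str = "",
) -> Experiment:
    n = len(genes)
    frame = pd.DataFrame(
        {
            "EnsemblID": list(genes),
            "geneName": list(geneName) if geneName is not None else [f"g{i}" for i in range(n)],
            "baseMean": np.asarray(baseMean if baseMean is not None else np.ones(n), dtype=float),
            "foldChange": np.asarray(foldChange if foldChange is not None else np.zeros(n), dtype=float),
            "pValue": np.asarray(pValue if pValue is not None else np.full(n, 0.5), dtype=float),
        }
    )
    return Experiment(
        id=eid, title=title or eid, visibility=visibility, icon="box",
        data=frame, dictionary=make_dictionary(),
    )


def random_experiment(rng: np.random.Generator, eid: str, n: int = 50,
                      missing_frac: float = 0.1) -> Experiment:
    genes = [f"ENSR{i:05d}" for i in rng.choice(10 * n, size=n, replace=False)]
    p = rng.uniform(0, 1, n)
    fc = rng.normal(0, 1, n)
    bm = rng.lognormal(2, 1, n)
    if missing_frac:
        for arr in (p, fc, bm):
            holes = rng.random(n) < missing_frac
            arr[holes] = np.nan
    return make_experiment(eid, genes, foldChange=fc, pValue=p, baseMean=bm)


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-cluster collection + annotation for cross-module tests."""
    cfg = SynthConfig(
        n_genes=400, n_clusters=2, experiments_per_cluster=3,
        n_null_experiments=1, n_terms=20, term_size_range=(5, 20), seed=11,
    )
    collection, truth = generate_collection(cfg)
    annotation, truth = generate_go_annotation(cfg, truth)
    return cfg, collection, annotation, truth


@pytest.fixture(scope="session")
def default_synth():
    """One collection under the default study conditions (3×5 clusters + 3 nulls)."""
    cfg = SynthConfig(seed=7)
    collection, truth = generate_collection(cfg)
    return cfg, collection, truth
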