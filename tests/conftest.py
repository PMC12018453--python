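import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from neurotrace import annotate as ann
from neurotrace import io_qc
from neurotrace import synthetic_data as syn


def make_count_matrix(values, gene_ids=None, cell_ids=None, cells=None):
    """Small dense helper: values is a (genes x cells) array-like."""
    values = np.asarray(values)
    g, c = values.shape
    gene_ids = gene_ids or [f"mm:g{i:03d}" for i in range(g)]
    cell_ids = cell_ids or [f"c{i}" for i in range(c)]
    cells_df = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if cells:
        for k, v in cells.items():
            cells_df[k] = v
    return io_qc.CountMatrix(
        X=sp.csr_matrix(values),
        genes=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        cells=cells_df,
    )


def make_normalized(values, gene_ids=None, cell_ids=None, cells=None):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    gene_ids = gene_ids or [f"mm:g{i:03d}" for i in range(g)]
    cell_ids = cell_ids or [f"c{i}" for i in range(c)]
    cells_df = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if cells:
        for k, v in cells.items():
            cells_df[k] = v
    return io_qc.NormalizedMatrix(
        values=sp.csr_matrix(values),
        genes=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        cells=cells_df,
        size_factors=np.ones(c),
    )


@pytest.fixture(scope="session")
def neuron_experiment():
    """Default-size neuron simulation without planted low-quality cells."""
    cfg = syn.SimConfig(seed=5, fraction_low_quality_cells=0.0)
    cm, truth = syn.generate_neuron_experiment(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def neuron_normalized(neuron_experiment):
    _, cm, _ = neuron_experiment
    return io_qc.log_normalize(cm, io_qc.size_factors(cm))


@pytest.fixture(scope="session")
def reference_atlas(neuron_experiment):
    cfg, _, _ = neuron_experiment
    return syn.generate_reference_atlas(cfg, cells_per_type=100)


@pytest.fixture(scope="session")
def neuron_hvgs(neuron_normalized):
    return ann.find_hvgs(neuron_normalized, 1000)


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The demonstration pipeline executed twice with the same seed."""
    from neurotrace import pipeline as pl

    base = tmp_path_factory.mktemp("demo")
    reports = []
    for name in ("run_a", "run_b"):
        cfg = pl.demo_config(seed=1, outdir=str(base / name))
        reports.append(pl.run_pipeline(cfg))
    return base, reports
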