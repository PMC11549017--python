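import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from phenocell.io import CellCountMatrix
from phenocell.pipeline import PipelineConfig, run_all
from phenocell.simulate import default_config, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_counts(matrix, clusters, cell_types=None, tissues=None) -> CellCountMatrix:
    """Build a small CellCountMatrix from a dense array and cluster labels."""
    matrix = np.asarray(matrix)
    n_genes, n_cells = matrix.shape
    clusters = list(clusters)
    assert len(clusters) == n_cells
    uniq = list(dict.fromkeys(clusters))
    cell_types = cell_types or {c: f"type_{c}" for c in uniq}
    tissues = tissues or {c: "tissueX" for c in uniq}
    cells = [f"cell{i}" for i in range(n_cells)]
    return CellCountMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=cells,
        counts=sp.csr_matrix(matrix),
        cell_cluster=dict(zip(cells, clusters)),
        cluster_celltype=cell_types,
        cluster_tissue=tissues,
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One default-scale synthetic dataset shared across tests."""
    cfg = default_config(seed=11)
    ccm, onts, coment, truth = simulate(cfg)
    return {"config": cfg, "counts": ccm, "onts": onts, "coment": coment, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full staged pipeline run on the default synthetic config."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=outdir, seed=11, sim=default_config(seed=11))
    summary = run_all(cfg)
    return {"config": cfg, "outdir": outdir, "summary": summary}
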