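import numpy as np
import pytest
import scipy.sparse as sp

import umithresh as ut
from umithresh.simulate import CellTypeSpec


def make_matrix(dense, genes=None, cells=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{i}" for i in range(dense.shape[1])]
    return ut.CountMatrix(genes, cells, sp.csc_matrix(dense))


@pytest.fixture
def tiny_matrix():
    # 4 genes x 3 cells, includes an all-zero cell
    return make_matrix(
        [[5, 0, 0], [0, 7, 0], [2, 1, 0], [0, 3, 0]],
        genes=["MT-A", "ACTB", "CD3D", "KRT19"],
        cells=["c1", "c2", "c3"],
    )


SMALL_SIM_TYPES = (
    CellTypeSpec.from_mean_depth("epithelial cells", "epithelial", 150, 5354.0, marker_gene_count=15),
    CellTypeSpec.from_mean_depth("fibroblasts", "stromal", 150, 3114.0, marker_gene_count=15),
    CellTypeSpec.from_mean_depth("T-cells", "immune", 150, 2154.0, marker_gene_count=15),
    CellTypeSpec.from_mean_depth("B-cells", "immune", 150, 1639.0, marker_gene_count=15),
)


@pytest.fixture(scope="session")
def small_sim():
    """600-cell, 600-gene simulated dataset shared across unit tests."""
    cfg = ut.SimConfig(n_genes=600, n_mito_genes=10, cell_types=SMALL_SIM_TYPES, seed=42)
    matrix, truth = ut.simulate_dataset(cfg)
    return matrix, truth, cfg


@pytest.fixture(scope="session")
def small_gold(small_sim):
    """Gold standard of the small simulation: QC-passing labelled cells, split."""
    matrix, truth, _ = small_sim
    labels = truth.to_label_table()
    stats = ut.compute_cell_stats(matrix)
    # gene bounds scaled down to the 600-gene simulated universe
    qc = ut.QCThresholds(min_umis=1500, min_genes=150, max_genes=600)
    partition = ut.apply_qc(stats, qc)
    gold = labels.subset(list(partition.index[partition == "high_quality"]))
    ct = gold.for_granularity("cell_type")
    train_ids, test_ids = ut.stratified_split(ct, ut.SplitSpec(seed=5))
    return {
        "matrix": matrix,
        "truth": truth,
        "labels": labels,
        "stats": stats,
        "partition": partition,
        "gold": gold,
        "cell_type": ct,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }


@pytest.fixture(scope="session")
def small_correlation(small_gold):
    g = small_gold
    m_train = g["matrix"].subset_cells(g["train_ids"])
    y = g["cell_type"].reindex(g["train_ids"]).to_numpy(dtype=object)
    return ut.CorrelationClassifier().fit(m_train, y)


@pytest.fixture(scope="session")
def default_runs(tmp_path_factory):
    """Two full default pipeline runs with the same master seed."""
    manifests = []
    dirs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"run_{tag}")
        cfg = ut.RunConfig(out_dir=str(out), master_seed=0, sim={})
        manifests.append(ut.run_pipeline(cfg))
        dirs.append(out)
    return dirs, manifests
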