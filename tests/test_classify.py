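import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import umithresh as ut
from umithresh.classify import RAND_LABEL

from conftest import make_matrix


def disjoint_signature_fixture(n_ref=5, seed=0):
    """Two labels with disjoint 10-gene signatures plus shared background."""
    rng = np.random.default_rng(seed)
    n_genes = 25  # 10 + 10 signature, 5 background
    cells = []
    labels = []
    for li, label in enumerate(("A", "B")):
        sig = slice(li * 10, li * 10 + 10)
        for _ in range(n_ref):
            v = rng.poisson(2, n_genes)
            v[sig] += rng.poisson(30, 10) + 5
            cells.append(v)
            labels.append(label)
    dense = np.array(cells).T
    m = make_matrix(dense)
    return m, np.array(labels, dtype=object)


def test_marker_genes_cover_both_signatures():
    m, y = disjoint_signature_fixture()
    clf = ut.CorrelationClassifier(pair_top_k=10).fit(m, y)
    # brute force: the ten genes with the largest median difference per direction
    dense = m.counts.toarray().T.astype(float)
    expected = set()
    for a, b in (("A", "B"), ("B", "A")):
        diff = np.median(dense[y == a], axis=0) - np.median(dense[y == b], axis=0)
        expected |= {m.genes[i] for i in np.argsort(-diff, kind="stable")[:10] if diff[i] > 0}
    assert set(clf.marker_genes_) == expected
    assert len(expected) == 20  # all signature genes, no background


def test_zero_top_k_rejected():
    m, y = disjoint_signature_fixture()
    with pytest.raises(ValueError):
        ut.CorrelationClassifier(pair_top_k=0).fit(m, y)


def test_single_label_rejected():
    m, y = disjoint_signature_fixture()
    with pytest.raises(ValueError):
        ut.CorrelationClassifier().fit(m, np.array(["A"] * len(y), dtype=object))


def test_fit_deterministic():
    m, y = disjoint_signature_fixture()
    a = ut.CorrelationClassifier().fit(m, y)
    b = ut.CorrelationClassifier().fit(m, y)
    assert a.marker_genes_ == b.marker_genes_


def test_self_reference_cell_gets_called_and_perfect_correlation():
    m, y = disjoint_signature_fixture()
    # with quantile 1.0 the label score is the max correlation: 1.0 for a clone
    clf = ut.CorrelationClassifier(score_quantile=1.0).fit(m, y)
    probe = m.subset_cells([m.cells[0]])  # a label-A reference cell itself
    sm = clf.score_matrix(probe)
    assert sm.calls[0] == "A"
    assert sm.column("A")[0] == pytest.approx(1.0)


def test_depth_invariance_of_scores():
    m, y = disjoint_signature_fixture()
    clf = ut.CorrelationClassifier().fit(m, y)
    probe = m.subset_cells(m.cells[:4])
    doubled = ut.CountMatrix(probe.genes, probe.cells, probe.counts * 3)
    a, b = clf.score_matrix(probe), clf.score_matrix(doubled)
    assert np.allclose(a.scores, b.scores)


def test_label_score_is_quantile_of_reference_correlations():
    """3-label toy fixture: score equals the 0.8 quantile of the 5 per-reference
    Spearman correlations, verified by direct enumeration."""
    rng = np.random.default_rng(4)
    n_genes = 30
    cells, labels = [], []
    for li, label in enumerate(("A", "B", "C")):
        for _ in range(5):
            v = rng.poisson(3, n_genes)
            v[li * 8 : li * 8 + 8] += rng.poisson(25, 8) + 3
            cells.append(v)
            labels.append(label)
    m = make_matrix(np.array(cells).T)
    y = np.array(labels, dtype=object)
    clf = ut.CorrelationClassifier(score_quantile=0.8).fit(m, y)

    probe_vec = rng.poisson(3, n_genes)
    probe_vec[:8] += 20
    probe = make_matrix(probe_vec[:, None], genes=m.genes, cells=["probe"])
    sm = clf.score_matrix(probe)

    dense = m.counts.toarray().T.astype(float)
    midx = clf.marker_indices_
    for k, label in enumerate(("A", "B", "C")):
        corrs = [
            spearmanr(probe_vec[midx], ref[midx]).statistic
            for ref in dense[y == label]
        ]
        assert sm.scores[0, k] == pytest.approx(np.quantile(corrs, 0.8), abs=1e-12)


def test_zero_variance_cell_flagged_with_zero_scores():
    m, y = disjoint_signature_fixture()
    clf = ut.CorrelationClassifier().fit(m, y)
    zero = make_matrix(np.zeros((len(m.genes), 1), dtype=int), genes=m.genes, cells=["z"])
    sm = clf.score_matrix(zero)
    assert sm.flagged[0]
    assert np.all(sm.scores[0] == 0)
    assert sm.calls[0] == "A"  # lexicographically smallest label


def test_correlation_scores_bounded():
    m, y = disjoint_signature_fixture()
    clf = ut.CorrelationClassifier().fit(m, y)
    sm = clf.score_matrix(m)
    assert np.all(sm.scores >= -1) and np.all(sm.scores <= 1)


# -- pair forest ------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_forest(request):
    rng = np.random.default_rng(9)
    n_genes = 60
    cells, labels = [], []
    for li, label in enumerate(("A", "B", "C")):
        for _ in range(40):
            v = rng.poisson(2, n_genes)
            v[li * 15 : li * 15 + 15] += rng.poisson(20, 15) + 4
            cells.append(v)
            labels.append(label)
    m = make_matrix(np.array(cells).T)
    y = np.array(labels, dtype=object)
    labels_series = pd.Series(y, index=m.cells)
    ms = ut.find_markers(m, labels_series, seed=0)
    clf = ut.PairForestClassifier(
        top_genes_per_label=15, top_gene_pairs=40, n_rand=20, n_trees=200, random_state=0
    ).fit(m, y, markers=ms)
    return m, y, ms, clf


def test_pair_indicator_definition():
    m, y = disjoint_signature_fixture(n_ref=25)
    labels_series = pd.Series(y, index=m.cells)
    ms = ut.find_markers(m, labels_series, seed=0)
    clf = ut.PairForestClassifier(
        top_genes_per_label=5, top_gene_pairs=10, n_rand=5, n_trees=50, random_state=0
    ).fit(m, y, markers=ms)
    dense = np.array([[5.0, 2.0], [2.0, 5.0], [3.0, 3.0]])
    clf2 = clf
    old = clf2._pair_idx
    clf2._pair_idx = np.array([[0, 1]])
    try:
        F = clf2._pair_matrix(dense)
    finally:
        clf2._pair_idx = old
    assert F.ravel().tolist() == [1.0, 0.0, 0.0]  # (5,2)->1, (2,5)->0, tie (3,3)->0


def test_training_set_accuracy_on_separable_fixture(trained_forest):
    m, y, _, clf = trained_forest
    assert (clf.predict(m) == y).mean() >= 0.99


def test_pair_features_deterministic(trained_forest):
    m, y, ms, clf = trained_forest
    again = ut.PairForestClassifier(
        top_genes_per_label=15, top_gene_pairs=40, n_rand=20, n_trees=200, random_state=0
    ).fit(m, y, markers=ms)
    assert again.pair_features_ == clf.pair_features_


def test_vote_fractions_sum_to_one(trained_forest):
    m, _, _, clf = trained_forest
    sm = clf.score_matrix(m)
    total = sm.scores.sum(axis=1) + sm.rand_scores
    assert np.allclose(total, 1.0)
    assert np.all(sm.scores >= 0) and np.all(sm.scores <= 1)


def test_shuffled_cells_score_higher_on_rand(trained_forest):
    m, _, _, clf = trained_forest
    rng = np.random.default_rng(123)
    dense = m.counts.toarray().T.astype(float)
    shuffled = np.column_stack([rng.permutation(dense[:, g]) for g in range(dense.shape[1])])
    real = clf.score_matrix(make_matrix(dense.T, genes=m.genes))
    noise = clf.score_matrix(make_matrix(shuffled.T, genes=m.genes))
    assert noise.rand_scores.mean() > real.rand_scores.mean()


def test_all_zero_cell_deterministic(trained_forest):
    m, _, _, clf = trained_forest
    zero = make_matrix(np.zeros((len(m.genes), 2), dtype=int), genes=m.genes, cells=["z1", "z2"])
    sm = clf.score_matrix(zero)
    assert np.allclose(sm.scores[0], sm.scores[1])


def test_missing_genes_treated_as_zero(trained_forest):
    m, _, _, clf = trained_forest
    keep = m.genes[: len(m.genes) // 2]
    partial = m.subset_genes(keep)
    sm = clf.score_matrix(partial)  # must not raise
    assert sm.scores.shape[1] == 3


def test_missing_markers_rejected(trained_forest):
    m, y, ms, _ = trained_forest
    with pytest.raises(ValueError, match="MarkerSet"):
        ut.PairForestClassifier().fit(m, y, markers=None)


# -- persistence ------------------------------------------------------------


def test_correlation_model_round_trip(tmp_path):
    m, y = disjoint_signature_fixture()
    clf = ut.CorrelationClassifier().fit(m, y)
    clf.save(tmp_path / "model.json")
    back = ut.CorrelationClassifier.load(tmp_path / "model.json")
    a, b = clf.score_matrix(m), back.score_matrix(m)
    assert np.allclose(a.scores, b.scores)
    assert list(a.calls) == list(b.calls)


def test_pair_forest_round_trip(tmp_path, trained_forest):
    m, _, _, clf = trained_forest
    clf.save(tmp_path / "model.json")
    back = ut.PairForestClassifier.load(tmp_path / "model.json")
    assert np.allclose(clf.score_matrix(m).scores, back.score_matrix(m).scores)
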