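import numpy as np
import pandas as pd
import pytest
from itertools import combinations

import umithresh as ut
from umithresh.classify import ScoreMatrix
from umithresh.evaluate import CONTROL, DEFAULT_GRID, SweepModel, SweepResult


# -- stratified split --------------------------------------------------------


def test_split_sizes_and_disjointness():
    labels = pd.Series(
        ["A"] * 1000 + ["B"] * 1000 + ["C"] * 1000,
        index=[f"c{i}" for i in range(3000)],
    )
    train, test = ut.stratified_split(labels, ut.SplitSpec(n_per_label=400, seed=0))
    assert len(train) == 600 and len(test) == 600  # 200 + 200 per label
    assert not set(train) & set(test)
    for ids in (train, test):
        counts = labels.reindex(ids).value_counts()
        assert (counts == 200).all()


def test_split_small_label_takes_everyone():
    labels = pd.Series(["A"] * 10 + ["B"] * 500, index=[f"c{i}" for i in range(510)])
    train, test = ut.stratified_split(labels, ut.SplitSpec(n_per_label=400, seed=1))
    got_a = [c for c in train + test if labels[c] == "A"]
    assert sorted(got_a) == [f"c{i}" for i in range(10)]
    a_train = [c for c in train if labels[c] == "A"]
    assert len(a_train) == 5  # floor(0.5 * 10)


def test_split_deterministic_and_seed_sensitive():
    labels = pd.Series(["A"] * 50 + ["B"] * 50, index=[f"c{i}" for i in range(100)])
    s = ut.SplitSpec(n_per_label=20, seed=3)
    assert ut.stratified_split(labels, s) == ut.stratified_split(labels, s)
    other = ut.stratified_split(labels, ut.SplitSpec(n_per_label=20, seed=4))
    assert other != ut.stratified_split(labels, s)


def test_split_rejects_singleton_label():
    labels = pd.Series(["A"] * 5 + ["B"], index=[f"c{i}" for i in range(6)])
    with pytest.raises(ValueError, match="fewer than 2"):
        ut.stratified_split(labels)


def test_split_spec_validation():
    with pytest.raises(ValueError):
        ut.SplitSpec(train_fraction=0.0)
    with pytest.raises(ValueError):
        ut.SplitSpec(n_per_label=1)


# -- confusion matrix --------------------------------------------------------


def test_confusion_matrix_counts():
    truth = ["A", "A", "B", "B", "B"]
    calls = ["A", "B", "B", "B", "C"]
    cm = ut.confusion_matrix(truth, calls)
    assert list(cm.index) == ["A", "B", "C"]
    assert cm.loc["A", "A"] == 1 and cm.loc["A", "B"] == 1
    assert cm.loc["B", "B"] == 2 and cm.loc["B", "C"] == 1
    assert cm.to_numpy().sum() == 5
    assert cm.loc["C"].sum() == 0  # predicted-only label gets an empty row


def test_confusion_matrix_length_mismatch():
    with pytest.raises(ValueError):
        ut.confusion_matrix(["A"], ["A", "B"])


# -- binary AUROCC -----------------------------------------------------------


def test_binary_auc_hand_examples():
    # perfect separation, perfect inversion, all tied
    assert ut.binary_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert ut.binary_auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0
    assert ut.binary_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
    # one tied pair across classes: 3.5 concordant of 4 comparisons
    assert ut.binary_auc([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)


def test_binary_auc_matches_brute_force_and_sklearn():
    rng = np.random.default_rng(0)
    scores = np.round(rng.normal(size=100), 1)  # coarse grid forces ties
    truth = rng.random(100) < 0.4
    got = ut.binary_auc(scores, truth)
    pos, neg = scores[truth], scores[~truth]
    pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
    assert got == pytest.approx(np.mean(pairs), abs=1e-12)
    from sklearn.metrics import roc_auc_score

    assert got == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)


def test_binary_auc_requires_both_classes():
    with pytest.raises(ValueError):
        ut.binary_auc([0.1, 0.2], [1, 1])


# -- multiclass AUROCC -------------------------------------------------------


def _score_matrix(scores, labels, calls=None):
    scores = np.asarray(scores, dtype=float)
    if calls is None:
        calls = np.array([labels[i] for i in scores.argmax(axis=1)], dtype=object)
    return ScoreMatrix(
        cells=[f"c{i}" for i in range(scores.shape[0])],
        labels=list(labels),
        scores=scores,
        calls=calls,
    )


def test_hand_till_reduces_to_binary_in_two_class_case():
    rng = np.random.default_rng(2)
    s = rng.random((60, 2))
    truth = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
    sm = _score_matrix(s, ["A", "B"])
    expected = 0.5 * (
        ut.binary_auc(s[:, 0], truth == "A") + ut.binary_auc(s[:, 1], truth == "B")
    )
    assert ut.multiclass_auc(sm, truth) == pytest.approx(expected, abs=1e-12)


def test_hand_till_three_class_brute_force():
    rng = np.random.default_rng(5)
    s = rng.random((90, 3))
    truth = np.array(["A"] * 30 + ["B"] * 30 + ["C"] * 30, dtype=object)
    sm = _score_matrix(s, ["A", "B", "C"])
    total = 0.0
    for a, b in combinations(("A", "B", "C"), 2):
        mask = (truth == a) | (truth == b)
        total += 0.5 * (
            ut.binary_auc(sm.column(a)[mask], truth[mask] == a)
            + ut.binary_auc(sm.column(b)[mask], truth[mask] == b)
        )
    assert ut.multiclass_auc(sm, truth) == pytest.approx(total / 3.0, abs=1e-12)


def test_hand_till_invariant_under_relabeling():
    rng = np.random.default_rng(6)
    s = rng.random((60, 3))
    truth = np.array(list("ABC") * 20, dtype=object)
    base = ut.multiclass_auc(_score_matrix(s, ["A", "B", "C"]), truth)
    # swap the names of A and C everywhere (columns must stay sorted)
    swapped_scores = s[:, [2, 1, 0]]
    swapped_truth = np.array(
        [{"A": "C", "C": "A"}.get(t, t) for t in truth], dtype=object
    )
    swapped = ut.multiclass_auc(_score_matrix(swapped_scores, ["A", "B", "C"]), swapped_truth)
    assert swapped == pytest.approx(base, abs=1e-12)


def test_perfect_scores_give_auc_one():
    truth = np.array(["A"] * 5 + ["B"] * 5 + ["C"] * 5, dtype=object)
    s = np.zeros((15, 3))
    for i, t in enumerate(truth):
        s[i, "ABC".index(t)] = 1.0
    sm = _score_matrix(s, ["A", "B", "C"])
    assert ut.multiclass_auc(sm, truth) == 1.0
    assert ut.multiclass_auc(sm, truth, method="macro_ovr") == 1.0


def test_multiclass_auc_missing_class_column_rejected():
    sm = _score_matrix(np.random.default_rng(0).random((4, 2)), ["A", "B"])
    truth = np.array(["A", "B", "C", "A"], dtype=object)
    with pytest.raises(ValueError, match="absent"):
        ut.multiclass_auc(sm, truth)
    with pytest.raises(ValueError, match="method"):
        ut.multiclass_auc(sm, np.array(["A", "B", "A", "B"], dtype=object), method="x")


# -- threshold selection -----------------------------------------------------


def _sweep_table(rows):
    return pd.DataFrame(rows, columns=["threshold", "classifier", "granularity", "auroc"])


def test_select_threshold_smallest_qualifying():
    t = _sweep_table(
        [
            (CONTROL, "corr", "cell_type", 0.99),
            (350, "corr", "cell_type", 0.89),
            (450, "corr", "cell_type", 0.92),
            (1500, "corr", "cell_type", 0.95),
        ]
    )
    sr = SweepResult(table=t)
    assert ut.select_threshold(sr, cutoff=0.9) == 450
    assert ut.select_threshold(sr, cutoff=0.7) == 350
    assert ut.select_threshold(sr, cutoff=0.99) is None  # control never qualifies


def test_select_threshold_inclusive_boundary():
    t = _sweep_table([(450, "corr", "cell_type", 0.9), (1500, "corr", "cell_type", 0.95)])
    assert ut.select_threshold(SweepResult(table=t), cutoff=0.9) == 450
    assert ut.select_threshold(SweepResult(table=t), cutoff=0.9, inclusive=False) == 1500


def test_select_threshold_filters_by_model_and_granularity():
    t = _sweep_table(
        [
            (100, "forest", "cell_type", 0.95),
            (450, "corr", "cell_type", 0.95),
            (900, "corr", "lineage", 0.95),
        ]
    )
    sr = SweepResult(table=t)
    assert ut.select_threshold(sr, classifier="corr", granularity="cell_type") == 450
    assert ut.select_threshold(sr, classifier="corr", granularity="lineage") == 900
    assert ut.select_threshold(sr, classifier="forest") == 100


def test_select_threshold_monotone_in_cutoff():
    rng = np.random.default_rng(8)
    aucs = np.sort(rng.random(len(DEFAULT_GRID)))
    t = _sweep_table([(th, "m", "g", a) for th, a in zip(DEFAULT_GRID, aucs)])
    sr = SweepResult(table=t)
    picks = [ut.select_threshold(sr, cutoff=c) for c in (0.2, 0.5, 0.8, 0.95)]
    chosen = [p for p in picks if p is not None]
    assert chosen == sorted(chosen)


# -- sweep -------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_sweep(small_gold, small_correlation):
    g = small_gold
    m_test = g["matrix"].subset_cells(g["test_ids"])
    models = [SweepModel("correlation", small_correlation, "cell_type")]
    grid = (0, 50, 450, 4000)
    sr = ut.threshold_sweep(m_test, g["labels"], models, grid=grid, base_seed=17)
    return g, m_test, models, grid, sr


def test_sweep_table_layout_and_control(small_sweep):
    g, m_test, models, grid, sr = small_sweep
    assert sorted(sr.table["threshold"]) == sorted([CONTROL, *grid])
    # control row scores the untransformed test matrix
    sm = models[0].model.score_matrix(m_test)
    truth = g["cell_type"].reindex(sm.cells).to_numpy(dtype=object)
    assert sr.auc(CONTROL, "correlation", "cell_type") == pytest.approx(
        ut.multiclass_auc(sm, truth)
    )
    stats = ut.compute_cell_stats(m_test)
    ctrl = sr.table[sr.table["threshold"] == CONTROL].iloc[0]
    assert ctrl["mean_umis"] == pytest.approx(stats["total_umis"].mean())


def test_sweep_grid_zero_collapses_to_chance(small_sweep):
    _, _, _, _, sr = small_sweep
    row = sr.table[sr.table["threshold"] == 0].iloc[0]
    assert row["mean_umis"] == 0.0
    assert row["auroc"] == pytest.approx(0.5)  # all-zero cells carry no signal


def test_sweep_depth_signal_ordering(small_sweep):
    _, _, _, _, sr = small_sweep
    assert sr.auc(4000, "correlation", "cell_type") >= sr.auc(50, "correlation", "cell_type")
    assert sr.auc(4000, "correlation", "cell_type") > 0.9


def test_sweep_deterministic(small_sweep):
    g, m_test, models, grid, sr = small_sweep
    again = ut.threshold_sweep(m_test, g["labels"], models, grid=grid, base_seed=17)
    pd.testing.assert_frame_equal(sr.table, again.table)


def test_sweep_confusions_complete(small_sweep):
    _, m_test, _, grid, sr = small_sweep
    assert set(sr.confusions) == {
        (t, "correlation", "cell_type") for t in [CONTROL, *grid]
    }
    for cm in sr.confusions.values():
        assert cm.to_numpy().sum() == len(m_test.cells)


def test_sweep_rejects_bad_grid(small_gold, small_correlation):
    g = small_gold
    m_test = g["matrix"].subset_cells(g["test_ids"][:20])
    models = [SweepModel("correlation", small_correlation, "cell_type")]
    with pytest.raises(ValueError, match="grid"):
        ut.threshold_sweep(m_test, g["labels"], models, grid=(100, 50))
    with pytest.raises(ValueError, match="grid"):
        ut.threshold_sweep(m_test, g["labels"], models, grid=(-5, 50))


def test_default_grid_shape():
    assert len(DEFAULT_GRID) == 20
    assert DEFAULT_GRID[0] == 0 and DEFAULT_GRID[-1] == 4000
    assert list(DEFAULT_GRID) == sorted(DEFAULT_GRID)
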