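"""Splitting, AUROCC computation, the depth sweep and threshold selection.

The sweep downsamples a held-out test set to each target depth on a grid,
scores it with the trained classifiers at each label granularity, and
records realized depth statistics plus a multiclass AUROCC per grid point.
The optimized threshold is then the smallest grid depth whose AUROCC
reaches the chosen cutoff (0.9 by default; 0.7 is a common relaxation for
datasets with intrinsically low expression).

Multiclass AUROCC defaults to the Hand & Till measure
``M = 2 / (c (c - 1)) * sum_{i<j} A(i, j)`` where ``A(i, j)`` averages the
two one-vs-one AUCs of the pair computed from each class's score column;
a macro one-vs-rest variant is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import ScoreMatrix
from .downsample import DownsampleSpec, downsample_matrix
from .io import CountMatrix, LabelTable
from .qc import compute_cell_stats

__all__ = [
    "SplitSpec",
    "DEFAULT_GRID",
    "SweepModel",
    "SweepResult",
    "stratified_split",
    "confusion_matrix",
    "binary_auc",
    "multiclass_auc",
    "threshold_sweep",
    "select_threshold",
]

DEFAULT_GRID: tuple[int, ...] = (
    0, 50, 100, 150, 200, 250, 300, 350, 400, 450,
    500, 600, 700, 800, 900, 1000, 1500, 2000, 3000, 4000,
)

CONTROL = -1  # sentinel threshold for the untransformed control row


@dataclass(frozen=True)
class SplitSpec:
    n_per_label: int = 400
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_per_label < 2:
            raise ValueError("n_per_label must be >= 2")


def stratified_split(labels, spec: SplitSpec | None = None) -> tuple[list[str], list[str]]:
    """Sample up to ``n_per_label`` cells per label, then split train/test.

    ``labels`` is a Series (barcode -> label) or a LabelTable (cell_type
    granularity is used).  Train size per label is the floor of
    ``train_fraction`` times the sampled count.  Deterministic given seed.
    """
    s = spec or SplitSpec()
    if isinstance(labels, LabelTable):
        labels = labels.for_granularity("cell_type")
    rng = np.random.default_rng(s.seed)
    train: list[str] = []
    test: list[str] = []
    for label in sorted(labels.unique()):
        pool = sorted(labels.index[labels == label])
        if len(pool) < 2:
            raise ValueError(f"label {label!r} has fewer than 2 cells")
        take = min(s.n_per_label, len(pool))
        chosen = rng.permutation(len(pool))[:take]
        sampled = [pool[i] for i in chosen]
        n_train = int(np.floor(s.train_fraction * take))
        train.extend(sampled[:n_train])
        test.extend(sampled[n_train:])
    return train, test


def confusion_matrix(truth, calls) -> pd.DataFrame:
    """Counts of truth label (rows) vs predicted label (columns)."""
    truth = np.asarray(truth, dtype=object)
    calls = np.asarray(calls, dtype=object)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls must have equal length")
    labels = sorted(set(truth) | set(calls))
    from sklearn.metrics import confusion_matrix as _cm

    mat = _cm(truth.astype(str), calls.astype(str), labels=[str(l) for l in labels])
    return pd.DataFrame(mat, index=labels, columns=labels)


def binary_auc(scores, truth) -> float:
    """AUROCC as the normalized rank-sum: P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("binary_auc requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def multiclass_auc(sm: ScoreMatrix, truth, method: str = "hand_till") -> float:
    """Multiclass AUROCC from per-label score columns.

    ``hand_till``: average over unordered class pairs of the mean of the two
    one-vs-one AUCs, each computed from one class's own score column on the
    cells of that pair.  ``macro_ovr``: mean one-vs-rest AUC per class.
    """
    truth = np.asarray(truth, dtype=object)
    present = sorted(set(truth))
    if len(present) < 2:
        raise ValueError("need at least 2 classes in truth")
    missing = [c for c in present if c not in sm.labels]
    if missing:
        raise ValueError(f"classes absent from score columns: {missing}")
    if method == "macro_ovr":
        return float(np.mean([binary_auc(sm.column(c), truth == c) for c in present]))
    if method != "hand_till":
        raise ValueError("method must be 'hand_till' or 'macro_ovr'")
    total = 0.0
    for a, b in combinations(present, 2):
        mask = (truth == a) | (truth == b)
        a_given_b = binary_auc(sm.column(a)[mask], truth[mask] == a)
        b_given_a = binary_auc(sm.column(b)[mask], truth[mask] == b)
        total += 0.5 * (a_given_b + b_given_a)
    n_pairs = len(present) * (len(present) - 1) / 2
    return float(total / n_pairs)


@dataclass(frozen=True)
class SweepModel:
    """A trained classifier entered into the sweep under a display name."""

    name: str
    model: object  # anything with .score_matrix(CountMatrix)
    granularity: str


@dataclass
class SweepResult:
    """Per-(threshold, classifier, granularity) depth stats and AUROCC.

    ``table`` rows with ``threshold == -1`` are the untransformed control.
    """

    table: pd.DataFrame
    confusions: dict = field(default_factory=dict, repr=False)

    def auc(self, threshold: int, classifier: str, granularity: str) -> float:
        t = self.table
        row = t[
            (t["threshold"] == threshold)
            & (t["classifier"] == classifier)
            & (t["granularity"] == granularity)
        ]
        return float(row["auroc"].iloc[0])


def _truth_for(truth: LabelTable, granularity: str, cells) -> np.ndarray:
    series = truth.for_granularity(granularity).reindex(cells)
    if series.isna().any():
        missing = series.index[series.isna()].tolist()
        raise ValueError(f"cells without {granularity} truth labels: {missing[:5]}")
    return series.to_numpy(dtype=object)


def threshold_sweep(
    m_test: CountMatrix,
    truth: LabelTable,
    models: list[SweepModel],
    grid=DEFAULT_GRID,
    base_seed: int = 0,
    mode: str = "paper_literal",
    auc_method: str = "hand_till",
) -> SweepResult:
    """Downsample the test set across the grid and assess every model.

    Per-threshold seeds derive from ``(base_seed, threshold)`` so grid
    points are independent but reproducible; one random draw per grid point
    serves both the realized depth statistics and the predictions.  An
    untransformed control row (threshold sentinel -1) is always included.
    """
    grid = list(grid)
    if any(t < 0 for t in grid) or sorted(set(grid)) != grid:
        raise ValueError("grid must be strictly increasing and non-negative")
    rows = []
    confusions = {}
    for target in [CONTROL] + grid:
        if target == CONTROL:
            ds = m_test
        else:
            seed = int(
                np.random.SeedSequence(entropy=base_seed, spawn_key=(target,)).generate_state(1)[0]
                % (2**31)
            )
            ds = downsample_matrix(m_test, DownsampleSpec(target=target, mode=mode, seed=seed))
        stats = compute_cell_stats(ds)
        for entry in models:
            sm = entry.model.score_matrix(ds)
            y = _truth_for(truth, entry.granularity, sm.cells)
            auc = multiclass_auc(sm, y, method=auc_method)
            rows.append(
                {
                    "threshold": target,
                    "classifier": entry.name,
                    "granularity": entry.granularity,
                    "mean_umis": float(stats["total_umis"].mean()),
                    "median_umis": float(stats["total_umis"].median()),
                    "mean_genes": float(stats["n_genes"].mean()),
                    "median_genes": float(stats["n_genes"].median()),
                    "auroc": auc,
                }
            )
            confusions[(target, entry.name, entry.granularity)] = confusion_matrix(y, sm.calls)
    return SweepResult(table=pd.DataFrame(rows), confusions=confusions)


def select_threshold(
    sr: SweepResult | pd.DataFrame,
    cutoff: float = 0.9,
    classifier: str | None = None,
    granularity: str | None = None,
    inclusive: bool = True,
) -> int | None:
    """Smallest grid threshold whose AUROCC reaches the cutoff, or None.

    ``inclusive=True`` uses ``>= cutoff``; set False for a strict ``>``.
    The untransformed control row never qualifies as a threshold.
    """
    t = sr.table if isinstance(sr, SweepResult) else sr
    t = t[t["threshold"] != CONTROL]
    if classifier is not None:
        t = t[t["classifier"] == classifier]
    if granularity is not None:
        t = t[t["granularity"] == granularity]
    ok = t["auroc"] >= cutoff if inclusive else t["auroc"] > cutoff
    qual = t.loc[ok, "threshold"]
    if qual.empty:
        return None
    return int(qual.min())
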