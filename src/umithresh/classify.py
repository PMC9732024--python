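"""Trainable multi-class cell classifiers.

Two estimators with the scikit-learn fit/predict contract, both trained on
raw (un-normalised) UMI counts:

:class:`CorrelationClassifier`
    A reference-based classifier.  Training stores the reference cells; a
    discriminative gene set is built from the top-k genes by difference of
    per-label median expression over every ordered label pair.  An unknown
    cell is scored against every reference cell by Spearman correlation over
    those genes, and a label's score is an upper quantile (default 0.8) of
    the correlations to that label's reference cells.  Because Spearman is
    rank-based, per-cell depth scaling leaves the scores unchanged.

:class:`PairForestClassifier`
    A top-scoring-gene-pair random forest.  Marker genes (``top_genes_per_label``
    per label) define a gene universe; ordered pairs (i, j) are scored by how
    well the binary indicator ``count_i > count_j`` separates each label from
    the rest, the ``top_gene_pairs`` best per label are kept, and a random
    forest is trained on the binary pair-feature matrix.  Per-gene-shuffled
    profiles labelled ``"rand"`` are appended so that nonsense inputs can be
    flagged instead of silently assigned a real label.

Both produce a :class:`ScoreMatrix` of per-cell per-label scores; argmax
ties break lexicographically by label name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix
from .markers import MarkerSet

__all__ = ["ScoreMatrix", "CorrelationClassifier", "PairForestClassifier", "RAND_LABEL"]

RAND_LABEL = "rand"


@dataclass
class ScoreMatrix:
    """Per-cell per-label scores with hard calls.

    ``labels`` are sorted lexicographically so that ``argmax`` resolves
    score ties toward the lexicographically smallest label.
    """

    cells: list[str]
    labels: list[str]
    scores: np.ndarray  # cells x labels
    calls: np.ndarray  # label per cell
    flagged: np.ndarray | None = None  # degenerate cells (e.g. zero variance)
    rand_scores: np.ndarray | None = None  # confidence flag from the forest

    def __post_init__(self) -> None:
        assert self.scores.shape == (len(self.cells), len(self.labels))
        assert list(self.labels) == sorted(self.labels)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.cells, columns=self.labels)
        df.index.name = "cell_barcode"
        df["call"] = self.calls
        return df

    def column(self, label: str) -> np.ndarray:
        return self.scores[:, self.labels.index(label)]


def _as_cells_by_genes(X) -> tuple[sp.csr_matrix, list[str] | None]:
    """Coerce input to a cells x genes CSR matrix, extracting gene names."""
    if isinstance(X, CountMatrix):
        return X.cells_by_genes(), list(X.genes)
    if isinstance(X, pd.DataFrame):
        return sp.csr_matrix(X.to_numpy()), [str(c) for c in X.columns]
    return sp.csr_matrix(X), None


def _barcodes(X, n: int) -> list[str]:
    if isinstance(X, CountMatrix):
        return list(X.cells)
    if isinstance(X, pd.DataFrame):
        return [str(i) for i in X.index]
    return [f"cell{i}" for i in range(n)]


def _spearman_block(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlations between rows of A and rows of B.

    Returns (corr matrix len(A) x len(B), zero-variance mask over rows of A).
    Average ranks are used for ties; zero-variance rows yield NaN columns
    which the caller must handle.
    """
    ra = rankdata(A, axis=1)
    rb = rankdata(B, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ra, axis=1)
    nb = np.linalg.norm(rb, axis=1)
    degenerate_a = na == 0
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    corr = (ra / na[:, None]) @ (rb / nb[:, None]).T
    return corr, degenerate_a


class CorrelationClassifier(BaseEstimator, ClassifierMixin):
    """Spearman-correlation reference classifier.

    Parameters
    ----------
    pair_top_k : int
        Genes kept per ordered label pair when building the discriminative
        gene set (ranked by difference of per-label median raw expression).
    score_quantile : float
        Quantile of per-reference-cell correlations used as the label score.
    """

    def __init__(self, pair_top_k: int = 10, score_quantile: float = 0.8):
        self.pair_top_k = pair_top_k
        self.score_quantile = score_quantile

    def fit(self, X, y, gene_names=None):
        if self.pair_top_k < 1:
            raise ValueError("pair_top_k must be >= 1 (empty feature space otherwise)")
        if not 0.0 < self.score_quantile <= 1.0:
            raise ValueError("score_quantile must lie in (0, 1]")
        M, names = _as_cells_by_genes(X)
        if gene_names is not None:
            names = list(gene_names)
        if names is None:
            names = [f"g{i}" for i in range(M.shape[1])]
        y = np.asarray(y, dtype=object)
        if len(y) != M.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 labels")

        dense = np.asarray(M.todense(), dtype=float)
        medians = {c: np.median(dense[y == c], axis=0) for c in self.classes_}
        marker_idx: dict[int, None] = {}
        for a in self.classes_:
            for b in self.classes_:
                if a == b:
                    continue
                diff = medians[a] - medians[b]
                top = np.argsort(-diff, kind="stable")[: self.pair_top_k]
                for i in top:
                    if diff[i] > 0:
                        marker_idx.setdefault(int(i), None)
        if not marker_idx:
            # fully degenerate reference (e.g. all medians equal): keep every gene
            marker_idx = {i: None for i in range(M.shape[1])}
        self.marker_indices_ = np.array(sorted(marker_idx), dtype=int)
        self.marker_genes_ = [names[i] for i in self.marker_indices_]
        self.gene_names_ = names
        self.reference_ = dense[:, self.marker_indices_]
        self.reference_labels_ = y.copy()
        return self

    def _align(self, X) -> np.ndarray:
        M, names = _as_cells_by_genes(X)
        dense = np.asarray(M.todense(), dtype=float)
        if names is None or names == self.gene_names_:
            return dense[:, self.marker_indices_]
        pos = {g: i for i, g in enumerate(names)}
        out = np.zeros((dense.shape[0], len(self.marker_genes_)))
        hits = 0
        for k, g in enumerate(self.marker_genes_):
            if g in pos:
                out[:, k] = dense[:, pos[g]]
                hits += 1
        if hits < 2:
            raise ValueError("test matrix shares fewer than 2 marker genes with the model")
        return out

    def score_matrix(self, X) -> ScoreMatrix:
        check_is_fitted(self, "reference_")
        Q = self._align(X)
        corr, degenerate = _spearman_block(Q, self.reference_)
        labels = [str(c) for c in self.classes_]
        scores = np.zeros((Q.shape[0], len(labels)))
        for k, c in enumerate(self.classes_):
            block = corr[:, self.reference_labels_ == c]
            scores[:, k] = np.quantile(block, self.score_quantile, axis=1)
        scores[degenerate] = 0.0
        calls = np.asarray(labels, dtype=object)[np.argmax(scores, axis=1)]
        calls[degenerate] = labels[0]
        return ScoreMatrix(
            cells=_barcodes(X, Q.shape[0]),
            labels=labels,
            scores=scores,
            calls=calls,
            flagged=degenerate,
        )

    def predict(self, X) -> np.ndarray:
        return self.score_matrix(X).calls

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        stem = path.with_suffix("")
        np.save(f"{stem}.reference.npy", self.reference_)
        meta = {
            "schema": "umithresh.correlation/1",
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "marker_genes": self.marker_genes_,
            "reference_labels": [str(c) for c in self.reference_labels_],
            "reference_array": f"{stem.name}.reference.npy",
        }
        path.write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "CorrelationClassifier":
        path = Path(path)
        meta = json.loads(path.read_text())
        model = cls(**meta["params"])
        model.classes_ = np.array(meta["classes"], dtype=object)
        model.marker_genes_ = meta["marker_genes"]
        model.gene_names_ = list(meta["marker_genes"])
        model.marker_indices_ = np.arange(len(model.marker_genes_))
        model.reference_ = np.load(path.parent / meta["reference_array"])
        model.reference_labels_ = np.array(meta["reference_labels"], dtype=object)
        return model


class PairForestClassifier(BaseEstimator, ClassifierMixin):
    """Top-scoring-gene-pair random forest classifier.

    Defaults mirror the standard training recipe for this family of models:
    100 top genes per label, 200 gene pairs per label, 50 shuffled "rand"
    profiles per label, 1000 trees.
    """

    def __init__(
        self,
        top_genes_per_label: int = 100,
        top_gene_pairs: int = 200,
        n_rand: int = 50,
        n_trees: int = 1000,
        random_state: int = 0,
    ):
        self.top_genes_per_label = top_genes_per_label
        self.top_gene_pairs = top_gene_pairs
        self.n_rand = n_rand
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y, markers: MarkerSet = None, gene_names=None):
        if markers is None or not markers.tables:
            raise ValueError("PairForestClassifier requires a non-empty MarkerSet")
        M, names = _as_cells_by_genes(X)
        if gene_names is not None:
            names = list(gene_names)
        if names is None:
            names = [f"g{i}" for i in range(M.shape[1])]
        y = np.asarray(y, dtype=object)
        labels = sorted(set(y))
        for label in labels:
            if label not in markers.tables or markers.tables[label].empty:
                raise ValueError(f"no markers available for label {label!r}")
        pos = {g: i for i, g in enumerate(names)}

        top_by_label = {
            label: [g for g in markers.genes_for(label, self.top_genes_per_label) if g in pos]
            for label in labels
        }
        universe: dict[str, None] = {}
        for gs in top_by_label.values():
            for g in gs:
                universe.setdefault(g, None)
        uni = list(universe)
        uni_idx = np.array([pos[g] for g in uni], dtype=int)
        dense = np.asarray(M[:, uni_idx].todense(), dtype=float)  # cells x universe

        rng = np.random.default_rng(np.random.SeedSequence(entropy=self.random_state))
        pair_set: dict[tuple[str, str], None] = {}
        uni_pos = {g: i for i, g in enumerate(uni)}
        n_cells = dense.shape[0]
        for label in labels:
            own = [uni_pos[g] for g in top_by_label[label]]
            if not own:
                continue
            in_mask = y == label
            # indicator means for every (own gene, universe gene) pair
            A = dense[:, own]  # cells x |own|
            cand_i, cand_j, disc = [], [], []
            for jj in range(len(uni)):
                ind = A > dense[:, [jj]]
                d = np.abs(ind[in_mask].mean(axis=0) - ind[~in_mask].mean(axis=0))
                for kk, ii in enumerate(own):
                    if ii == jj:
                        continue
                    cand_i.append(ii)
                    cand_j.append(jj)
                    disc.append(d[kk])
            disc = np.asarray(disc)
            want = min(self.top_gene_pairs, disc.size)
            if want < self.top_gene_pairs:
                import warnings

                warnings.warn(
                    f"label {label!r}: only {disc.size} candidate pairs "
                    f"(requested {self.top_gene_pairs}); keeping all"
                )
            order = np.argsort(-disc, kind="stable")[:want]
            for k in order:
                pair_set.setdefault((uni[cand_i[k]], uni[cand_j[k]]), None)

        self.pair_features_ = list(pair_set)
        if not self.pair_features_:
            raise ValueError("no pair features could be constructed")
        self.universe_ = uni
        self._pair_idx = np.array(
            [(uni_pos[a], uni_pos[b]) for a, b in self.pair_features_], dtype=int
        )

        F = self._pair_matrix(dense)
        # per-gene shuffled profiles exercise the "rand" rejection label
        n_rand_total = self.n_rand * len(labels)
        rand_dense = np.empty((n_rand_total, dense.shape[1]))
        for g in range(dense.shape[1]):
            rand_dense[:, g] = dense[rng.integers(0, n_cells, size=n_rand_total), g]
        F_rand = self._pair_matrix(rand_dense)

        y_ext = np.concatenate([y, np.array([RAND_LABEL] * n_rand_total, dtype=object)])
        seed = int(rng.integers(0, 2**31 - 1))
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1
        )
        self.forest_.fit(np.vstack([F, F_rand]), y_ext.astype(str))
        self.classes_ = np.array(labels, dtype=object)
        return self

    def _pair_matrix(self, dense: np.ndarray) -> np.ndarray:
        i, j = self._pair_idx[:, 0], self._pair_idx[:, 1]
        # ties (equal counts) score 0, like the strict > indicator
        return (dense[:, i] > dense[:, j]).astype(np.float64)

    def _align(self, X) -> np.ndarray:
        M, names = _as_cells_by_genes(X)
        dense = np.asarray(M.todense(), dtype=float)
        if names is None:
            if dense.shape[1] != len(self.universe_):
                raise ValueError("unnamed test matrix must match the universe width")
            return dense
        pos = {g: i for i, g in enumerate(names)}
        out = np.zeros((dense.shape[0], len(self.universe_)))
        for k, g in enumerate(self.universe_):
            if g in pos:  # missing genes treated as count 0
                out[:, k] = dense[:, pos[g]]
        return out

    def score_matrix(self, X) -> ScoreMatrix:
        check_is_fitted(self, "forest_")
        dense = self._align(X)
        F = self._pair_matrix(dense)
        proba = self.forest_.predict_proba(F)
        forest_labels = list(self.forest_.classes_)
        real = [str(c) for c in self.classes_]
        scores = np.zeros((F.shape[0], len(real)))
        for k, c in enumerate(real):
            scores[:, k] = proba[:, forest_labels.index(c)]
        rand_scores = (
            proba[:, forest_labels.index(RAND_LABEL)]
            if RAND_LABEL in forest_labels
            else np.zeros(F.shape[0])
        )
        calls = np.asarray(real, dtype=object)[np.argmax(scores, axis=1)]
        return ScoreMatrix(
            cells=_barcodes(X, F.shape[0]),
            labels=real,
            scores=scores,
            calls=calls,
            rand_scores=rand_scores,
        )

    def predict(self, X) -> np.ndarray:
        return self.score_matrix(X).calls

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        import joblib

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        stem = path.with_suffix("")
        joblib.dump(self.forest_, f"{stem}.forest.joblib")
        meta = {
            "schema": "umithresh.pairforest/1",
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "universe": self.universe_,
            "pair_features": [list(p) for p in self.pair_features_],
            "forest_file": f"{stem.name}.forest.joblib",
        }
        path.write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PairForestClassifier":
        import joblib

        path = Path(path)
        meta = json.loads(path.read_text())
        model = cls(**meta["params"])
        model.classes_ = np.array(meta["classes"], dtype=object)
        model.universe_ = meta["universe"]
        model.pair_features_ = [tuple(p) for p in meta["pair_features"]]
        uni_pos = {g: i for i, g in enumerate(model.universe_)}
        model._pair_idx = np.array(
            [(uni_pos[a], uni_pos[b]) for a, b in model.pair_features_], dtype=int
        )
        model.forest_ = joblib.load(path.parent / meta["forest_file"])
        return model
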