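"""One-vs-rest marker-gene discovery.

For each label the rest of the cells form the contrast group; both groups
are subsampled to at most ``max_cells_per_ident`` cells.  A gene is a marker
when (i) it is detected in at least ``min_pct`` of the label's cells,
(ii) the natural-log fold change of depth-normalised (counts-per-10k) mean
expression with pseudocount 1 is at least ``logfc_threshold``, and (iii) the
chosen two-group test is significant after Bonferroni adjustment across all
genes.  Markers are ranked by descending log fold change.

The default test is the Wilcoxon rank-sum; a negative-binomial
likelihood-ratio test is available via ``test="negbinom"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .io import CountMatrix, LabelTable

__all__ = ["MarkerParams", "MarkerSet", "find_markers"]


@dataclass(frozen=True)
class MarkerParams:
    min_pct: float = 0.5
    logfc_threshold: float = 0.5
    max_cells_per_ident: int = 2000
    test: str = "wilcoxon"
    alpha: float = 0.05
    adjust: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pct <= 1.0:
            raise ValueError("min_pct must lie in [0, 1]")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be >= 0")
        if self.max_cells_per_ident < 1:
            raise ValueError("max_cells_per_ident must be >= 1")
        if self.test not in ("wilcoxon", "negbinom"):
            raise ValueError("test must be 'wilcoxon' or 'negbinom'")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError("adjust must be 'bonferroni' or 'bh'")


@dataclass
class MarkerSet:
    """Per-label ranked marker tables.

    ``tables[label]`` has columns gene, log_fold_change, pct_in, pct_out,
    adjusted_p, sorted by descending log fold change.
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: MarkerParams = field(default_factory=MarkerParams)

    def genes_for(self, label: str, top: int | None = None) -> list[str]:
        df = self.tables[label]
        if top is not None:
            df = df.head(top)
        return df["gene"].tolist()

    @property
    def labels(self) -> list[str]:
        return sorted(self.tables)

    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.labels:
            for g in self.tables[label]["gene"]:
                seen.setdefault(g, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label in self.labels:
            df = self.tables[label].copy()
            df.insert(0, "label", label)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["label", "gene", "log_fold_change", "pct_in", "pct_out", "adjusted_p"])
        return pd.concat(frames, ignore_index=True)


def _cp10k(X: sp.csr_matrix) -> sp.csr_matrix:
    """Depth-normalise rows (cells) to 10,000 counts."""
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.where(totals > 0, 1e4 / np.maximum(totals, 1), 0.0)
    return sp.csr_matrix(sp.diags(scale) @ X)


def _negbinom_pvalues(in_counts, out_counts, in_depth, out_depth) -> np.ndarray:
    """Per-gene likelihood-ratio test under a negative-binomial model.

    Fits gene-wise NB regressions (intercept + group indicator, log-depth
    offset) and compares against the intercept-only fit.
    """
    import statsmodels.api as sm
    from scipy.stats import chi2

    y = np.concatenate([in_counts, out_counts], axis=0)
    group = np.concatenate([np.ones(in_counts.shape[0]), np.zeros(out_counts.shape[0])])
    offset = np.log(np.concatenate([in_depth, out_depth]).clip(min=1))
    X0 = np.ones((y.shape[0], 1))
    X1 = np.column_stack([np.ones_like(group), group])
    pvals = np.ones(y.shape[1])
    for g in range(y.shape[1]):
        yy = y[:, g]
        # moment estimate of the NB dispersion keeps the IRLS fit stable even
        # under perfect separation (a marker absent from one group)
        mu = max(yy.mean(), 1e-8)
        alpha = max((yy.var(ddof=1) - mu) / mu**2, 1e-8)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll1 = sm.GLM(yy, X1, family=fam, offset=offset).fit().llf
                ll0 = sm.GLM(yy, X0, family=fam, offset=offset).fit().llf
            stat = max(0.0, 2.0 * (ll1 - ll0))
            pvals[g] = chi2.sf(stat, df=1)
        except Exception:
            pvals[g] = 1.0
    return pvals


def find_markers(
    m: CountMatrix,
    labels: LabelTable | pd.Series,
    params: MarkerParams | None = None,
    seed: int = 0,
    granularity: str = "cell_type",
) -> MarkerSet:
    """One-vs-rest markers for every label present on the matrix's cells."""
    p = params or MarkerParams()
    if isinstance(labels, LabelTable):
        lab = labels.for_granularity(granularity)
    else:
        lab = labels
    lab = lab.reindex(m.cells).dropna()
    uniq = sorted(lab.unique())
    if len(uniq) < 2:
        raise ValueError("marker discovery requires at least 2 labels")
    small = [l for l in uniq if (lab == l).sum() < 3]
    if small:
        raise ValueError(f"labels with fewer than 3 cells: {small}")

    X = m.subset_cells(list(lab.index)).cells_by_genes()  # cells x genes
    y = lab.values
    depth = np.asarray(X.sum(axis=1)).ravel()
    norm = _cp10k(X)
    rng = np.random.default_rng(seed)

    n_genes = m.n_genes
    tables: dict[str, pd.DataFrame] = {}
    for label in uniq:
        in_idx = np.nonzero(y == label)[0]
        out_idx = np.nonzero(y != label)[0]
        if in_idx.size > p.max_cells_per_ident:
            in_idx = np.sort(rng.choice(in_idx, p.max_cells_per_ident, replace=False))
        if out_idx.size > p.max_cells_per_ident:
            out_idx = np.sort(rng.choice(out_idx, p.max_cells_per_ident, replace=False))

        Xin, Xout = X[in_idx], X[out_idx]
        pct_in = np.asarray((Xin > 0).mean(axis=0)).ravel()
        pct_out = np.asarray((Xout > 0).mean(axis=0)).ravel()
        mean_in = np.asarray(norm[in_idx].mean(axis=0)).ravel()
        mean_out = np.asarray(norm[out_idx].mean(axis=0)).ravel()
        logfc = np.log((mean_in + 1.0) / (mean_out + 1.0))

        gate = (pct_in >= p.min_pct) & (logfc >= p.logfc_threshold)
        cand = np.nonzero(gate)[0]
        if cand.size == 0:
            warnings.warn(f"no gene passed the marker gates for label {label!r}")
            tables[label] = pd.DataFrame(
                columns=["gene", "log_fold_change", "pct_in", "pct_out", "adjusted_p"]
            )
            continue

        if p.test == "wilcoxon":
            a = np.asarray(norm[in_idx][:, cand].todense())
            b = np.asarray(norm[out_idx][:, cand].todense())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mannwhitneyu(a, b, axis=0, alternative="two-sided")
            pvals = np.atleast_1d(res.pvalue)
        else:
            pvals = _negbinom_pvalues(
                np.asarray(Xin[:, cand].todense()),
                np.asarray(Xout[:, cand].todense()),
                depth[in_idx],
                depth[out_idx],
            )

        if p.adjust == "bonferroni":
            adj = np.minimum(pvals * n_genes, 1.0)
        else:
            from statsmodels.stats.multitest import multipletests

            adj = multipletests(pvals, method="fdr_bh")[1]

        keep = adj <= p.alpha
        idx = cand[keep]
        df = pd.DataFrame(
            {
                "gene": [m.genes[i] for i in idx],
                "log_fold_change": logfc[idx],
                "pct_in": pct_in[idx],
                "pct_out": pct_out[idx],
                "adjusted_p": adj[keep],
            }
        ).sort_values("log_fold_change", ascending=False, kind="mergesort")
        if df.empty:
            warnings.warn(f"no gene passed the significance test for label {label!r}")
        tables[label] = df.reset_index(drop=True)
    return MarkerSet(tables=tables, params=p)
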