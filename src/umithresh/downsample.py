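"""Stochastic depth reduction of UMI count matrices.

Two transforms are provided:

* **Poisson multiplicative-factor downsampling** — for each cell with total
  count ``N`` and target depth ``T``, a rate ``lam = T / N`` is formed and one
  Poisson(lam) deviate is drawn per gene; the gene's count is multiplied by
  its deviate.  The expected downsampled total is ``N * lam = T``.  Note this
  is *not* binomial thinning: a gene's whole count either survives (possibly
  multiplied by k > 1) or drops to zero.  A ``binomial_thinning`` comparison
  mode is included for reference.
* **Gene dropout** — each cell expressing more than ``max_genes`` genes has a
  uniformly random subset of its expressed genes silenced until exactly
  ``max_genes`` remain; output is either the binary expression matrix or the
  original counts restricted to the surviving genes.

Randomness is drawn from per-cell substreams derived from ``(seed, cell
index)`` so matrices downsample reproducibly and cells independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "DownsampleSpec",
    "GeneDownsampleSpec",
    "poisson_pmf",
    "downsample_cell",
    "downsample_matrix",
    "binarize",
    "downsample_genes",
    "PoissonDownsampler",
    "GeneDownsampler",
]

MODES = ("paper_literal", "capped", "binomial_thinning")
GENE_OUTPUT_MODES = ("binary", "restore_counts")


@dataclass(frozen=True)
class DownsampleSpec:
    """Target UMI depth, lam-handling mode and seed.

    ``paper_literal`` uses lam = target/total even when it exceeds 1 (shallow
    cells are then up-sampled in expectation); ``capped`` clips lam at 1 so a
    cell is never inflated beyond its observed depth.
    """

    target: int
    mode: str = "paper_literal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target < 0:
            raise ValueError("target must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class GeneDownsampleSpec:
    max_genes: int
    output_mode: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_genes < 0:
            raise ValueError("max_genes must be >= 0")
        if self.output_mode not in GENE_OUTPUT_MODES:
            raise ValueError(f"output_mode must be one of {GENE_OUTPUT_MODES}")


def poisson_pmf(x, lam):
    """Poisson probability mass lam**x * exp(-lam) / x!.

    Accepts scalars or arrays; raises on negative ``x`` or ``lam``.
    """
    x_arr = np.asarray(x)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(x_arr < 0) or np.any(lam_arr < 0):
        raise ValueError("poisson_pmf requires x >= 0 and lam >= 0")
    if not np.allclose(x_arr, np.round(x_arr)):
        raise ValueError("x must be integral")
    from scipy.stats import poisson

    out = poisson.pmf(x_arr, lam_arr)
    if np.isscalar(x) and np.isscalar(lam):
        return float(out)
    return out


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,)))


def downsample_cell(
    counts: np.ndarray, spec: DownsampleSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Apply the per-gene multiplicative Poisson factor to one cell.

    Cells with zero total pass through unchanged (lam is undefined).
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total == 0:
        return counts.copy()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam = spec.target / total
    if spec.mode == "capped":
        lam = min(1.0, lam)
    if spec.mode == "binomial_thinning":
        p = min(1.0, lam)
        out = np.zeros_like(counts)
        nz = counts > 0
        out[nz] = rng.binomial(counts[nz], p)
        return out
    out = np.zeros_like(counts)
    nz = counts > 0
    # deviates for zero-count genes contribute nothing; draw only where needed
    factors = rng.poisson(lam, size=int(nz.sum()))
    out[nz] = counts[nz] * factors
    return out


def downsample_matrix(m: CountMatrix, spec: DownsampleSpec) -> CountMatrix:
    """Downsample every cell independently with per-cell substreams of the seed."""
    counts = m.genes_by_cells().tocsc()
    n_zero_total = 0
    cols = []
    for j in range(m.n_cells):
        col = counts[:, j]
        data = col.data
        if data.sum() == 0:
            n_zero_total += 1
            cols.append(col)
            continue
        rng = _cell_rng(spec.seed, j)
        lam = spec.target / float(data.sum())
        if spec.mode == "capped":
            lam = min(1.0, lam)
        if spec.mode == "binomial_thinning":
            new_data = rng.binomial(data, min(1.0, lam))
        else:
            new_data = data * rng.poisson(lam, size=data.size)
        new = sp.csc_matrix((new_data, col.indices, col.indptr), shape=col.shape)
        new.eliminate_zeros()
        cols.append(new)
    out = sp.hstack(cols, format="csc") if cols else sp.csc_matrix((m.n_genes, 0), dtype=np.int64)
    result = CountMatrix(m.genes, m.cells, out.astype(np.int64))
    result.n_zero_total_cells = n_zero_total  # type: ignore[attr-defined]
    return result


def binarize(m: CountMatrix) -> CountMatrix:
    """Binary expression matrix: 1 wherever the count is >= 1."""
    b = (m.genes_by_cells() > 0).astype(np.int64)
    return CountMatrix(m.genes, m.cells, b)


def downsample_genes(m: CountMatrix, spec: GeneDownsampleSpec) -> CountMatrix:
    """Silence random expressed genes per cell down to ``max_genes``.

    Cells already at or under ``max_genes`` expressed genes are untouched.
    ``binary`` mode returns the (masked) binary matrix; ``restore_counts``
    returns the original counts on the surviving genes.
    """
    counts = m.genes_by_cells().tocsc()
    cols = []
    for j in range(m.n_cells):
        col = counts[:, j].copy()
        expressed = col.data > 0
        e = int(expressed.sum())
        if e > spec.max_genes:
            rng = _cell_rng(spec.seed, j)
            drop_local = rng.choice(e, size=e - spec.max_genes, replace=False)
            expressed_pos = np.nonzero(expressed)[0]
            col.data[expressed_pos[drop_local]] = 0
            col.eliminate_zeros()
        cols.append(col)
    out = sp.hstack(cols, format="csc") if cols else counts
    masked = CountMatrix(m.genes, m.cells, out.astype(np.int64))
    if spec.output_mode == "binary":
        return binarize(masked)
    return masked


# ---------------------------------------------------------------------------
# transformer-style wrappers


class PoissonDownsampler:
    """Stateless transformer wrapping :func:`downsample_matrix`."""

    def __init__(self, target: int = 450, mode: str = "paper_literal", seed: int = 0):
        self.target = target
        self.mode = mode
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"target": self.target, "mode": self.mode, "seed": self.seed}

    def set_params(self, **params) -> "PoissonDownsampler":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "PoissonDownsampler":
        DownsampleSpec(self.target, self.mode, self.seed)  # validate
        return self

    def transform(self, m: CountMatrix) -> CountMatrix:
        return downsample_matrix(m, DownsampleSpec(self.target, self.mode, self.seed))


class GeneDownsampler:
    """Stateless transformer wrapping :func:`downsample_genes`."""

    def __init__(self, max_genes: int = 200, output_mode: str = "binary", seed: int = 0):
        self.max_genes = max_genes
        self.output_mode = output_mode
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"max_genes": self.max_genes, "output_mode": self.output_mode, "seed": self.seed}

    def set_params(self, **params) -> "GeneDownsampler":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "GeneDownsampler":
        GeneDownsampleSpec(self.max_genes, self.output_mode, self.seed)
        return self

    def transform(self, m: CountMatrix) -> CountMatrix:
        return downsample_genes(m, GeneDownsampleSpec(self.max_genes, self.output_mode, self.seed))
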