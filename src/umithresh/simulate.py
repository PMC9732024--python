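"""Synthetic labelled scRNA-seq-like count data.

The generator emulates the statistical structure the threshold-optimization
framework assumes about a solid-tumour dataset:

* several cell types with type-specific log-normal sequencing-depth tiers —
  a deep "epithelial-like" population and shallower stromal / lymphocyte
  populations, so a fixed UMI floor discards the shallow types
  preferentially;
* disjoint planted marker-gene blocks per type, up-weighted by a fold
  factor over a shared, highly skewed (log-normal) baseline expression
  profile;
* mitochondrial genes (``MT-`` prefix) carrying a realistic share of each
  cell's counts;
* a low-quality tail: a fraction of cells with depth multiplied down and
  mitochondrial share boosted.

Counts are gamma–Poisson (negative-binomial) draws around the cell's
depth-scaled expression proportions; dispersion 0 degenerates to pure
Poisson.  Output is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, LabelTable

__all__ = ["CellTypeSpec", "SimConfig", "SimTruth", "simulate_dataset", "default_config"]


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    lineage: str
    n_cells: int
    depth_log_mean: float
    depth_log_sd: float
    marker_gene_count: int
    marker_fold: float

    @classmethod
    def from_mean_depth(
        cls, name, lineage, n_cells, mean_depth, depth_log_sd=0.45,
        marker_gene_count=25, marker_fold=10.0,
    ) -> "CellTypeSpec":
        mu = math.log(mean_depth) - depth_log_sd**2 / 2.0
        return cls(name, lineage, n_cells, mu, depth_log_sd, marker_gene_count, marker_fold)

    @property
    def mean_depth(self) -> float:
        return math.exp(self.depth_log_mean + self.depth_log_sd**2 / 2.0)


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1500
    n_mito_genes: int = 15
    cell_types: tuple = ()
    baseline_dispersion: float = 0.3
    baseline_log_sd: float = 1.0
    type_profile_log_sd: float = 1.0
    mito_baseline_fraction: float = 0.08
    low_quality_fraction: float = 0.15
    low_quality_depth_factor: float = 0.25
    low_quality_mito_boost: float = 2.0
    n_samples: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            object.__setattr__(self, "cell_types", _default_types())
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be below n_genes")
        if sum(t.n_cells for t in self.cell_types) <= 0:
            raise ValueError("total number of cells must be positive")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise ValueError("low_quality_fraction must lie in [0, 1]")
        if not 0.0 < self.low_quality_depth_factor <= 1.0:
            raise ValueError("low_quality_depth_factor must lie in (0, 1]")
        if self.low_quality_mito_boost < 1.0:
            raise ValueError("low_quality_mito_boost must be >= 1")
        if self.baseline_dispersion < 0:
            raise ValueError("baseline_dispersion must be >= 0")
        n_marker = sum(t.marker_gene_count for t in self.cell_types)
        if n_marker > self.n_genes - self.n_mito_genes:
            raise ValueError(
                f"{n_marker} planted marker genes do not fit into "
                f"{self.n_genes - self.n_mito_genes} non-mitochondrial genes"
            )


def _default_types() -> tuple:
    """Depth tiers mimic a breast-tumour cohort where epithelial (cancer)
    cells run deep (~5,350 UMIs) while stromal (~3,100) and lymphocyte
    (~2,150 / ~1,640) populations run shallow."""
    return (
        CellTypeSpec.from_mean_depth("epithelial cells", "epithelial", 500, 5354.0),
        CellTypeSpec.from_mean_depth("fibroblasts", "stromal", 500, 3114.0),
        CellTypeSpec.from_mean_depth("T-cells", "immune", 500, 2154.0),
        CellTypeSpec.from_mean_depth("B-cells", "immune", 500, 1639.0),
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **overrides)


@dataclass
class SimTruth:
    """Per-cell ground truth for a simulated dataset."""

    table: pd.DataFrame  # index: cell barcode
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_label_table(self) -> LabelTable:
        rows = []
        for bc, row in self.table.iterrows():
            rows.append(
                {
                    "cell_barcode": bc,
                    "label": row["cell_type"],
                    "granularity": "cell_type",
                    "sample_id": row["sample_id"],
                }
            )
            rows.append(
                {
                    "cell_barcode": bc,
                    "label": row["lineage"],
                    "granularity": "lineage",
                    "sample_id": row["sample_id"],
                }
            )
        return LabelTable(pd.DataFrame(rows))


def simulate_dataset(cfg: SimConfig | None = None) -> tuple[CountMatrix, SimTruth]:
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"MT-G{i + 1}" for i in range(cfg.n_mito_genes)] + [
        f"GENE{i + 1:05d}" for i in range(cfg.n_genes - cfg.n_mito_genes)
    ]
    mito_mask = np.zeros(cfg.n_genes, dtype=bool)
    mito_mask[: cfg.n_mito_genes] = True

    # shared skewed baseline; mitochondrial genes scaled to their target share
    base = rng.lognormal(mean=0.0, sigma=cfg.baseline_log_sd, size=cfg.n_genes)
    non_mito_sum = base[~mito_mask].sum()
    target_mito = cfg.mito_baseline_fraction
    base[mito_mask] *= (target_mito / (1.0 - target_mito)) * non_mito_sum / base[mito_mask].sum()

    # disjoint planted marker blocks over non-mitochondrial genes
    marker_genes: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    cursor = cfg.n_mito_genes
    for t in cfg.cell_types:
        idx = np.arange(cursor, cursor + t.marker_gene_count)
        cursor += t.marker_gene_count
        marker_genes[t.name] = [genes[i] for i in idx]
        marker_idx[t.name] = idx
    any_marker = np.zeros(cfg.n_genes, dtype=bool)
    for idx in marker_idx.values():
        any_marker[idx] = True

    profiles = {}
    for t in cfg.cell_types:
        prof = base.copy()
        if cfg.type_profile_log_sd > 0:
            # cell types differ transcriptome-wide, not only at their markers;
            # planted marker blocks stay canonical (no jitter) so that a
            # marker of one type is never over-expressed in another
            jitter = rng.lognormal(0.0, cfg.type_profile_log_sd, size=cfg.n_genes)
            jitter[any_marker] = 1.0
            prof *= jitter
        prof[marker_idx[t.name]] *= t.marker_fold
        profiles[t.name] = prof / prof.sum()

    rows = []
    cols = []
    barcodes = []
    truth_rows = []
    shape = 1.0 / cfg.baseline_dispersion if cfg.baseline_dispersion > 0 else None
    cell_i = 0
    for t in cfg.cell_types:
        prof = profiles[t.name]
        for _ in range(t.n_cells):
            depth = rng.lognormal(t.depth_log_mean, t.depth_log_sd)
            low_quality = bool(rng.random() < cfg.low_quality_fraction)
            p = prof
            if low_quality:
                depth *= cfg.low_quality_depth_factor
                p = prof.copy()
                p[mito_mask] *= cfg.low_quality_mito_boost
                p /= p.sum()
            rate = depth * p
            if shape is not None:
                rate = rate * rng.gamma(shape, 1.0 / shape, size=cfg.n_genes)
            counts = rng.poisson(rate)
            nz = np.nonzero(counts)[0]
            rows.append(nz)
            cols.append(counts[nz])
            bc = f"cell{cell_i:05d}"
            barcodes.append(bc)
            truth_rows.append(
                {
                    "cell_barcode": bc,
                    "cell_type": t.name,
                    "lineage": t.lineage,
                    "sample_id": f"sample{cell_i % cfg.n_samples + 1}",
                    "intended_depth": float(depth),
                    "low_quality": low_quality,
                }
            )
            cell_i += 1

    indptr = np.concatenate([[0], np.cumsum([len(r) for r in rows])])
    mat = sp.csc_matrix(
        (np.concatenate(cols), np.concatenate(rows), indptr),
        shape=(cfg.n_genes, cell_i),
        dtype=np.int64,
    )
    truth = SimTruth(
        table=pd.DataFrame(truth_rows).set_index("cell_barcode"),
        marker_genes=marker_genes,
    )
    return CountMatrix(genes, barcodes, mat), truth
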