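"""Per-cell quality-control statistics, QC partitioning and lineage maps.

The default thresholds reproduce a stringent breast-tumour gold-standard
filter: cells are kept when they have more than 1,500 total UMIs, between
500 and 7,000 expressed genes, under 20% mitochondrial content, and at most
15,000 UMIs (a cap against missed doublets).  Cells that fail *only* the
depth / gene floor form the rescue pool that a lowered, optimized threshold
can re-admit; cells failing the mitochondrial or doublet rules are excluded
outright and are never rescuable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, LabelTable

__all__ = [
    "QCThresholds",
    "LineageMap",
    "DEFAULT_LINEAGE_MAP",
    "compute_cell_stats",
    "apply_qc",
    "aggregate_to_lineage",
]

HIGH_QUALITY = "high_quality"
RESCUE_POOL = "rescue_pool"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class QCThresholds:
    """Boundary conventions follow the filter's wording literally:
    strict ``>`` on the UMI floor, inclusive gene bounds, strict ``<`` on
    the mitochondrial fraction, strict ``>`` on the doublet cap."""

    min_umis: int = 1500
    min_genes: int = 500
    max_genes: int = 7000
    max_mito: float = 0.20
    doublet_umi_cap: int = 15000

    def __post_init__(self) -> None:
        if self.min_umis < 0:
            raise ValueError("min_umis must be >= 0")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ValueError("max_mito must lie in [0, 1]")


# cell-type -> lineage aggregation used for coarse labels
DEFAULT_LINEAGE_MAP: dict[str, str] = {
    "epithelial cells": "epithelial",
    "fibroblasts": "stromal",
    "endothelial cells": "stromal",
    "chondrocytes": "stromal",
    "osteoblast": "stromal",
    "smooth muscles": "stromal",
    "T-cells": "immune",
    "B-cells": "immune",
    "macrophages": "immune",
    "monocytes": "immune",
    "NK cells": "immune",
    "neutrophils": "immune",
}


@dataclass
class LineageMap:
    """Many-to-one map from cell-type label to lineage label."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGE_MAP))

    def __getitem__(self, cell_type: str) -> str:
        return self.mapping[cell_type]

    def __contains__(self, cell_type: str) -> bool:
        return cell_type in self.mapping


def compute_cell_stats(m: CountMatrix, mito_gene_pattern: str = "MT-") -> pd.DataFrame:
    """Per-cell totals, expressed-gene counts and mitochondrial fractions.

    Returns a DataFrame indexed by ``cell_barcode`` with columns
    ``total_umis``, ``n_genes`` and ``mito_fraction``.  The mitochondrial
    fraction of an all-zero cell is defined as 0.
    """
    if not mito_gene_pattern:
        raise ValueError("mito_gene_pattern must be a non-empty prefix")
    counts = m.genes_by_cells()
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_rows = np.array([g.startswith(mito_gene_pattern) for g in m.genes], dtype=bool)
    if mito_rows.any():
        mito = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "total_umis": total.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_fraction": frac,
        },
        index=pd.Index(m.cells, name="cell_barcode"),
    )


def apply_qc(stats: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.Series:
    """Partition cells into high_quality / rescue_pool / excluded.

    ``excluded`` holds cells that fail the mitochondrial or doublet-cap
    rules (never rescuable); ``high_quality`` holds cells passing every
    rule; everything else — cells failing only the UMI / gene floor —
    lands in ``rescue_pool``.  The three sets are disjoint and exhaustive.
    """
    t = thresholds or QCThresholds()
    total = stats["total_umis"]
    n_genes = stats["n_genes"]
    mito = stats["mito_fraction"]

    excluded = (mito >= t.max_mito) | (total > t.doublet_umi_cap)
    passes_depth = (total > t.min_umis) & (n_genes >= t.min_genes) & (n_genes <= t.max_genes)
    high = ~excluded & passes_depth

    part = pd.Series(RESCUE_POOL, index=stats.index, name="qc_partition", dtype=object)
    part[excluded] = EXCLUDED
    part[high] = HIGH_QUALITY
    return part


def aggregate_to_lineage(
    labels: LabelTable, lineage_map: LineageMap | dict | None = None, strict: bool = True
) -> LabelTable:
    """Map cell-type labels to lineage labels, preserving cardinality.

    With ``strict=False`` unmapped cell types become ``"unassigned"``.
    """
    mapping = lineage_map.mapping if isinstance(lineage_map, LineageMap) else lineage_map
    if mapping is None:
        mapping = DEFAULT_LINEAGE_MAP
    df = labels.table
    ct = df[df["granularity"] == "cell_type"].copy()
    unmapped = sorted(set(ct["label"]) - set(mapping))
    if unmapped and strict:
        raise KeyError(f"cell types without a lineage mapping: {unmapped}")
    ct["label"] = ct["label"].map(mapping).fillna("unassigned")
    ct["granularity"] = "lineage"
    return LabelTable(ct.reset_index(drop=True))
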