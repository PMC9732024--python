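"""Reading and writing count matrices, label tables and run configs.

On disk the matrix follows the 10x Genomics convention: genes are rows,
cells are columns, and the Matrix Market triplet file is accompanied by
``features.tsv`` / ``barcodes.tsv`` siblings (gzipped variants accepted
transparently).  Matrix Market coordinates are 1-based on disk and 0-based
in memory, as usual.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "LabelTable",
    "read_count_matrix",
    "write_count_matrix",
    "read_labels",
    "write_labels",
    "read_config",
]

GRANULARITIES = ("lineage", "cell_type")


class ValidationError(ValueError):
    """Raised when an on-disk object violates a format invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})
        raise ValidationError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI count matrix, genes x cells.

    Attributes
    ----------
    genes : list of str
        Gene identifiers (rows).
    cells : list of str
        Cell barcodes (columns).
    counts : scipy.sparse.csc_matrix
        Integer counts with shape ``(len(genes), len(cells))``.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csc_matrix

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        self.counts = sp.csc_matrix(self.counts)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.genes)}, {len(self.cells)})"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                g, c = self._offending(lambda d: d < 0)
                raise ValidationError(
                    f"negative count at gene {self.genes[g]!r}, cell {self.cells[c]!r}"
                )
            if not np.allclose(data, np.round(data)):
                g, c = self._offending(lambda d: ~np.isclose(d, np.round(d)))
                raise ValidationError(
                    f"non-integer count at gene {self.genes[g]!r}, cell {self.cells[c]!r}"
                )
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)

    def _offending(self, pred) -> tuple[int, int]:
        coo = self.counts.tocoo()
        bad = np.nonzero(pred(coo.data))[0][0]
        return int(coo.row[bad]), int(coo.col[bad])

    # -- accessors -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def genes_by_cells(self) -> sp.csc_matrix:
        """Counts with genes as rows (the on-disk orientation)."""
        return self.counts

    def cells_by_genes(self) -> sp.csr_matrix:
        """Counts with cells as rows (the estimator orientation)."""
        return sp.csr_matrix(self.counts.T)

    def cell_index(self, barcodes: Iterable[str]) -> np.ndarray:
        pos = {b: i for i, b in enumerate(self.cells)}
        try:
            return np.array([pos[b] for b in barcodes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"barcode {exc.args[0]!r} not in matrix") from None

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index(barcodes)
        return CountMatrix(self.genes, [self.cells[i] for i in idx], self.counts[:, idx])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CountMatrix([self.genes[i] for i in idx], self.cells, self.counts[idx, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.cells == other.cells
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class LabelTable:
    """Cell annotations: one row per (cell_barcode, granularity).

    Columns: ``cell_barcode``, ``label``, ``granularity`` (one of
    ``lineage`` / ``cell_type``), optional ``sample_id``.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("cell_barcode", "label", "granularity")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"label table missing required column {col!r}")
        bad = sorted(set(df["granularity"]) - set(GRANULARITIES))
        if bad:
            raise ValidationError(f"unknown granularity values: {bad}")
        dup = df.duplicated(subset=["cell_barcode", "granularity"], keep=False)
        if dup.any():
            dups = sorted(df.loc[dup, "cell_barcode"].unique().tolist())
            raise ValidationError(
                f"duplicate (cell_barcode, granularity) rows for barcodes {dups[:10]}"
            )
        self.table = df.reset_index(drop=True)

    def for_granularity(self, granularity: str) -> pd.Series:
        """Labels at one granularity as a Series indexed by barcode."""
        sub = self.table[self.table["granularity"] == granularity]
        return pd.Series(sub["label"].values, index=sub["cell_barcode"].values, name="label")

    def subset(self, barcodes: Sequence[str]) -> "LabelTable":
        keep = self.table["cell_barcode"].isin(set(barcodes))
        return LabelTable(self.table.loc[keep].copy())

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        a = self.table.fillna("")
        b = other.table.fillna("")
        return list(a.columns) == list(b.columns) and a.equals(b)


# ---------------------------------------------------------------------------
# count-matrix I/O


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_sibling(base: Path, names: Sequence[str]) -> Path:
    for name in names:
        for cand in (base / name, base / (name + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {list(names)} found next to matrix in {base}")


def _resolve_mtx_dir(path: Path) -> tuple[Path, Path, Path]:
    path = Path(path)
    if path.is_dir():
        mtx = _find_sibling(path, ["matrix.mtx"])
        base = path
    else:
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        mtx, base = path, path.parent
    features = _find_sibling(base, ["features.tsv", "genes.tsv"])
    barcodes = _find_sibling(base, ["barcodes.tsv"])
    return mtx, features, barcodes


def _read_id_column(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(path, dialect: str = "mtx_triplet") -> CountMatrix:
    """Read a genes x cells UMI matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: the ``matrix.mtx[.gz]`` file or the directory
        holding the 10x trio. For ``dense_csv``: a CSV with gene ids in the
        first column and one column per cell barcode.
    dialect
        ``mtx_triplet`` or ``dense_csv``.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mtx, features, barcodes = _resolve_mtx_dir(path)
        with _open_maybe_gz(mtx, "rb") as fh:
            mat = scipy.io.mmread(fh)
        genes = _read_id_column(features)
        cells = _read_id_column(barcodes)
        return CountMatrix(genes, cells, sp.csc_matrix(mat))
    if dialect == "dense_csv":
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            sp.csc_matrix(df.to_numpy()),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_matrix(m: CountMatrix, path, dialect: str = "mtx_triplet") -> None:
    """Write ``m`` so that :func:`read_count_matrix` round-trips exactly."""
    path = Path(path)
    if dialect == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        # mmwrite emits an integer-field file for integer dtypes
        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, m.counts.tocoo())
        (path / "matrix.mtx").write_bytes(buf.getvalue())
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in m.genes))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cells))
        return
    if dialect == "dense_csv":
        df = pd.DataFrame(m.counts.toarray(), index=m.genes, columns=m.cells)
        df.index.name = "gene"
        df.to_csv(path)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# label-table I/O


def _sep_for(path: Path) -> str:
    return "\t" if str(path).removesuffix(".gz").endswith(".tsv") else ","


def read_labels(path) -> LabelTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return LabelTable(df)


def write_labels(t: LabelTable, path) -> None:
    path = Path(path)
    t.table.to_csv(path, sep=_sep_for(path), index=False)


def read_config(path) -> dict:
    """Read a JSON or YAML run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
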