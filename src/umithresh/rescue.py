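"""Apply the optimized UMI threshold and account for rescued cells.

Rescued cells are members of the QC rescue pool whose total UMI count
exceeds the optimized threshold (same strict-``>`` convention as the
original floor).  Their class identity for gain accounting comes from the
trained classifier's calls, since ground truth is unknown for real rescue
pools; when a truth table is supplied (synthetic data) an agreement table
is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, LabelTable
from .qc import HIGH_QUALITY, RESCUE_POOL

__all__ = ["RescueReport", "rescue_cells"]


@dataclass
class RescueReport:
    optimized_threshold: int
    initial_threshold: int
    gains: pd.DataFrame  # per (granularity, label): initial/rescued/still-excluded counts
    rescued_labels: LabelTable
    composition: pd.DataFrame | None = None  # per-sample class frequencies before/after
    agreement: dict = field(default_factory=dict, repr=False)

    def percent_gain(self, granularity: str, label: str) -> float:
        g = self.gains
        row = g[(g["granularity"] == granularity) & (g["label"] == label)]
        return float(row["percent_gain"].iloc[0])

    def to_json_dict(self) -> dict:
        return {
            "optimized_threshold": self.optimized_threshold,
            "initial_threshold": self.initial_threshold,
            "gains": self.gains.to_dict(orient="records"),
            "n_rescued": int(len(self.rescued_labels.table) // max(1, self.rescued_labels.table["granularity"].nunique())),
        }


def _per_class_counts(labels: np.ndarray) -> pd.Series:
    return pd.Series(labels).value_counts().sort_index()


def rescue_cells(
    m: CountMatrix,
    stats: pd.DataFrame,
    partition: pd.Series,
    t_opt: int,
    classifiers: dict,
    hq_labels: LabelTable,
    initial_threshold: int = 1500,
    sample_ids: pd.Series | None = None,
    truth: LabelTable | None = None,
) -> RescueReport:
    """Classify and tabulate the cells a lowered threshold re-admits.

    Parameters
    ----------
    classifiers
        Mapping granularity -> fitted classifier with ``score_matrix``.
    hq_labels
        Labels of the initially retained (high-quality) cells, used for the
        per-class initial counts.
    truth
        Optional ground-truth labels of rescue-pool cells; when given, a
        truth-vs-call agreement confusion table is added per granularity.
    """
    if t_opt >= initial_threshold:
        raise ValueError(
            f"optimized threshold {t_opt} must be below the initial threshold "
            f"{initial_threshold}: nothing to rescue"
        )
    pool = partition.index[partition == RESCUE_POOL]
    totals = stats.loc[pool, "total_umis"]
    rescued_barcodes = list(totals.index[totals > t_opt])
    still_excluded = list(totals.index[totals <= t_opt])
    hq_barcodes = list(partition.index[partition == HIGH_QUALITY])

    # classify rescued cells at every requested granularity
    rescued_rows = []
    calls_by_gran: dict[str, pd.Series] = {}
    agreement: dict[str, pd.DataFrame] = {}
    if rescued_barcodes:
        sub = m.subset_cells(rescued_barcodes)
        for gran, model in sorted(classifiers.items()):
            sm = model.score_matrix(sub)
            calls = pd.Series(sm.calls, index=rescued_barcodes)
            calls_by_gran[gran] = calls
            for bc, call in calls.items():
                rescued_rows.append({"cell_barcode": bc, "label": call, "granularity": gran})
            if truth is not None:
                from .evaluate import confusion_matrix

                tr = truth.for_granularity(gran).reindex(rescued_barcodes)
                ok = tr.notna()
                if ok.any():
                    agreement[gran] = confusion_matrix(
                        tr[ok].to_numpy(dtype=object), calls[ok].to_numpy(dtype=object)
                    )
    rescued_labels = LabelTable(
        pd.DataFrame(rescued_rows, columns=["cell_barcode", "label", "granularity"])
    )

    # per-class gain accounting
    gain_rows = []
    for gran in sorted(classifiers):
        initial = _per_class_counts(
            hq_labels.for_granularity(gran).reindex(hq_barcodes).dropna().to_numpy(dtype=object)
        )
        rescued = (
            _per_class_counts(calls_by_gran[gran].to_numpy(dtype=object))
            if gran in calls_by_gran
            else pd.Series(dtype=int)
        )
        for label in sorted(set(initial.index) | set(rescued.index)):
            ini = int(initial.get(label, 0))
            res = int(rescued.get(label, 0))
            gain_rows.append(
                {
                    "granularity": gran,
                    "label": label,
                    "initial_count": ini,
                    "rescued_count": res,
                    "percent_gain": 100.0 * res / ini if ini > 0 else np.nan,
                    "is_new": ini == 0,
                }
            )
        gain_rows.append(
            {
                "granularity": gran,
                "label": "__total__",
                "initial_count": int(initial.sum()),
                "rescued_count": int(rescued.sum()),
                "percent_gain": 100.0 * rescued.sum() / initial.sum() if initial.sum() else np.nan,
                "is_new": False,
            }
        )
    gains = pd.DataFrame(gain_rows)
    gains.attrs["still_excluded_count"] = len(still_excluded)

    composition = None
    if sample_ids is not None:
        composition = _composition(
            hq_barcodes, rescued_barcodes, hq_labels, calls_by_gran, sample_ids, sorted(classifiers)
        )

    return RescueReport(
        optimized_threshold=t_opt,
        initial_threshold=initial_threshold,
        gains=gains,
        rescued_labels=rescued_labels,
        composition=composition,
        agreement=agreement,
    )


def _composition(hq_barcodes, rescued_barcodes, hq_labels, calls_by_gran, sample_ids, grans):
    """Per-sample relative class frequencies before and after rescue."""
    rows = []
    for gran in grans:
        before = hq_labels.for_granularity(gran).reindex(hq_barcodes).dropna()
        after = before.copy()
        if gran in calls_by_gran:
            after = pd.concat([before, calls_by_gran[gran]])
        for phase, series in (("before", before), ("after", after)):
            df = pd.DataFrame({"label": series, "sample_id": sample_ids.reindex(series.index)})
            df = df.dropna()
            freq = (
                df.groupby(["sample_id", "label"], observed=True).size()
                / df.groupby("sample_id", observed=True).size()
            )
            for (sid, label), f in freq.items():
                rows.append(
                    {
                        "granularity": gran,
                        "phase": phase,
                        "sample_id": sid,
                        "label": label,
                        "frequency": float(f),
                    }
                )
    return pd.DataFrame(rows)
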