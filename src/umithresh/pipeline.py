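"""End-to-end orchestration: qc -> split -> markers -> train -> sweep -> select -> rescue.

A single master seed drives the whole run; each stage derives its own seed
through a fixed ``SeedSequence(entropy=master_seed, spawn_key=(stage_id,))``
hash, so adding a stage never perturbs earlier stages' randomness and
re-running a config reproduces every artifact bit for bit.  Every artifact
is written under the output directory and listed in ``manifest.json`` with
its SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import CorrelationClassifier, PairForestClassifier
from .downsample import MODES
from .evaluate import (
    DEFAULT_GRID,
    SplitSpec,
    SweepModel,
    select_threshold,
    threshold_sweep,
)
from .io import CountMatrix, LabelTable, read_count_matrix, read_labels, write_count_matrix, write_labels
from .markers import MarkerParams, find_markers
from .qc import QCThresholds, apply_qc, compute_cell_stats
from .rescue import rescue_cells
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("umithresh")

STAGE_IDS = {"simulate": 0, "split": 1, "markers": 2, "train": 3, "sweep": 4, "rescue": 5}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Either ``sim`` (synthetic-data parameters) or ``matrix_path`` +
    ``labels_path`` must be provided.
    """

    out_dir: str = "run"
    master_seed: int = 0
    sim: dict | None = None
    matrix_path: str | None = None
    matrix_dialect: str = "mtx_triplet"
    labels_path: str | None = None
    qc: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    classifiers: tuple = ("correlation", "pairforest")
    correlation: dict = field(default_factory=dict)
    pairforest: dict = field(default_factory=dict)
    grid: tuple = DEFAULT_GRID
    downsample_mode: str = "paper_literal"
    auc_cutoff: float = 0.9
    select_classifier: str = "correlation"
    select_granularity: str = "cell_type"
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("at least one classifier must be enabled")
        bad = set(self.classifiers) - {"correlation", "pairforest"}
        if bad:
            raise ValueError(f"unknown classifiers: {sorted(bad)}")
        if self.downsample_mode not in MODES:
            raise ValueError(f"downsample_mode must be one of {MODES}")
        if self.sim is None and (self.matrix_path is None or self.labels_path is None):
            raise ValueError("provide either sim parameters or matrix_path + labels_path")
        if self.select_classifier not in self.classifiers:
            raise ValueError("select_classifier must be one of the enabled classifiers")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("classifiers", "grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        d["grid"] = list(self.grid)
        return d


def _stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "schema": "umithresh.manifest/1",
        "version": __version__,
        "config": {k: v for k, v in cfg.to_dict().items() if k != "out_dir"},
        "stages": {},
    }

    def record(name: str, rel: str) -> None:
        artifacts[name] = rel

    stage = "simulate"
    try:
        if cfg.sim is not None:
            sim_cfg = SimConfig(**{**cfg.sim, "seed": _stage_seed(cfg.master_seed, "simulate")})
            matrix, truth = simulate_dataset(sim_cfg)
            labels = truth.to_label_table()
            write_count_matrix(matrix, out / "matrix", dialect="mtx_triplet")
            write_labels(labels, out / "labels.tsv")
            record("matrix", "matrix/matrix.mtx")
            record("labels", "labels.tsv")
        else:
            matrix = read_count_matrix(cfg.matrix_path, dialect=cfg.matrix_dialect)
            labels = read_labels(cfg.labels_path)
            truth = None
        log.info("dataset: %d genes x %d cells", matrix.n_genes, matrix.n_cells)

        stage = "qc"
        stats = compute_cell_stats(matrix, cfg.mito_prefix)
        thresholds = QCThresholds(**cfg.qc)
        partition = apply_qc(stats, thresholds)
        stats_out = stats.copy()
        stats_out["qc_partition"] = partition
        stats_out.to_csv(out / "cell_stats.csv")
        record("cell_stats", "cell_stats.csv")
        counts = partition.value_counts().to_dict()
        manifest["stages"]["qc"] = {"partition_counts": {k: int(v) for k, v in counts.items()}}
        log.info("qc partition: %s", counts)

        stage = "split"
        hq = partition.index[partition == "high_quality"]
        gold = labels.subset(list(hq))
        ct = gold.for_granularity("cell_type")
        split = SplitSpec(**{**cfg.split, "seed": _stage_seed(cfg.master_seed, "split")})
        train_ids, test_ids = [], []
        from .evaluate import stratified_split

        train_ids, test_ids = stratified_split(ct, split)
        (out / "split.json").write_text(
            json.dumps({"train": train_ids, "test": test_ids}, sort_keys=True)
        )
        record("split", "split.json")
        log.info("split: %d train / %d test cells", len(train_ids), len(test_ids))

        m_train = matrix.subset_cells(train_ids)
        m_test = matrix.subset_cells(test_ids)
        y = {g: gold.for_granularity(g) for g in ("lineage", "cell_type")}

        stage = "markers"
        marker_params = MarkerParams(**cfg.markers)
        marker_seed = _stage_seed(cfg.master_seed, "markers")
        marker_sets = {}
        need_markers = "pairforest" in cfg.classifiers
        if need_markers:
            for gran in ("lineage", "cell_type"):
                ms = find_markers(
                    m_train, y[gran].reindex(train_ids), marker_params, seed=marker_seed
                )
                marker_sets[gran] = ms
                ms.to_frame().to_csv(out / f"markers_{gran}.tsv", sep="\t", index=False)
                record(f"markers_{gran}", f"markers_{gran}.tsv")

        stage = "train"
        train_seed = _stage_seed(cfg.master_seed, "train")
        models: list[SweepModel] = []
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for gran in ("lineage", "cell_type"):
            y_train = y[gran].reindex(train_ids).to_numpy(dtype=object)
            if "correlation" in cfg.classifiers:
                clf = CorrelationClassifier(**cfg.correlation)
                clf.fit(m_train, y_train)
                clf.save(models_dir / f"correlation_{gran}.json")
                record(f"model_correlation_{gran}", f"models/correlation_{gran}.json")
                models.append(SweepModel("correlation", clf, gran))
            if "pairforest" in cfg.classifiers:
                clf = PairForestClassifier(**{**cfg.pairforest, "random_state": train_seed})
                clf.fit(m_train, y_train, markers=marker_sets[gran])
                clf.save(models_dir / f"pairforest_{gran}.json")
                record(f"model_pairforest_{gran}", f"models/pairforest_{gran}.json")
                models.append(SweepModel("pairforest", clf, gran))

        stage = "sweep"
        sweep = threshold_sweep(
            m_test,
            gold,
            models,
            grid=cfg.grid,
            base_seed=_stage_seed(cfg.master_seed, "sweep"),
            mode=cfg.downsample_mode,
        )
        sweep.table.to_csv(out / "sweep.csv", index=False)
        record("sweep", "sweep.csv")

        selected = select_threshold(
            sweep, cfg.auc_cutoff, cfg.select_classifier, cfg.select_granularity
        )
        selection = {
            "cutoff": cfg.auc_cutoff,
            "classifier": cfg.select_classifier,
            "granularity": cfg.select_granularity,
            "selected_threshold": selected,
        }
        (out / "selection.json").write_text(json.dumps(selection, sort_keys=True))
        record("selection", "selection.json")
        log.info("selected threshold: %s", selected)

        stage = "rescue"
        min_umis = thresholds.min_umis
        if selected is not None and selected < min_umis:
            by_gran = {m.name: {} for m in models}
            for m in models:
                by_gran[m.name][m.granularity] = m.model
            clf_for_rescue = by_gran[cfg.select_classifier]
            sample_ids = None
            if "sample_id" in labels.table.columns:
                sid = labels.table.drop_duplicates("cell_barcode").set_index("cell_barcode")[
                    "sample_id"
                ]
                if sid.notna().any():
                    sample_ids = sid
            report = rescue_cells(
                matrix,
                stats,
                partition,
                selected,
                clf_for_rescue,
                gold,
                initial_threshold=min_umis,
                sample_ids=sample_ids,
                truth=labels if cfg.sim is not None else None,
            )
            report.gains.to_csv(out / "rescue_gains.csv", index=False)
            write_labels(report.rescued_labels, out / "rescued_labels.tsv")
            (out / "rescue.json").write_text(json.dumps(report.to_json_dict(), sort_keys=True))
            record("rescue_gains", "rescue_gains.csv")
            record("rescued_labels", "rescued_labels.tsv")
            record("rescue", "rescue.json")
        else:
            manifest["stages"]["rescue"] = {"skipped": True, "selected": selected}
    except Exception as exc:
        partial = dict(manifest)
        partial["failed_stage"] = stage
        partial["error"] = str(exc)
        partial["artifacts"] = {k: {"path": v} for k, v in artifacts.items()}
        (out / "manifest.partial.json").write_text(json.dumps(partial, indent=1, sort_keys=True))
        raise PipelineError(stage, exc) from exc

    manifest["selected_threshold"] = selected
    manifest["artifacts"] = {
        name: {"path": rel, "sha256": _sha256(out / rel)} for name, rel in sorted(artifacts.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
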