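"""End-to-end experiment runner: simulate/load -> fit -> evaluate -> explain.

Every stage is seeded explicitly and the emitted bundle (JSON reports, CSV
tables, model checkpoint, manifest) suffices to re-run bit-identically or to
recompute the metrics from the saved predictions alone.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import FeatureTable, read_table
from .evaluation import BootstrapConfig, metric_report
from .explain import per_sample_report
from .model import NAMClassifier
from .nam import NAMConfig
from .synthetic import SyntheticSpec, default_hematology_spec, generate_cohort
from .training import TrainConfig

log = logging.getLogger("hemonam")


@dataclass
class RunConfig:
    """Everything one experiment needs; every stochastic stage has a seed."""

    input_csv: str | None = None           # mutually exclusive with synthetic
    synthetic: SyntheticSpec | None = None
    label_column: str = "label"
    test_fraction: float = 0.2
    split_seed: int = 0
    augment: str | None = "train-only"     # train-only | pre-split | none
    monitor_fraction: float = 0.1
    nam: NAMConfig = field(default_factory=NAMConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    calibration_bins: int = 10
    output_dir: str = "hemonam_run"
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.pop("schema_version", None)
        nam = NAMConfig(**{**doc.pop("nam", {})})
        if isinstance(nam.hidden_sizes, list):
            nam.hidden_sizes = tuple(nam.hidden_sizes)
        train = TrainConfig(**doc.pop("train", {}))
        boot = BootstrapConfig(**doc.pop("bootstrap", {}))
        synth = doc.pop("synthetic", None)
        spec = None
        if synth is not None:
            if isinstance(synth, dict) and set(synth) <= {"n", "seed"}:
                spec = default_hematology_spec(**synth)
            else:
                raise ValueError("synthetic config must give n and/or seed "
                                 "(custom specs are loaded from JSON via "
                                 "SyntheticSpec.from_json)")
        return cls(synthetic=spec, nam=nam, train=train, bootstrap=boot,
                   **doc)


@dataclass
class RunBundle:
    """Paths of every artifact one run produced."""

    output_dir: Path
    manifest: dict

    def path(self, key: str) -> Path:
        return self.output_dir / self.manifest["files"][key]


def _load_input(config: RunConfig) -> tuple[FeatureTable, object | None]:
    if (config.input_csv is None) == (config.synthetic is None):
        raise ValueError("exactly one of input_csv / synthetic must be set")
    if config.input_csv is not None:
        log.info("stage=load reading cohort from %s", config.input_csv)
        return read_table(config.input_csv, config.label_column), None
    log.info("stage=simulate generating synthetic cohort n=%d seed=%d",
             config.synthetic.n, config.synthetic.seed)
    table, gt = generate_cohort(config.synthetic)
    return table, gt


def run_experiment(config: RunConfig) -> RunBundle:
    """Execute all stages and write the artifact bundle.

    Identical config (seeds included) produces a bit-identical bundle.
    Any stage failure is re-raised with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        table, gt = _load_input(config)

        stage = "fit"
        log.info("stage=fit split=%.2f augment=%s", config.test_fraction,
                 config.augment)
        augment = None if config.augment in (None, "none") else config.augment
        model = NAMClassifier(table, nam_config=config.nam,
                              train_config=config.train, add_ratios=True)
        res = model.fit(test_fraction=config.test_fraction,
                        split_seed=config.split_seed, augment=augment,
                        monitor_fraction=config.monitor_fraction,
                        seed=config.train.seed)
        log.info("stage=fit modeling-table rows=%d stopped epoch=%d "
                 "best=%d", res.train_table.n + res.test_table.n,
                 res.trace.stop_epoch, res.trace.best_epoch)

        stage = "evaluate"
        metrics = res.metrics(bootstrap=config.bootstrap)
        calib = res.calibration(n_bins=config.calibration_bins)
        log.info("stage=evaluate accuracy=%.3f auc=%.3f brier=%.4f",
                 metrics["accuracy"], metrics["roc_auc"], calib.brier)

        stage = "explain"
        attrs = res.attributions()
        importance = res.importance(bootstrap=config.bootstrap)
        classwise = res.classwise()
        examples = [per_sample_report(attrs, i, top_k=10)
                    for i in range(min(4, attrs.n))]

        stage = "write"
        files = {
            "metrics": "metrics.json",
            "calibration": "calibration.json",
            "importance": "importance.json",
            "classwise": "classwise.json",
            "attributions": "attributions.csv",
            "predictions": "predictions.csv",
            "trace": "trace.csv",
            "checkpoint": "checkpoint.json",
            "per_sample": "per_sample_reports.json",
            "run_meta": "run_meta.json",
        }
        (out / files["metrics"]).write_text(
            json.dumps(metrics.to_dict(), indent=1))
        (out / files["calibration"]).write_text(
            json.dumps(calib.to_dict(), indent=1))
        (out / files["importance"]).write_text(
            json.dumps(importance.to_dict(), indent=1))
        (out / files["classwise"]).write_text(
            json.dumps(classwise.to_dict(), indent=1))
        attrs.to_dataframe().to_csv(out / files["attributions"], index=False)
        pd.DataFrame({
            "probability": res.test_predictions.probabilities,
            "logit": res.test_predictions.logits,
            "label": res.test_table.labels,
        }).to_csv(out / files["predictions"], index=False)
        res.trace.to_dataframe().to_csv(out / files["trace"], index=False)
        res.params.save(out / files["checkpoint"], res.scaler)
        (out / files["per_sample"]).write_text(json.dumps(examples, indent=1))
        meta = {
            "version": __version__,
            "schema_version": config.schema_version,
            "config": {
                "input_csv": config.input_csv,
                "synthetic": None if config.synthetic is None else
                             {"n": config.synthetic.n,
                              "seed": config.synthetic.seed},
                "test_fraction": config.test_fraction,
                "split_seed": config.split_seed,
                "augment": config.augment,
                "monitor_fraction": config.monitor_fraction,
                "nam": {"hidden_sizes": list(config.nam.hidden_sizes),
                        "dropout_rate": config.nam.dropout_rate},
                "train": config.train.__dict__,
                "bootstrap": config.bootstrap.__dict__,
                "calibration_bins": config.calibration_bins,
            },
        }
        (out / files["run_meta"]).write_text(json.dumps(meta, indent=1))
        if gt is not None:
            files["synthetic_spec"] = "synthetic_spec.json"
            config.synthetic.to_json(out / files["synthetic_spec"])
            files["cohort"] = "cohort.csv"
            table.write_csv(out / files["cohort"])
        manifest = {"files": files}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return RunBundle(out, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def evaluate_predictions_csv(path: str | Path, threshold: float = 0.5,
                             bootstrap: BootstrapConfig | None = None):
    """Recompute the metric suite from a saved predictions CSV."""
    df = pd.read_csv(path)
    return metric_report(df["probability"].to_numpy(),
                         df["label"].to_numpy(dtype=int), threshold,
                         bootstrap)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
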