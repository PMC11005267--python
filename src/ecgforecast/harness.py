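"""Experiment orchestration: per-record preprocess/train/predict and the
RMSE/MAE comparison tables.

Each record gets its own freshly initialised model per registered
architecture (no pooled training). Metrics are computed in normalized
space and de-normalized back to mV for the table output; both are kept in
the per-record results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import model as mdl
from .embedding import EmbeddingConfig, embed, split_train_eval
from .preprocess import denoise, zscore_fit_apply
from .signal_io import ECGRecord, read_csv_record
from .synth_ecg import NoiseSpec, SynthConfig, generate_clean_ecg, add_noise

__all__ = [
    "ExperimentConfig",
    "ComparisonTable",
    "MODEL_REGISTRY",
    "run_experiment",
    "relative_reduction",
]

logger = logging.getLogger(__name__)


def _unimplemented(name: str) -> Callable:
    def factory(**_kwargs):
        raise NotImplementedError(
            f"comparison slot {name!r} is registered but not implemented"
        )

    return factory


# Comparison slots; only the recurrent pair is implemented.
MODEL_REGISTRY: dict[str, Callable] = {
    "nested_lstm": mdl.NestedLSTM,
    "lstm": mdl.PlainLSTM,
    "bi_lstm": _unimplemented("bi_lstm"),
    "esn": _unimplemented("esn"),
    "svm": _unimplemented("svm"),
}


@dataclass
class RecordSpec:
    """One experiment input: either a CSV path or a synthesis request."""

    record_id: str
    csv_path: Optional[str] = None
    synth: Optional[SynthConfig] = None

    def load(self) -> ECGRecord:
        if (self.csv_path is None) == (self.synth is None):
            raise ValueError(f"record {self.record_id}: give csv_path xor synth")
        if self.csv_path is not None:
            rec = read_csv_record(self.csv_path, sampling_rate=250.0)
            return ECGRecord(
                rec.samples, rec.sampling_rate, record_id=self.record_id
            )
        clean = generate_clean_ecg(self.synth)
        noisy = add_noise(clean, self.synth.noise_spec, self.synth.seed)
        return ECGRecord(
            noisy.samples, noisy.sampling_rate, record_id=self.record_id
        )


@dataclass
class ExperimentConfig:
    records: list[RecordSpec]
    models: list[str] = field(default_factory=lambda: ["nested_lstm", "lstm"])
    denoise_enabled: bool = True
    wavelet: str = "db6"
    levels: int = 7
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    training: mdl.TrainingConfig = field(default_factory=mdl.TrainingConfig)
    eval_protocol: str = "holdout"  # "holdout" (80/20) or "in_sample"
    train_fraction: float = 0.8
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("at least one record is required")
        if self.eval_protocol not in ("holdout", "in_sample"):
            raise ValueError("eval_protocol must be 'holdout' or 'in_sample'")
        for spec in self.records:
            if spec.csv_path is not None and not Path(spec.csv_path).exists():
                raise FileNotFoundError(
                    f"record {spec.record_id}: missing file {spec.csv_path}"
                )
        unknown = [m for m in self.models if m not in MODEL_REGISTRY]
        if unknown:
            raise ValueError(f"unknown model tags: {unknown}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "records": [r.record_id for r in self.records],
                "models": self.models,
                "denoise": self.denoise_enabled,
                "wavelet": self.wavelet,
                "levels": self.levels,
                "m": self.embedding.m,
                "tau": self.embedding.tau,
                "training": vars(self.training),
                "eval": self.eval_protocol,
                "train_fraction": self.train_fraction,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        records = []
        for item in raw.get("records", []):
            synth = None
            if "synth" in item:
                s = dict(item["synth"])
                s["noise_spec"] = tuple(
                    NoiseSpec(**n) for n in s.get("noise_spec", [])
                )
                synth = SynthConfig(**s)
            records.append(
                RecordSpec(
                    record_id=item["record_id"],
                    csv_path=item.get("csv_path"),
                    synth=synth,
                )
            )
        kwargs = {}
        if "embedding" in raw:
            kwargs["embedding"] = EmbeddingConfig(**raw["embedding"])
        if "training" in raw:
            kwargs["training"] = mdl.TrainingConfig(**raw["training"])
        for key in (
            "models",
            "denoise_enabled",
            "wavelet",
            "levels",
            "eval_protocol",
            "train_fraction",
            "output_dir",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(records=records, **kwargs)


@dataclass
class ComparisonTable:
    """Records x models error table with a per-model averages footer."""

    metric: str
    units: str
    frame: pd.DataFrame

    @classmethod
    def build(
        cls, metric: str, units: str, cells: dict[str, dict[str, float]]
    ) -> "ComparisonTable":
        frame = pd.DataFrame(cells).T  # rows: record_id, cols: model
        frame.loc["Average"] = frame.mean(axis=0)
        frame.index.name = f"record ({metric}, {units})"
        return cls(metric=metric, units=units, frame=frame)

    @property
    def averages(self) -> dict[str, float]:
        return self.frame.loc["Average"].to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, float_format="%.6f")


def relative_reduction(avg_proposed: float, avg_baseline: float) -> float:
    """Percent reduction of the proposed model's average error versus a
    baseline: ``100 * (baseline - proposed) / baseline``."""
    if avg_baseline == 0:
        raise ZeroDivisionError("baseline average is zero")
    return 100.0 * (avg_baseline - avg_proposed) / avg_baseline


def _process_record(
    record: ECGRecord, config: ExperimentConfig, seed: int
) -> dict:
    """Run the full per-record pipeline; returns metrics per model tag."""
    t0 = time.perf_counter()
    raw = record
    if config.denoise_enabled:
        record, thresholds = denoise(
            record, levels=config.levels, wavelet=config.wavelet
        )
    else:
        thresholds = None
    normalized, stats = zscore_fit_apply(record.samples)
    dataset = embed(normalized, config.embedding)
    if config.eval_protocol == "holdout":
        train_set, eval_set = split_train_eval(
            dataset, train_fraction=config.train_fraction, strict=True
        )
    else:
        train_set = eval_set = dataset
    out: dict = {
        "record_id": record.record_id,
        "n_samples": len(record),
        "n_pairs": dataset.n,
        "normalization": {"mean": stats.mean, "std": stats.std},
        "thresholds": thresholds.to_dict() if thresholds else None,
        "models": {},
    }
    for tag in config.models:
        t1 = time.perf_counter()
        model = MODEL_REGISTRY[tag](
            input_size=1, hidden_size=config.training.hidden_size
        )
        rng = np.random.default_rng(seed)
        params = model.init_params(rng, config.training.init_scale)
        tcfg = mdl.TrainingConfig(**{**vars(config.training), "seed": seed})
        params, history = mdl.train(model, params, train_set, tcfg)
        preds = model.predict(params, eval_set.inputs)
        result = mdl.ForecastResult(
            predictions=preds,
            targets=eval_set.targets,
            model_tag=tag,
            record_id=record.record_id,
        )
        result_mv = result.rescaled(stats.std, stats.mean)
        out["models"][tag] = {
            "rmse_norm": result.rmse,
            "mae_norm": result.mae,
            "rmse_mv": result_mv.rmse,
            "mae_mv": result_mv.mae,
            "final_loss": history[-1] if history else None,
            "epochs_run": len(history),
            "seconds": time.perf_counter() - t1,
            "result": result_mv,
        }
        logger.info(
            "record=%s model=%s rmse_mv=%.4f mae_mv=%.4f epochs=%d (%.1fs)",
            record.record_id,
            tag,
            result_mv.rmse,
            result_mv.mae,
            len(history),
            time.perf_counter() - t1,
        )
    out["seconds"] = time.perf_counter() - t0
    del raw
    return out


def run_experiment(
    config: ExperimentConfig, fail_fast: bool = False
) -> tuple[ComparisonTable, ComparisonTable, dict]:
    """Run every record through the pipeline and build the RMSE and MAE
    comparison tables (mV units, averages footer). Returns the two tables
    plus a summary dict with per-record details and failures."""
    cfg_hash = config.config_hash()
    rmse_cells: dict[str, dict[str, float]] = {}
    mae_cells: dict[str, dict[str, float]] = {}
    summary: dict = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "records": {},
        "failures": {},
    }
    master = np.random.default_rng(config.seed)
    for spec in config.records:
        record_seed = int(master.integers(0, 2**31 - 1))
        try:
            record = spec.load()
            info = _process_record(record, config, record_seed)
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            if fail_fast:
                raise
            logger.error("record %s failed: %s", spec.record_id, exc)
            summary["failures"][spec.record_id] = str(exc)
            continue
        info["seed"] = record_seed
        rmse_cells[spec.record_id] = {
            tag: info["models"][tag]["rmse_mv"] for tag in config.models
        }
        mae_cells[spec.record_id] = {
            tag: info["models"][tag]["mae_mv"] for tag in config.models
        }
        for tag in config.models:
            info["models"][tag].pop("result")
        summary["records"][spec.record_id] = info
    if not rmse_cells:
        raise RuntimeError("every record failed; no tables to build")
    rmse_table = ComparisonTable.build("RMSE", "mV", rmse_cells)
    mae_table = ComparisonTable.build("MAE", "mV", mae_cells)
    summary["averages"] = {
        "rmse_mv": rmse_table.averages,
        "mae_mv": mae_table.averages,
    }
    if len(config.models) >= 2 and "nested_lstm" in config.models:
        baseline_tags = [t for t in config.models if t != "nested_lstm"]
        summary["relative_reduction_pct"] = {
            "rmse": {
                t: relative_reduction(
                    rmse_table.averages["nested_lstm"], rmse_table.averages[t]
                )
                for t in baseline_tags
            },
            "mae": {
                t: relative_reduction(
                    mae_table.averages["nested_lstm"], mae_table.averages[t]
                )
                for t in baseline_tags
            },
        }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        rmse_table.to_csv(outdir / "rmse.csv")
        mae_table.to_csv(outdir / "mae.csv")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return rmse_table, mae_table, summary
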