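"""Pipeline orchestration: configuration, seed fan-out, validation, stages.

A single YAML run configuration drives simulate → encode → train →
featurize → baseline → evaluate → heatmap.  One global seed fans out to
per-stage seeds through a stable hash of the stage name, so any stage can
be re-run independently yet reproducibly, and every artifact is stamped
with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, dae, evaluate, heatmap, io, synthetic
from .schema import EncodingSchema, split_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "encode", "train", "featurize", "baseline",
          "eval_mortality", "eval_comorbidity", "heatmap")


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: crc32 of the stage name mixed into the global seed."""
    return int((global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    output_dir: str = "run"
    seed: int = 0
    schema_path: str | None = None          # None → default synthetic vocabulary
    input_path: str | None = None           # None → simulate a cohort
    n_patients: int = 500
    latent_dim: int = 32
    noise_variance: float = 0.1
    epochs: int = 10
    batch_size: int = 100
    baseline_methods: tuple = ("hand",)
    window_days: int = 180
    classifier: str = "svm"
    threshold: float = 0.8
    n_folds: int = 5
    grid_size: int = 30
    smoothing: float = 5.0
    tsne_perplexity: float = 30.0
    strict_codes: bool = False
    stages: tuple = STAGES

    _KNOWN = None  # class cache of field names

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_methods", "stages"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)

    def to_yaml(self, path: str | Path) -> None:
        obj = dataclasses.asdict(self)
        obj["baseline_methods"] = list(self.baseline_methods)
        obj["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_input(path: str | Path) -> dict:
    """Structural validation plus a cohort summary in the style of a
    prevalence table (patients, records, death rate, per-comorbidity rates).

    Malformed lines are reported with their line number; validation continues.
    """
    errors: list[str] = []
    patients = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                p = io.patient_from_dict(obj)
                dates = [r["admission_time"] for r in obj["records"]]
                if dates != sorted(dates):
                    errors.append(f"line {i}: records not sorted by admission_time (auto-sortable)")
                patients.append(p)
            except Exception as exc:  # noqa: BLE001 - reported, not fatal
                errors.append(f"line {i}: {exc}")
    n_rec = sum(len(p.records) for p in patients)
    como_counts: dict[str, int] = {}
    for p in patients:
        for c in p.comorbidities:
            como_counts[c] = como_counts.get(c, 0) + 1
    n = len(patients)
    return {
        "n_patients": n,
        "n_records": n_rec,
        "death_rate": (sum(p.died for p in patients) / n) if n else float("nan"),
        "comorbidity_prevalence": {
            k: v / n for k, v in sorted(como_counts.items())
        } if n else {},
        "errors": errors,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns a manifest of artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed}
    manifest: dict = {"stamp": stamp, "timings": {}, "artifacts": {}}

    def _log(stage: str, t0: float, **counts) -> None:
        dt = time.perf_counter() - t0
        manifest["timings"][stage] = round(dt, 3)
        logger.info("stage=%s elapsed=%.2fs %s", stage, dt,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    try:
        stage = "simulate"
        t0 = time.perf_counter()
        if config.schema_path:
            schema = io.load_schema(config.schema_path)
        else:
            schema = synthetic.default_synthetic_schema()
        if config.input_path:
            patients = io.read_patients(config.input_path)
        elif stage in config.stages:
            cohort = synthetic.generate_cohort(
                synthetic.CohortConfig(
                    n_patients=config.n_patients, seed=derive_seed(config.seed, stage)
                ),
                schema,
            )
            patients = cohort.patients
            p_path = out / "patients.jsonl"
            io.write_patients(patients, p_path)
            manifest["artifacts"]["patients"] = str(p_path)
        else:
            raise ValueError("no input_path and simulate stage disabled")
        _log(stage, t0, patients=len(patients))

        stage = "encode"
        t0 = time.perf_counter()
        samples = split_cohort(patients, schema, strict=config.strict_codes)
        _log(stage, t0, samples=len(samples))

        stage = "train"
        model = None
        if stage in config.stages:
            t0 = time.perf_counter()
            model = dae.train(
                [s.tensor for s in samples],
                dae.DaeConfig(
                    latent_dim=config.latent_dim,
                    noise_variance=config.noise_variance,
                    epochs=config.epochs,
                    batch_size=config.batch_size,
                    seed=derive_seed(config.seed, stage),
                ),
                schema_fingerprint=schema.fingerprint(),
            )
            m_path = out / "model.npz"
            dae.save_model(model, m_path)
            manifest["artifacts"]["model"] = str(m_path)
            _log(stage, t0, final_loss=round(model.training_log[-1], 3))

        pid = [s.patient_id for s in samples]
        plen = [s.prefix_length for s in samples]
        feats: dict[str, np.ndarray] = {}

        stage = "featurize"
        if model is not None and stage in config.stages:
            t0 = time.perf_counter()
            F = dae.sample_deep_features(samples, model, schema)
            f_path = out / "features_deep.csv"
            io.write_features(F, pid, plen, f_path, method="deep")
            feats["deep"] = F
            manifest["artifacts"]["features_deep"] = str(f_path)
            _log(stage, t0, dim=F.shape[1])

        stage = "baseline"
        if stage in config.stages:
            t0 = time.perf_counter()
            rec_by_pid = {p.patient_id: p.records for p in patients}
            for method in config.baseline_methods:
                F = baselines.baseline_features(
                    samples, rec_by_pid, schema, method,
                    window=baselines.WindowSpec(config.window_days),
                    n_components=baselines.SMALL_SCALE_HYPERPARAMS.get(method),
                    seed=derive_seed(config.seed, f"baseline:{method}"),
                )
                f_path = out / f"features_{method}.csv"
                io.write_features(F, pid, plen, f_path, method=method)
                feats[method] = F
                manifest["artifacts"][f"features_{method}"] = str(f_path)
            _log(stage, t0, methods=len(config.baseline_methods))

        died = np.array([s.died for s in samples])
        pid_arr = np.array(pid)
        ecfg = evaluate.EvalConfig(
            classifier=config.classifier, threshold=config.threshold,
            n_folds=config.n_folds, seed=derive_seed(config.seed, "eval"),
        )

        stage = "eval_mortality"
        if stage in config.stages and feats:
            t0 = time.perf_counter()
            # natural class balance for mortality; NearMiss is a
            # rare-comorbidity device
            mcfg = dataclasses.replace(ecfg, undersampler="none")
            rows = []
            for method, F in feats.items():
                r = evaluate.evaluate_mortality(F, died, pid_arr, mcfg)
                rows.append({"method": method, "task": "mortality",
                             "auc": r.auc, "accuracy": r.accuracy, "f1": r.f1})
            rep = pd.DataFrame(rows)
            r_path = out / "mortality_report.csv"
            rep.to_csv(r_path, index=False)
            manifest["artifacts"]["mortality_report"] = str(r_path)
            _log(stage, t0, methods=len(rows))

        stage = "eval_comorbidity"
        if stage in config.stages and feats:
            t0 = time.perf_counter()
            labels = pd.DataFrame(
                {c: [int(c in s.comorbidities) for s in samples]
                 for c in sorted({c for s in samples for c in s.comorbidities})}
            )
            rows = []
            for method, F in feats.items():
                res, _scores = evaluate.evaluate_comorbidity(F, labels, pid_arr, ecfg)
                for task, r in res.items():
                    rows.append({"method": method, "task": task, "auc": r.auc,
                                 "accuracy": r.accuracy, "f1": r.f1})
            rep = pd.DataFrame(rows)
            r_path = out / "comorbidity_report.csv"
            rep.to_csv(r_path, index=False)
            manifest["artifacts"]["comorbidity_report"] = str(r_path)
            _log(stage, t0, tasks=labels.shape[1])

        stage = "heatmap"
        if stage in config.stages and "deep" in feats:
            t0 = time.perf_counter()
            emb = heatmap.project_2d(
                feats["deep"], seed=derive_seed(config.seed, stage),
                perplexity=min(config.tsne_perplexity, (len(samples) - 1) / 3),
                died=died,
            )
            blocks = heatmap.grid_assign(emb, config.grid_size)
            grid = heatmap.mortality_grid(blocks, died, config.grid_size, config.smoothing)
            t_path = out / "blocks.csv"
            heatmap.grid_table(grid).to_csv(t_path, index=False)
            img_path = out / "heatmap.png"
            heatmap.render_heatmap(grid, str(img_path))
            manifest["artifacts"]["blocks"] = str(t_path)
            manifest["artifacts"]["heatmap"] = str(img_path)
            _log(stage, t0, blocks=config.grid_size ** 2)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        (out / "error.json").write_text(json.dumps(record))
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
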