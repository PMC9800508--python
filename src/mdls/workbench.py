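"""File formats, configuration, seeding and the end-to-end pipeline.

Signals travel as plain CSV (``time,ch01..chNN``, time in seconds with six
decimals, voltages at full float precision) with an optional JSON sidecar
holding the generating configuration and label.  Feature matrices, CV score
tables and reports are CSV/JSON.  A single global seed fans out to per-stage
seeds through a stable hash of the stage name, so any stage can be rerun in
isolation and two runs with the same config are byte-identical.
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

from . import classify, explain, features, preprocess, select, simulate
from .classify import ClassifierSpec
from .features import FeatureMatrix
from .simulate import MultiChannelSignal, ParticleSpec, SimulationConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# signal CSV I/O


def write_signal_csv(signal: MultiChannelSignal, path, config=None) -> None:
    """``time,ch01..chNN`` CSV; float samples at full precision.

    When ``config`` is given, a JSON sidecar (same stem, ``.json``) stores the
    generating configuration and the label.
    """
    path = Path(path)
    C = signal.n_channels
    header = "time," + ",".join(f"ch{c + 1:02d}" for c in range(C))
    t = signal.times_s
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(signal.n_samples):
            row = ",".join(repr(float(v)) for v in signal.samples[i])
            fh.write(f"{t[i]:.6f},{row}\n")
    if config is not None:
        sidecar = {
            "config": config_to_dict(config),
            "label": signal.label,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_signal_csv(path, fs_hz: float | None = None) -> MultiChannelSignal:
    """Parse a signal CSV, validating the schema.

    The sampling rate is inferred from the time column (and cross-checked
    against ``fs_hz`` when given); a JSON sidecar, if present, supplies the
    label and declared channel count.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if len(cols) < 2 or cols[0] != "time":
        raise ValueError(f"{path}: expected header 'time,ch01..chNN', got {cols}")
    expected = ["time"] + [f"ch{c + 1:02d}" for c in range(len(cols) - 1)]
    if cols != expected:
        raise ValueError(f"{path}: channel columns must be named ch01..ch{len(cols) - 1:02d}")

    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0]) + 2  # 1-based incl. header
        raise ValueError(f"{path}: ragged or missing values at file row {bad}")

    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.nonzero(dt <= 0)[0][0]) + 3
        raise ValueError(f"{path}: time column not strictly increasing at file row {bad}")
    dt_med = float(np.median(dt))
    # stored times carry 6 decimals, so allow that quantization
    if np.any(np.abs(dt - dt_med) > 1e-6 + 1e-9):
        bad = int(np.nonzero(np.abs(dt - dt_med) > 1e-6 + 1e-9)[0][0]) + 3
        raise ValueError(f"{path}: non-uniform time step at file row {bad}")
    fs = 1.0 / dt_med
    if fs_hz is not None and abs(fs - fs_hz) > 1e-9 * fs_hz + 1e-6:
        raise ValueError(
            f"{path}: time step {dt_med} inconsistent with fs={fs_hz} Hz"
        )

    label = None
    angles = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label")
        cfg = meta.get("config") or {}
        if "detector_angles_deg" in cfg:
            angles = tuple(cfg["detector_angles_deg"])
            if len(angles) != len(cols) - 1:
                raise ValueError(
                    f"{path}: file has {len(cols) - 1} channel columns but the "
                    f"sidecar declares {len(angles)} channels"
                )
    if angles is None:
        angles = tuple(float(i) for i in range(len(cols) - 1))
    return MultiChannelSignal(
        samples=df[expected[1:]].to_numpy(dtype=float),
        fs_hz=fs_hz if fs_hz is not None else fs,
        channel_angles_deg=angles,
        label=label,
    )


# ---------------------------------------------------------------------------
# configuration


def config_to_dict(cfg) -> dict:
    """Dataclass -> JSON-safe dict (complex numbers as [re, im])."""
    def convert(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: convert(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, complex):
            return {"re": v.real, "im": v.imag}
        if isinstance(v, (tuple, list)):
            return [convert(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        return v

    return convert(cfg)


def particle_from_dict(d: dict) -> ParticleSpec:
    ri = d.get("refractive_index", 1.59)
    if isinstance(ri, dict):
        ri = complex(ri["re"], ri["im"])
    return ParticleSpec(
        diameter_um=d["diameter_um"], refractive_index=ri, label=d.get("label")
    )


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "particle" in d:
        d["particle"] = particle_from_dict(d["particle"])
    if "detector_angles_deg" in d:
        d["detector_angles_deg"] = tuple(d["detector_angles_deg"])
    return SimulationConfig(**d)


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run."""

    seed: int = 0
    classes: tuple[ParticleSpec, ...] = simulate.DEFAULT_CLASSES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_recordings_per_class: int = 4
    denoise_cutoff_hz: float = 100.0
    denoise_order: int = 2
    window_ms: float = 250.0
    step_ms: float = 150.0
    lam: float = features.DEFAULT_LAMBDA
    eps: float = features.DEFAULT_EPS
    sparsity_sqrt: bool = False
    uniform_scaling: bool = False
    selection_method: str = "rfe"
    selection_grid: tuple[int, ...] = select.DEFAULT_GRID
    folds: int = 5
    split_ratio: float = 0.7
    primary_classifier: str = "svm"
    explain_background: int = 100
    explain_samples: int = 20
    n_permutations: int = 200

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "classes" in d:
            d["classes"] = tuple(particle_from_dict(p) for p in d["classes"])
        if "simulation" in d:
            d["simulation"] = simulation_config_from_dict(d["simulation"])
        if "selection_grid" in d:
            d["selection_grid"] = tuple(d["selection_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        canonical = json.dumps(config_to_dict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def classifier_specs(seed: int) -> dict[str, ClassifierSpec]:
    return {
        "lr": ClassifierSpec(model="lr", seed=seed),
        "rf": ClassifierSpec(model="rf", seed=seed),
        "svm": ClassifierSpec(model="svm", seed=seed),
    }


# ---------------------------------------------------------------------------
# the one-command pipeline


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """simulate -> denoise -> window -> features -> sweep/select -> train ->
    evaluate -> explain; writes every artifact into ``out_dir``.

    Returns a summary dict (also stored as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mdls")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "start"
    try:
        logger.info("pipeline config hash %s seed %d", config.config_hash(), config.seed)

        stage = "simulate"
        sim_cfg = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        signals = simulate.make_labeled_dataset(
            config.classes, config.n_recordings_per_class, sim_cfg
        )

        stage = "denoise"
        signals = [
            preprocess.denoise(s, config.denoise_cutoff_hz, config.denoise_order)
            for s in signals
        ]

        stage = "features"
        fm = features.extract_features(
            signals,
            window_ms=config.window_ms,
            step_ms=config.step_ms,
            lam=config.lam,
            eps=config.eps,
            sparsity_sqrt=config.sparsity_sqrt,
            uniform_scaling=config.uniform_scaling,
        )
        fm.to_csv(out / "features.csv")
        logger.info(
            "feature matrix: %d windows x %d features (sparsity_sqrt=%s, "
            "uniform_scaling=%s, lambda=%g)",
            fm.n_windows, fm.n_features, config.sparsity_sqrt,
            config.uniform_scaling, config.lam,
        )

        stage = "split"
        X_tr, X_te, y_tr, y_te = classify.split_train_test(
            fm.X, fm.y, ratio=config.split_ratio, seed=stage_seed(config.seed, "split")
        )

        stage = "select"
        specs = classifier_specs(stage_seed(config.seed, "train"))
        estimators = {name: classify.build_estimator(s) for name, s in specs.items()}
        # elimination/CV operate on standardized features; strip the pipelines
        # and the SVM probability machinery (not needed for accuracy sweeps)
        bare = {
            name: classify.without_probability(
                est[-1] if hasattr(est, "steps") else est
            )
            for name, est in estimators.items()
        }
        cv_scores = select.sweep_feature_counts(
            X_tr,
            y_tr,
            method=config.selection_method,
            estimators=bare,
            grid=config.selection_grid,
            folds=config.folds,
            seed=stage_seed(config.seed, "select"),
        )
        cv_scores.to_csv(out / "cv_scores.csv", index=False)
        primary = cv_scores[cv_scores.classifier == config.primary_classifier]
        best_k = int(primary.loc[primary.mean_score.idxmax(), "k"])
        if config.selection_method == "rfe":
            ranker = bare[config.primary_classifier]
            retained = select.rfe_select(X_tr, y_tr, best_k, ranker)
            retained_names = [fm.names[j] for j in retained]
            (out / "retained.json").write_text(
                json.dumps(
                    {"method": "rfe", "k": best_k, "indices": retained.tolist(),
                     "names": retained_names},
                    indent=2,
                )
            )
            X_tr_sel, X_te_sel = X_tr[:, retained], X_te[:, retained]
            sel_names = retained_names
        else:
            _, pca, scaler = select.pca_reduce(X_tr, best_k)
            X_tr_sel = pca.transform(scaler.transform(X_tr))[:, :best_k]
            X_te_sel = pca.transform(scaler.transform(X_te))[:, :best_k]
            sel_names = [f"pc{i + 1}" for i in range(best_k)]
            (out / "retained.json").write_text(
                json.dumps(
                    {"method": "pca", "k": best_k,
                     "loadings": pca.components_[:best_k].tolist()},
                    indent=2,
                )
            )
        logger.info("selection: %s, k=%d", config.selection_method, best_k)

        stage = "train/evaluate"
        evaluation = {}
        models = {}
        for name, spec in specs.items():
            model = classify.train_classifier(spec, X_tr_sel, y_tr)
            models[name] = model
            evaluation[name] = classify.evaluate(model, X_te_sel, y_te).to_dict()
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))

        stage = "explain"
        rng = np.random.default_rng(stage_seed(config.seed, "explain"))
        bg_idx = rng.choice(
            len(X_tr_sel), size=min(config.explain_background, len(X_tr_sel)),
            replace=False,
        )
        ex_idx = rng.choice(
            len(X_te_sel), size=min(config.explain_samples, len(X_te_sel)),
            replace=False,
        )
        report = explain.shapley_values(
            models[config.primary_classifier],
            X_tr_sel[bg_idx],
            X_te_sel[ex_idx],
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "shapley"),
            feature_names=sel_names,
        )
        pd.DataFrame(report.phi, columns=sel_names).to_csv(
            out / "shapley.csv", index=False
        )
        ranking = explain.rank_features(report, top=min(20, len(sel_names)))
        f1_share = explain.block_share(report, "_f1")
        (out / "shapley_summary.json").write_text(
            json.dumps(
                {
                    "ranking": ranking.to_dict(orient="records"),
                    "base_values": report.base_values.tolist(),
                    "f1_block_share": f1_share,
                },
                indent=2,
            )
        )
        logger.info("zero-order-moment block carries %.1f%% of mean |phi|", 100 * f1_share)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config_to_dict(config),
            "n_windows": int(fm.n_windows),
            "n_features": int(fm.n_features),
            "selected_k": best_k,
            "test_accuracy": {
                name: evaluation[name]["accuracy"] for name in evaluation
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
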