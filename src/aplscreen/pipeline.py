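"""End-to-end orchestration: simulate -> render -> CNN -> Grad-CAM ->
quantify -> screen -> explain, from a single seeded configuration.

Artifacts land under ``out_dir/{stage}/`` and are listed, with content
hashes, in ``out_dir/manifest.json``.  A stage is skipped on re-run when
its configuration hash and its artifacts' content hashes are unchanged.

Two profiles are shipped: ``desk`` (vgg-tiny, ~100-sample cohort, a few
epochs at a desk-scale learning rate) finishes on one CPU in minutes and
is what the tests exercise; ``full`` records the full-scale configuration
(VGG16, 100 epochs at the low full-data learning rate, study-sized
cohort).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnnroi, prep, quant, screen, synthgram

logger = logging.getLogger(__name__)

PROFILES = {
    "desk": dict(
        n_per_class={"APL": 40, "AML": 30, "ALL": 20, "HC": 30},
        n_events=8000,
        arch="vgg-tiny",
        train=dict(learning_rate=1e-3, momentum=0.9, weight_decay=1e-4,
                   epochs=10, batch_size=10),
    ),
    "full": dict(
        n_per_class={"APL": 94, "AML": 765, "ALL": 323, "HC": 750},
        n_events=12000,
        arch="vgg16",
        train=dict(learning_rate=1e-6, momentum=0.9, weight_decay=1e-4,
                   epochs=100, batch_size=10),
    ),
}

_KNOWN_KEYS = {"out_dir", "seed", "profile", "n_per_class", "n_events", "arch",
               "train", "foreground_threshold", "cluster_top_k", "roi_threshold",
               "roi_min_area", "test_fraction", "screen", "cam_weights",
               "cam_target"}
_SCREEN_KEYS = {"folds", "rfe_tol", "min_sensitivity", "threshold_rule",
                "run_rfe", "run_grid", "rfe_trees"}


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    profile: str = "desk"
    n_per_class: dict = field(default_factory=dict)
    n_events: int = 0
    arch: str = ""
    train: cnnroi.TrainHyperparams = None
    foreground_threshold: float = 10.0
    cluster_top_k: int = 3
    roi_threshold: float = 0.5
    roi_min_area: int = 20
    test_fraction: float = 0.2
    screen: dict = field(default_factory=dict)
    # heatmap flavor feeding ROI extraction; the spatially resolved
    # decomposition stays discriminative for desk-scale networks
    cam_weights: str = "elementwise"
    cam_target: str = "margin"

    def quant_config(self) -> quant.QuantConfig:
        return quant.QuantConfig(self.foreground_threshold, self.cluster_top_k)


def validate_config(raw) -> RunConfig:
    """Build a RunConfig from a dict or YAML text; profile defaults are
    filled in, unknown keys rejected, hyperparameters bounds-checked."""
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise synthgram.ConfigurationError("config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise synthgram.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    missing = [k for k in ("out_dir",) if k not in raw]
    if missing:
        raise synthgram.ConfigurationError(f"missing required keys: {missing}")
    profile = raw.get("profile", "desk")
    if profile not in PROFILES:
        raise synthgram.ConfigurationError(f"unknown profile {profile!r}")
    defaults = PROFILES[profile]
    train_kwargs = dict(defaults["train"])
    train_kwargs.update(raw.get("train", {}))
    train_kwargs.setdefault("seed", raw.get("seed", 0))
    hp = cnnroi.TrainHyperparams(**train_kwargs)   # bounds-checked there
    screen_cfg = dict(raw.get("screen", {}))
    bad = set(screen_cfg) - _SCREEN_KEYS
    if bad:
        raise synthgram.ConfigurationError(f"unknown screen keys: {sorted(bad)}")
    cfg = RunConfig(
        out_dir=str(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        profile=profile,
        n_per_class=dict(raw.get("n_per_class", defaults["n_per_class"])),
        n_events=int(raw.get("n_events", defaults["n_events"])),
        arch=raw.get("arch", defaults["arch"]),
        train=hp,
        foreground_threshold=float(raw.get("foreground_threshold", 10.0)),
        cluster_top_k=int(raw.get("cluster_top_k", 3)),
        roi_threshold=float(raw.get("roi_threshold", 0.5)),
        roi_min_area=int(raw.get("roi_min_area", 20)),
        test_fraction=float(raw.get("test_fraction", 0.2)),
        screen=screen_cfg,
        cam_weights=raw.get("cam_weights", "elementwise"),
        cam_target=raw.get("cam_target", "margin"),
    )
    if not 0.0 < cfg.test_fraction < 1.0:
        raise synthgram.ValidationError("test_fraction must be in (0, 1)")
    if not 0.0 < cfg.roi_threshold < 1.0:
        raise synthgram.ValidationError("roi_threshold must be in (0, 1)")
    cfg.quant_config()  # bounds-check quant settings
    return cfg


# ---------------------------------------------------------------------------
# manifest helpers


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.doc = {"stages": {}}
        if path.exists():
            self.doc = json.loads(path.read_text())

    def stage_fresh(self, stage: str, cfg_hash: str) -> bool:
        entry = self.doc["stages"].get(stage)
        if not entry or entry["config_hash"] != cfg_hash:
            return False
        for rel, digest in entry["artifacts"].items():
            p = self.path.parent / rel
            if not p.exists() or _hash_file(p) != digest:
                return False
        return True

    def record(self, stage: str, cfg_hash: str, files: list[Path],
               elapsed: float) -> None:
        root = self.path.parent
        self.doc["stages"][stage] = {
            "config_hash": cfg_hash,
            "elapsed_s": round(elapsed, 3),
            "artifacts": {str(p.relative_to(root)): _hash_file(p) for p in files},
        }
        self.path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# the run


@dataclass
class PipelineResult:
    config: RunConfig
    manifest: dict
    cnn_history: dict[str, list]
    reports: dict[str, dict[str, screen.EvaluationReport]]
    results: dict[str, screen.ScreeningResults]
    attribution: screen.AttributionMatrix
    scatter: pd.DataFrame
    routine: pd.DataFrame
    split: tuple[np.ndarray, np.ndarray]


def run_pipeline(config: RunConfig | dict | str) -> PipelineResult:
    """Execute every stage; deterministic given the config (incl. seed)."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    t_all = time.time()

    # --- simulate ---------------------------------------------------------
    sim_hash = _hash_config({"n_per_class": cfg.n_per_class, "seed": cfg.seed,
                             "n_events": cfg.n_events})
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    t0 = time.time()
    cohort = synthgram.generate_cohort(cfg.n_per_class, seed=cfg.seed,
                                       n_events=cfg.n_events)
    routine = synthgram.cohort_to_frame(cohort)
    routine_path = sim_dir / "routine.csv"
    if not manifest.stage_fresh("simulate", sim_hash):
        routine.to_csv(routine_path, index=False)
        manifest.record("simulate", sim_hash, [routine_path], time.time() - t0)
        logger.info("simulate: %d samples", len(cohort))
    else:
        logger.info("simulate: fresh, skipped write")

    # --- render -----------------------------------------------------------
    render_hash = _hash_config({"sim": sim_hash})
    render_dir = out / "render"
    render_dir.mkdir(exist_ok=True)
    t0 = time.time()
    images: dict[str, dict[str, prep.ScattergramImage]] = {}
    png_paths = []
    write = not manifest.stage_fresh("render", render_hash)
    rows = []
    for s in cohort:
        views = prep.render_sample(s)
        images[s.sample_id] = views
        row = {"sample_id": s.sample_id, "class": s.class_name}
        for vname, img in views.items():
            path = render_dir / prep.image_filename(s.sample_id, img.view)
            if write:
                prep.save_png(img, render_dir)
            png_paths.append(path)
            row[f"png_{vname}"] = path.name
        row.update(s.routine_params)
        rows.append(row)
    cohort_manifest = render_dir / "cohort.csv"
    if write:
        pd.DataFrame(rows).to_csv(cohort_manifest, index=False)
        manifest.record("render", render_hash, png_paths + [cohort_manifest],
                        time.time() - t0)

    labels4 = np.array([s.class_name for s in cohort])
    y = (labels4 == "APL").astype(int)
    sample_ids = [s.sample_id for s in cohort]
    train_idx, test_idx = screen.stratified_split(
        y, cfg.test_fraction, cfg.seed, strata=labels4)

    # --- train CNNs (training split only) ---------------------------------
    cnn_dir = out / "cnn"
    cnn_dir.mkdir(exist_ok=True)
    cnn_hash = _hash_config({"render": render_hash, "arch": cfg.arch,
                             "train": asdict(cfg.train),
                             "test_fraction": cfg.test_fraction})
    models: dict[str, cnnroi.CnnModel] = {}
    history: dict[str, list] = {}
    t0 = time.time()
    fresh = manifest.stage_fresh("train-cnn", cnn_hash)
    for vi, view in enumerate(prep.ALL_VIEWS):
        ckpt = cnn_dir / f"{view.name}.npz"
        hist_path = cnn_dir / f"{view.name}_history.json"
        if fresh:
            models[view.name] = cnnroi.load_checkpoint(ckpt)
            history[view.name] = json.loads(hist_path.read_text())
            continue
        stack = np.stack([images[sid][view.name].pixels for sid in sample_ids])
        model = cnnroi.build_cnn(cfg.arch, seed=cfg.seed * 131 + vi,
                                 view_name=view.name)
        hp = cnnroi.TrainHyperparams(**{**asdict(cfg.train),
                                        "seed": cfg.train.seed * 131 + vi})
        hist = cnnroi.train_cnn(model, stack[train_idx], y[train_idx], hp)
        cnnroi.save_checkpoint(model, ckpt)
        hist_path.write_text(json.dumps(hist))
        models[view.name] = model
        history[view.name] = hist
        logger.info("train-cnn %s: final acc %.3f", view.name,
                    hist[-1]["accuracy"] if hist else float("nan"))
    if not fresh:
        files = [cnn_dir / f"{v.name}{sfx}" for v in prep.ALL_VIEWS
                 for sfx in (".npz", "_history.json")]
        manifest.record("train-cnn", cnn_hash, files, time.time() - t0)

    # --- Grad-CAM + quantify ----------------------------------------------
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    feat_hash = _hash_config({"cnn": cnn_hash, "roi_threshold": cfg.roi_threshold,
                              "roi_min_area": cfg.roi_min_area,
                              "fg": cfg.foreground_threshold,
                              "top_k": cfg.cluster_top_k,
                              "cam": [cfg.cam_weights, cfg.cam_target]})
    scatter_path = feat_dir / "scatter.csv"
    t0 = time.time()
    if manifest.stage_fresh("quantify", feat_hash):
        scatter = pd.read_csv(scatter_path)
    else:
        qcfg = cfg.quant_config()
        feats = []
        for sid in sample_ids:
            rois = {}
            for view in prep.ALL_VIEWS:
                heat = cnnroi.grad_cam(models[view.name], images[sid][view.name],
                                       weights=cfg.cam_weights,
                                       target=cfg.cam_target)
                rois[view.name] = cnnroi.extract_rois(heat, cfg.roi_threshold,
                                                      cfg.roi_min_area)
            feats.append(quant.quantify_sample(images[sid], rois, qcfg, sid))
        scatter = quant.features_to_frame(feats)
        scatter.to_csv(scatter_path, index=False)
        manifest.record("quantify", feat_hash, [scatter_path], time.time() - t0)

    # --- screening models --------------------------------------------------
    screen_dir = out / "screen"
    screen_dir.mkdir(exist_ok=True)
    reports: dict[str, dict[str, screen.EvaluationReport]] = {}
    results: dict[str, screen.ScreeningResults] = {}
    screen_files = []
    t0 = time.time()
    for mode in ("rfc-s", "rfc-c"):
        table = screen.assemble_features(
            scatter if mode == "rfc-s" else None, routine, mode)
        train_t, test_t = table.subset(train_idx), table.subset(test_idx)
        sc = screen.ScreenConfig(mode=mode, **cfg.screen)
        res = screen.ScreeningModel(train_t, sc).fit(seed=cfg.seed)
        results[mode] = res
        reports[mode] = {"train": res.train_report,
                         "test": res.evaluate(test_t)}
        mdir = screen_dir / mode
        mdir.mkdir(exist_ok=True)
        (mdir / "bundle.pkl").write_bytes(res.bundle.to_bytes())
        sidecar = {
            "selected_features": res.bundle.selected_features,
            "threshold": res.bundle.threshold,
            "hyperparams": {k: str(v) for k, v in res.bundle.hyperparams.items()},
            "seed": cfg.seed,
            "scaler_mean": res.bundle.scaler.mean.tolist(),
            "scaler_sd": res.bundle.scaler.sd.tolist(),
        }
        (mdir / "bundle.json").write_text(json.dumps(sidecar, indent=2))
        (mdir / "report.json").write_text(json.dumps(
            {split: rep.as_dict() for split, rep in reports[mode].items()},
            indent=2))
        pd.DataFrame({
            "sample_id": np.asarray(sample_ids)[test_idx],
            "score": reports[mode]["test"].scores,
            "label": y[test_idx],
        }).to_csv(mdir / "test_scores.csv", index=False)
        screen_files += [mdir / "bundle.pkl", mdir / "bundle.json",
                         mdir / "report.json", mdir / "test_scores.csv"]

    # --- explain (test split of the RFC-S model) --------------------------
    table_s = screen.assemble_features(scatter, routine, "rfc-s")
    attribution = results["rfc-s"].explain(table_s.subset(test_idx))
    shap_path = screen_dir / "rfc-s" / "shap_mean_abs.csv"
    attribution.mean_abs().rename("mean_abs_attribution").to_csv(shap_path)
    screen_files.append(shap_path)
    screen_hash = _hash_config({"feat": feat_hash, "screen": cfg.screen,
                                "seed": cfg.seed})
    manifest.record("screen", screen_hash, screen_files, time.time() - t0)
    logger.info("pipeline done in %.1fs", time.time() - t_all)

    return PipelineResult(cfg, manifest.doc, history, reports, results,
                          attribution, scatter, routine,
                          (train_idx, test_idx))
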