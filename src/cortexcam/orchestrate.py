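"""Configuration and the canned end-to-end experiment.

``run_experiment`` strings all stages together on a synthetic cohort:
simulate -> (optional forward/inverse) -> preprocess -> volumize ->
per-fold pretrain/fine-tune/evaluate -> explain -> aggregate/statistics,
writing a JSON report plus CSV tables and aggregate heatmaps.  Every
output embeds the config hash and seed, and the whole run is reproducible
from (config, seed).

The configuration is a nested dataclass tree that round-trips losslessly
through YAML; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analyze, cnn, explain, inverse, io, synthdata, volumize

__all__ = [
    "PipelineConfig",
    "SynthConfig",
    "InverseConfig",
    "VolumizeConfig",
    "CnnConfig",
    "ExplainConfig",
    "load_config",
    "save_config",
    "config_hash",
    "run_experiment",
]


@dataclass(frozen=True)
class SynthConfig:
    n_vertices: int = 2000
    n_regions: int = 8
    n_per_group: int = 10
    n_trials: int = 40
    delta: float = 0.5
    noise_sd: float = 0.5
    subject_sd: float = 0.2
    window_ms: tuple[float, float] = (300.0, 350.0)
    rho_score: float = 0.26
    score_name: str = "cognition"
    surface_seed: int = 7


@dataclass(frozen=True)
class InverseConfig:
    enabled: bool = False
    n_channels: int = 32
    sensor_noise_sd: float = 0.05
    lambda_reg: float | None = None
    depth_exponent: float = 0.5
    snr: float = 3.0


@dataclass(frozen=True)
class VolumizeConfig:
    grid_size: int = 24  # desk-scale default; the full-scale grid is 120
    mode: str = "3d"


@dataclass(frozen=True)
class CnnConfig:
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    fc_width: int = 32
    batch_size: int = 16
    max_epochs: int = 40
    patience: int = 8
    lr: float | None = None
    weight_decay: float = 1e-5
    n_folds: int | None = 3
    reserve_control_fraction: float = 0.3


@dataclass(frozen=True)
class ExplainConfig:
    methods: tuple[str, ...] = ("lrp", "ggcam")
    gamma: float = 0.25
    eps: float = 1e-9
    max_samples_per_fold: int = 40


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    volumize: VolumizeConfig = field(default_factory=VolumizeConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    seed: int = 0
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        sections = {
            "synth": SynthConfig,
            "inverse": InverseConfig,
            "volumize": VolumizeConfig,
            "cnn": CnnConfig,
            "explain": ExplainConfig,
        }
        top_known = set(sections) | {"seed", "out_dir"}
        unknown = set(d) - top_known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, cls in sections.items():
            sub = dict(d.get(name, {}))
            known = {f.name for f in fields(cls)}
            bad = set(sub) - known
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            kwargs[name] = cls(**sub)
        return PipelineConfig(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "results/run")),
            **kwargs,
        )


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(config.to_dict())), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific configuration (the output path is excluded:
    identical experiments written to different directories share a hash)."""
    d = config.to_dict()
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages


def build_cohort(config: PipelineConfig):
    """Surface, effect spec, cohort table (with scores) and projection map."""
    s = config.synth
    surface = synthdata.make_sphere_surface(s.n_vertices, s.n_regions, s.surface_seed)
    espec = synthdata.default_effect_spec(
        surface,
        delta=s.delta,
        noise_sd=s.noise_sd,
        subject_sd=s.subject_sd,
        window_ms=tuple(s.window_ms),
        seed=config.seed,
    )
    cohort = synthdata.cohort_table(espec, s.n_per_group, s.n_trials)
    cohort = synthdata.simulate_clinical_scores(
        cohort, s.rho_score, s.score_name, seed=config.seed + 1
    )
    mmap = volumize.make_mollweide_map(surface, config.volumize.grid_size)
    return surface, espec, cohort, mmap


def _maybe_inverse_chain(trials, surface, config: PipelineConfig, subject_index: int):
    inv = config.inverse
    if not inv.enabled:
        return trials
    lf = synthdata.make_lead_field(surface, inv.n_channels, seed=config.seed)
    sensors = inverse.project_to_sensors(
        trials, lf, inv.sensor_noise_sd, seed=config.seed * 100003 + subject_index
    )
    return inverse.wmne_inverse(
        sensors, lf, inv.lambda_reg, inv.depth_exponent, template=trials
    )


def simulate_and_volumize(config: PipelineConfig):
    """Stream the cohort subject by subject into a stacked volume dataset,
    collecting per-subject ROI/window mean current density along the way."""
    surface, espec, cohort, mmap = build_cohort(config)
    roi_mask = surface.region_mask(espec.roi_region_id)
    parts, roi_rows = [], []
    for row, trials in synthdata.iter_subject_trials(surface, espec, cohort):
        trials = _maybe_inverse_chain(trials, surface, config, int(row["subject_index"]))
        pre = synthdata.preprocess_trial(
            trials.data, trials.fs_hz, trials.t_start_ms
        )
        times = trials.times_ms
        lo, hi = espec.window_ms
        sel = (times >= lo) & (times < hi)
        roi_rows.append(
            {
                "subject_id": row["subject_id"],
                "group": row["group"],
                "roi_mean": float(pre[:, roi_mask][:, :, sel].mean()),
            }
        )
        pre_set = replace_data(trials, pre)
        parts.append(
            cnn.stack_volumes(
                volumize.volumize_trialset(pre_set, mmap, config.volumize.mode)
            )
        )
    dataset = cnn.VolumeDataset.concat(parts)
    roi_df = pd.DataFrame(roi_rows).merge(
        cohort[["subject_id", "a_s", config.synth.score_name]], on="subject_id"
    )
    return surface, espec, cohort, mmap, dataset, roi_df


def replace_data(trials: synthdata.SourceTrialSet, data) -> synthdata.SourceTrialSet:
    return synthdata.SourceTrialSet(
        data=data,
        t_start_ms=trials.t_start_ms,
        t_end_ms=trials.t_end_ms,
        fs_hz=trials.fs_hz,
        subject_id=trials.subject_id,
        group=trials.group,
    )


def _arch_for(config: PipelineConfig) -> cnn.ArchConfig:
    g = config.volumize.grid_size
    shape = (g, g, 16) if config.volumize.mode == "3d" else (g, g)
    return cnn.ArchConfig(
        mode=config.volumize.mode,
        input_shape=shape,
        conv_channels=tuple(config.cnn.conv_channels),
        fc_width=config.cnn.fc_width,
    )


def _train_config(config: PipelineConfig, fold_index: int, lr=None) -> cnn.TrainConfig:
    c = config.cnn
    return cnn.TrainConfig(
        batch_size=c.batch_size,
        max_epochs=c.max_epochs,
        patience=c.patience,
        lr=c.lr if lr is None else lr,
        weight_decay=c.weight_decay,
        seed=config.seed * 1009 + fold_index,
    )


def choose_reserve_controls(
    cohort: pd.DataFrame, fraction: float, seed: int
) -> list[str]:
    controls = cohort.loc[cohort["group"] == "control", "subject_id"].tolist()
    n = max(1, int(round(fraction * len(controls))))
    rng = np.random.default_rng(seed + 17)
    return sorted(rng.choice(controls, n, replace=False).tolist())


def run_fold(
    config: PipelineConfig,
    dataset: cnn.VolumeDataset,
    sp_id: str,
    reserve_ids: list[str],
    fold_index: int,
) -> dict:
    """Pretrain / fine-tune / evaluate / explain one leave-one-subject-out
    fold; returns metrics, logs and per-sample heatmaps of the evaluation
    split."""
    t_fold = time.time()
    model = cnn.build_model(_arch_for(config), seed=config.seed * 131 + fold_index)
    cfg = _train_config(config, fold_index)
    model, pre_log = cnn.pretrain(
        model, dataset, sp_id, cfg, exclude_subjects=tuple(reserve_ids)
    )
    sp_ds = dataset.subset(np.flatnonzero(dataset.subject_ids.astype(str) == sp_id))
    res_ds = dataset.subset(
        np.isin(dataset.subject_ids.astype(str), reserve_ids)
    )
    # head-only training is cheap: give it more room than the conv stage
    ft_cfg = replace(
        _train_config(config, fold_index, lr=pre_log.lr),
        max_epochs=2 * config.cnn.max_epochs,
        patience=2 * config.cnn.patience,
    )
    model, eval_ds, ft_log = cnn.fine_tune(
        model, sp_ds, res_ds, ft_cfg, pretrain_subjects=tuple(pre_log.train_subjects)
    )
    metrics = cnn.evaluate(model, eval_ds.X, eval_ds.y)

    probs = cnn.predict_proba(model, eval_ds.X)
    preds = (probs >= 0.5).astype(int)
    rules = explain.PropagationRules(
        gamma=config.explain.gamma, eps=config.explain.eps
    )
    n_exp = min(len(eval_ds), config.explain.max_samples_per_fold)
    heat = {m: [] for m in config.explain.methods}
    for i in range(n_exp):
        xin = eval_ds.X[i, ..., 0]
        sid = f"{sp_id}_fold{fold_index}_{i}"
        if "lrp" in heat:
            heat["lrp"].append(
                explain.lrp(model, xin, rules, model_id=sp_id, sample_id=sid).values
            )
        if "ggcam" in heat:
            heat["ggcam"].append(
                explain.guided_grad_cam(model, xin, model_id=sp_id, sample_id=sid).values
            )
        if "gradcam" in heat:
            heat["gradcam"].append(
                explain.grad_cam(model, xin, model_id=sp_id, sample_id=sid).values
            )
    return {
        "sp_id": sp_id,
        "runtime_s": time.time() - t_fold,
        "metrics": metrics,
        "pretrain_log": pre_log,
        "finetune_log": ft_log,
        "heatmaps": {m: np.array(v) for m, v in heat.items() if v},
        "predictions": preds[:n_exp],
        "labels": eval_ds.y[:n_exp].astype(int),
        "audit_train_subjects": pre_log.train_subjects,
    }


def effect_mask_volume(
    mask2d: np.ndarray,
    window_ms: tuple[float, float],
    windows=volumize.BINS_3D_MS,
) -> np.ndarray:
    """(H, W, n_bins) bool mask: ROI footprint in the bins overlapping the
    planted window."""
    lo, hi = window_ms
    vol = np.zeros(mask2d.shape + (len(windows),), dtype=bool)
    for i, (blo, bhi) in enumerate(windows):
        if blo < hi and bhi > lo:
            vol[..., i] = mask2d
    return vol


def run_experiment(config: PipelineConfig | str) -> dict:
    """Execute the full pipeline and write report + tables to out_dir."""
    if isinstance(config, (str, Path)):
        config = load_config(str(config))
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    surface, espec, cohort, mmap, dataset, roi_df = simulate_and_volumize(config)
    reserve_ids = choose_reserve_controls(
        cohort, config.cnn.reserve_control_fraction, config.seed
    )
    patient_ids = cohort.loc[cohort["group"] == "patient", "subject_id"].tolist()
    if config.cnn.n_folds is not None:
        patient_ids = patient_ids[: config.cnn.n_folds]

    folds = []
    for k, sp in enumerate(patient_ids):
        folds.append(run_fold(config, dataset, sp, reserve_ids, k))

    # pooled saliency analysis across folds
    roi_mask2d = volumize.region_pixel_mask(mmap, surface, espec.roi_region_id)
    mask_vol = effect_mask_volume(roi_mask2d, espec.window_ms)
    localization, localization_all, peaks, agg_store = {}, {}, {}, []
    all_preds = np.concatenate([f["predictions"] for f in folds])
    all_labels = np.concatenate([f["labels"] for f in folds])
    for method in config.explain.methods:
        maps = np.concatenate(
            [f["heatmaps"][method] for f in folds if method in f["heatmaps"]]
        )
        agg = analyze.aggregate_heatmaps(
            maps, all_preds, all_labels, "patient", "correct", method=method
        )
        agg_all = analyze.aggregate_heatmaps(
            maps, all_preds, all_labels, "all", "all", method=method
        )
        agg_incorrect = analyze.aggregate_heatmaps(
            maps, all_preds, all_labels, "all", "incorrect", method=method
        )
        if config.volumize.mode == "3d":
            if agg.values is not None:
                localization[method] = analyze.localization_score(agg, mask_vol)
                tc = analyze.roi_time_course(agg, roi_mask2d)
                peaks[method] = list(tc.peak_window_ms)
            localization_all[method] = analyze.localization_score(agg_all, mask_vol)
        agg_store.append((method, "patient_correct", agg))
        agg_store.append((method, "all_samples", agg_all))
        agg_store.append((method, "incorrect", agg_incorrect))

    # statistics mirroring the clinical tables
    stats_table = analyze.group_stats_table(
        roi_df, ["roi_mean", config.synth.score_name]
    )
    rho, p = analyze.pearson_one_tailed(
        roi_df["roi_mean"], roi_df[config.synth.score_name], "positive"
    )

    metrics = [f["metrics"] for f in folds]
    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_volumes": len(dataset),
        "n_folds": len(folds),
        "fold_metrics": [m.to_dict() for m in metrics],
        "fold_runtime_s": [f["runtime_s"] for f in folds],
        "mean_accuracy": float(np.mean([m.accuracy for m in metrics])),
        "mean_auroc": float(np.mean([m.auroc for m in metrics])),
        "pretrain_lr": [f["pretrain_log"].lr for f in folds],
        "localization_score": localization,
        "localization_score_all_samples": localization_all,
        "peak_window_ms": peaks,
        "planted_window_ms": list(espec.window_ms),
        "roi_score_correlation": {"rho": rho, "p_one_tailed": p},
        "group_stats": stats_table.to_dict(orient="records"),
        "runtime_s": time.time() - t0,
    }

    stats_table.to_csv(out / "group_stats.csv", index=False)
    roi_df.to_csv(out / "roi_per_subject.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    hm_path = out / "aggregate_heatmaps.h5"
    if hm_path.exists():
        hm_path.unlink()
    agg_objs = [
        explain.RelevanceVolume(
            values=a.values, method=m, model_id=chash, sample_id=cell
        )
        for m, cell, a in agg_store
        if a.values is not None
    ]
    io.save_heatmaps(str(hm_path), agg_objs, meta={"config_hash": chash,
                                                   "seed": config.seed})
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
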