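"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate ->
chemotherapy-benefit -> immunotherapy-response.

Each stage reads its inputs from, and writes its artifacts under, a single
run directory; a JSON manifest records the configuration hash, per-stage
output file hashes and timestamps, so a re-run with the same configuration
and seeds can be verified byte-for-byte on the deterministic stages. A stage
failure marks the manifest and skips everything downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import treatment as tr
from .network import NetworkConfig, MultiTaskNet, train as train_net, predict
from .preprocess import ImageVolume, SliceStack, preprocess_volume
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run", "STAGES"]

STAGES = ("simulate", "preprocess", "train", "predict", "evaluate",
          "chemo-benefit", "immuno-response")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 20230823
    stages: tuple[str, ...] = STAGES
    train_fraction: float = 0.7
    horizon_months: float = 60.0
    bootstrap_b: int = 20
    target_spacing: tuple[float, float, float] = (2.5, 0.75, 0.75)
    hu_window: tuple[float, float] = (-150.0, 150.0)
    n_slices: int = 5
    crop_size: int = 160
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig(max_epochs=10))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("generator", {}).items()})
        net = NetworkConfig(**raw.pop("network", {"max_epochs": 10}))
        for key in ("stages", "target_spacing", "hu_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, network=net, **raw)

    def config_hash(self) -> str:
        blob = json.dumps({
            "run": {k: v for k, v in dataclasses.asdict(self).items()
                    if k not in ("generator", "network")},
            "generator": dataclasses.asdict(self.generator),
            "network": dataclasses.asdict(self.network),
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, ev.CoxFit):
        return {"summary": _jsonable(obj.summary), "n": obj.n,
                "n_events": obj.n_events}
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
    generate_cohort(gen, out_dir=out / "cohort", write_images=True)
    return [out / "cohort" / "cohort.csv", out / "cohort" / "generator_config.yaml"]


def _stage_preprocess(cfg: RunConfig, out: Path) -> list[Path]:
    cohort_dir = out / "cohort"
    table = pd.read_csv(cohort_dir / "cohort.csv")
    stack_dir = out / "stacks"
    stack_dir.mkdir(exist_ok=True)
    paths = []
    for _, row in table.iterrows():
        vol = ImageVolume.from_nifti(cohort_dir / row["volume_path"])
        mask = ImageVolume.from_nifti(cohort_dir / row["mask_path"])
        stack = preprocess_volume(vol, mask, target_spacing=cfg.target_spacing,
                                  window=cfg.hu_window, k=cfg.n_slices,
                                  crop=cfg.crop_size)
        sp = stack_dir / f"{row['subject_id']}.npz"
        stack.save(sp)
        paths.append(str(sp))
    table["stack_path"] = paths
    manifest = out / "preprocessed.csv"
    table.to_csv(manifest, index=False)
    return [manifest]


def _load_stacks(table: pd.DataFrame) -> np.ndarray:
    return np.stack([SliceStack.load(p).planes for p in table["stack_path"]])


def _split(table: pd.DataFrame, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    n_train = max(int(round(fraction * len(table))), 2)
    return np.sort(idx[:n_train]), np.sort(idx[n_train:])


def _stage_train(cfg: RunConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "preprocessed.csv")
    train_idx, _ = _split(table, cfg.train_fraction, cfg.seed)
    sub = table.iloc[train_idx]
    stacks = _load_stacks(sub)
    net_cfg = dataclasses.replace(cfg.network, seed=cfg.seed)
    net, history = train_net(net_cfg, stacks,
                             sub["true_class"].to_numpy(),
                             sub["time"].to_numpy(),
                             sub["event"].to_numpy(bool))
    ckpt = out / "model" / "checkpoint.npz"
    net.save(ckpt)
    hist_path = out / "model" / "history.json"
    with open(hist_path, "w") as fh:
        json.dump({"loss_tme": history.epoch_loss_tme,
                   "loss_cox": history.epoch_loss_cox}, fh, indent=2)
    return [ckpt, hist_path]


def _stage_predict(cfg: RunConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "preprocessed.csv")
    net = MultiTaskNet.load(out / "model" / "checkpoint.npz")
    probs, risk = predict(net, _load_stacks(table))
    pred = table[["subject_id"]].copy()
    for k in range(4):
        pred[f"p_class{k + 1}"] = probs[:, k]
    pred["predicted_class"] = probs.argmax(axis=1) + 1
    pred["dls"] = risk
    pred_path = out / "predictions.csv"
    pred.to_csv(pred_path, index=False)
    return [pred_path]


def _effective_horizon(times: np.ndarray, horizon: float) -> float:
    return float(min(horizon, np.quantile(times, 0.9)))


def _stage_evaluate(cfg: RunConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "preprocessed.csv").merge(
        pd.read_csv(out / "predictions.csv"), on="subject_id")
    train_idx, val_idx = _split(table, cfg.train_fraction, cfg.seed)
    train_df = table.iloc[train_idx].reset_index(drop=True)
    val_df = table.iloc[val_idx].reset_index(drop=True)
    metrics: dict = {}

    # TME classification on the held-out split
    probs = val_df[[f"p_class{k}" for k in (1, 2, 3, 4)]].to_numpy()
    rep = ev.classification_report(val_df["predicted_class"], val_df["true_class"],
                                   probs)
    metrics["classification"] = {
        "accuracy": rep.accuracy, "accuracy_ci": rep.accuracy_ci,
        "confusion": rep.confusion, "per_class": rep.per_class}

    # prognosis: training-median cutoff, KM/log-rank, C-index, ROC
    cutoff = ev.median_cutoff(train_df["dls"])
    groups = ev.risk_groups(val_df["dls"], cutoff)
    times = val_df["time"].to_numpy()
    events = val_df["event"].to_numpy(bool)
    horizon = _effective_horizon(times, cfg.horizon_months)
    stat = p = None
    if len(np.unique(groups)) == 2 and events.any():
        stat, p = ev.log_rank_test(times, events, groups)
    metrics["prognosis"] = {
        "dls_cutoff_training_median": cutoff,
        "log_rank": {"statistic": stat, "p": p},
        "c_index_dls": ev.concordance_index(val_df["dls"], times, events),
        "horizon_months": horizon,
        "auc_dls_at_horizon": ev.time_dependent_roc(val_df["dls"], times,
                                                    events, horizon)["auc"],
    }
    try:
        metrics["prognosis"]["cox_univariable_dls"] = ev.cox_fit(val_df, ["dls"])
    except ValueError as exc:
        metrics["prognosis"]["cox_univariable_dls"] = {"error": str(exc)}

    # drop covariates that are constant in either split (tiny-cohort guard)
    clinical = [c for c in ev.DEFAULT_CLINICAL_COVARIATES
                if train_df[c].std() > 0 and val_df[c].std() > 0]
    covs = ["dls"] + clinical
    # covariates enter as continuous terms here, so validation cohorts with
    # sparsely observed levels still score
    integ = ev.integrated_model(train_df.astype({c: float for c in clinical}),
                                clinical_covariates=clinical)
    metrics["integrated"] = {
        "fit": integ.fit,
        "strata_cutpoints": integ.strata_cutpoints,
        "chi2_importance": ev.chi2_importance(integ.fit).to_dict(),
    }
    lp_val = integ.linear_predictor(val_df)
    try:
        clin_fit = ev.cox_fit(train_df, clinical)
        lp_clin = clin_fit.linear_predictor(val_df)
        metrics["integrated"]["nri_vs_clinical"] = ev.nri_timepoint(
            lp_val, lp_clin, times, events, horizon, n_boot=100, rng=cfg.seed)
    except ValueError as exc:
        metrics["integrated"]["nri_vs_clinical"] = {"error": str(exc)}

    # prediction-error curves for nested models
    grid = np.quantile(times, [0.2, 0.35, 0.5, 0.65, 0.8])
    grid = np.unique(np.clip(grid, 1e-3, times.max() - 1e-6))

    def make_cox_model(cov_list):
        def fit(df_train):
            f = ev.cox_fit(df_train, cov_list)
            t0, e0 = df_train["time"].to_numpy(), df_train["event"].to_numpy(bool)
            km = ev.km_estimate(t0, e0)
            lp_train = f.linear_predictor(df_train)

            def pred(df_test):
                lp = f.linear_predictor(df_test) - lp_train.mean()
                base = np.asarray([km.survival_at(t) for t in grid], dtype=float)
                return np.clip(base[None, :], 1e-12, 1.0) ** np.exp(lp)[:, None]
            return pred
        return fit

    models = {"stage_only": make_cox_model(["stage"]),
              "clinical": make_cox_model(clinical),
              "dls_only": make_cox_model(["dls"]),
              "integrated": make_cox_model(covs)}
    try:
        pec = ev.prediction_error_632plus(models, val_df, grid,
                                          B=cfg.bootstrap_b, rng=cfg.seed)
        metrics["prediction_error"] = {
            name: {"ibs": r["ibs"], "n_failed": r["n_failed"]}
            for name, r in pec.items()}
        curves = pd.DataFrame({"time": grid, **{n: r["err632plus"]
                                                for n, r in pec.items()}})
        curves.to_csv(out / "prediction_error_curves.csv", index=False)
    except ValueError as exc:
        metrics["prediction_error"] = {"error": str(exc)}

    # calibration of the integrated model at the horizon
    km_all = ev.km_estimate(train_df["time"], train_df["event"])
    base_h = float(km_all.survival_at(horizon))
    surv_val = np.clip(base_h, 1e-12, 1.0) ** np.exp(
        lp_val - integ.linear_predictor(train_df).mean())
    cal = ev.calibration_curve(surv_val, times, events, horizon)
    cal.to_csv(out / "calibration.csv", index=False)
    metrics["calibration_bins"] = len(cal)

    path = out / "metrics.json"
    with open(path, "w") as fh:
        json.dump(_jsonable(metrics), fh, indent=2)
    return [path, out / "calibration.csv"]


def _stage_chemo(cfg: RunConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "preprocessed.csv").merge(
        pd.read_csv(out / "predictions.csv"), on="subject_id")
    sub = table[table["stage"].isin([2, 3])].reset_index(drop=True)
    results: dict = {"per_class": {}}
    pairs_rows = []
    for klass in (1, 2, 3, 4):
        cls_df = sub[sub["predicted_class"] == klass].reset_index(drop=True)
        entry: dict = {"n": int(len(cls_df))}
        try:
            scores = tr.fit_propensity(cls_df)
            match = tr.match_1to1_nearest(cls_df, scores, seed=cfg.seed)
            matched = cls_df.iloc[match.matched_indices].reset_index(drop=True)
            entry["n_matched"] = int(len(matched))
            entry["effect"] = tr.stratum_treatment_effect(matched)
            entry["balance"] = match.balance
            for t_i, c_i in match.pairs:
                pairs_rows.append({"predicted_class": klass,
                                   "treated": cls_df.loc[t_i, "subject_id"],
                                   "control": cls_df.loc[c_i, "subject_id"]})
        except ValueError as exc:
            entry["error"] = str(exc)
        results["per_class"][klass] = entry
    try:
        results["interaction_class_x_chemo"] = {
            k: v for k, v in tr.interaction_test(sub, "predicted_class").items()
            if k != "fit"}
    except ValueError as exc:
        results["interaction_class_x_chemo"] = {"error": str(exc)}
    path = out / "chemo_benefit.json"
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
    pd.DataFrame(pairs_rows).to_csv(out / "matched_pairs.csv", index=False)
    return [path, out / "matched_pairs.csv"]


def _stage_immuno(cfg: RunConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "preprocessed.csv").merge(
        pd.read_csv(out / "predictions.csv"), on="subject_id")
    table["cps_category"] = [tr.categorize_cps(c) for c in table["cps"]]
    tree = None
    try:
        tree = tr.fit_response_tree(table["predicted_class"],
                                    table["cps_category"], table["response"],
                                    seed=cfg.seed)
    except ValueError:
        pass
    report = tr.response_report(table, tree)
    # PFS by predicted class
    try:
        stat, p = ev.log_rank_test(table["pfs_time"], table["pfs_event"],
                                   table["predicted_class"])
        report["pfs_log_rank"] = {"statistic": stat, "p": p}
    except ValueError as exc:
        report["pfs_log_rank"] = {"error": str(exc)}
    path = out / "immuno_response.json"
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    tree_path = out / "response_tree.json"
    with open(tree_path, "w") as fh:
        json.dump(tree.to_json_dict() if tree else {"error": "tree not fitted"},
                  fh, indent=2)
    if tree is not None:
        (out / "response_tree.txt").write_text(tree.to_text())
    return [path, tree_path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "chemo-benefit": _stage_chemo,
    "immuno-response": _stage_immuno,
}


def run(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "version": _package_version(), "stages": {}}
    failed = False
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        entry: dict = {"status": "skipped_after_failure"}
        if not failed:
            t0 = time.time()
            try:
                outputs = _STAGE_FNS[stage](cfg, out)
                entry = {"status": "ok",
                         "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                         "seconds": round(time.time() - t0, 3)}
            except Exception as exc:
                failed = True
                entry = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        manifest["stages"][stage] = entry
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _package_version() -> str:
    from importlib.metadata import version, PackageNotFoundError
    try:
        return version("tmesurv")
    except PackageNotFoundError:
        return "unknown"
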