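"""Accuracy and prognosis statistics for the imaging survival model.

Covers the full downstream evaluation battery: multi-class classification
metrics, Kaplan-Meier / log-rank, Cox proportional-hazards fits (Breslow
ties throughout, matching the training loss convention), time-dependent ROC
at a clinical horizon, DeLong AUC comparison, Harrell's C-index, IPCW Brier
score / integrated Brier score, .632+ bootstrap prediction-error curves,
continuous net reclassification improvement, calibration curves, Wald-chi2
variable importance, and the integrated (imaging + clinicopathologic) Cox
model with frozen 8-level risk strata.

Conventions: risk scores are log-hazard-like (higher = worse); survival
probabilities are P(T > t). Cutoffs and strata boundaries are always fitted
on a training cohort and applied frozen elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sksurv.metrics import brier_score as _sksurv_brier
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "KMEstimate", "km_estimate", "log_rank_test",
    "CoxFit", "cox_fit",
    "time_dependent_roc", "delong_auc", "delong_compare",
    "ClassificationReport", "classification_report",
    "concordance_index", "nri_timepoint",
    "brier_and_ibs", "prediction_error_632plus",
    "calibration_curve", "chi2_importance",
    "IntegratedModel", "integrated_model",
    "median_cutoff", "risk_groups",
]


def _check_records(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be aligned 1-D arrays")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("survival times must be positive and finite")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit estimate: right-continuous step function + Greenwood SE."""

    timeline: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    at_risk: pd.DataFrame

    def survival_at(self, t):
        scalar = np.ndim(t) == 0
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.timeline, tt, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out[0]) if scalar else out


def km_estimate(times, events) -> KMEstimate:
    times, events = _check_records(times, events)
    if times.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    # Greenwood variance: S(t)^2 * sum d/(n(n-d))
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n - d > 0, d / (n * (n - d)), 0.0)
    var = surv ** 2 * np.cumsum(terms)
    return KMEstimate(timeline, surv, var, table)


def log_rank_test(times, events, groups) -> tuple[float, float]:
    """Two-sided chi-square log-rank test across >= 2 groups."""
    times, events = _check_records(times, events)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if not events.any():
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Breslow partial-likelihood fit with Wald inference.

    ``summary`` columns: coef, se, hr, hr_lower, hr_upper, z, p.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.summary.index].to_numpy(dtype=float)
        return x @ self.summary["coef"].to_numpy()


def cox_fit(df: pd.DataFrame, covariates: Sequence[str],
            duration_col: str = "time", event_col: str = "event") -> CoxFit:
    times, events = _check_records(df[duration_col], df[event_col])
    x = df[list(covariates)].to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] != times.size:
        raise ValueError("covariate matrix misaligned with outcomes")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant covariate in Cox model")
    if events.sum() < len(covariates):
        raise ValueError("fewer events than covariates")
    model = PHReg(times, x, status=events.astype(int), ties="breslow")
    res = model.fit(disp=False, maxiter=200)
    coefs = np.asarray(res.params)
    ses = np.asarray(res.bse)
    if not (np.all(np.isfinite(coefs)) and np.all(np.isfinite(ses))
            and np.max(np.abs(coefs)) < 50):
        raise ValueError("Cox fit did not converge (monotone likelihood?)")
    z = coefs / ses
    summary = pd.DataFrame({
        "coef": coefs, "se": ses, "hr": np.exp(coefs),
        "hr_lower": np.exp(coefs - 1.959963984540054 * ses),
        "hr_upper": np.exp(coefs + 1.959963984540054 * ses),
        "z": z, "p": 2 * stats.norm.sf(np.abs(z)),
    }, index=list(covariates))
    return CoxFit(summary=summary, log_likelihood=float(model.loglike(coefs)),
                  n=int(times.size), n_events=int(events.sum()))


# ---------------------------------------------------------------------------
# time-dependent ROC (KM cumulative/dynamic estimator)
# ---------------------------------------------------------------------------

def time_dependent_roc(scores, times, events, horizon: float) -> dict:
    """Cumulative-case / dynamic-control ROC at ``horizon``.

    Censoring is handled with Kaplan-Meier estimates inside the score strata
    (the estimator behind the classic survivalROC "KM" method):

        sens(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
        spec(c) =      S(t | X <= c) P(X <= c) / S(t)

    Returns {"fpr", "tpr", "cutoffs", "auc"}; AUC by trapezoid.
    """
    times, events = _check_records(times, events)
    scores = np.asarray(scores, dtype=float)
    if horizon <= 0 or horizon > times.max():
        raise ValueError("horizon must lie within follow-up")
    if not np.any(events & (times <= horizon)):
        raise ValueError("no events before the horizon")
    s_all = float(km_estimate(times, events).survival_at(horizon))
    # walk cutoffs from high to low: the above-threshold set only grows, so
    # the (fpr, tpr) sequence is monotone by construction
    cutoffs = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in cutoffs:
        above = scores > c
        p_above = above.mean()
        s_above = (float(km_estimate(times[above], events[above]).survival_at(horizon))
                   if above.any() else 1.0)
        s_below = (float(km_estimate(times[~above], events[~above]).survival_at(horizon))
                   if (~above).any() else 1.0)
        denom_sens = 1.0 - s_all
        denom_spec = s_all
        sens = (1.0 - s_above) * p_above / denom_sens if denom_sens > 0 else 0.0
        spec = s_below * (1.0 - p_above) / denom_spec if denom_spec > 0 else 0.0
        tpr.append(float(np.clip(sens, 0.0, 1.0)))
        fpr.append(float(np.clip(1.0 - spec, 0.0, 1.0)))
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_arr = np.maximum.accumulate(np.asarray(fpr))  # guard float jitter
    tpr_arr = np.maximum.accumulate(np.asarray(tpr))
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return {"fpr": fpr_arr, "tpr": tpr_arr, "cutoffs": cutoffs, "auc": auc}


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _placements(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-subject placement values (midrank convention)."""
    pos = scores[labels]
    neg = scores[~labels]
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), V01 analogous
    v10 = np.array([np.mean((neg < p) + 0.5 * (neg == p)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    return float(v10.mean()), v10, v01


def delong_auc(scores, labels) -> float:
    labels = np.asarray(labels).astype(bool)
    auc, _, _ = _placements(np.asarray(scores, dtype=float), labels)
    return auc


def delong_compare(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test for a difference in AUC on the same subjects."""
    labels = np.asarray(labels).astype(bool)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("need both positive and negative subjects")
    auc_a, v10a, v01a = _placements(scores_a, labels)
    auc_b, v10b, v01b = _placements(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "delta_auc": delta,
            "z": float(z), "p": p}


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    confusion: pd.DataFrame
    per_class: pd.DataFrame       # sensitivity/specificity/ppv/npv/auc rows
    accuracy: float
    accuracy_ci: tuple[float, float]
    n: int


def classification_report(predicted, truth, probs=None) -> ClassificationReport:
    """One-vs-others metrics for the four TME classes.

    ``probs`` (n, 4), if given, yields per-class one-vs-others AUCs.
    Accuracy CI is the normal approximation p +/- 1.96 sqrt(p(1-p)/n).
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    classes = [1, 2, 3, 4]
    if np.any(~np.isin(predicted, classes)) or np.any(~np.isin(truth, classes)):
        raise ValueError("labels must be in {1, 2, 3, 4}")
    n = truth.size
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(truth, predicted):
        conf.loc[t, p] += 1
    rows = {}
    for k in classes:
        tp = int(((predicted == k) & (truth == k)).sum())
        fp = int(((predicted == k) & (truth != k)).sum())
        fn = int(((predicted != k) & (truth == k)).sum())
        tn = n - tp - fp - fn
        rows[k] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "ppv": tp / (tp + fp) if tp + fp else np.nan,
            "npv": tn / (tn + fn) if tn + fn else np.nan,
            "auc": (delong_auc(np.asarray(probs)[:, k - 1], truth == k)
                    if probs is not None else np.nan),
        }
    acc = float((predicted == truth).mean())
    half = 1.959963984540054 * np.sqrt(acc * (1 - acc) / n)
    return ClassificationReport(
        confusion=conf, per_class=pd.DataFrame(rows).T,
        accuracy=acc, accuracy_ci=(max(acc - half, 0.0), min(acc + half, 1.0)),
        n=n)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(risk_scores, times, events) -> float:
    """Harrell's C for a risk score (higher score = earlier event)."""
    times, events = _check_records(times, events)
    if not events.any():
        raise ValueError("no comparable pairs: no events")
    return float(_lifelines_cindex(times, -np.asarray(risk_scores, dtype=float),
                                   events))


# ---------------------------------------------------------------------------
# censoring weights
# ---------------------------------------------------------------------------

def _censoring_survival(times, events) -> KMEstimate:
    """KM of the censoring distribution G(t) (events and censorings swapped)."""
    return km_estimate(times, ~np.asarray(events).astype(bool))


# ---------------------------------------------------------------------------
# continuous NRI with IPCW
# ---------------------------------------------------------------------------

def nri_timepoint(scores_new, scores_old, times, events, horizon: float,
                  n_boot: int = 200, rng=None) -> dict:
    """Category-free NRI of the new vs old risk score at ``horizon``.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    with events/nonevents by the horizon weighted by inverse censoring
    probabilities; bootstrap percentile CI and normal-approximation p.
    """
    times, events = _check_records(times, events)
    scores_new = np.asarray(scores_new, dtype=float)
    scores_old = np.asarray(scores_old, dtype=float)
    if horizon > times.max():
        raise ValueError("horizon beyond follow-up")

    def _nri(idx) -> float:
        t, e = times[idx], events[idx]
        new, old = scores_new[idx], scores_old[idx]
        g = _censoring_survival(t, e)
        up = new > old
        down = new < old
        is_event = e & (t <= horizon)
        is_nonevent = t > horizon
        w_event = np.where(is_event, 1.0 / np.maximum(g.survival_at(t), 1e-12), 0.0)
        g_h = float(np.maximum(g.survival_at(horizon), 1e-12))
        w_non = np.where(is_nonevent, 1.0 / g_h, 0.0)
        if w_event.sum() == 0 or w_non.sum() == 0:
            return np.nan
        p_up_e = (w_event * up).sum() / w_event.sum()
        p_dn_e = (w_event * down).sum() / w_event.sum()
        p_up_n = (w_non * up).sum() / w_non.sum()
        p_dn_n = (w_non * down).sum() / w_non.sum()
        return (p_up_e - p_dn_e) + (p_dn_n - p_up_n)

    n = times.size
    point = _nri(np.arange(n))
    rng = np.random.default_rng(rng)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        val = _nri(idx)
        if np.isfinite(val):
            boots.append(val)
    boots = np.asarray(boots)
    if boots.size >= 10:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        se = boots.std(ddof=1)
        z = point / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        lo = hi = np.nan
        p = np.nan
    return {"nri": float(point), "ci": (float(lo), float(hi)), "p": p,
            "n_boot_used": int(boots.size)}


# ---------------------------------------------------------------------------
# Brier score / IBS / .632+ prediction error
# ---------------------------------------------------------------------------

def _surv_y(times, events):
    return np.array(list(zip(np.asarray(events).astype(bool),
                             np.asarray(times, dtype=float))),
                    dtype=[("event", bool), ("time", float)])


def brier_and_ibs(surv_probs: np.ndarray, times, events, grid) -> tuple[np.ndarray, float]:
    """IPCW Brier curve on ``grid`` and its normalized trapezoid integral.

    ``surv_probs`` is (n, len(grid)): each subject's predicted P(T > t).
    """
    times, events = _check_records(times, events)
    grid = np.asarray(grid, dtype=float)
    surv_probs = np.asarray(surv_probs, dtype=float)
    if grid.min() <= 0 or grid.max() >= times.max():
        raise ValueError("grid must lie strictly inside follow-up")
    y = _surv_y(times, events)
    _, bs = _sksurv_brier(y, y, surv_probs, grid)
    if grid.size == 1:
        return bs, float(bs[0])
    ibs = float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))
    return bs, ibs


def _ipcw_brier_manual(surv_at_t: np.ndarray, times, events, t: float,
                       g: KMEstimate) -> float:
    """Plain IPCW Brier at one timepoint (used for the no-information error)."""
    died = (times <= t) & events
    alive = times > t
    g_tminus = np.maximum(g.survival_at(np.asarray(times) - 1e-9), 1e-12)
    g_t = float(np.maximum(g.survival_at(t), 1e-12))
    contrib = np.where(died, (0.0 - surv_at_t) ** 2 / g_tminus, 0.0) \
        + np.where(alive, (1.0 - surv_at_t) ** 2 / g_t, 0.0)
    return float(contrib.mean())


def prediction_error_632plus(models: Mapping[str, Callable],
                             df: pd.DataFrame, grid, B: int = 50, rng=None,
                             duration_col: str = "time",
                             event_col: str = "event") -> dict:
    """Bootstrap .632+ prediction-error (Brier) curves per model.

    ``models`` maps a name to ``fit(train_df) -> predict``, where
    ``predict(test_df)`` returns an (n_test, len(grid)) survival-probability
    matrix. Resamples whose refit fails are dropped (and counted).
    Returns {name: {"grid", "apparent", "err632plus", "ibs", "n_failed"}}.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(rng)
    times = df[duration_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=bool)
    y = _surv_y(times, events)
    g = _censoring_survival(times, events)
    n = len(df)
    boot_indices = [rng.integers(0, n, size=n) for _ in range(B)]
    out = {}
    for name, fit in models.items():
        predict = fit(df)
        apparent = _sksurv_brier(y, y, predict(df), grid)[1]
        oob_sum = np.zeros_like(grid)
        oob_cnt = np.zeros_like(grid)
        n_failed = 0
        for idx in boot_indices:
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size < 5:
                continue
            try:
                pred_b = fit(df.iloc[idx].reset_index(drop=True))
                probs = pred_b(df.iloc[oob].reset_index(drop=True))
                _, bs = _sksurv_brier(y, y[oob], probs, grid)
            except Exception:
                n_failed += 1
                continue
            oob_sum += bs
            oob_cnt += 1
        err_boot = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), apparent)
        # no-information error: every prediction scored against every outcome
        surv_matrix = predict(df)
        gamma = np.array([
            np.mean([_ipcw_brier_manual(np.full(n, surv_matrix[i, k]), times,
                                        events, t, g) for i in range(n)])
            for k, t in enumerate(grid)
        ])
        err_boot_prime = np.minimum(err_boot, gamma)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(
                (err_boot_prime > apparent) & (gamma > apparent),
                (err_boot_prime - apparent) / (gamma - apparent), 0.0)
        r = np.clip(r, 0.0, 1.0)
        w = 0.632 / (1.0 - 0.368 * r)
        curve = (1.0 - w) * apparent + w * err_boot_prime
        ibs = float(np.trapezoid(curve, grid) / (grid[-1] - grid[0])) \
            if grid.size > 1 else float(curve[0])
        out[name] = {"grid": grid, "apparent": apparent,
                     "err632plus": curve, "ibs": ibs, "n_failed": n_failed}
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_curve(pred_surv: np.ndarray, times, events, horizon: float,
                      bins: int = 4) -> pd.DataFrame:
    """Quantile-binned predicted vs KM-observed survival at ``horizon``.

    Bins that cannot be formed (ties in predictions) are merged by qcut;
    returns one row per effective bin with Greenwood-based 95% CI.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    times, events = _check_records(times, events)
    pred_surv = np.asarray(pred_surv, dtype=float)
    binned = pd.qcut(pred_surv, q=bins, duplicates="drop", labels=False)
    if binned is None or np.all(pd.isna(binned)):
        binned = np.zeros(pred_surv.size, dtype=int)
    rows = []
    for b in np.unique(binned):
        sel = binned == b
        km = km_estimate(times[sel], events[sel])
        obs = float(km.survival_at(horizon))
        idx = np.searchsorted(km.timeline, horizon, side="right") - 1
        se = float(np.sqrt(km.variance[idx])) if idx >= 0 else 0.0
        rows.append({
            "bin": int(b), "n": int(sel.sum()),
            "mean_predicted": float(pred_surv[sel].mean()),
            "observed_km": obs,
            "ci_lower": max(obs - 1.96 * se, 0.0),
            "ci_upper": min(obs + 1.96 * se, 1.0),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variable importance and the integrated model
# ---------------------------------------------------------------------------

def chi2_importance(fit: CoxFit) -> pd.Series:
    """Relative Wald-chi2 contribution of each (1-df) model term."""
    chi2 = (fit.summary["coef"] / fit.summary["se"]) ** 2
    return chi2 / chi2.sum()


@dataclass
class IntegratedModel:
    """Imaging score + clinicopathologic Cox model with frozen risk strata."""

    fit: CoxFit
    covariates: list[str]
    strata_cutpoints: np.ndarray    # 7 interior quantiles of the training lp
    training_levels: dict = field(default_factory=dict)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        for cov in self.covariates:
            levels = self.training_levels.get(cov)
            if levels is not None:
                unseen = set(np.unique(df[cov])) - levels
                if unseen:
                    raise ValueError(f"unseen level(s) {unseen} for {cov!r}")
        return self.fit.linear_predictor(df)

    def strata(self, df: pd.DataFrame) -> np.ndarray:
        """Risk stratum 1 (lowest lp) .. 8 (highest), frozen cutpoints."""
        lp = self.linear_predictor(df)
        return np.searchsorted(self.strata_cutpoints, lp, side="right") + 1


DEFAULT_CLINICAL_COVARIATES = ["t_stage", "n_stage", "m_stage", "cea",
                               "location", "differentiation"]


def integrated_model(train_df: pd.DataFrame, dls_col: str = "dls",
                     clinical_covariates: Sequence[str] = tuple(DEFAULT_CLINICAL_COVARIATES),
                     duration_col: str = "time", event_col: str = "event",
                     n_strata: int = 8) -> IntegratedModel:
    """Fit the integrated Cox model on a training cohort.

    Strata are equal-quantile bins of the training linear predictor; the
    cutpoints are frozen and applied unchanged to validation cohorts.
    Categorical-ish integer covariates record their training levels so an
    unseen level at application raises.
    """
    covs = [dls_col] + list(clinical_covariates)
    fit = cox_fit(train_df, covs, duration_col, event_col)
    lp = fit.linear_predictor(train_df)
    qs = np.linspace(0, 1, n_strata + 1)[1:-1]
    cuts = np.quantile(lp, qs)
    levels = {}
    for cov in covs:
        vals = train_df[cov]
        if pd.api.types.is_integer_dtype(vals) and vals.nunique() <= 10:
            levels[cov] = set(vals.unique())
    return IntegratedModel(fit=fit, covariates=covs, strata_cutpoints=cuts,
                           training_levels=levels)


# ---------------------------------------------------------------------------
# risk dichotomization
# ---------------------------------------------------------------------------

def median_cutoff(training_scores) -> float:
    """The training-cohort median — the only admissible source of a cutoff."""
    return float(np.median(np.asarray(training_scores, dtype=float)))


def risk_groups(scores, cutoff: float) -> np.ndarray:
    """Dichotomize at a (training-derived) cutoff: 'low' < cutoff <= 'high'."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores >= cutoff, "high", "low")
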