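"""Treatment-effect analyses keyed to the predicted TME classes.

Two clinical questions are addressed:

* **Adjuvant chemotherapy benefit** — within each predicted TME class
  (optionally further split by the survival-score group), treated and
  untreated patients are 1:1 propensity-matched on clinicopathologic
  covariates and the within-stratum chemotherapy hazard ratio is estimated;
  a Cox interaction test (marker x treatment product term) formalizes the
  effect modification.
* **Anti-PD-1 immunotherapy response** — PD-L1 CPS is categorized with the
  clinical cutoffs (high >= 10, intermediate 1-<10, low < 1) and combined
  with the predicted TME class in a shallow CART model; objective response
  rates and AUC comparisons (DeLong) quantify the added value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.tree import DecisionTreeClassifier, export_text
import statsmodels.api as sm

from .evaluate import cox_fit, delong_auc, delong_compare, log_rank_test

__all__ = [
    "PROPENSITY_COVARIATES",
    "fit_propensity", "match_1to1_nearest", "PropensityMatch",
    "stratum_treatment_effect", "interaction_test",
    "categorize_cps", "CPS_CATEGORIES",
    "ResponseTreeModel", "fit_response_tree", "response_report",
]

#: Clinicopathologic variables entering the treatment propensity model.
PROPENSITY_COVARIATES = ["age", "sex", "differentiation", "cea", "ca199",
                         "location", "t_stage", "n_stage", "size_cm", "lauren"]

CPS_CATEGORIES = ("low", "intermediate", "high")


# ---------------------------------------------------------------------------
# propensity-score matching
# ---------------------------------------------------------------------------

def fit_propensity(df: pd.DataFrame, treatment_col: str = "chemo",
                   covariates: Sequence[str] = tuple(PROPENSITY_COVARIATES),
                   ) -> np.ndarray:
    """Logistic propensity of treatment given covariates; scores in (0, 1)."""
    treat = df[treatment_col].to_numpy(dtype=int)
    if not np.isin(treat, [0, 1]).all():
        raise ValueError("treatment must be binary 0/1")
    x = df[list(covariates)].to_numpy(dtype=float)
    if np.all(x.std(axis=0) == 0):
        return np.full(len(df), treat.mean())
    # drop constant columns (no information, would break the fit)
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    model = sm.Logit(treat, sm.add_constant(x))
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise ValueError(f"propensity model failed (separation?): {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 30:
        raise ValueError("propensity model shows separation")
    return np.asarray(res.predict())


@dataclass
class PropensityMatch:
    pairs: list[tuple[int, int]]           # (treated_idx, control_idx) positions
    scores: np.ndarray
    caliper: float | None
    balance: pd.DataFrame                  # standardized mean differences

    @property
    def matched_indices(self) -> np.ndarray:
        return np.array(sorted({i for pair in self.pairs for i in pair}), dtype=int)


def _smd(x, treat) -> float:
    a, b = x[treat], x[~treat]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def match_1to1_nearest(df: pd.DataFrame, scores, treatment_col: str = "chemo",
                       caliper: float | str | None = None,
                       covariates: Sequence[str] = tuple(PROPENSITY_COVARIATES),
                       seed: int = 0) -> PropensityMatch:
    """Greedy 1:1 nearest-neighbor matching on the logit propensity.

    Treated subjects are processed in seeded random order, each taking the
    nearest unused control, without replacement. ``caliper=None`` disables
    the caliper (the default); ``caliper="auto"`` uses 0.2 x SD of the logit
    scores. Returns matched pairs and a pre/post balance table of
    standardized mean differences.
    """
    scores = np.asarray(scores, dtype=float)
    treat = df[treatment_col].to_numpy(dtype=int).astype(bool)
    if treat.all() or not treat.any():
        raise ValueError("both treatment arms must be non-empty")
    lscore = logit(np.clip(scores, 1e-12, 1 - 1e-12))
    if caliper == "auto":
        caliper_val: float | None = 0.2 * float(lscore.std(ddof=1))
    else:
        caliper_val = caliper
    rng = np.random.default_rng(seed)
    treated_idx = np.flatnonzero(treat)
    control_idx = np.flatnonzero(~treat)
    order = rng.permutation(len(treated_idx))
    available = np.ones(len(control_idx), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ti in treated_idx[order]:
        if not available.any():
            break
        cand = np.flatnonzero(available)
        dists = np.abs(lscore[control_idx[cand]] - lscore[ti])
        best = cand[int(np.argmin(dists))]
        if caliper_val is not None and np.min(dists) > caliper_val:
            continue
        pairs.append((int(ti), int(control_idx[best])))
        available[best] = False
    if not pairs:
        raise ValueError("no matches found")
    matched = np.array(sorted({i for p in pairs for i in p}), dtype=int)
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            continue
        x = df[cov].to_numpy(dtype=float)
        rows.append({"covariate": cov,
                     "smd_pre": _smd(x, treat),
                     "smd_post": _smd(x[matched], treat[matched])})
    return PropensityMatch(pairs=pairs, scores=scores, caliper=caliper_val,
                           balance=pd.DataFrame(rows))


def stratum_treatment_effect(df: pd.DataFrame, treatment_col: str = "chemo",
                             duration_col: str = "time",
                             event_col: str = "event") -> dict:
    """Chemo-vs-none hazard ratio and log-rank p within one stratum.

    ``df`` should already be restricted to the stratum (e.g. one predicted
    TME class of the matched cohort).
    """
    if not df[event_col].astype(bool).any():
        raise ValueError("no events in stratum")
    fit = cox_fit(df, [treatment_col], duration_col, event_col)
    row = fit.summary.loc[treatment_col]
    _, lr_p = log_rank_test(df[duration_col], df[event_col], df[treatment_col])
    return {"hr": float(row["hr"]),
            "ci": (float(row["hr_lower"]), float(row["hr_upper"])),
            "p": float(row["p"]), "log_rank_p": float(lr_p),
            "n": int(len(df)), "n_events": int(df[event_col].sum())}


def interaction_test(df: pd.DataFrame, marker_col: str,
                     treatment_col: str = "chemo",
                     duration_col: str = "time",
                     event_col: str = "event") -> dict:
    """Cox model with marker, treatment and their product; Wald p for the
    product term (the formal effect-modification test)."""
    work = df[[duration_col, event_col, marker_col, treatment_col]].copy()
    work["_interaction"] = work[marker_col].astype(float) * work[treatment_col].astype(float)
    if work["_interaction"].std() == 0:
        raise ValueError("marker x treatment term is collinear/constant")
    fit = cox_fit(work, [marker_col, treatment_col, "_interaction"],
                  duration_col, event_col)
    row = fit.summary.loc["_interaction"]
    return {"coef": float(row["coef"]), "se": float(row["se"]),
            "p": float(row["p"]), "fit": fit}


# ---------------------------------------------------------------------------
# CPS and the response decision tree
# ---------------------------------------------------------------------------

def categorize_cps(cps: float) -> str:
    """Clinical CPS bins: high (>= 10), intermediate (1 <= CPS < 10), low (< 1)."""
    if cps < 0 or not np.isfinite(cps):
        raise ValueError(f"CPS must be a non-negative number, got {cps}")
    if cps >= 10:
        return "high"
    if cps >= 1:
        return "intermediate"
    return "low"


@dataclass
class ResponseTreeModel:
    """Shallow CART over (TME class, CPS category) for objective response."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    leaf_table: pd.DataFrame
    trivial: bool = False

    def predict_proba(self, tme_class, cps_category) -> np.ndarray:
        x = _tree_features(tme_class, cps_category)
        if self.trivial:
            return np.full(len(x), float(self.leaf_table["response_rate"].iloc[0]))
        return self.tree.predict_proba(x)[:, 1]

    def to_text(self) -> str:
        if self.trivial:
            return f"root: response_rate={self.leaf_table['response_rate'].iloc[0]:.3f}"
        return export_text(self.tree, feature_names=self.feature_names)

    def to_json_dict(self) -> dict:
        return {"trivial": self.trivial,
                "features": self.feature_names,
                "leaves": self.leaf_table.to_dict(orient="records")}


_TREE_FEATURES = ["tme_class_1", "tme_class_2", "tme_class_3", "tme_class_4",
                  "cps_ordinal"]


def _tree_features(tme_class, cps_category) -> np.ndarray:
    tme_class = np.asarray(tme_class, dtype=int)
    cats = np.asarray([CPS_CATEGORIES.index(c) for c in np.asarray(cps_category)])
    onehot = np.zeros((tme_class.size, 4))
    onehot[np.arange(tme_class.size), tme_class - 1] = 1.0
    return np.column_stack([onehot, cats.astype(float)])


def fit_response_tree(tme_class, cps_category, objective_response,
                      max_depth: int = 3, min_leaf: int = 10,
                      seed: int = 0) -> ResponseTreeModel:
    """CART (Gini) on TME class x CPS category; leaf response rates as scores.

    A single-class outcome yields a trivial root stump (with a warning in
    the returned model rather than an exception).
    """
    y = np.asarray(objective_response, dtype=int)
    if y.size < 20:
        raise ValueError("need at least 20 subjects to fit the response tree")
    x = _tree_features(tme_class, cps_category)
    if len(np.unique(y)) < 2:
        leaf = pd.DataFrame([{"leaf": 0, "n": int(y.size),
                              "response_rate": float(y.mean())}])
        return ResponseTreeModel(tree=DecisionTreeClassifier(), trivial=True,
                                 feature_names=_TREE_FEATURES, leaf_table=leaf)
    tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                  min_samples_leaf=min_leaf, random_state=seed)
    tree.fit(x, y)
    leaves = tree.apply(x)
    rows = [{"leaf": int(l), "n": int((leaves == l).sum()),
             "response_rate": float(y[leaves == l].mean())}
            for l in np.unique(leaves)]
    return ResponseTreeModel(tree=tree, feature_names=_TREE_FEATURES,
                             leaf_table=pd.DataFrame(rows))


def response_report(df: pd.DataFrame, tree: ResponseTreeModel | None = None,
                    class_col: str = "predicted_class",
                    cps_col: str = "cps", response_col: str = "response") -> dict:
    """Objective response rates by group and AUC comparison of the models.

    Reports ORR per predicted TME class and per CPS category, plus DeLong
    AUCs/comparisons for CPS alone, TME class alone (inverted so class 1
    scores highest), and the composite tree model when provided. Subjects
    with missing response are excluded (count reported).
    """
    work = df.copy()
    missing = int(work[response_col].isna().sum())
    work = work.dropna(subset=[response_col])
    y = work[response_col].to_numpy(dtype=int)
    work["cps_category"] = [categorize_cps(c) for c in work[cps_col]]
    orr_by_class = work.groupby(class_col)[response_col].agg(["mean", "size"])
    orr_by_cps = work.groupby("cps_category")[response_col].agg(["mean", "size"])
    cps_score = work[cps_col].to_numpy(dtype=float)
    tme_score = 5.0 - work[class_col].to_numpy(dtype=float)  # class 1 = most responsive
    out = {
        "n": int(len(work)), "n_missing_response": missing,
        "overall_orr": float(y.mean()),
        "orr_by_class": orr_by_class, "orr_by_cps": orr_by_cps,
    }
    labels = y.astype(bool)
    degenerate = labels.all() or not labels.any()
    if degenerate:  # AUCs undefined for a single-class outcome
        out["auc_cps"] = out["auc_tme"] = np.nan
        return out
    out["auc_cps"] = delong_auc(cps_score, labels)
    out["auc_tme"] = delong_auc(tme_score, labels)
    out["compare_tme_vs_cps"] = delong_compare(tme_score, cps_score, labels)
    if tree is not None:
        composite = tree.predict_proba(work[class_col], work["cps_category"])
        out["auc_composite"] = delong_auc(composite, labels)
        out["compare_composite_vs_cps"] = delong_compare(composite, cps_score,
                                                         labels)
    return out
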