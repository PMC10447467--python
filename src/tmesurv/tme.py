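"""Ground-truth tumor-microenvironment (TME) labels from immunohistochemistry.

Two validated biomarkers summarize the TME of a gastric tumor:

* the gastric-cancer immune score ``IS_GC`` — a fixed weighted sum of
  immune-cell densities (CD3, CD8, CD45RO, CD66b) measured at the tumor
  center (CT) and the invasive margin (IM);
* periostin (POSTN) — a stromal extracellular-matrix protein scored by
  stain intensity x stain extent, averaged over five high-power fields.

Each score is dichotomized at its *training-cohort* median and the two
binary axes define four TME classes:

====== ========== ==========
class  IS_GC      POSTN
====== ========== ==========
1      high       low
2      high       high
3      low        low
4      low        high
====== ========== ==========

Class 1 (immune-rich / stroma-poor) carries the best prognosis, class 4
(immune-poor / stroma-rich) the worst.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IHCPanel",
    "PostnFields",
    "TmeThresholds",
    "IS_GC_WEIGHTS",
    "compute_is_gc",
    "compute_postn_score",
    "fit_thresholds",
    "assign_tme_class",
    "label_cohort",
]

#: Published weights of the IS_GC immune score. Keys name the marker and the
#: region it is counted in (im = invasive margin, ct = center of tumor);
#: densities are nucleated stained cells per field.
IS_GC_WEIGHTS: dict[str, float] = {
    "cd3_im": 0.149,
    "cd3_ct": 0.021,
    "cd8_im": 0.044,
    "cd45ro_ct": 0.096,
    "cd66b_im": -0.173,
}

INTENSITY_GRADES = (0, 1, 2, 3)
EXTENT_GRADES = (0, 1, 2, 3, 4)
N_POSTN_FIELDS = 5


@dataclass(frozen=True)
class IHCPanel:
    """Immune-cell densities (cells per field) entering the IS_GC score."""

    cd3_im: float
    cd3_ct: float
    cd8_im: float
    cd45ro_ct: float
    cd66b_im: float

    def __post_init__(self) -> None:
        for name in IS_GC_WEIGHTS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"density {name}={v!r} must be finite and >= 0")


@dataclass(frozen=True)
class PostnFields:
    """Periostin staining grades for five high-power fields.

    Each field is an (intensity, extent) pair; intensity in {0..3}
    (negative/weak/moderate/strong), extent in {0..4} (0-4%, 5-24%,
    25-49%, 50-74%, >75% of the field stained).
    """

    fields: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.fields) != N_POSTN_FIELDS:
            raise ValueError(f"expected {N_POSTN_FIELDS} fields, got {len(self.fields)}")
        for intensity, extent in self.fields:
            if intensity not in INTENSITY_GRADES:
                raise ValueError(f"intensity grade {intensity!r} not in {INTENSITY_GRADES}")
            if extent not in EXTENT_GRADES:
                raise ValueError(f"extent grade {extent!r} not in {EXTENT_GRADES}")


@dataclass(frozen=True)
class TmeThresholds:
    """Training-cohort medians used to dichotomize the two TME axes.

    The thresholds are *fitted once* on a training cohort and applied frozen
    everywhere else; ``source_cohort_id`` records where they came from.
    """

    is_gc_median: float
    postn_median: float
    source_cohort_id: str = "unspecified"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TmeThresholds":
        with open(path) as fh:
            return cls(**json.load(fh))


def compute_is_gc(panel: IHCPanel) -> float:
    """Weighted immune score; CD66b (neutrophils) enters negatively."""
    return float(sum(w * getattr(panel, k) for k, w in IS_GC_WEIGHTS.items()))


def compute_postn_score(fields: PostnFields) -> float:
    """Mean over the five fields of intensity x extent; range [0, 12]."""
    return float(np.mean([i * e for i, e in fields.fields]))


def fit_thresholds(
    train_is_gc_scores: Sequence[float],
    train_postn_scores: Sequence[float],
    source_cohort_id: str = "unspecified",
) -> TmeThresholds:
    """Median-dichotomization thresholds from a training cohort.

    Even n uses the mean of the two central order statistics (the usual
    sample median).
    """
    is_gc = np.asarray(train_is_gc_scores, dtype=float)
    postn = np.asarray(train_postn_scores, dtype=float)
    if is_gc.size < 2 or postn.size < 2:
        raise ValueError("need at least 2 training scores per axis")
    return TmeThresholds(
        is_gc_median=float(np.median(is_gc)),
        postn_median=float(np.median(postn)),
        source_cohort_id=source_cohort_id,
    )


def assign_tme_class(is_gc: float, postn: float, thresholds: TmeThresholds) -> int:
    """Quadrant assignment. Values exactly at a median count as 'high'."""
    high_is = is_gc >= thresholds.is_gc_median
    high_postn = postn >= thresholds.postn_median
    if high_is:
        return 1 if not high_postn else 2
    return 3 if not high_postn else 4


def label_cohort(table: pd.DataFrame, thresholds: TmeThresholds | None = None) -> pd.DataFrame:
    """Score and classify a cohort table.

    ``table`` needs the five IS_GC density columns plus
    ``postn_intensity_1..5`` / ``postn_extent_1..5``. If ``thresholds`` is
    None they are fitted on this table (training-cohort use). Returns a copy
    with ``is_gc``, ``postn_score`` and ``tme_class`` columns.
    """
    out = table.copy()
    is_gc = []
    postn = []
    for _, row in table.iterrows():
        panel = IHCPanel(**{k: float(row[k]) for k in IS_GC_WEIGHTS})
        fields = PostnFields(
            tuple(
                (int(row[f"postn_intensity_{i}"]), int(row[f"postn_extent_{i}"]))
                for i in range(1, N_POSTN_FIELDS + 1)
            )
        )
        is_gc.append(compute_is_gc(panel))
        postn.append(compute_postn_score(fields))
    out["is_gc"] = is_gc
    out["postn_score"] = postn
    if thresholds is None:
        thresholds = fit_thresholds(is_gc, postn)
    out["tme_class"] = [
        assign_tme_class(s, p, thresholds) for s, p in zip(is_gc, postn)
    ]
    return out
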