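"""Seeded synthetic phantom cohorts for end-to-end exercise of the pipeline.

No public imaging/IHC dataset accompanies the gastric-cancer TME problem, so
this module generates cohorts with the statistical structure the downstream
analyses assume:

* CT-like tumor phantoms: an ellipsoid of soft-tissue density on a textured
  background, whose *intra-tumor texture amplitude increases with TME class*
  (class 1 most homogeneous, class 4 most heterogeneous) — the imaging
  correlate the network is meant to learn;
* IHC panels and periostin stain grades constructed so the recomputed
  IS_GC / POSTN scores fall in the quadrant of the subject's true class
  (configurable label noise);
* survival from a proportional-hazards model whose log-hazard is monotone
  in TME class, with independent uniform administrative censoring;
* class-dependent chemotherapy effects (defaults: the per-class hazard
  ratios 0.258 / 0.691 / 0.831 / 1.669);
* PD-L1 CPS values spanning the three clinical categories, and
  immunotherapy response from a logistic model in TME class and CPS whose
  intercepts are solved so the marginal per-class response rates match
  69.0 / 53.3 / 18.4 / 17.2 %.

Everything is driven by one integer seed; per-subject RNG streams are
spawned from it so cohorts are reproducible subject-by-subject.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, optimize
from scipy.special import expit, logit

from . import tme
from .preprocess import ImageVolume, preprocess_volume

__all__ = [
    "GeneratorConfig",
    "SurvivalRecord",
    "generate_phantom",
    "sample_ihc_panel",
    "sample_outcome",
    "generate_cohort",
    "generate_imaging_dataset",
    "solve_response_intercepts",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored follow-up: observed time (months) and event flag."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if not (self.time > 0 and np.isfinite(self.time)):
            raise ValueError(f"time must be positive and finite, got {self.time}")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Hazards are per month; HU amplitudes refer to the texture standard
    deviation inside the tumor. ``heterogeneity_scale`` must increase
    strictly from class 1 to class 4.
    """

    n_subjects: int = 200
    volume_shape: tuple[int, int, int] = (40, 96, 96)          # (z, y, x) voxels
    voxel_spacing: tuple[float, float, float] = (2.5, 0.75, 0.75)  # mm
    class_mixture: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    heterogeneity_scale: tuple[float, float, float, float] = (5.0, 25.0, 60.0, 110.0)
    texture_sigmas: tuple[float, float] = (1.0, 2.5)           # voxels, two scales
    tumor_mean_hu: float = 80.0
    background_mean_hu: float = 30.0
    background_noise_hu: float = 8.0
    baseline_hazard: float = 0.03                              # events / month
    log_hr_per_class: tuple[float, float, float, float] = (0.0, 0.8, 1.6, 2.4)
    stage_log_hr: float = 0.2                                  # per stage level
    weibull_shape: float = 1.0                                 # 1 = exponential
    censor_window: float = 60.0                                # months
    chemo_fraction: float = 0.5
    chemo_confounding: float = 0.4                             # stage -> treatment logit
    chemo_log_hr_per_class: tuple[float, float, float, float] = (
        math.log(0.258), math.log(0.691), math.log(0.831), math.log(1.669))
    is_gc_threshold: float = 40.0
    postn_threshold: float = 4.0
    label_noise: float = 0.0
    stage_class_correlation: float = 0.3
    cps_category_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    response_cps_slope: float = 0.8                            # logit per CPS category
    response_class_orr: tuple[float, float, float, float] = (0.690, 0.533, 0.184, 0.172)
    pfs_baseline_hazard: float = 0.08
    pfs_response_log_hr: float = -1.0
    seed: int = 20230823

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if not all(a < b for a, b in zip(self.heterogeneity_scale,
                                         self.heterogeneity_scale[1:])):
            raise ValueError("heterogeneity_scale must be strictly increasing")
        if self.censor_window <= 0:
            raise ValueError("censor_window must be positive")
        if any(n < 32 for n in self.volume_shape):
            raise ValueError("volume_shape must be at least 32 voxels per axis")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


# ---------------------------------------------------------------------------
# imaging phantoms
# ---------------------------------------------------------------------------

def _texture(shape, sigmas, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance multi-scale texture: sum of Gaussian-filtered noise."""
    acc = np.zeros(shape)
    for sigma in sigmas:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        acc += f / f.std()
    return acc / acc.std()


def generate_phantom(config: GeneratorConfig, true_class: int,
                     rng: np.random.Generator) -> tuple[ImageVolume, ImageVolume]:
    """One ellipsoidal tumor phantom and its binary mask.

    Intensities are HU-like, clipped to [-200, 300]; intra-tumor texture
    has standard deviation ``heterogeneity_scale[true_class - 1]``.
    """
    if true_class not in (1, 2, 3, 4):
        raise ValueError(f"true_class must be 1..4, got {true_class}")
    nz, ny, nx = config.volume_shape
    # random ellipsoid axes, bounded by the volume
    rz = rng.uniform(4.0, min(12.0, nz / 2 - 2))
    ry = rng.uniform(12.0, min(30.0, ny / 2 - 4))
    rx = rng.uniform(12.0, min(30.0, nx / 2 - 4))
    if min(rz, ry, rx) < 1.5:  # ellipsoid support narrower than 3 voxels
        raise ValueError(f"degenerate tumor shape: radii ({rz:.1f}, {ry:.1f}, {rx:.1f})")
    cz = nz / 2 + rng.uniform(-2, 2)
    cy = ny / 2 + rng.uniform(-4, 4)
    cx = nx / 2 + rng.uniform(-4, 4)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    mask = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
            + ((xx - cx) / rx) ** 2) <= 1.0
    background = (config.background_mean_hu
                  + config.background_noise_hu
                  * _texture(config.volume_shape, config.texture_sigmas, rng))
    amp = config.heterogeneity_scale[true_class - 1]
    tumor = config.tumor_mean_hu + (
        amp * _texture(config.volume_shape, config.texture_sigmas, rng)
        if amp > 0 else 0.0)
    voxels = np.where(mask, tumor, background)
    voxels = np.clip(voxels, -200.0, 300.0)
    volume = ImageVolume(voxels, config.voxel_spacing)
    mask_vol = ImageVolume(mask.astype(np.float64), config.voxel_spacing)
    return volume, mask_vol


# ---------------------------------------------------------------------------
# IHC panels
# ---------------------------------------------------------------------------

_CLASS_QUADRANT = {1: (True, False), 2: (True, True),
                   3: (False, False), 4: (False, True)}  # (high IS, high POSTN)

# achievable intensity x extent products and one representative grading each
_POSTN_PRODUCTS = {0: (0, 0), 1: (1, 1), 2: (1, 2), 3: (1, 3), 4: (1, 4),
                   6: (2, 3), 8: (2, 4), 9: (3, 3), 12: (3, 4)}
_PRODUCT_VALUES = np.array(sorted(_POSTN_PRODUCTS))


def _compose_postn_fields(target: float, want_high: bool, threshold: float,
                          rng: np.random.Generator) -> tme.PostnFields:
    """Five (intensity, extent) fields whose mean product sits on the right
    side of ``threshold`` (ties count as high), near ``target``."""
    products = []
    remaining = 5.0 * target
    for slots in range(5, 0, -1):
        want = remaining / slots
        jitter = rng.normal(0, 0.8)
        p = int(_PRODUCT_VALUES[np.argmin(np.abs(_PRODUCT_VALUES - (want + jitter)))])
        products.append(p)
        remaining -= p
    products = np.array(products)
    for _ in range(60):  # nudge onto the required side of the threshold
        mean = products.mean()
        if want_high and mean >= threshold:
            break
        if not want_high and mean < threshold:
            break
        i = int(np.argmin(products) if want_high else np.argmax(products))
        pos = int(np.searchsorted(_PRODUCT_VALUES, products[i]))
        pos = min(pos + 1, len(_PRODUCT_VALUES) - 1) if want_high else max(pos - 1, 0)
        products[i] = _PRODUCT_VALUES[pos]
    return tme.PostnFields(tuple(_POSTN_PRODUCTS[int(p)] for p in products))


def sample_ihc_panel(true_class: int, thresholds: tuple[float, float],
                     rng: np.random.Generator, label_noise: float = 0.0,
                     ) -> tuple[tme.IHCPanel, tme.PostnFields]:
    """IHC densities and POSTN grades consistent with ``true_class``.

    With probability ``label_noise`` the panel is drawn from a uniformly
    random *other* quadrant (off-diagonal confusion mass ~= label_noise).
    Marker densities are gamma-distributed cells/field; the CD3-IM (or
    CD66b-IM) density is then adjusted so the recomputed IS_GC lands a
    clear margin on the intended side of the threshold.
    """
    if true_class not in _CLASS_QUADRANT:
        raise ValueError(f"true_class must be 1..4, got {true_class}")
    effective = true_class
    if label_noise > 0 and rng.random() < label_noise:
        effective = int(rng.choice([c for c in (1, 2, 3, 4) if c != true_class]))
    want_high_is, want_high_postn = _CLASS_QUADRANT[effective]
    is_thr, postn_thr = thresholds

    margin = 0.5 + abs(rng.normal(8.0, 4.0))
    target_is = is_thr + margin if want_high_is else is_thr - margin
    cd3_ct = rng.gamma(4.0, 30.0)
    cd8_im = rng.gamma(4.0, 25.0)
    cd45ro_ct = rng.gamma(4.0, 20.0)
    cd3_im = rng.gamma(4.0, 50.0)
    cd66b_im = 0.0
    partial = (0.149 * cd3_im + 0.021 * cd3_ct + 0.044 * cd8_im
               + 0.096 * cd45ro_ct)
    if target_is >= partial:
        cd3_im += (target_is - partial) / 0.149
    else:
        cd66b_im = (partial - target_is) / 0.173
    panel = tme.IHCPanel(cd3_im=cd3_im, cd3_ct=cd3_ct, cd8_im=cd8_im,
                         cd45ro_ct=cd45ro_ct, cd66b_im=cd66b_im)

    span_high = max(12.0 - postn_thr, 0.5)
    span_low = max(postn_thr, 0.5)
    if want_high_postn:
        target_p = postn_thr + rng.uniform(0.4, 0.4 + 0.8 * span_high)
    else:
        target_p = postn_thr - rng.uniform(0.4, 0.4 + 0.8 * span_low)
    fields = _compose_postn_fields(np.clip(target_p, 0.0, 12.0),
                                   want_high_postn, postn_thr, rng)
    return panel, fields


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def sample_outcome(linear_predictor: float, config: GeneratorConfig,
                   rng: np.random.Generator) -> SurvivalRecord:
    """Draw one right-censored survival record from the hazard model.

    Event times follow a Weibull proportional-hazards model with shape
    ``weibull_shape`` (1 = exponential, rate baseline_hazard * exp(lp));
    censoring is uniform on (0, censor_window], independent of covariates.
    """
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not np.isfinite(linear_predictor):
        raise ValueError("linear predictor must be finite")
    rate = config.baseline_hazard * math.exp(linear_predictor)
    e = rng.exponential(1.0)
    event_time = (e / rate) ** (1.0 / config.weibull_shape)
    censor_time = rng.uniform(0.0, config.censor_window)
    censor_time = max(censor_time, 1e-6)
    time = min(event_time, censor_time)
    return SurvivalRecord(time=max(time, 1e-6), event=event_time <= censor_time)


def solve_response_intercepts(config: GeneratorConfig) -> np.ndarray:
    """Per-class intercepts a_c with E_k[expit(a_c + slope*k)] = target ORR,
    expectation over the CPS-category distribution (k = 0, 1, 2)."""
    probs = np.asarray(config.cps_category_probs)
    ks = np.arange(3)

    def marginal(a, target):
        return float(probs @ expit(a + config.response_cps_slope * ks)) - target

    return np.array([optimize.brentq(marginal, -15, 15, args=(t,))
                     for t in config.response_class_orr])


def _sample_cps(rng: np.random.Generator, probs) -> tuple[float, int]:
    k = int(rng.choice(3, p=probs))
    if k == 0:
        return float(rng.uniform(0.0, 1.0)), k
    if k == 1:
        return float(rng.uniform(1.0, 10.0)), k
    return float(min(10.0 + rng.exponential(15.0), 100.0)), k


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_STAGE_CUTS = np.array([-0.8, 0.2, 1.0])  # latent -> stage I..IV


def _subject_row(config: GeneratorConfig, subject_id: int,
                 rng: np.random.Generator, intercepts: np.ndarray) -> dict:
    c = int(rng.choice(4, p=config.class_mixture)) + 1
    # weak stage-class correlation through a shared latent
    latent = config.stage_class_correlation * (c - 2.5) / 1.5 + rng.standard_normal()
    stage = int(np.searchsorted(_STAGE_CUTS, latent)) + 1
    t_stage = int(np.clip(stage + rng.integers(-1, 2), 1, 4))
    n_stage = int(np.clip(stage - 1 + rng.integers(0, 3), 0, 3))
    m_stage = int(stage == 4)
    age = float(np.clip(rng.normal(59.0, 11.0), 25.0, 88.0))
    sex = int(rng.random() < 0.65)
    size_cm = float(rng.lognormal(1.2, 0.4))
    cea = float(rng.lognormal(1.0, 1.0))
    ca199 = float(rng.lognormal(2.0, 1.0))
    location = int(rng.integers(1, 4))
    differentiation = int(rng.integers(1, 4))
    lauren = int(rng.integers(1, 4))

    chemo_logit = logit(config.chemo_fraction) + config.chemo_confounding * (stage - 2.5)
    chemo = int(rng.random() < expit(chemo_logit))

    panel, fields = sample_ihc_panel(
        c, (config.is_gc_threshold, config.postn_threshold), rng,
        label_noise=config.label_noise)
    is_gc = tme.compute_is_gc(panel)
    postn = tme.compute_postn_score(fields)

    lp = (config.log_hr_per_class[c - 1]
          + config.stage_log_hr * (stage - 2.5)
          + chemo * config.chemo_log_hr_per_class[c - 1])
    outcome = sample_outcome(lp, config, rng)

    cps, cps_cat = _sample_cps(rng, config.cps_category_probs)
    p_resp = float(expit(intercepts[c - 1] + config.response_cps_slope * cps_cat))
    response = int(rng.random() < p_resp)
    if response:
        best = "CR" if rng.random() < 0.2 else "PR"
    else:
        best = "SD" if rng.random() < 0.5 else "PD"
    pfs_lp = (config.log_hr_per_class[c - 1]
              + config.pfs_response_log_hr * response)
    pfs_cfg = dataclasses.replace(config, baseline_hazard=config.pfs_baseline_hazard)
    pfs = sample_outcome(pfs_lp, pfs_cfg, rng)

    row = {
        "subject_id": f"S{subject_id:05d}",
        "true_class": c,
        "age": age, "sex": sex, "stage": stage,
        "t_stage": t_stage, "n_stage": n_stage, "m_stage": m_stage,
        "size_cm": size_cm, "cea": cea, "ca199": ca199,
        "location": location, "differentiation": differentiation,
        "lauren": lauren,
        "chemo": chemo,
        "time": outcome.time, "event": int(outcome.event),
        "cps": cps, "cps_category": ("low", "intermediate", "high")[cps_cat],
        "response": response, "best_response": best,
        "pfs_time": pfs.time, "pfs_event": int(pfs.event),
        "is_gc": is_gc, "postn_score": postn,
    }
    row.update({k: getattr(panel, k) for k in tme.IS_GC_WEIGHTS})
    for i, (intensity, extent) in enumerate(fields.fields, start=1):
        row[f"postn_intensity_{i}"] = intensity
        row[f"postn_extent_{i}"] = extent
    return row


def generate_cohort(config: GeneratorConfig, out_dir=None,
                    write_images: bool = True) -> pd.DataFrame:
    """Generate the full cohort table (and, optionally, phantom images).

    When ``out_dir`` is given, per-subject NIfTI volume/mask pairs are
    written under ``out_dir/images`` and a ``cohort.csv`` manifest plus the
    generator config are written last; an ``.incomplete`` marker flags a
    partially written directory until the manifest lands.
    """
    seed_seqs = np.random.SeedSequence(config.seed).spawn(max(config.n_subjects, 1))
    intercepts = solve_response_intercepts(config)
    out_path = Path(out_dir) if out_dir is not None else None
    marker = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        marker = out_path / ".incomplete"
        marker.touch()

    rows = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(seed_seqs[i])
        row = _subject_row(config, i, rng, intercepts)
        if out_path is not None and write_images:
            volume, mask = generate_phantom(config, row["true_class"], rng)
            img_dir = out_path / "images"
            img_dir.mkdir(exist_ok=True)
            vol_path = img_dir / f"{row['subject_id']}_ct.nii.gz"
            mask_path = img_dir / f"{row['subject_id']}_mask.nii.gz"
            volume.to_nifti(vol_path)
            mask.to_nifti(mask_path)
            # manifest paths are relative to the cohort directory, so the
            # manifest is byte-identical for identical (config, seed)
            row["volume_path"] = str(vol_path.relative_to(out_path))
            row["mask_path"] = str(mask_path.relative_to(out_path))
        rows.append(row)

    columns = list(rows[0].keys()) if rows else ["subject_id", "true_class"]
    table = pd.DataFrame(rows, columns=columns)
    if out_path is not None:
        config.to_yaml(out_path / "generator_config.yaml")
        table.to_csv(out_path / "cohort.csv", index=False)
        marker.unlink()
    return table


def generate_imaging_dataset(config: GeneratorConfig) -> dict:
    """In-memory cohort with preprocessed slice stacks, for training runs.

    Returns ``{"stacks": (n, 5, 160, 160), "classes", "times", "events",
    "table"}``. Phantoms are regenerated from the same per-subject streams
    as :func:`generate_cohort`, so the table rows match.
    """
    seed_seqs = np.random.SeedSequence(config.seed).spawn(max(config.n_subjects, 1))
    intercepts = solve_response_intercepts(config)
    rows, stacks = [], []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(seed_seqs[i])
        row = _subject_row(config, i, rng, intercepts)
        volume, mask = generate_phantom(config, row["true_class"], rng)
        stack = preprocess_volume(volume, mask)
        stacks.append(stack.planes)
        rows.append(row)
    table = pd.DataFrame(rows)
    return {
        "stacks": np.stack(stacks) if stacks else np.empty((0, 5, 160, 160)),
        "classes": table["true_class"].to_numpy() if len(table) else np.array([], int),
        "times": table["time"].to_numpy() if len(table) else np.array([]),
        "events": table["event"].to_numpy(bool) if len(table) else np.array([], bool),
        "table": table,
    }
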