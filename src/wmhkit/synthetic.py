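"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`gen_flair_phantom` — a FLAIR-like brain phantom: noisy tissue
  background inside an ellipsoidal brain mask, dark ellipsoidal ventricles,
  an exclusion region standing in for cerebellum + brainstem, and hyperintense
  ellipsoidal lesions of exactly known voxel count.  Lesions are rasterized by
  center-of-voxel inclusion so the true volume is an exact voxel count times
  the voxel volume.
* :func:`gen_cohort` — a per-subject table of demographics and instrument
  scores whose group-membership (WMH+/WMH-) log-odds follow a configurable
  logistic model, with MCAR missingness.
* :func:`gen_gm_maps` — two groups of grey-matter density maps with a
  volumetric deficit of known size planted inside a hippocampal stand-in ROI.

All generators are bit-reproducible for a fixed ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import ImageVolume

__all__ = [
    "Ellipsoid",
    "LesionSpec",
    "PhantomSpec",
    "FlairPhantom",
    "CohortSpec",
    "GmMapSpec",
    "GmMapSet",
    "default_phantom_spec",
    "default_cohort_spec",
    "default_gm_spec",
    "gen_flair_phantom",
    "gen_cohort",
    "gen_gm_maps",
    "random_phantom_spec",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center in voxel indices, radii in mm."""

    center_vox: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def rasterize(self, grid_shape, voxel_size_mm) -> np.ndarray:
        """Binary mask of voxels whose centers fall inside the ellipsoid."""
        grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
        acc = np.zeros(grid_shape, dtype=float)
        for g, c, dv, r in zip(grids, self.center_vox, voxel_size_mm, self.radii_mm):
            if r <= 0:
                raise ValueError("ellipsoid radii must be positive")
            acc = acc + (((g - c) * dv) / r) ** 2
        return acc <= 1.0


@dataclass(frozen=True)
class LesionSpec:
    """One hyperintense lesion: geometry plus contrast multiplier k.

    Pre-noise lesion intensity is ``background_mean + k * background_sd``;
    k >= 3 keeps the lesion above the mean + 1.5 SD detection threshold by
    construction at the default 2 mm smoothing.
    """

    center_vox: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    contrast_k: float = 4.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 100.0
    background_sd: float = 5.0
    lesions: tuple[LesionSpec, ...] = ()
    brain: Ellipsoid = Ellipsoid((32.0, 32.0, 30.0), (52.0, 60.0, 44.0))
    ventricles: tuple[Ellipsoid, ...] = (
        Ellipsoid((26.0, 34.0, 32.0), (6.0, 20.0, 8.0)),
        Ellipsoid((38.0, 34.0, 32.0), (6.0, 20.0, 8.0)),
    )
    exclusion: tuple[Ellipsoid, ...] = (Ellipsoid((32.0, 18.0, 14.0), (20.0, 16.0, 14.0)),)
    #: ventricle intensity offset in background-SD units.  FLAIR nulls the
    #: CSF signal, so ventricles sit near the noise floor, far below brain
    #: tissue; the resulting bimodal intensity histogram is what places the
    #: mean + 1.5 SD threshold in the gap between tissue and lesions, as on
    #: real images.
    ventricle_offset_sd: float = -12.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.background_sd <= 0:
            raise ValueError("background_sd must be > 0")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape too small")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


def default_phantom_spec(rng_seed: int = 0) -> PhantomSpec:
    """The default three-lesion phantom (one subcortical, two periventricular).

    Lesion radii 5/7/9 mm at 2 mm isotropic rasterize to 81/179/389 voxels
    (648/1432/3112 mm^3), a per-subject load inside the range observed for
    WMH+ subjects.
    """
    return PhantomSpec(
        lesions=(
            LesionSpec((20.0, 50.0, 38.0), (5.0, 5.0, 5.0), 4.0),
            LesionSpec((45.0, 34.0, 32.0), (7.0, 7.0, 7.0), 4.0),
            LesionSpec((18.0, 26.0, 36.0), (9.0, 9.0, 9.0), 4.0),
        ),
        rng_seed=rng_seed,
    )


@dataclass
class FlairPhantom:
    """Output bundle of :func:`gen_flair_phantom`."""

    flair: ImageVolume
    brain_mask: ImageVolume
    ventricle_mask: ImageVolume
    exclusion_mask: ImageVolume
    truth: pd.DataFrame  # lesion_id, n_voxels, volume_mm3, contrast_k, centers


def _default_affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def gen_flair_phantom(spec: PhantomSpec, noise: bool = True) -> FlairPhantom:
    """Render a FLAIR phantom with exactly known lesion volumes.

    Parameters
    ----------
    spec : PhantomSpec
    noise : bool
        If False the additive Gaussian noise field is omitted, so lesion
        voxels carry exactly ``background_mean + k * background_sd``.

    Raises
    ------
    ValueError
        If a lesion has voxels outside the brain mask or inside a ventricle
        (the error names the offending lesion index), or if two lesions
        overlap (truth voxel counts would be ambiguous).
    """
    spec.validate()
    affine = _default_affine(spec.voxel_size_mm)
    brain = spec.brain.rasterize(spec.grid_shape, spec.voxel_size_mm)
    vent = np.zeros(spec.grid_shape, dtype=bool)
    for e in spec.ventricles:
        vent |= e.rasterize(spec.grid_shape, spec.voxel_size_mm)
    vent &= brain
    excl = np.zeros(spec.grid_shape, dtype=bool)
    for e in spec.exclusion:
        excl |= e.rasterize(spec.grid_shape, spec.voxel_size_mm)
    excl &= brain

    img = np.full(spec.grid_shape, spec.background_mean, dtype=float)
    img[vent] = spec.background_mean + spec.ventricle_offset_sd * spec.background_sd

    seen = np.zeros(spec.grid_shape, dtype=bool)
    rows = []
    vox_vol = float(np.prod(spec.voxel_size_mm))
    for i, les in enumerate(spec.lesions):
        mask = Ellipsoid(les.center_vox, les.radii_mm).rasterize(
            spec.grid_shape, spec.voxel_size_mm
        )
        if not mask.any():
            raise ValueError(f"lesion {i} rasterizes to zero voxels")
        if (mask & ~brain).any() or (mask & vent).any():
            raise ValueError(
                f"lesion {i} lies outside the brain mask or intersects a ventricle"
            )
        if (mask & seen).any():
            raise ValueError(f"lesion {i} overlaps a previously placed lesion")
        seen |= mask
        img[mask] = spec.background_mean + les.contrast_k * spec.background_sd
        n = int(mask.sum())
        rows.append(
            {
                "lesion_id": i,
                "n_voxels": n,
                "volume_mm3": n * vox_vol,
                "contrast_k": les.contrast_k,
                "center_i": les.center_vox[0],
                "center_j": les.center_vox[1],
                "center_k": les.center_vox[2],
            }
        )

    if noise:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.background_sd, size=spec.grid_shape)
    img[~brain] = 0.0

    truth = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "n_voxels", "volume_mm3", "contrast_k",
            "center_i", "center_j", "center_k",
        ],
    )
    mk = lambda a: ImageVolume(a.astype(np.uint8), affine.copy())
    return FlairPhantom(
        flair=ImageVolume(img, affine.copy()),
        brain_mask=mk(brain),
        ventricle_mask=mk(vent),
        exclusion_mask=mk(excl),
        truth=truth,
    )


def random_phantom_spec(
    rng: np.random.Generator,
    n_lesions: int,
    radius_range_mm: tuple[float, float] = (4.0, 9.0),
    contrast_k: float = 4.0,
    base: PhantomSpec | None = None,
    max_tries: int = 500,
) -> PhantomSpec:
    """Sample a phantom spec with randomly placed, non-overlapping lesions.

    Placement is rejection sampling: candidate centers are drawn inside the
    brain ellipsoid and accepted only if the rasterized lesion is fully inside
    the brain, clear of ventricles and the exclusion region, and disjoint from
    lesions already placed.
    """
    base = base if base is not None else PhantomSpec()
    brain = base.brain.rasterize(base.grid_shape, base.voxel_size_mm)
    vent = np.zeros(base.grid_shape, dtype=bool)
    for e in base.ventricles:
        vent |= e.rasterize(base.grid_shape, base.voxel_size_mm)
    excl = np.zeros(base.grid_shape, dtype=bool)
    for e in base.exclusion:
        excl |= e.rasterize(base.grid_shape, base.voxel_size_mm)
    forbidden = vent | excl | ~brain

    lesions: list[LesionSpec] = []
    occupied = np.zeros(base.grid_shape, dtype=bool)
    tries = 0
    while len(lesions) < n_lesions:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all lesions; relax the geometry")
        r = float(rng.uniform(*radius_range_mm))
        center = tuple(float(rng.uniform(6, n - 6)) for n in base.grid_shape)
        mask = Ellipsoid(center, (r, r, r)).rasterize(base.grid_shape, base.voxel_size_mm)
        if not mask.any() or (mask & forbidden).any() or (mask & occupied).any():
            continue
        occupied |= mask
        lesions.append(LesionSpec(center, (r, r, r), contrast_k))
    return replace(
        base,
        lesions=tuple(lesions),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorDef:
    name: str
    mean: float
    sd: float
    #: per-unit log-odds slope in the generating logit model
    log_odds: float = 0.0

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_odds)


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a synthetic WMH+/WMH- cohort.

    ``2 * n_per_group`` subjects are drawn; group membership is Bernoulli with
    logit = intercept + sum(slope_j * score_j), so the realised group sizes
    are random and their marginal fraction approaches the model-implied value
    as n grows.  ``intercept=None`` centers the logit at the predictor means
    (balanced marginal).  Predictors are jointly Gaussian with exchangeable
    correlation ``predictor_corr``.
    """

    n_per_group: int = 30
    predictors: tuple[PredictorDef, ...] = ()
    intercept: float | None = None
    predictor_corr: float = 0.3
    missing_rate: float = 0.0
    #: demographics for matching: mean/SD of age and education
    age_mean: float = 64.0
    age_sd: float = 7.0
    education_mean: float = 13.0
    education_sd: float = 3.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for p in self.predictors:
            if p.sd <= 0:
                raise ValueError(f"predictor {p.name}: sd must be > 0")
            if not np.isfinite(p.log_odds):
                raise ValueError(f"predictor {p.name}: non-finite slope")
        if self.intercept is not None and not np.isfinite(self.intercept):
            raise ValueError("non-finite intercept")
        if not (-0.99 < self.predictor_corr < 0.99):
            raise ValueError("predictor_corr out of range")


def default_cohort_spec(rng_seed: int = 0, n_per_group: int = 30) -> CohortSpec:
    """Six neuropsychiatric instrument scores with odds ratios in the
    1.11-1.24 per-point range typical of the univariate WMH screens."""
    ors = {
        "BDI": (6.0, 5.0, 1.18),
        "ARS": (10.0, 6.0, 1.18),
        "STAI_Y1": (35.0, 8.0, 1.18),
        "STAI_Y2": (36.0, 8.0, 1.11),
        "STAXI_T": (15.0, 4.0, 1.17),
        "FRS": (10.0, 5.0, 1.24),
    }
    preds = tuple(
        PredictorDef(name, m, s, math.log(o)) for name, (m, s, o) in ors.items()
    )
    return CohortSpec(n_per_group=n_per_group, predictors=preds, rng_seed=rng_seed)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: subject_id, group, age, gender, education, scores.

    Missing score values are inserted completely at random at
    ``spec.missing_rate`` per cell (demographics are never missing).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = 2 * spec.n_per_group
    k = len(spec.predictors)

    if k:
        corr = np.full((k, k), spec.predictor_corr)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, k)) @ chol.T
        means = np.array([p.mean for p in spec.predictors])
        sds = np.array([p.sd for p in spec.predictors])
        # instrument scores are non-negative integers; the recorded values
        # (clipped + rounded) feed the logit so the generating model is
        # exactly the model of the data
        scores = np.round(np.clip(means + z * sds, 0.0, None))
    else:
        scores = np.empty((n, 0))

    slopes = np.array([p.log_odds for p in spec.predictors])
    intercept = (
        spec.intercept
        if spec.intercept is not None
        else -float(np.dot(slopes, [p.mean for p in spec.predictors]))
    )
    logit = intercept + scores @ slopes
    p_pos = 1.0 / (1.0 + np.exp(-logit))
    group = np.where(rng.random(n) < p_pos, "WMH+", "WMH-")

    age = np.clip(np.round(rng.normal(spec.age_mean, spec.age_sd, n)), 50, 80)
    education = np.clip(
        np.round(rng.normal(spec.education_mean, spec.education_sd, n)), 5, 22
    )
    gender = np.where(rng.random(n) < 0.5, "F", "M")

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": group,
            "age": age.astype(int),
            "gender": gender,
            "education": education.astype(int),
        }
    )
    for j, p in enumerate(spec.predictors):
        df[p.name] = scores[:, j]
    if spec.missing_rate > 0 and k:
        miss = rng.random((n, k)) < spec.missing_rate
        for j, p in enumerate(spec.predictors):
            df.loc[miss[:, j], p.name] = np.nan
    return df


# ---------------------------------------------------------------------------
# grey-matter density maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GmMapSpec:
    """Two-group GM density maps with a deficit planted inside a ROI.

    The maps emulate segmented, normalized, modulated GM density images on a
    shared grid: a constant tissue baseline plus spatially smoothed Gaussian
    noise whose *marginal* per-voxel SD is held at ``noise_sd`` regardless of
    ``smoothness_fwhm_mm`` (the smoothed field is rescaled by its exact
    discrete-kernel norm).  Group WMH+ has ``effect_size`` subtracted at every
    ROI voxel, so the in-ROI voxelwise mean difference equals ``effect_size``
    in expectation and 0 elsewhere.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    roi: Ellipsoid = Ellipsoid((16.0, 16.0, 16.0), (6.0, 10.5, 6.0))
    baseline: float = 0.5
    effect_size: float = 0.16
    noise_sd: float = 0.08
    smoothness_fwhm_mm: float = 6.0
    n_per_group: int = 15
    rng_seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("smoothness_fwhm_mm must be >= 0")


def default_gm_spec(rng_seed: int = 0, **kw) -> GmMapSpec:
    return replace(GmMapSpec(), rng_seed=rng_seed, **kw)


@dataclass
class GmMapSet:
    """Output of :func:`gen_gm_maps`: per-group map lists plus the ROI mask."""

    wmh_pos: list[ImageVolume]
    wmh_neg: list[ImageVolume]
    roi_mask: ImageVolume


def _smooth_unit_noise(rng, shape, sigma_vox) -> np.ndarray:
    """Smoothed white noise rescaled to unit marginal SD.

    The rescaling factor is the exact l2 norm of the discrete smoothing
    kernel, obtained by filtering a unit impulse with the same truncation.
    """
    white = rng.standard_normal(shape)
    if all(s == 0 for s in sigma_vox):
        return white
    smoothed = gaussian_filter(white, sigma_vox)
    imp = np.zeros(shape)
    imp[tuple(n // 2 for n in shape)] = 1.0
    kern = gaussian_filter(imp, sigma_vox)
    norm = float(np.sqrt((kern**2).sum()))
    return smoothed / norm


def gen_gm_maps(spec: GmMapSpec, roi_mask: ImageVolume | None = None) -> GmMapSet:
    """Generate the two groups of GM maps and the ROI mask.

    An explicit ``roi_mask`` overrides the spec's ellipsoid; its grid must
    match ``spec.grid_shape``.
    """
    spec.validate()
    affine = _default_affine(spec.voxel_size_mm)
    if roi_mask is None:
        roi = spec.roi.rasterize(spec.grid_shape, spec.voxel_size_mm)
        roi_vol = ImageVolume(roi.astype(np.uint8), affine)
    else:
        if roi_mask.shape != tuple(spec.grid_shape):
            raise ValueError(
                f"roi_mask shape {roi_mask.shape} does not match grid {spec.grid_shape}"
            )
        roi = roi_mask.data.astype(bool)
        roi_vol = roi_mask
    if not roi.any():
        raise ValueError("roi_mask is empty")

    rng = np.random.default_rng(spec.rng_seed)
    sigma_vox = tuple(
        spec.smoothness_fwhm_mm * FWHM_TO_SIGMA / dv for dv in spec.voxel_size_mm
    )

    def draw(effect: float) -> ImageVolume:
        data = spec.baseline + spec.noise_sd * _smooth_unit_noise(
            rng, tuple(spec.grid_shape), sigma_vox
        )
        if effect:
            data = data - effect * roi
        return ImageVolume(data, affine.copy())

    pos = [draw(spec.effect_size) for _ in range(spec.n_per_group)]
    neg = [draw(0.0) for _ in range(spec.n_per_group)]
    return GmMapSet(wmh_pos=pos, wmh_neg=neg, roi_mask=roi_vol)
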