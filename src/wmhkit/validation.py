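"""Parameter-recovery and calibration experiments.

Each function here runs the package on freshly generated synthetic data with
known ground truth and measures how well the truth is recovered: lesion
volumes from phantoms, generating odds ratios from cohorts, type-I error and
power of the Box-Tidwell check, familywise error calibration and power of the
permutation ROI comparison.  They are used by the test suite and by
``scripts/acceptance.py``; all randomness is controlled by explicit seeds.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import DetectParams, WmhDetector
from .logistic import box_tidwell_check, fit_logistic_univariate
from .roi import RoiParams, permutation_fwe
from .synthetic import (
    CohortSpec,
    Ellipsoid,
    GmMapSpec,
    PredictorDef,
    default_gm_spec,
    default_phantom_spec,
    gen_cohort,
    gen_flair_phantom,
    gen_gm_maps,
)

__all__ = [
    "matched_lesion_volumes",
    "lesion_recovery_experiment",
    "or_recovery_experiment",
    "box_tidwell_type1_experiment",
    "box_tidwell_power_experiment",
    "fwe_null_calibration",
    "roi_power_experiment",
]


def matched_lesion_volumes(spec, phantom, result, connectivity: int = 26) -> pd.DataFrame:
    """Per true lesion, the volume of the detected component that overlaps it.

    Each ground-truth lesion is matched to the detected connected component
    with the largest voxel overlap (0 if nothing overlaps).  Scattered false
    positives elsewhere do not influence the matched volumes.
    """
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(3, order)
    labels, _ = ndimage.label(result.wmh_map.volume.data, structure=structure)
    vox_vol = result.wmh_map.volume.voxel_volume_mm3
    rows = []
    for _, row in phantom.truth.iterrows():
        les = spec.lesions[int(row["lesion_id"])]
        mask = Ellipsoid(les.center_vox, les.radii_mm).rasterize(
            spec.grid_shape, spec.voxel_size_mm
        )
        ids, counts = np.unique(labels[mask & (labels > 0)], return_counts=True)
        detected = float((labels == ids[np.argmax(counts)]).sum() * vox_vol) if len(ids) else 0.0
        rows.append(
            {
                "lesion_id": int(row["lesion_id"]),
                "true_mm3": float(row["volume_mm3"]),
                "detected_mm3": detected,
                "rel_err": detected / float(row["volume_mm3"]) - 1.0,
            }
        )
    return pd.DataFrame(rows)


def lesion_recovery_experiment(
    n_seeds: int = 20, base_seed: int = 0, params: DetectParams | None = None
) -> pd.DataFrame:
    """Detect the default three-lesion phantom over many noise seeds.

    Returns one row per (seed, lesion) with true and matched detected volume.
    """
    params = params if params is not None else DetectParams()
    frames = []
    for s in range(n_seeds):
        spec = default_phantom_spec(rng_seed=base_seed + s)
        ph = gen_flair_phantom(spec)
        res = WmhDetector(
            ph.flair, ph.brain_mask, ph.ventricle_mask, ph.exclusion_mask, params=params
        ).fit()
        df = matched_lesion_volumes(spec, ph, res, connectivity=params.connectivity)
        df.insert(0, "seed", base_seed + s)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def or_recovery_experiment(
    true_or: float = 1.18,
    n_per_group: int = 10000,
    seed: int = 0,
    predictor: PredictorDef | None = None,
) -> float:
    """Generate a large cohort from a single-predictor logit and refit.

    The default predictor emulates a state-anxiety score (mean 35, SD 8) with
    a generating odds ratio of ``true_or`` per point; returns the estimated
    univariate odds ratio.
    """
    pred = predictor if predictor is not None else PredictorDef(
        "STAI_Y1", 35.0, 8.0, math.log(true_or)
    )
    spec = CohortSpec(
        n_per_group=n_per_group,
        predictors=(dataclasses.replace(pred, log_odds=math.log(true_or)),),
        predictor_corr=0.0,
        rng_seed=seed,
    )
    cohort = gen_cohort(spec)
    res = fit_logistic_univariate(cohort["group"], cohort[pred.name], name=pred.name)
    return res.odds_ratio


def _bt_rejected(rng, n: int, curvature: float) -> bool:
    """One Box-Tidwell run: linear logit when curvature=0, quadratic else."""
    x = rng.uniform(1.0, 10.0, size=n)
    logit = 0.25 * (x - 5.5) + curvature * (x - 5.5) ** 2
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
    if y.sum() in (0, n):
        return False
    res = box_tidwell_check(y, pd.DataFrame({"x": x}))
    return bool((res.table["p"] < 0.05).any()) and not res.separated


def box_tidwell_type1_experiment(
    reps: int = 500, n: int = 1000, seed: int = 0
) -> float:
    """Type-I error of the X*ln(X) Wald test under a truly linear logit."""
    rng = np.random.default_rng(seed)
    return float(np.mean([_bt_rejected(rng, n, 0.0) for _ in range(reps)]))


def box_tidwell_power_experiment(
    reps: int = 200, n: int = 2000, seed: int = 0, curvature: float = 0.15
) -> float:
    """Power of the check under a strongly quadratic logit."""
    rng = np.random.default_rng(seed)
    return float(np.mean([_bt_rejected(rng, n, curvature) for _ in range(reps)]))


def fwe_null_calibration(
    runs: int = 200,
    seed: int = 0,
    n_per_group: int = 15,
    n_permutations: int = 500,
    gm_spec: GmMapSpec | None = None,
) -> float:
    """Familywise false-positive rate of the permutation max-statistic test.

    Each run generates null GM maps (planted effect 0), runs the two-sided
    permutation FWE procedure over the ROI, and scores whether *any* voxel
    reaches FWE p < 0.05.  The returned fraction should sit near (at or
    just below, by the discreteness of Monte-Carlo p-values) 0.05.
    """
    base = gm_spec if gm_spec is not None else default_gm_spec()
    hits = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(runs):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = dataclasses.replace(base, effect_size=0.0, n_per_group=n_per_group, rng_seed=s)
        gm = gen_gm_maps(spec)
        params = RoiParams(n_permutations=n_permutations, rng_seed=s + 1)
        p = permutation_fwe(gm.wmh_neg, gm.wmh_pos, gm.roi_mask, params)
        hits += int(np.nanmin(p.data) < params.alpha_fwe)
    return hits / runs


def roi_power_experiment(
    seeds: int = 50,
    seed: int = 0,
    n_per_group: int = 15,
    n_permutations: int = 500,
    effect_in_sd: float = 2.0,
    gm_spec: GmMapSpec | None = None,
) -> float:
    """Fraction of seeds with an FWE-significant voxel inside the deficit.

    The planted deficit is ``effect_in_sd`` times the per-voxel noise SD; the
    test is one-tailed in the deficit direction (WMH- > WMH+), matching the
    directional contrast of interest.
    """
    base = gm_spec if gm_spec is not None else default_gm_spec()
    spec0 = dataclasses.replace(
        base,
        effect_size=effect_in_sd * base.noise_sd,
        n_per_group=n_per_group,
    )
    hits = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(seeds):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = dataclasses.replace(spec0, rng_seed=s)
        gm = gen_gm_maps(spec)
        params = RoiParams(
            n_permutations=n_permutations, rng_seed=s + 1, side="greater"
        )
        p = permutation_fwe(gm.wmh_neg, gm.wmh_pos, gm.roi_mask, params)
        sig = p.data[gm.roi_mask.data.astype(bool)] < params.alpha_fwe
        hits += int(np.any(sig))
    return hits / seeds
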