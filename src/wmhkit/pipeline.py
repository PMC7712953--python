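"""End-to-end pipeline driver: simulate -> detect -> match -> stats -> ROI.

One YAML config (or :class:`PipelineConfig`) drives everything; every stage
writes its artifacts under the output directory and appends to a run log that
records package/library versions and every parameter actually used.  A fixed
``seed`` makes the whole run reproducible; per-stage RNG streams are spawned
from it.  Stage failures raise :class:`PipelineError` naming the stage;
artifacts written before the failure are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import MatchingError, MatchParams, match_groups, write_cohort
from .detection import DetectParams, WmhDetector, overlap_map
from .logistic import CohortLogisticScreen
from .roi import RoiGroupComparison, RoiParams
from .synthetic import (
    default_cohort_spec,
    default_gm_spec,
    default_phantom_spec,
    gen_cohort,
    gen_flair_phantom,
    gen_gm_maps,
    random_phantom_spec,
)
from .volume import write_volume

log = logging.getLogger("wmhkit.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the protocol's values
    (2 mm FWHM, k = 1.5, 150 mm^3, tolerance 0.30, FWE 0.05, extent 50)."""

    seed: int = 0
    n_per_group: int = 15
    n_lesions_range: tuple[int, int] = (1, 4)
    missing_rate: float = 0.05
    detect: DetectParams = field(default_factory=DetectParams)
    match: MatchParams = field(default_factory=MatchParams)
    roi: RoiParams = field(default_factory=lambda: RoiParams(n_permutations=1000))
    tolerance_cutoff: float = 0.30
    box_tidwell_shift: float = 1.0
    save_volumes: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key, sub in (
            ("detect", DetectParams),
            ("match", MatchParams),
            ("roi", RoiParams),
        ):
            if key in raw:
                kw[key] = sub(**raw.pop(key))
        simple = {
            f.name for f in dataclasses.fields(cls) if f.name not in ("detect", "match", "roi")
        }
        unknown = set(raw) - simple
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_lesions_range" in raw:
            raw["n_lesions_range"] = tuple(raw["n_lesions_range"])
        kw.update(raw)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _versions() -> dict:
    import nibabel
    import scipy
    import statsmodels

    return {
        "wmhkit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline; returns the run-log dict (also written to disk).

    Stages: simulate (cohort, FLAIR phantoms, GM maps) -> detect (WMH maps,
    lesion tables, Table-4-style load summary, overlap map) -> match ->
    stats (univariate / tolerance / Box-Tidwell / multivariable) ->
    roi (voxelwise t + permutation FWE + cluster filter) -> report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    runlog: dict = {
        "versions": _versions(),
        "config": config.to_dict(),
        "stages": {},
    }
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage = "simulate"
    try:
        # ------------------------------------------------------------------
        rng = np.random.default_rng(seeds[0])
        cspec = dataclasses.replace(
            default_cohort_spec(
                rng_seed=int(rng.integers(2**31 - 1)), n_per_group=config.n_per_group
            ),
            missing_rate=config.missing_rate,
        )
        cohort = gen_cohort(cspec)
        write_cohort(cohort, outdir / "cohort.csv")
        phantoms = {}
        for _, row in cohort.iterrows():
            sid = row["subject_id"]
            if row["group"] == "WMH+":
                n_les = int(rng.integers(*config.n_lesions_range))
                pspec = random_phantom_spec(rng, n_lesions=max(n_les, 1))
            else:
                pspec = dataclasses.replace(
                    default_phantom_spec(int(rng.integers(2**31 - 1))), lesions=()
                )
            phantoms[sid] = gen_flair_phantom(pspec)
        gspec = default_gm_spec(
            rng_seed=int(rng.integers(2**31 - 1)), n_per_group=config.n_per_group
        )
        gm = gen_gm_maps(gspec)
        if config.save_volumes:
            vol_dir = outdir / "volumes"
            vol_dir.mkdir(exist_ok=True)
            first = next(iter(phantoms.values()))
            write_volume(first.brain_mask, vol_dir / "brain_mask.nii.gz")
            write_volume(first.ventricle_mask, vol_dir / "ventricle_mask.nii.gz")
            write_volume(first.exclusion_mask, vol_dir / "exclusion_mask.nii.gz")
            write_volume(gm.roi_mask, vol_dir / "roi_mask.nii.gz")
        runlog["stages"]["simulate"] = {
            "n_subjects": len(cohort),
            "n_wmh_pos_planned": int((cohort["group"] == "WMH+").sum()),
        }
        log.info("simulate: %d subjects", len(cohort))

        # ------------------------------------------------------------------
        stage = "detect"
        loads, detected_groups, maps_pos = [], {}, []
        for sid, ph in phantoms.items():
            res = WmhDetector(
                ph.flair,
                ph.brain_mask,
                ph.ventricle_mask,
                ph.exclusion_mask,
                params=config.detect,
                subject_id=sid,
            ).fit()
            pv, sc, tot = res.loads
            loads.append(
                {
                    "subject_id": sid,
                    "threshold": res.threshold,
                    "n_lesions": len(res.lesion_table),
                    "periventricular_mm3": pv,
                    "subcortical_mm3": sc,
                    "total_mm3": tot,
                    "classification": res.classification,
                }
            )
            detected_groups[sid] = res.classification
            if res.classification == "WMH+":
                maps_pos.append(res.wmh_map)
        loads_df = pd.DataFrame(loads)
        loads_df.to_csv(outdir / "wmh_loads.csv", index=False)
        if maps_pos:
            ov = overlap_map(maps_pos)
            if config.save_volumes:
                write_volume(ov, outdir / "wmh_overlap.nii.gz")
        planned = cohort.set_index("subject_id")["group"]
        agreement = float(
            np.mean([detected_groups[s] == planned[s] for s in detected_groups])
        )
        runlog["stages"]["detect"] = {
            "n_wmh_pos_detected": int((loads_df["classification"] == "WMH+").sum()),
            "agreement_with_planned": agreement,
        }
        log.info("detect: agreement with planned groups %.2f", agreement)
        cohort = cohort.assign(
            group=[detected_groups[s] for s in cohort["subject_id"]]
        )

        # ------------------------------------------------------------------
        stage = "match"
        cases = cohort[cohort["group"] == "WMH+"]
        pool = cohort[cohort["group"] == "WMH-"]
        unmatched: list[str] = []
        pairs = pd.DataFrame(columns=["case_id", "control_id", "age_diff", "education_diff"])
        if len(cases) > len(pool):
            # more cases than potential controls: the excess cannot be paired
            unmatched += list(cases["subject_id"].iloc[len(pool):])
            cases = cases.iloc[: len(pool)]
        # matching failures are reported, not fatal: downstream statistics
        # use the full cohort, as the screening procedure does
        while len(cases):
            try:
                pairs = match_groups(cases, pool, config.match)
                break
            except MatchingError as e:
                unmatched += e.unmatched_ids
                cases = cases[~cases["subject_id"].isin(e.unmatched_ids)]
        pairs.to_csv(outdir / "matched_pairs.csv", index=False)
        runlog["stages"]["match"] = {
            "n_pairs": int(len(pairs)),
            "unmatched_cases": unmatched,
        }
        log.info("match: %d pairs, %d unmatched", len(pairs), len(unmatched))

        # ------------------------------------------------------------------
        stage = "stats"
        n_pos = int((cohort["group"] == "WMH+").sum())
        n_neg = int((cohort["group"] == "WMH-").sum())
        if min(n_pos, n_neg) < 3:
            runlog["stages"]["stats"] = {
                "skipped": True,
                "reason": f"degenerate outcome: {n_pos} WMH+ vs {n_neg} WMH-",
            }
            log.warning("stats: skipped (%s)", runlog["stages"]["stats"]["reason"])
        else:
            screen = CohortLogisticScreen(
                cohort,
                tolerance_cutoff=config.tolerance_cutoff,
                box_tidwell_shift=config.box_tidwell_shift,
            ).fit()
            screen.univariate_table.to_csv(outdir / "univariate.csv", index=False)
            if screen.tolerance is not None:
                screen.tolerance.table.to_csv(outdir / "tolerance.csv", index=False)
            if screen.linearity is not None:
                screen.linearity.table.to_csv(outdir / "box_tidwell.csv", index=False)
            summary = {"selected": screen.selected, "retained": screen.retained}
            if screen.multivariable is not None:
                mv = screen.multivariable
                mv.coef_table.to_csv(outdir / "multivariable.csv", index=False)
                summary.update(
                    model_chi2=mv.model_chi2,
                    model_p=mv.model_p,
                    nagelkerke_r2=mv.pseudo_r2["nagelkerke"],
                    accuracy_overall=mv.accuracy_overall,
                )
            (outdir / "stats_summary.txt").write_text(screen.summary() + "\n")
            runlog["stages"]["stats"] = summary
            log.info("stats: retained predictors %s", screen.retained)

        # ------------------------------------------------------------------
        stage = "roi"
        roi_res = RoiGroupComparison(
            gm.wmh_neg, gm.wmh_pos, gm.roi_mask, params=config.roi
        ).fit()
        roi_res.clusters.to_csv(outdir / "roi_clusters.csv", index=False)
        (outdir / "roi_summary.txt").write_text(roi_res.summary() + "\n")
        runlog["stages"]["roi"] = {
            "n_clusters": int(len(roi_res.clusters)),
            "max_cluster_vox": int(roi_res.clusters["size_vox"].max())
            if len(roi_res.clusters)
            else 0,
        }
        log.info("roi: %d surviving clusters", len(roi_res.clusters))

        # ------------------------------------------------------------------
        stage = "report"
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(runlog, fh, indent=2, default=str)
    except Exception as e:  # noqa: BLE001 - any stage failure is wrapped
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(runlog, fh, indent=2, default=str)
        raise PipelineError(stage, e) from e
    return runlog
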