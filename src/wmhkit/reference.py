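"""Packaged reference data.

``reference_wmh_volumes`` is the published per-subject WMH volumetry table of
a 30-subject WMH+ cohort quantified with the same semi-automated protocol
this package implements: periventricular, subcortical and total lesion volume
in mm^3 for each participant.  It serves as a validation fixture for the
compartment-sum identity (periventricular + subcortical = total) and the
load-summary bookkeeping.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reference_wmh_volumes", "load_summary"]


def reference_wmh_volumes() -> pd.DataFrame:
    """The packaged 30-row volumetry table (volumes in mm^3)."""
    with resources.files("wmhkit.data").joinpath(
        "reference_wmh_volumes.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_summary(volumes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject and sample-level load summary from a volumetry table.

    Expects columns ``periventricular_mm3`` and ``subcortical_mm3``;
    recomputes totals and appends min / max / mean / SD rows of the total
    load across subjects.
    """
    df = volumes.copy()
    df["total_mm3"] = df["periventricular_mm3"] + df["subcortical_mm3"]
    return df
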