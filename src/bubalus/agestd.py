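"""Age standardization of repeated measurements to a target age.

Field measurements are taken whenever the crew visits a farm, so each
animal carries a short series of records at arbitrary ages.  Analysis
requires a single value per animal at a reference age (365 d here).  The
standardized value is taken from the straight line through the two
measurements flanking the target age, or — when the target lies outside
the observed range — through the two measurements nearest to it
(extrapolation).  A single measurement is passed through unchanged and
flagged as unstandardized.

Linear two-point interpolation is exact for any affine growth
trajectory; the extrapolation distance is recorded per cell so distant
extrapolations can be screened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedValue",
    "StandardizedTable",
    "value_at_age",
    "standardize_table",
    "DEFAULT_TARGET_AGE",
    "DEFAULT_MAX_EXTRAPOLATION_DAYS",
]

DEFAULT_TARGET_AGE = 365
#: QC threshold: extrapolations beyond this many days are flagged, not dropped.
DEFAULT_MAX_EXTRAPOLATION_DAYS = 90


@dataclass(frozen=True)
class StandardizedValue:
    """A single age-standardized value with its QC flags."""

    value: float
    #: days between the target age and the nearest observed age (0 if bracketed)
    extrapolation_days: float
    #: True when only one measurement existed (no slope available)
    unstandardized: bool = False


def value_at_age(
    ages, values, target_age: float = DEFAULT_TARGET_AGE
) -> StandardizedValue:
    """Estimate the trait value at ``target_age`` from successive measurements.

    Parameters
    ----------
    ages, values
        Measurement ages (days) and trait values, in any order.
    target_age
        Age, in days, at which the trait value is wanted.

    Raises
    ------
    ValueError
        On an empty series or two records at the same age with
        conflicting values.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size == 0:
        raise ValueError("empty measurement series")
    if ages.shape != values.shape:
        raise ValueError("ages and values differ in length")
    order = np.argsort(ages, kind="stable")
    ages, values = ages[order], values[order]
    dup = np.flatnonzero(np.diff(ages) == 0)
    if dup.size:
        if np.any(values[dup] != values[dup + 1]):
            i = dup[np.flatnonzero(values[dup] != values[dup + 1])[0]]
            raise ValueError(
                f"conflicting measurements at age {ages[i]:g}: "
                f"{values[i]:g} vs {values[i + 1]:g}"
            )
        keep = np.concatenate([[True], np.diff(ages) > 0])
        ages, values = ages[keep], values[keep]
    if ages.size == 1:
        return StandardizedValue(
            float(values[0]), abs(float(ages[0]) - target_age), unstandardized=True
        )
    if ages[0] <= target_age <= ages[-1]:
        # bracketed: linear interpolation between the flanking points
        return StandardizedValue(float(np.interp(target_age, ages, values)), 0.0)
    # outside the range: extend the line through the two nearest points
    if target_age < ages[0]:
        (a0, a1), (v0, v1) = ages[:2], values[:2]
        distance = ages[0] - target_age
    else:
        (a0, a1), (v0, v1) = ages[-2:], values[-2:]
        distance = target_age - ages[-1]
    slope = (v1 - v0) / (a1 - a0)
    return StandardizedValue(float(v0 + slope * (target_age - a0)), float(distance))


@dataclass(frozen=True)
class StandardizedTable:
    """Wide per-animal table of standardized values plus QC companions."""

    values: pd.DataFrame
    extrapolation_days: pd.DataFrame
    unstandardized: pd.DataFrame

    def flagged(self, max_days: float = DEFAULT_MAX_EXTRAPOLATION_DAYS) -> pd.DataFrame:
        """Boolean mask of cells extrapolated beyond ``max_days``."""
        return self.extrapolation_days > max_days


def standardize_table(
    raw: pd.DataFrame, target_age: float = DEFAULT_TARGET_AGE
) -> StandardizedTable:
    """Standardize a long-format measurement table to one row per animal.

    ``raw`` needs columns ``animal``, ``trait``, ``age_days``, ``value``.
    Cells are never dropped; extrapolation distance and the
    single-measurement flag are recorded per (animal, trait) for QC.
    """
    required = {"animal", "trait", "age_days", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    records: dict[str, dict[str, float]] = {}
    extrap: dict[str, dict[str, float]] = {}
    single: dict[str, dict[str, bool]] = {}
    for (animal, trait), grp in raw.groupby(["animal", "trait"], sort=False):
        sv = value_at_age(grp["age_days"], grp["value"], target_age)
        records.setdefault(animal, {})[trait] = sv.value
        extrap.setdefault(animal, {})[trait] = sv.extrapolation_days
        single.setdefault(animal, {})[trait] = sv.unstandardized
    values = pd.DataFrame.from_dict(records, orient="index").rename_axis("animal")
    traits = list(values.columns)
    return StandardizedTable(
        values,
        pd.DataFrame.from_dict(extrap, orient="index").rename_axis("animal")[traits],
        pd.DataFrame.from_dict(single, orient="index").rename_axis("animal")[traits],
    )
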