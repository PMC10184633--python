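"""Scale handling and imputation applied ahead of statistics and time-course work.

Two distinct imputation procedures are provided, matching their distinct
purposes:

* :func:`impute_downshifted_normal` — left-censored (MNAR) imputation for
  label-free proteomic intensities: missing entries are drawn from a
  normal distribution downshifted below each sample's observed
  distribution (Perseus-style, per column), reflecting proteins near the
  detection limit.  Used before moderated testing on LFQ layers.
* :func:`interpolate_timecourse` — plain linear-in-time interpolation of
  missing replicate medians, used only when reconstructing time courses
  for correlation and AUC work, never for the differential tests (SILAC
  ratios are tested on non-imputed values only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import OmicsMatrix, TimeCourse

__all__ = [
    "impute_downshifted_normal",
    "interpolate_timecourse",
    "complete_case_filter",
]


def impute_downshifted_normal(
    m: OmicsMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int = 0,
) -> OmicsMatrix:
    """Impute missing values from a downshifted normal, per sample column.

    For column *j* with observed mean ``mu_j`` and standard deviation
    ``sd_j``, each missing entry is drawn from
    ``Normal(mu_j - shift * sd_j, (width * sd_j)^2)``.  Observed cells are
    never altered.  Deterministic for a given seed.

    Raises if any column has fewer than 3 observed values (the column
    statistics would be meaningless).
    """
    rng = np.random.default_rng(seed)
    data = m.data.copy()
    for col in data.columns:
        x = data[col].to_numpy(dtype=float, copy=True)
        missing = np.isnan(x)
        obs = x[~missing]
        if obs.size < 3:
            raise ValueError(f"sample {col!r} has fewer than 3 observed values")
        if missing.any():
            mu, sd = obs.mean(), obs.std(ddof=1)
            x[missing] = rng.normal(mu - shift * sd, width * sd, size=int(missing.sum()))
            data[col] = x
    return OmicsMatrix(layer=m.layer, scale=m.scale, data=data)


def interpolate_timecourse(tc: TimeCourse) -> TimeCourse:
    """Fill missing medians by linear interpolation against time.

    Interior gaps are interpolated linearly in hours; leading/trailing
    gaps take the nearest observed value.  Requires >= 2 observed medians.
    Replicate-level values are left untouched.
    """
    medians = np.asarray(tc.medians, dtype=float).copy()
    obs = ~np.isnan(medians)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed medians to interpolate")
    if not obs.all():
        medians[~obs] = np.interp(tc.times_h[~obs], tc.times_h[obs], medians[obs])
    return TimeCourse(
        feature=tc.feature,
        condition=tc.condition,
        times_h=tc.times_h,
        replicate_values=tc.replicate_values,
        medians=medians,
    )


def complete_case_filter(m: OmicsMatrix, min_fraction: float = 1.0) -> OmicsMatrix:
    """Keep features observed in at least ``min_fraction`` of replicates of
    every (condition, time) group.

    The default of 1.0 is a per-group complete-case filter (all replicate
    values present in each group).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    keep = pd.Series(True, index=m.data.index)
    groups: dict[tuple, list[str]] = {}
    for s, col in zip(m.samples, m.data.columns):
        groups.setdefault((s.condition, s.time_h), []).append(col)
    for cols in groups.values():
        frac = m.data[cols].notna().mean(axis=1)
        keep &= frac >= min_fraction
    data = m.data.loc[keep]
    features = [f for f, k in zip(m.features, keep) if k]
    return OmicsMatrix(layer=m.layer, scale=m.scale, data=data, features=features, samples=list(m.samples))
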