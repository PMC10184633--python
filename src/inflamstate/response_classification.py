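"""Response classification of combined TNFa + IFNg stimulation responses.

Each differentially regulated feature's combined-stimulation time course
is compared with the single-stimulus courses by

* **shape** — Pearson correlation of the combined course with each single
  course (classes S1 TNFa-shape, S2 IFNg-shape, S3 common shape, S4
  combined-specific shape), and
* **effect size** — ratios of trapezoidal areas under the deflection
  curves, combined over single (classes E1 TNFa effect, E2 IFNg effect,
  E3 super-additive combined effect; ratio threshold 2).

The final call combines both: SYNERGY if S4 or E3; TNF if S1, or S3 with
E1; IFN if S2, or S3 with E2; COMMON if S3 otherwise; else NOT_CLASSIFIED.
Synergy is further decomposed into the fractions of the combined AUC
attributable to TNFa alone, IFNg alone, and the super-additive excess.

Courses are replicate-median deflections from the matched control course
(fallback: the t = 0 value), with missing medians linearly interpolated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    Condition,
    FeatureId,
    OmicsMatrix,
    ThresholdConfig,
    TimeCourse,
    extract_timecourse,
)
from .preprocess import interpolate_timecourse

__all__ = [
    "ShapeClass",
    "EffectClass",
    "ResponseClass",
    "SynergyDecomposition",
    "timecourse_auc",
    "timecourse_correlation",
    "classify_shape",
    "classify_effect",
    "assign_response_class",
    "additive_expectation",
    "synergy_decomposition",
    "deflection_course",
    "classify_feature",
    "classify_dataset",
]


class ShapeClass(str, enum.Enum):
    S1 = "S1"  # TNFa shape
    S2 = "S2"  # IFNg shape
    S3 = "S3"  # common shape
    S4 = "S4"  # combined-specific shape
    NONE = "NONE"


class EffectClass(str, enum.Enum):
    E1 = "E1"  # TNFa effect
    E2 = "E2"  # IFNg effect
    E3 = "E3"  # super-additive combined effect
    NONE = "NONE"


class ResponseClass(str, enum.Enum):
    TNF = "TNF"
    IFN = "IFN"
    COMMON = "COMMON"
    SYNERGY = "SYNERGY"
    NOT_CLASSIFIED = "NOT_CLASSIFIED"


@dataclass(frozen=True)
class SynergyDecomposition:
    """Fractions of the combined AUC carried by each single stimulus and by
    the super-additive excess; the three sum to 1 (may be negative under
    antagonism)."""

    feature: FeatureId | None
    frac_tnf: float
    frac_ifn: float
    frac_excess: float

    def __post_init__(self) -> None:
        total = self.frac_tnf + self.frac_ifn + self.frac_excess
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {total}")


def timecourse_auc(tc: TimeCourse | tuple[np.ndarray, np.ndarray]) -> float:
    """Signed trapezoidal area (log2 x hours) under a deflection course.

    Accepts a TimeCourse whose medians are already deflections from
    baseline (complete — interpolate first), or a ``(times_h, values)``
    pair.
    """
    if isinstance(tc, TimeCourse):
        times, values = tc.times_h, tc.medians
    else:
        times, values = (np.asarray(a, dtype=float) for a in tc)
    if times.size < 2:
        raise ValueError("need at least 2 timepoints for an AUC")
    if np.any(np.isnan(values)):
        raise ValueError("course has missing values; interpolate before AUC")
    return float(np.trapezoid(values, times))


def timecourse_correlation(
    comb: np.ndarray | TimeCourse,
    single: np.ndarray | TimeCourse,
    times_comb: np.ndarray | None = None,
    times_single: np.ndarray | None = None,
) -> float:
    """Pearson correlation of two median deflection courses on one grid.

    Returns NaN (undefined) when either course has zero variance; the
    shape classification lets NaN fall through to NONE.
    """
    if isinstance(comb, TimeCourse):
        comb, times_comb = comb.medians, comb.times_h
    if isinstance(single, TimeCourse):
        single, times_single = single.medians, single.times_h
    comb = np.asarray(comb, dtype=float)
    single = np.asarray(single, dtype=float)
    if times_comb is not None and times_single is not None and not np.array_equal(times_comb, times_single):
        raise ValueError("time grids do not match")
    if comb.size != single.size:
        raise ValueError("time grids do not match")
    if comb.size < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    if np.std(comb) == 0 or np.std(single) == 0:
        return float("nan")
    return float(np.corrcoef(comb, single)[0, 1])


def classify_shape(r_tnf: float, r_ifn: float, cfg: ThresholdConfig | None = None) -> ShapeClass:
    """Shape class from the two correlations (strict inequalities; missing
    correlations give NONE)."""
    cfg = cfg or ThresholdConfig()
    hi, lo = cfg.r_high, cfg.r_low
    if r_tnf is None or r_ifn is None or math.isnan(r_tnf) or math.isnan(r_ifn):
        return ShapeClass.NONE
    if r_tnf > hi and r_ifn > hi:
        return ShapeClass.S3
    if r_tnf > hi and r_ifn < hi:
        return ShapeClass.S1
    if r_ifn > hi and r_tnf < hi:
        return ShapeClass.S2
    if r_tnf < lo and r_ifn < lo:
        return ShapeClass.S4
    return ShapeClass.NONE


def _auc_ratio(auc_comb: float, auc_single: float) -> float:
    """|combined| / |single| with guards: near-zero denominators and
    sign disagreement (single course opposing the combined direction) give
    +inf — the single stimulus cannot explain the combined response."""
    eps = 1e-6 * abs(auc_comb)
    if auc_single * auc_comb < 0:
        return math.inf
    return abs(auc_comb) / max(abs(auc_single), eps)


def classify_effect(
    auc_comb: float,
    auc_tnf: float,
    auc_ifn: float,
    cfg: ThresholdConfig | None = None,
) -> EffectClass:
    """Effect class from AUC ratios combined/single (threshold 2, strict)."""
    cfg = cfg or ThresholdConfig()
    if auc_comb == 0 or math.isnan(auc_comb) or math.isnan(auc_tnf) or math.isnan(auc_ifn):
        return EffectClass.NONE
    q = cfg.auc_ratio
    ratio_tnf = _auc_ratio(auc_comb, auc_tnf)
    ratio_ifn = _auc_ratio(auc_comb, auc_ifn)
    if ratio_tnf > q and ratio_ifn > q:
        return EffectClass.E3
    if ratio_tnf < q and ratio_ifn > q:
        return EffectClass.E1
    if ratio_tnf > q and ratio_ifn < q:
        return EffectClass.E2
    return EffectClass.NONE


def assign_response_class(
    shape: ShapeClass,
    effect: EffectClass,
    synergy_rule: str = "s4_or_e3",
) -> ResponseClass:
    """Final response class from (shape, effect).

    Default precedence: SYNERGY if S4 or E3; then TNF if S1 or S3+E1; IFN
    if S2 or S3+E2; COMMON if S3; else NOT_CLASSIFIED.  The alternative
    reading ``synergy_rule="s3_or_e3"`` (combined class when S3 or E3) is
    selectable but conflicts with the common-class rule and is not the
    default.
    """
    if synergy_rule not in ("s4_or_e3", "s3_or_e3"):
        raise ValueError(f"unknown synergy_rule: {synergy_rule!r}")
    synergy_shape = ShapeClass.S3 if synergy_rule == "s3_or_e3" else ShapeClass.S4
    if shape is synergy_shape or effect is EffectClass.E3:
        return ResponseClass.SYNERGY
    if shape is ShapeClass.S1 or (shape is ShapeClass.S3 and effect is EffectClass.E1):
        return ResponseClass.TNF
    if shape is ShapeClass.S2 or (shape is ShapeClass.S3 and effect is EffectClass.E2):
        return ResponseClass.IFN
    if shape is ShapeClass.S3:
        return ResponseClass.COMMON
    return ResponseClass.NOT_CLASSIFIED


def additive_expectation(
    tc_tnf: TimeCourse | tuple[np.ndarray, np.ndarray],
    tc_ifn: TimeCourse | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise sum of the two single-stimulus median deflection courses
    (the gray 'expected if additive' curve)."""
    t1, v1 = (tc_tnf.times_h, tc_tnf.medians) if isinstance(tc_tnf, TimeCourse) else tc_tnf
    t2, v2 = (tc_ifn.times_h, tc_ifn.medians) if isinstance(tc_ifn, TimeCourse) else tc_ifn
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if not np.array_equal(t1, t2):
        raise ValueError("time grids do not match")
    return t1, np.asarray(v1, dtype=float) + np.asarray(v2, dtype=float)


def synergy_decomposition(
    auc_tnf: float,
    auc_ifn: float,
    auc_comb: float,
    feature: FeatureId | None = None,
) -> SynergyDecomposition:
    """Split the combined AUC into TNFa, IFNg and excess fractions.

    ``frac_excess = 1 - frac_tnf - frac_ifn`` corresponds to
    [TNFa+IFNg] - TNFa - IFNg; negative values indicate antagonism and
    are reported as-is.
    """
    if auc_comb == 0:
        raise ValueError("combined AUC is zero; decomposition undefined")
    frac_tnf = auc_tnf / auc_comb
    frac_ifn = auc_ifn / auc_comb
    return SynergyDecomposition(
        feature=feature,
        frac_tnf=frac_tnf,
        frac_ifn=frac_ifn,
        frac_excess=1.0 - frac_tnf - frac_ifn,
    )


def deflection_course(
    m: OmicsMatrix,
    feature: FeatureId | str,
    condition: Condition,
    baseline: str = "ctrl_course",
) -> tuple[np.ndarray, np.ndarray]:
    """Median deflection course of a feature under a condition.

    ``baseline="ctrl_course"`` subtracts the matched control median course
    (both courses interpolated over missing medians first);
    ``baseline="t0"`` subtracts the condition's own t = 0 median.
    """
    tc = interpolate_timecourse(extract_timecourse(m, feature, condition))
    if baseline == "ctrl_course":
        ctrl = interpolate_timecourse(extract_timecourse(m, feature, Condition.CTRL))
        return tc.times_h, tc.medians - ctrl.medians
    if baseline == "t0":
        return tc.times_h, tc.medians - tc.medians[0]
    raise ValueError(f"unknown baseline: {baseline!r}")


def classify_feature(
    m: OmicsMatrix,
    feature: FeatureId | str,
    cfg: ThresholdConfig | None = None,
    baseline: str = "ctrl_course",
    synergy_rule: str = "s4_or_e3",
) -> dict:
    """Classify one feature; returns all stored intermediates."""
    cfg = cfg or ThresholdConfig()
    times, d_tnf = deflection_course(m, feature, Condition.TNF, baseline)
    _, d_ifn = deflection_course(m, feature, Condition.IFN, baseline)
    _, d_comb = deflection_course(m, feature, Condition.TNF_IFN, baseline)
    r_tnf = timecourse_correlation(d_comb, d_tnf, times, times)
    r_ifn = timecourse_correlation(d_comb, d_ifn, times, times)
    auc_tnf = timecourse_auc((times, d_tnf))
    auc_ifn = timecourse_auc((times, d_ifn))
    auc_comb = timecourse_auc((times, d_comb))
    shape = classify_shape(r_tnf, r_ifn, cfg)
    effect = classify_effect(auc_comb, auc_tnf, auc_ifn, cfg)
    final = assign_response_class(shape, effect, synergy_rule)
    if auc_comb != 0:
        dec = synergy_decomposition(auc_tnf, auc_ifn, auc_comb)
        fracs = (dec.frac_tnf, dec.frac_ifn, dec.frac_excess)
    else:
        fracs = (np.nan, np.nan, np.nan)
    return {
        "feature": str(feature),
        "r_tnf": r_tnf,
        "r_ifn": r_ifn,
        "auc_tnf": auc_tnf,
        "auc_ifn": auc_ifn,
        "auc_comb": auc_comb,
        "shape": shape.value,
        "effect": effect.value,
        "final": final.value,
        "frac_tnf": fracs[0],
        "frac_ifn": fracs[1],
        "frac_excess": fracs[2],
    }


def classify_dataset(
    m: OmicsMatrix,
    features: Iterable[FeatureId | str] | None = None,
    cfg: ThresholdConfig | None = None,
    baseline: str = "ctrl_course",
    synergy_rule: str = "s4_or_e3",
) -> pd.DataFrame:
    """Classify a set of features (default: all features in the matrix).

    In the full pipeline ``features`` is the set significant in the
    combined condition from the differential stage — only differentially
    regulated features enter classification.
    """
    feats = list(features) if features is not None else list(m.data.index)
    rows = [classify_feature(m, f, cfg, baseline, synergy_rule) for f in feats]
    df = pd.DataFrame(rows)
    df.attrs["baseline"] = baseline
    df.attrs["synergy_rule"] = synergy_rule
    df.attrs["layer"] = m.layer.value
    return df
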