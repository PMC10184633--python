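"""Differential event calling with an empirical-Bayes moderated t-statistic.

For every feature, stimulus and timepoint the contrast is stimulus versus
control at the matched time.  Per-feature residual variances are shrunk
toward a common prior estimated by moment matching on the log-variance
scale (scaled inverse-chi-square prior with hyperparameters ``d0``,
``s0^2``), giving the moderated t

    t = log2FC / sqrt(s2_post * (1/n1 + 1/n2)),
    s2_post = (d0 * s0^2 + df * s2) / (d0 + df),

referred to a t distribution with ``d0 + df`` degrees of freedom (normal
when ``d0`` is infinite).  P values are Benjamini-Hochberg adjusted within
each (layer, condition, timepoint) family and an event is significant when
adjusted p < alpha and |log2FC| > lfc_min (secretome uses its stricter
alpha).

A no-intercept linear-model variant for log SILAC ratios (which are
already stimulus/control contrasts within a sample, and are never
imputed) is provided by :func:`fit_silac_no_intercept`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_model import STIMULI, Condition, Layer, OmicsMatrix, ThresholdConfig

__all__ = [
    "ModerationFit",
    "estimate_effects",
    "fit_moderation",
    "moderated_t",
    "bh_adjust",
    "call_events",
    "run_differential",
    "fit_silac_no_intercept",
]

_D0_CAP = 1e6  # prior df above this is treated as infinite


@dataclass(frozen=True)
class ModerationFit:
    """Empirical-Bayes hyperparameters: prior df ``d0`` (may be inf) and
    prior variance ``s0_sq``."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


def estimate_effects(m: OmicsMatrix, condition: Condition, time_h: float) -> pd.DataFrame:
    """Per-feature effect and variance for stimulus vs control at one time.

    Returns a frame indexed by feature label with columns ``log2fc``
    (mean difference on the log scale), ``s2`` (pooled within-arm
    variance), ``df`` (n1 + n2 - 2), ``n1``, ``n2`` and ``testable``.
    Features with fewer than two observed replicates in either arm are
    flagged untestable (their statistics are NaN).
    """
    stim_cols = m.columns_for(condition, time_h)
    ctrl_cols = m.columns_for(Condition.CTRL, time_h)
    if not stim_cols or not ctrl_cols:
        raise ValueError(f"no samples for {condition.value} or CTRL at t={time_h}")
    stim = m.data[stim_cols].to_numpy(dtype=float)
    ctrl = m.data[ctrl_cols].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(stim), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(stim, axis=1)
        mean2 = np.nanmean(ctrl, axis=1)
        var1 = np.nanvar(stim, axis=1, ddof=1)
        var2 = np.nanvar(ctrl, axis=1, ddof=1)
    log2fc = mean1 - mean2
    df = n1 + n2 - 2.0
    with np.errstate(all="ignore"):
        s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
    out = pd.DataFrame(
        {
            "log2fc": np.where(testable, log2fc, np.nan),
            "s2": np.where(testable, s2, np.nan),
            "df": np.where(testable, df, np.nan),
            "n1": n1,
            "n2": n2,
            "testable": testable,
        },
        index=m.data.index,
    )
    return out


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    while special.polygamma(1, lo) < y:
        lo /= 10.0
        if lo < 1e-300:
            return lo
    while special.polygamma(1, hi) > y:
        hi *= 10.0
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_moderation(s2: np.ndarray, df: np.ndarray) -> ModerationFit:
    """Moment-match the scaled inverse-chi-square prior on log variances.

    With ``z = log(s2)``, ``E[z] = log(s0^2) + psi(d0/2) - log(d0/2) +
    log(df/2) - psi(df/2)`` and ``Var[z] = psi'(df/2) + psi'(d0/2)``;
    the excess of the observed spread of ``z`` over the sampling term
    ``psi'(df/2)`` identifies ``d0`` via the trigamma inverse, and the
    mean then identifies ``s0^2``.  Zero (or negative) excess spread
    yields ``d0 = inf`` with ``s0^2`` the geometric-mean-style estimate.

    Requires >= 10 strictly positive variances.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise ValueError(
            f"need >= 10 positive variances to fit the prior (got {s2.size}); "
            "use an ordinary t-test instead"
        )
    z = np.log(s2)
    if np.allclose(z, z[0], rtol=0.0, atol=1e-12):
        # degenerate input: no spread at all, not even sampling spread;
        # the only consistent prior pins every posterior at the common value
        return ModerationFit(d0=math.inf, s0_sq=float(s2[0]))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    excess = evar - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return ModerationFit(d0=math.inf, s0_sq=float(math.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    if d0 >= _D0_CAP:
        return ModerationFit(d0=math.inf, s0_sq=float(math.exp(emean)))
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return ModerationFit(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t(
    log2fc: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    fit: ModerationFit,
    n1: np.ndarray,
    n2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistic and two-sided p value per feature.

    ``d0 = 0`` reduces to the ordinary two-sample t; ``d0 = inf`` pins the
    posterior variance at ``s0^2`` and refers t to the normal.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if math.isinf(fit.d0):
        s2_post = np.full_like(s2, fit.s0_sq)
        dof = np.full_like(df, math.inf)
    else:
        s2_post = (fit.d0 * fit.s0_sq + df * s2) / (fit.d0 + df) if fit.d0 > 0 else s2
        dof = fit.d0 + df
    with np.errstate(all="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = log2fc / se
    p = np.where(
        np.isinf(dof),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.maximum(dof, 1e-300)),
    )
    return t, np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_events(results: pd.DataFrame, cfg: ThresholdConfig, layer: Layer) -> pd.DataFrame:
    """Apply BH within each (condition, time) family and flag significance.

    ``results`` is a long frame with at least columns feature, condition,
    time_h, log2fc, p.  Adds ``p_adj`` and ``significant`` columns;
    significant = (p_adj < alpha) and (|log2fc| > lfc_min) with the
    layer-appropriate alpha.
    """
    alpha = cfg.alpha_for(layer)
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(["condition", "time_h"]).groups.items():
        sub = out.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "p_adj"] = bh_adjust(sub.loc[ok, "p"].to_numpy())
    out["significant"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > cfg.lfc_min)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    out.attrs["bh_family"] = "per (layer, condition, timepoint)"
    out.attrs["alpha"] = alpha
    out.attrs["lfc_min"] = cfg.lfc_min
    return out


def run_differential(
    m: OmicsMatrix,
    cfg: ThresholdConfig | None = None,
    conditions: Sequence[Condition] = STIMULI,
    fit: ModerationFit | None = None,
) -> pd.DataFrame:
    """Full differential stage for one layer.

    Estimates effects for every (stimulus, timepoint) contrast, fits one
    moderation prior per layer across all contrasts, computes moderated
    t / p, BH-adjusts within (condition, time) families and flags
    significant events.  Returns a long frame with one row per testable
    feature x condition x timepoint.
    """
    cfg = cfg or ThresholdConfig()
    blocks = []
    for cond in conditions:
        for t in m.times_h:
            eff = estimate_effects(m, cond, t)
            eff = eff[eff["testable"]]
            if eff.empty:
                continue
            blocks.append(
                eff.assign(condition=cond.value, time_h=t).rename_axis("feature").reset_index()
            )
    if not blocks:
        raise ValueError("no testable contrasts")
    long = pd.concat(blocks, ignore_index=True)
    if fit is None:
        fit = fit_moderation(long["s2"].to_numpy(), long["df"].to_numpy())
    t_mod, p = moderated_t(
        long["log2fc"].to_numpy(),
        long["s2"].to_numpy(),
        long["df"].to_numpy(),
        fit,
        long["n1"].to_numpy(),
        long["n2"].to_numpy(),
    )
    long["t_mod"] = t_mod
    long["p"] = p
    long["layer"] = m.layer.value
    out = call_events(long, cfg, m.layer)
    out.attrs["moderation_d0"] = fit.d0
    out.attrs["moderation_s0_sq"] = fit.s0_sq
    return out


def fit_silac_no_intercept(ratios: pd.DataFrame) -> pd.DataFrame:
    """No-intercept linear model for log SILAC ratios against zero.

    ``ratios`` has one column per condition and one row per replicate
    observation (NaN = missing; never imputed).  The least-squares fit of
    ``ratio ~ 0 + condition`` makes each condition effect the mean of its
    observed ratios, with a pooled residual variance on ``n_obs - k``
    degrees of freedom and a t test of each effect against zero.

    Conditions with fewer than 2 observed ratios are flagged untestable.
    """
    effects, counts, rss = {}, {}, 0.0
    for cond in ratios.columns:
        x = ratios[cond].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        counts[cond] = obs.size
        effects[cond] = float(obs.mean()) if obs.size else np.nan
        if obs.size:
            rss += float(np.sum((obs - obs.mean()) ** 2))
    k = sum(1 for c in ratios.columns if counts[c] > 0)
    n_obs = sum(counts.values())
    df_res = n_obs - k
    s2 = rss / df_res if df_res > 0 else np.nan
    rows = []
    for cond in ratios.columns:
        n = counts[cond]
        testable = n >= 2 and df_res > 0
        if testable and s2 > 0:
            tstat = effects[cond] / math.sqrt(s2 / n)
            p = 2.0 * stats.t.sf(abs(tstat), df_res)
        elif testable:
            tstat, p = 0.0 if effects[cond] == 0 else math.inf * np.sign(effects[cond]), (1.0 if effects[cond] == 0 else 0.0)
        else:
            tstat, p = np.nan, np.nan
        rows.append(
            {"condition": cond, "effect": effects[cond], "n": n, "df": df_res, "t": tstat, "p": p, "testable": testable}
        )
    return pd.DataFrame(rows)
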