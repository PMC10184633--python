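"""Synthetic multi-omics stimulation time courses with known ground truth.

Emulates the structure of a cytokine-stimulation study on endothelial
cells: four arms (control, TNFa, IFNg, TNFa+IFNg) sampled over a shared
grid from 0 to 24 h in three biological replicates, with layer-typical
kinetics — fast phosphosite transients within minutes, transient
(peak 30 min - 4 h) versus sustained (rising to 24 h) transcript
responses, and lagged protein accumulation at 8-24 h.  Replicate noise is
i.i.d. Gaussian on the log scale; proteomic layers lose values with a
probability that decreases logistically with underlying intensity
(missing-not-at-random, mimicking the MS detection limit).

The combined arm adds ``synergy_multiplier x (TNF deflection + IFN
deflection)``: multiplier 1 is exactly additive, >= 2 is super-additive
(ground-truth synergy), slightly below 1 models the saturating shared
response typical of features driven to a common ceiling by both stimuli.

Everything is driven by a single seeded RNG in feature-major order, so a
given config + seed reproduces matrices bit-identically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    Condition,
    FeatureId,
    Layer,
    OmicsMatrix,
    SampleKey,
    Scale,
    write_omics_matrix,
)

__all__ = [
    "ShapeKind",
    "ShapeSpec",
    "TrueClass",
    "GroundTruth",
    "SimConfig",
    "shape_value",
    "generate_dataset",
    "write_fixture",
    "default_truth_plan",
    "LAYER_SCALES",
    "LAYER_BASELINES",
]

DEFAULT_TIMES_H = (0.0, 0.0333, 0.5, 4.0, 8.0, 12.0, 24.0)

LAYER_SCALES: dict[Layer, Scale] = {
    Layer.PHOSPHO: Scale.LOG2_SILAC_RATIO,
    Layer.TRANSCRIPT: Scale.VST,
    Layer.PROTEIN: Scale.LOG2_LFQ,
    Layer.SECRETOME: Scale.LOG2_LFQ,
}

# Typical central log-scale baselines per layer (SILAC ratios centre on 0).
LAYER_BASELINES: dict[Layer, float] = {
    Layer.PHOSPHO: 0.0,
    Layer.TRANSCRIPT: 8.0,
    Layer.PROTEIN: 22.0,
    Layer.SECRETOME: 22.0,
}

PROTEOMIC_LAYERS = (Layer.PHOSPHO, Layer.PROTEIN, Layer.SECRETOME)


class ShapeKind(str, enum.Enum):
    TRANSIENT_PEAK = "transient_peak"
    SUSTAINED_RISE = "sustained_rise"
    LAGGED_RISE = "lagged_rise"
    FAST_DECAY = "fast_decay"
    FLAT = "flat"


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric log2-deflection curve for one stimulus response.

    Functional forms (all zero at t = 0):

    * TRANSIENT_PEAK — log-normal-in-time bump
      ``A * exp(-ln(t / t_peak)^2 / (2 * width^2))``, maximal at ``t_peak_h``.
    * SUSTAINED_RISE — saturating exponential ``A * (1 - exp(-t / rate))``.
    * LAGGED_RISE — the same saturating form delayed by ``lag_h`` hours.
    * FAST_DECAY — exponential relaxation to A with a small time constant
      (A < 0 models rapid dephosphorylation).
    * FLAT — identically zero.
    """

    kind: ShapeKind
    amplitude: float = 0.0
    t_peak_h: float = 4.0
    rate: float = 6.0
    lag_h: float = 0.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind is ShapeKind.FLAT and self.amplitude != 0.0:
            raise ValueError("FLAT shapes must have amplitude 0")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def shape_value(s: ShapeSpec, t_h: float) -> float:
    """Log2 deflection from baseline of shape ``s`` at time ``t_h`` hours."""
    if t_h < 0:
        raise ValueError(f"time must be non-negative, got {t_h}")
    if s.kind is ShapeKind.FLAT or t_h == 0.0:
        return 0.0
    if s.kind is ShapeKind.TRANSIENT_PEAK:
        z = math.log(t_h / s.t_peak_h)
        return s.amplitude * math.exp(-(z * z) / (2.0 * s.width * s.width))
    if s.kind in (ShapeKind.SUSTAINED_RISE, ShapeKind.FAST_DECAY):
        return s.amplitude * (1.0 - math.exp(-t_h / s.rate))
    if s.kind is ShapeKind.LAGGED_RISE:
        t_eff = max(t_h - s.lag_h, 0.0)
        return s.amplitude * (1.0 - math.exp(-t_eff / s.rate))
    raise ValueError(f"unknown shape kind: {s.kind}")


class TrueClass(str, enum.Enum):
    TNF = "TNF"
    IFN = "IFN"
    COMMON = "COMMON"
    SYNERGY = "SYNERGY"
    NULL = "NULL"


@dataclass(frozen=True)
class GroundTruth:
    """Planned response of one feature: per-stimulus shapes and synergy.

    Combined-arm deflection = ``synergy_multiplier * (tnf + ifn)``.
    SYNERGY requires multiplier >= 2 by construction so the AUC-ratio-2
    effect rule is satisfiable; NULL features have both shapes FLAT.
    """

    feature: FeatureId
    true_class: TrueClass
    tnf_shape: ShapeSpec
    ifn_shape: ShapeSpec
    synergy_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.synergy_multiplier < 0:
            raise ValueError("synergy_multiplier must be >= 0")
        if (self.true_class is TrueClass.SYNERGY) != (self.synergy_multiplier >= 2):
            raise ValueError("true_class is SYNERGY iff synergy_multiplier >= 2")
        if self.true_class is TrueClass.NULL and not (
            self.tnf_shape.kind is ShapeKind.FLAT and self.ifn_shape.kind is ShapeKind.FLAT
        ):
            raise ValueError("NULL features must have FLAT shapes on both stimuli")


@dataclass
class SimConfig:
    """Simulation settings.

    ``missing_logistic = (midpoint, slope)`` sets the per-value missingness
    probability ``1 / (1 + exp(slope * (x - midpoint)))`` applied to
    proteomic layers only: values far above the midpoint are nearly always
    observed, values below it drop out, emulating the MS detection limit.
    The midpoint is expressed as an offset below each layer's baseline.
    """

    n_features_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c.value: 20 for c in TrueClass}
    )
    times_h: Sequence[float] = DEFAULT_TIMES_H
    n_replicates: int = 3
    noise_sd: float = 0.2
    missing_logistic: tuple[float, float] = (4.0, 1.0)  # (offset below baseline, slope)
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize class keys (YAML reads a bare NULL key as None)
        norm: dict[str, int] = {}
        for k, v in dict(self.n_features_per_class).items():
            key = "NULL" if k is None else (k.value if isinstance(k, TrueClass) else str(k))
            norm[TrueClass(key).value] = int(v)
        self.n_features_per_class = norm
        times = tuple(float(t) for t in self.times_h)
        if 0.0 not in times or 24.0 not in times:
            raise ValueError("times_h must include 0 and 24")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.times_h = times


_CLASS_MULTIPLIER = {
    TrueClass.TNF: 1.0,
    TrueClass.IFN: 1.0,
    TrueClass.COMMON: 0.8,  # mildly saturating shared response
    TrueClass.SYNERGY: 3.0,
    TrueClass.NULL: 1.0,
}


def _layer_shape(layer: Layer, amplitude: float) -> ShapeSpec:
    """A layer-typical response shape with the study's stated timing."""
    if layer is Layer.PHOSPHO:
        # rapid (de)phosphorylation within minutes
        return ShapeSpec(ShapeKind.FAST_DECAY, amplitude=amplitude, rate=0.01)
    if layer is Layer.TRANSCRIPT:
        return ShapeSpec(ShapeKind.SUSTAINED_RISE, amplitude=amplitude, rate=6.0)
    # protein / secretome: lagged accumulation over 8-24 h
    return ShapeSpec(ShapeKind.LAGGED_RISE, amplitude=amplitude, rate=6.0, lag_h=6.0)


def default_truth_plan(
    cfg: SimConfig,
    layer: Layer,
    amplitude: float = 2.5,
    rng: np.random.Generator | None = None,
) -> list[GroundTruth]:
    """Build a balanced ground-truth plan for one layer.

    Each class receives ``cfg.n_features_per_class[class]`` features with
    layer-typical kinetics; amplitudes alternate in sign occasionally for
    the phospho layer (dephosphorylation) and are positive elsewhere,
    matching the predominantly upregulated responses the stimuli induce.
    """
    rng = rng or np.random.default_rng(cfg.seed + 17)
    plan: list[GroundTruth] = []
    flat = ShapeSpec(ShapeKind.FLAT)
    for cls_name, n in cfg.n_features_per_class.items():
        cls = TrueClass(cls_name)
        for i in range(n):
            amp = amplitude * float(rng.uniform(1.0, 1.4))
            if layer is Layer.PHOSPHO and i % 2:
                amp = -amp
            gene = f"{layer.value.upper()[:4]}{cls.value}{i:04d}"
            site = f"S{100 + i}" if layer is Layer.PHOSPHO else None
            fid = FeatureId(layer=layer, gene=gene, site=site)
            tnf = _layer_shape(layer, amp) if cls in (TrueClass.TNF, TrueClass.COMMON, TrueClass.SYNERGY) else flat
            ifn = _layer_shape(layer, amp) if cls in (TrueClass.IFN, TrueClass.COMMON, TrueClass.SYNERGY) else flat
            plan.append(
                GroundTruth(
                    feature=fid,
                    true_class=cls,
                    tnf_shape=tnf,
                    ifn_shape=ifn,
                    synergy_multiplier=_CLASS_MULTIPLIER[cls],
                )
            )
    return plan


def _sample_grid(cfg: SimConfig) -> list[SampleKey]:
    keys = []
    for cond in Condition:
        for t in cfg.times_h:
            for r in range(1, cfg.n_replicates + 1):
                keys.append(SampleKey(condition=cond, time_h=t, replicate=r))
    return keys


def generate_dataset(
    cfg: SimConfig,
    truth_plan: Sequence[GroundTruth],
) -> tuple[dict[Layer, OmicsMatrix], pd.DataFrame]:
    """Generate per-layer matrices plus a ground-truth table.

    Control = baseline + noise; single-stimulus arms add the respective
    shape deflection; the combined arm adds ``multiplier * (tnf + ifn)``.
    A single RNG stream seeded from ``cfg.seed`` drives noise then
    missingness in feature-major order, so identical config + seed give
    bit-identical output.
    """
    if not truth_plan:
        raise ValueError("truth_plan must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_grid(cfg)
    sample_cols = [str(s) for s in samples]
    midpoint_offset, slope = cfg.missing_logistic

    by_layer: dict[Layer, list[GroundTruth]] = {}
    for gt in truth_plan:
        by_layer.setdefault(gt.feature.layer, []).append(gt)

    matrices: dict[Layer, OmicsMatrix] = {}
    truth_rows = []
    for layer in sorted(by_layer, key=lambda l: l.value):
        plan = by_layer[layer]
        baseline_mu = LAYER_BASELINES[layer]
        rows = np.empty((len(plan), len(samples)))
        for i, gt in enumerate(plan):
            base = baseline_mu + (rng.normal(0.0, 1.0) if layer is not Layer.PHOSPHO else 0.0)
            signal = np.empty(len(samples))
            for j, s in enumerate(samples):
                if s.condition is Condition.CTRL:
                    defl = 0.0
                elif s.condition is Condition.TNF:
                    defl = shape_value(gt.tnf_shape, s.time_h)
                elif s.condition is Condition.IFN:
                    defl = shape_value(gt.ifn_shape, s.time_h)
                else:
                    defl = gt.synergy_multiplier * (
                        shape_value(gt.tnf_shape, s.time_h) + shape_value(gt.ifn_shape, s.time_h)
                    )
                signal[j] = base + defl
            noisy = signal + rng.normal(0.0, cfg.noise_sd, size=len(samples))
            if layer in PROTEOMIC_LAYERS and layer is not Layer.PHOSPHO:
                p_missing = 1.0 / (1.0 + np.exp(slope * (noisy - (baseline_mu - midpoint_offset))))
                drop = rng.uniform(size=len(samples)) < p_missing
                noisy = np.where(drop, np.nan, noisy)
            rows[i] = noisy
            truth_rows.append(
                {
                    "feature": str(gt.feature),
                    "layer": layer.value,
                    "true_class": gt.true_class.value,
                    "synergy_multiplier": gt.synergy_multiplier,
                    "tnf_amplitude": gt.tnf_shape.amplitude,
                    "ifn_amplitude": gt.ifn_shape.amplitude,
                }
            )
        df = pd.DataFrame(rows, index=[str(gt.feature) for gt in plan], columns=sample_cols)
        matrices[layer] = OmicsMatrix(layer=layer, scale=LAYER_SCALES[layer], data=df)
    truth = pd.DataFrame(truth_rows)
    return matrices, truth


def write_fixture(
    dataset: tuple[dict[Layer, OmicsMatrix], pd.DataFrame],
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write per-layer matrix TSVs plus the ground-truth table.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Matrix files round-trip through
    ``core_model.read_omics_matrix``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    matrices, truth = dataset
    paths: dict[str, Path] = {}
    for layer, m in matrices.items():
        p = out_dir / f"{layer.value}.tsv"
        write_omics_matrix(m, p)
        paths[layer.value] = p
    tp = out_dir / "ground_truth.tsv"
    truth.to_csv(tp, sep="\t", index=False)
    paths["ground_truth"] = tp
    return paths
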