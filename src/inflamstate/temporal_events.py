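"""When do significant events occur per omics layer and stimulus?

An *event* for a feature is its first attainment of significance over the
time grid (onset); cumulative curves count features whose onset falls at
or before each grid time, reproducing the layered temporal paradigm of
endothelial activation (phospho-signaling within minutes, transcription
at hours, protein accumulation towards 24 h).  A per-timepoint counting
mode (events recounted at every significant time) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import Condition, Layer

__all__ = ["EventCurve", "first_onset", "cumulative_event_curve", "onset_ordering", "plot_event_curves"]


@dataclass
class EventCurve:
    """Cumulative significant-event counts for one layer and condition."""

    layer: Layer
    condition: Condition
    times_h: np.ndarray
    cumulative_count: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.cumulative_count = np.asarray(self.cumulative_count, dtype=int)
        if np.any(np.diff(self.cumulative_count) < 0):
            raise ValueError("cumulative_count must be non-decreasing")


def first_onset(results: pd.DataFrame, feature: str, condition: Condition | str | None = None) -> float | None:
    """Earliest time at which the feature is significant, or None if never.

    ``results`` is a long differential frame with columns feature,
    condition, time_h, significant.  Restrict to one condition if given.
    """
    sub = results[results["feature"] == feature]
    if condition is not None:
        cond = condition.value if isinstance(condition, Condition) else condition
        sub = sub[sub["condition"] == cond]
    hit = sub[sub["significant"]]
    if hit.empty:
        return None
    return float(hit["time_h"].min())


def _onsets(results: pd.DataFrame, layer: Layer, condition: Condition) -> pd.Series:
    sub = results[(results["layer"] == layer.value) & (results["condition"] == condition.value)]
    sig = sub[sub["significant"]]
    return sig.groupby("feature")["time_h"].min()


def cumulative_event_curve(
    results: pd.DataFrame,
    layer: Layer,
    condition: Condition,
    mode: str = "onset",
) -> EventCurve:
    """Event counts over the grid.

    ``mode="onset"`` (default): at each grid time, the number of features
    whose first significant time is <= that time (monotone by
    construction; final value = number of ever-significant features).
    ``mode="per_timepoint"``: the running maximum of the raw per-time
    significant-call counts, keeping the EventCurve monotone; use
    :func:`per_timepoint_counts` for the raw non-cumulative view.
    """
    if mode not in ("onset", "per_timepoint"):
        raise ValueError(f"unknown mode: {mode!r}")
    sub = results[(results["layer"] == layer.value) & (results["condition"] == condition.value)]
    times = np.sort(sub["time_h"].unique())
    if mode == "per_timepoint":
        counts = np.array(
            [int(sub[(sub["time_h"] == t) & sub["significant"]].shape[0]) for t in times]
        )
        cum = np.maximum.accumulate(counts)
        return EventCurve(layer=layer, condition=condition, times_h=times, cumulative_count=cum)
    onsets = _onsets(results, layer, condition)
    counts = np.array([int((onsets <= t).sum()) for t in times])
    return EventCurve(layer=layer, condition=condition, times_h=times, cumulative_count=counts)


def per_timepoint_counts(results: pd.DataFrame, layer: Layer, condition: Condition) -> pd.Series:
    """Number of significant calls at each timepoint (not de-duplicated)."""
    sub = results[(results["layer"] == layer.value) & (results["condition"] == condition.value)]
    sig = sub[sub["significant"]]
    return sig.groupby("time_h").size().reindex(np.sort(sub["time_h"].unique()), fill_value=0)


def onset_ordering(results: pd.DataFrame, condition: Condition) -> list[tuple[Layer, float]]:
    """Layers ranked by median first-onset time under one stimulus.

    Ties are broken by mean onset, then layer name.  Layers with zero
    events are excluded (with a warning via the returned list simply not
    containing them).
    """
    import warnings

    entries = []
    for layer_val in sorted(results["layer"].unique()):
        layer = Layer(layer_val)
        onsets = _onsets(results, layer, condition)
        if onsets.empty:
            warnings.warn(f"layer {layer.value} has no significant events; excluded from ranking")
            continue
        entries.append((layer, float(onsets.median()), float(onsets.mean())))
    entries.sort(key=lambda e: (e[1], e[2], e[0].value))
    return [(layer, med) for layer, med, _ in entries]


def plot_event_curves(curves: list[EventCurve], ax=None):
    """Simple area/line chart of cumulative event curves (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.fill_between(c.times_h, c.cumulative_count, alpha=0.3)
        ax.plot(c.times_h, c.cumulative_count, label=f"{c.layer.value} / {c.condition.value}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative significant features")
    ax.legend()
    return ax
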