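"""Shared domain types for cytokine time-course omics data, plus TSV readers/writers.

The pipeline operates on feature x sample matrices on an analysis scale
(log2 LFQ intensity, log2 SILAC ratio, or variance-stabilized transcript
level).  Samples span a factorial design of stimulation condition
(control, TNFa, IFNg, TNFa+IFNg), time after stimulation (hours) and
biological replicate.  Sample columns are encoded in headers as
``CONDITION_T<hours>h_R<rep>``, e.g. ``TNF_IFN_T0.5h_R2``; hours may be
fractional (2 min = 0.0333 h).  Missing values are written as ``NA``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "Scale",
    "Condition",
    "FeatureId",
    "SampleKey",
    "OmicsMatrix",
    "TimeCourse",
    "ThresholdConfig",
    "read_omics_matrix",
    "write_omics_matrix",
    "extract_timecourse",
    "read_edge_table",
    "read_keyword_table",
    "read_gene_list",
]


class Layer(str, enum.Enum):
    """Omics layer a feature belongs to."""

    PHOSPHO = "phospho"
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"
    SECRETOME = "secretome"


class Scale(str, enum.Enum):
    """Analysis scale of matrix values."""

    LOG2_LFQ = "log2_lfq"
    LOG2_SILAC_RATIO = "log2_silac_ratio"
    VST = "vst"


class Condition(str, enum.Enum):
    """Stimulation arm."""

    CTRL = "CTRL"
    TNF = "TNF"
    IFN = "IFN"
    TNF_IFN = "TNF_IFN"


STIMULI = (Condition.TNF, Condition.IFN, Condition.TNF_IFN)


@dataclass(frozen=True, order=True)
class FeatureId:
    """A measured feature: a gene symbol, optionally a phosphosite on it.

    ``site`` is present iff ``layer`` is phospho (site key e.g. ``S379``).
    String form is ``GENE`` or ``GENE|SITE``.
    """

    layer: Layer
    gene: str
    site: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("FeatureId.gene must be non-empty")
        if (self.layer is Layer.PHOSPHO) != (self.site is not None):
            raise ValueError(
                f"site must be present iff layer is phospho "
                f"(got layer={self.layer.value!r}, site={self.site!r})"
            )
        object.__setattr__(self, "gene", self.gene.upper())

    def __str__(self) -> str:
        return self.gene if self.site is None else f"{self.gene}|{self.site}"

    @classmethod
    def parse(cls, label: str, layer: Layer) -> "FeatureId":
        """Parse ``GENE`` or ``GENE|SITE`` (phospho only) into a FeatureId."""
        if "|" in label:
            gene, site = label.split("|", 1)
            return cls(layer=layer, gene=gene, site=site)
        return cls(layer=layer, gene=label, site=None)


@dataclass(frozen=True, order=True)
class SampleKey:
    """One sample: condition, time in hours, replicate number (1-based)."""

    condition: Condition
    time_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be non-negative, got {self.time_h}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    def __str__(self) -> str:
        return f"{self.condition.value}_T{self.time_h:g}h_R{self.replicate}"


_SAMPLE_RE = re.compile(r"^(?P<cond>[A-Z_]+)_T(?P<time>[0-9.]+)h_R(?P<rep>[0-9]+)$")


def parse_sample_key(token: str) -> SampleKey:
    """Parse a ``CONDITION_T<hours>h_R<rep>`` header token."""
    m = _SAMPLE_RE.match(token)
    if m is None:
        raise ValueError(f"malformed sample header token: {token!r}")
    cond = m.group("cond")
    try:
        condition = Condition(cond)
    except ValueError:
        raise ValueError(
            f"malformed sample header token: {token!r} (unknown condition {cond!r})"
        ) from None
    return SampleKey(condition=condition, time_h=float(m.group("time")), replicate=int(m.group("rep")))


@dataclass
class OmicsMatrix:
    """One omics layer's feature x sample value table.

    ``data`` is a pandas DataFrame indexed by feature string labels with
    sample-token columns; entries may be NaN (missing at the value level).
    The sample grid must be complete: every (condition, time) pair present
    for the full replicate set.
    """

    layer: Layer
    scale: Scale
    data: pd.DataFrame
    features: list[FeatureId] = field(default_factory=list)
    samples: list[SampleKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features:
            self.features = [FeatureId.parse(str(ix), self.layer) for ix in self.data.index]
        if not self.samples:
            self.samples = [parse_sample_key(str(c)) for c in self.data.columns]
        if len(self.features) != self.data.shape[0] or len(self.samples) != self.data.shape[1]:
            raise ValueError("feature/sample lists do not match data dimensions")
        labels = [str(f) for f in self.features]
        dup = pd.Index(labels)[pd.Index(labels).duplicated()]
        if len(dup):
            raise ValueError(f"duplicate feature id: {dup[0]!r}")
        self._validate_grid()

    def _validate_grid(self) -> None:
        reps_per_ct: dict[tuple[Condition, float], set[int]] = {}
        for s in self.samples:
            reps_per_ct.setdefault((s.condition, s.time_h), set()).add(s.replicate)
        rep_sets = set(frozenset(v) for v in reps_per_ct.values())
        if len(rep_sets) > 1:
            raise ValueError(
                "inconsistent replicate grid: replicate sets differ across "
                "(condition, time) pairs"
            )

    @property
    def conditions(self) -> list[Condition]:
        return sorted({s.condition for s in self.samples}, key=lambda c: c.value)

    @property
    def times_h(self) -> np.ndarray:
        return np.array(sorted({s.time_h for s in self.samples}))

    @property
    def n_replicates(self) -> int:
        return len({s.replicate for s in self.samples})

    def columns_for(self, condition: Condition, time_h: float | None = None) -> list[str]:
        out = []
        for s, col in zip(self.samples, self.data.columns):
            if s.condition is condition and (time_h is None or s.time_h == time_h):
                out.append(col)
        return out

    def feature_labels(self) -> list[str]:
        return [str(f) for f in self.features]


@dataclass
class TimeCourse:
    """One feature under one condition: replicate values over ordered times.

    ``medians`` summarizes replicates per time ignoring missing entries;
    a time with all replicates missing has a NaN median.
    """

    feature: FeatureId
    condition: Condition
    times_h: np.ndarray
    replicate_values: np.ndarray  # (replicates, times), NaN = missing
    medians: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.replicate_values = np.asarray(self.replicate_values, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if self.replicate_values.shape[1] != self.times_h.size:
            raise ValueError("replicate_values column count must match times_h")
        if self.medians is None:
            with np.errstate(all="ignore"):
                self.medians = _nanmedian_allow_empty(self.replicate_values)
        else:
            self.medians = np.asarray(self.medians, dtype=float)
            if self.medians.size != self.times_h.size:
                raise ValueError("medians length must match times_h")


def _nanmedian_allow_empty(a: np.ndarray) -> np.ndarray:
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        col = a[:, j]
        obs = col[~np.isnan(col)]
        if obs.size:
            out[j] = np.median(obs)
    return out


@dataclass
class ThresholdConfig:
    """All numeric decision thresholds used across the pipeline.

    Defaults follow the study conventions: BH-adjusted p < 0.05 with
    |log2FC| > 1 (secretome p < 0.01); shape correlation cuts 0.7/0.3;
    AUC-ratio cut 2; interaction-edge score > 0.95 (receptor-ligand edges
    > 0.4); downshifted-normal imputation width 0.3, shift 1.8.
    """

    alpha: float = 0.05
    alpha_secretome: float = 0.01
    lfc_min: float = 1.0
    r_high: float = 0.7
    r_low: float = 0.3
    auc_ratio: float = 2.0
    edge_score_min: float = 0.95
    ligand_score_min: float = 0.4
    impute_width: float = 0.3
    impute_shift: float = 1.8

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_secretome"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if not self.r_low < self.r_high:
            raise ValueError("require r_low < r_high")
        if self.auc_ratio <= 1:
            raise ValueError("auc_ratio must exceed 1")
        if not 0 <= self.edge_score_min <= 1:
            raise ValueError("edge_score_min must lie in [0,1]")

    def alpha_for(self, layer: Layer) -> float:
        return self.alpha_secretome if layer is Layer.SECRETOME else self.alpha


# ---------------------------------------------------------------------------
# I/O


def read_omics_matrix(path: str | Path, layer: Layer, scale: Scale) -> OmicsMatrix:
    """Read a delimited feature x sample matrix.

    First column holds feature ids (``GENE`` or ``GENE|SITE``); remaining
    headers are ``CONDITION_T<hours>h_R<rep>`` tokens.  Empty cells and
    ``NA`` are missing.  Tab and comma delimiters are auto-detected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=["NA", ""], keep_default_na=False,
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id: {dup[0]!r}")
    samples = [parse_sample_key(str(c)) for c in df.columns]
    features = [FeatureId.parse(str(ix), layer) for ix in df.index]
    df.index = [str(f) for f in features]  # upper-cased gene symbols
    return OmicsMatrix(layer=layer, scale=scale, data=df.astype(float), features=features, samples=samples)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write the matrix in the TSV dialect `read_omics_matrix` accepts.

    Values are written with full float precision so a write/read round trip
    is bit-identical on present entries and preserves the missingness mask.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    m.data.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g", index_label="feature")


def extract_timecourse(m: OmicsMatrix, feature: FeatureId | str, condition: Condition) -> TimeCourse:
    """Pull one feature/condition out of the matrix as a replicate time course."""
    label = str(feature)
    if label not in m.data.index:
        raise KeyError(f"unknown feature: {label!r}")
    fid = feature if isinstance(feature, FeatureId) else FeatureId.parse(label, m.layer)
    times = m.times_h
    reps = sorted({s.replicate for s in m.samples})
    values = np.full((len(reps), times.size), np.nan)
    row = m.data.loc[label]
    for s, col in zip(m.samples, m.data.columns):
        if s.condition is condition:
            i = reps.index(s.replicate)
            j = int(np.searchsorted(times, s.time_h))
            values[i, j] = row[col]
    return TimeCourse(feature=fid, condition=condition, times_h=times, replicate_values=values)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a (node_a, node_b, combined_score) interaction-edge TSV."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["node_a", "node_b", "combined_score"]
    df["combined_score"] = df["combined_score"].astype(float)
    bad = df[(df.combined_score < 0) | (df.combined_score > 1)]
    if len(bad):
        raise ValueError(f"combined_score outside [0,1] at row {bad.index[0]}")
    return df


def read_keyword_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column (gene, keyword) annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene", "keyword"]
    df["gene"] = df["gene"].str.upper()
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-column gene list (e.g. a cytokine-registry membership file)."""
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]
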