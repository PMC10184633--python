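"""End-to-end pipeline: simulate -> preprocess -> differential -> classify
-> events (-> network), with a YAML config, a run manifest and
deterministic seeding.

Re-running with an identical config and seed reproduces every output file
byte-identically; the manifest records the config hash, seed, per-stage
row counts and the SHA-256 of each output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .core_model import (
    Condition,
    Layer,
    OmicsMatrix,
    ThresholdConfig,
    read_edge_table,
    read_gene_list,
    read_omics_matrix,
)
from .differential import run_differential
from .network_summary import collapse_features_to_genes, filter_edges, hub_composition
from .preprocess import impute_downshifted_normal
from .response_classification import classify_dataset
from .synthetic_data import (
    LAYER_SCALES,
    SimConfig,
    default_truth_plan,
    generate_dataset,
    write_fixture,
)
from .temporal_events import cumulative_event_curve, onset_ordering

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

LFQ_LAYERS = (Layer.PROTEIN, Layer.SECRETOME)


@dataclass
class PipelineConfig:
    """Everything one run needs: input paths or simulation settings,
    thresholds, deviation flags and the seed."""

    seed: int = 0
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    sim: SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # layer -> matrix path
    edges_path: str | None = None
    hubs_path: str | None = None
    registry_path: str | None = None
    baseline: str = "ctrl_course"
    synergy_rule: str = "s4_or_e3"
    impute: bool = True

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        thr = ThresholdConfig(**d.get("thresholds", {}))
        sim_d = d.get("simulate")
        sim = None
        if sim_d is not None:
            sim = SimConfig(**{**sim_d, "seed": sim_d.get("seed", d.get("seed", 0))})
        return cls(
            seed=int(d.get("seed", 0)),
            thresholds=thr,
            sim=sim,
            inputs=dict(d.get("inputs", {})),
            edges_path=d.get("edges"),
            hubs_path=d.get("hubs"),
            registry_path=d.get("registry"),
            baseline=d.get("baseline", "ctrl_course"),
            synergy_rule=d.get("synergy_rule", "s4_or_e3"),
            impute=bool(d.get("impute", True)),
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    blob = json.dumps(asdict(cfg), default=enc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every configured stage, writing stage TSVs and a manifest.

    Returns the manifest dict.  Any stage error propagates with its stage
    name; files already written keep a ``.partial`` marker next to them in
    that case.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
        "outputs": {},
    }
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    try:
        matrices = _stage_inputs(cfg, out, manifest)
        diff_all = _stage_differential(cfg, out, manifest, matrices)
        _stage_classify(cfg, out, manifest, matrices, diff_all)
        _stage_events(cfg, out, manifest, diff_all)
        _stage_network(cfg, out, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    marker.unlink()
    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_inputs(cfg: PipelineConfig, out: Path, manifest: dict) -> dict[Layer, OmicsMatrix]:
    if cfg.sim is not None:
        plan = []
        for layer in (Layer.PHOSPHO, Layer.TRANSCRIPT, Layer.PROTEIN):
            plan.extend(default_truth_plan(cfg.sim, layer))
        matrices, truth = generate_dataset(cfg.sim, plan)
        write_fixture((matrices, truth), out / "data", overwrite=True)
        manifest["stages"]["simulate"] = {
            "n_features": int(sum(m.data.shape[0] for m in matrices.values())),
            "layers": sorted(l.value for l in matrices),
        }
        return matrices
    if not cfg.inputs:
        raise ValueError("config provides neither simulation settings nor input paths")
    matrices = {}
    for layer_name, path in cfg.inputs.items():
        layer = Layer(layer_name)
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
        matrices[layer] = read_omics_matrix(p, layer, LAYER_SCALES[layer])
    manifest["stages"]["load"] = {"layers": sorted(l.value for l in matrices)}
    return matrices


def _stage_differential(
    cfg: PipelineConfig, out: Path, manifest: dict, matrices: dict[Layer, OmicsMatrix]
) -> pd.DataFrame:
    frames = []
    for layer, m in sorted(matrices.items(), key=lambda kv: kv[0].value):
        if cfg.impute and layer in LFQ_LAYERS and m.data.isna().any().any():
            m = impute_downshifted_normal(
                m, cfg.thresholds.impute_width, cfg.thresholds.impute_shift, seed=cfg.seed + 1
            )
        res = run_differential(m, cfg.thresholds)
        res.to_csv(out / f"differential_{layer.value}.tsv", sep="\t", index=False)
        frames.append(res)
    diff_all = pd.concat(frames, ignore_index=True)
    manifest["stages"]["differential"] = {
        "rows": int(len(diff_all)),
        "significant": int(diff_all["significant"].sum()),
    }
    return diff_all


def _stage_classify(
    cfg: PipelineConfig,
    out: Path,
    manifest: dict,
    matrices: dict[Layer, OmicsMatrix],
    diff_all: pd.DataFrame,
) -> None:
    frames = []
    for layer, m in sorted(matrices.items(), key=lambda kv: kv[0].value):
        sub = diff_all[
            (diff_all["layer"] == layer.value)
            & (diff_all["condition"] == Condition.TNF_IFN.value)
            & diff_all["significant"]
        ]
        feats = sorted(sub["feature"].unique())
        if not feats:
            continue
        cl = classify_dataset(m, feats, cfg.thresholds, cfg.baseline, cfg.synergy_rule)
        cl["layer"] = layer.value
        cl.to_csv(out / f"classes_{layer.value}.tsv", sep="\t", index=False)
        frames.append(cl)
    n = int(sum(len(f) for f in frames))
    counts = (
        pd.concat(frames)["final"].value_counts().to_dict() if frames else {}
    )
    manifest["stages"]["classify"] = {"rows": n, "class_counts": {k: int(v) for k, v in counts.items()}}


def _stage_events(cfg: PipelineConfig, out: Path, manifest: dict, diff_all: pd.DataFrame) -> None:
    rows = []
    for layer_val in sorted(diff_all["layer"].unique()):
        for cond in (Condition.TNF, Condition.IFN, Condition.TNF_IFN):
            curve = cumulative_event_curve(diff_all, Layer(layer_val), cond)
            for t, c in zip(curve.times_h, curve.cumulative_count):
                rows.append(
                    {"layer": layer_val, "condition": cond.value, "time_h": t, "cumulative_count": int(c)}
                )
    curves = pd.DataFrame(rows)
    curves.to_csv(out / "event_curves.tsv", sep="\t", index=False)
    ordering = onset_ordering(diff_all, Condition.TNF_IFN)
    manifest["stages"]["events"] = {
        "rows": int(len(curves)),
        "onset_ordering": [{"layer": l.value, "median_onset_h": m} for l, m in ordering],
    }


def _stage_network(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    if cfg.edges_path is None:
        return
    edges = filter_edges(read_edge_table(cfg.edges_path), cfg.thresholds.edge_score_min)
    edges.to_csv(out / "edges_filtered.tsv", sep="\t", index=False)
    stage: dict[str, Any] = {"edges_kept": int(len(edges))}
    if cfg.hubs_path is not None:
        hubs_df = pd.read_csv(cfg.hubs_path, sep="\t")
        hubs = dict(zip(hubs_df.iloc[:, 0].str.upper(), hubs_df.iloc[:, 1]))
        classes = []
        for p in sorted(out.glob("classes_*.tsv")):
            classes.append(pd.read_csv(p, sep="\t"))
        if classes:
            gene_classes = collapse_features_to_genes(pd.concat(classes, ignore_index=True))
            comp = hub_composition(gene_classes, hubs)
            comp.to_csv(out / "hub_composition.tsv", sep="\t", index=False)
            stage["hubs"] = int(len(comp))
    manifest["stages"]["network"] = stage
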