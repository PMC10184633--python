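"""Interaction-network composition summaries over classified features.

Consumes a locally supplied scored interaction-edge table (STRING-style
combined scores in [0,1]) together with the response-classification
table: filters edges at a confidence cutoff, collapses feature-level
classes to gene level, summarizes the class composition of user-supplied
interaction hubs (donut-plot fractions), applies the annotation-based
receptor/ligand definition rules, and overlays a cytokine-registry gene
list on secretome differential results.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import Layer, ThresholdConfig

__all__ = [
    "filter_edges",
    "edge_graph",
    "collapse_features_to_genes",
    "hub_composition",
    "classify_receptors_ligands",
    "cytokine_overlay",
]

RESPONSE_CLASSES = ("TNF", "IFN", "SYNERGY", "COMMON", "NOT_CLASSIFIED")

# Gene-level primary class when layers disagree.
LAYER_PRIORITY = (Layer.TRANSCRIPT.value, Layer.PROTEIN.value, Layer.PHOSPHO.value, Layer.SECRETOME.value)

RECEPTOR_KEYWORDS = {"extracellular", "gpi-anchor"}
LIGAND_KEYWORDS = {"secreted", "signal", "extracellular space", "extracellular region"}


def filter_edges(edges: pd.DataFrame, min_score: float = 0.95) -> pd.DataFrame:
    """Keep edges with combined_score strictly above ``min_score``.

    Symmetric duplicates (A-B / B-A) are collapsed keeping the maximum
    score; self-edges are dropped.  Scores must lie in [0,1].
    """
    if len(edges) and ((edges["combined_score"] < 0) | (edges["combined_score"] > 1)).any():
        raise ValueError("combined_score outside [0,1]")
    e = edges[edges["combined_score"] > min_score].copy()
    e = e[e["node_a"] != e["node_b"]]
    if e.empty:
        return e.reset_index(drop=True)
    key = e.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
    e = e.assign(_key=key).sort_values("combined_score", ascending=False)
    e = e.drop_duplicates("_key", keep="first").drop(columns="_key")
    return e.sort_index().reset_index(drop=True)


def edge_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected graph view of an edge table (for component counts etc.)."""
    g = nx.Graph()
    for r in edges.itertuples(index=False):
        g.add_edge(r.node_a, r.node_b, weight=r.combined_score)
    return g


def _gene_of(feature: str) -> str:
    return feature.split("|", 1)[0]


def collapse_features_to_genes(classes: pd.DataFrame) -> pd.DataFrame:
    """Collapse feature-level response classes to one row per gene.

    ``classes`` needs columns feature, layer (or a ``layer`` attr) and
    final.  Per-layer classes are retained as separate ``class_<layer>``
    columns; the ``primary`` class follows the fixed layer priority
    transcript > protein > phospho > secretome.  Within one layer,
    multiple features of a gene (e.g. phosphosites) contribute their most
    frequent class (ties: first alphabetically).
    """
    df = classes.copy()
    if "layer" not in df.columns:
        df["layer"] = df.attrs.get("layer", "unknown")
    df["gene"] = df["feature"].map(_gene_of)
    rows = {}
    for (gene, layer), sub in df.groupby(["gene", "layer"]):
        counts = sub["final"].value_counts()
        top = counts[counts == counts.max()].index.min()
        rows.setdefault(gene, {})[f"class_{layer}"] = top
    out = []
    for gene, cols in rows.items():
        primary = None
        for layer in LAYER_PRIORITY:
            if f"class_{layer}" in cols:
                primary = cols[f"class_{layer}"]
                break
        if primary is None:
            primary = next(iter(cols.values()))
        out.append({"gene": gene, "primary": primary, **cols})
    return pd.DataFrame(out).sort_values("gene").reset_index(drop=True)


def hub_composition(gene_classes: pd.DataFrame, hubs: Mapping[str, str]) -> pd.DataFrame:
    """Per-hub fraction of each response class (fractions sum to 1).

    ``hubs`` maps gene -> hub label (unassigned genes allowed and
    ignored).  Hubs whose genes carry no class are skipped with a warning.
    """
    cls = gene_classes.set_index("gene")["primary"]
    rows = []
    hub_genes: dict[str, list[str]] = {}
    for gene, hub in hubs.items():
        if not hub:
            raise ValueError(f"empty hub label for gene {gene!r}")
        hub_genes.setdefault(hub, []).append(gene)
    for hub, genes in sorted(hub_genes.items()):
        present = [g for g in genes if g in cls.index]
        if not present:
            warnings.warn(f"hub {hub!r} has no classified genes; skipped")
            continue
        counts = cls.loc[present].value_counts()
        n = counts.sum()
        row = {"hub": hub, "n_genes": int(n)}
        for c in RESPONSE_CLASSES:
            row[c] = float(counts.get(c, 0)) / n
        rows.append(row)
    return pd.DataFrame(rows)


def classify_receptors_ligands(
    keywords: pd.DataFrame,
    edges: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Receptor/ligand flags per gene from annotation keywords and edges.

    A gene is a *receptor* when annotated with the "extracellular" keyword
    or a "GPI-anchor" topology domain.  A gene is a *ligand* when it (a)
    interacts with a receptor at combined score > ligand_score_min
    (default 0.4) and (b) carries a "secreted"/"signal" keyword or the
    "extracellular space"/"extracellular region" terms.  Both flags may
    co-occur.
    """
    cfg = cfg or ThresholdConfig()
    kw = keywords.copy()
    kw["keyword"] = kw["keyword"].str.lower()
    by_gene = kw.groupby("gene")["keyword"].apply(set)
    genes = sorted(by_gene.index)
    receptor = {g: bool(by_gene[g] & RECEPTOR_KEYWORDS) for g in genes}
    partners: dict[str, float] = {}
    for r in edges.itertuples(index=False):
        if r.combined_score > cfg.ligand_score_min:
            for g, other in ((r.node_a, r.node_b), (r.node_b, r.node_a)):
                if receptor.get(other, False):
                    partners[g] = max(partners.get(g, 0.0), float(r.combined_score))
    rows = []
    for g in genes:
        is_rec = receptor[g]
        is_lig = (g in partners) and bool(by_gene[g] & LIGAND_KEYWORDS)
        flag = "both" if is_rec and is_lig else "receptor" if is_rec else "ligand" if is_lig else "neither"
        rows.append({"gene": g, "receptor": is_rec, "ligand": is_lig, "flag": flag})
    return pd.DataFrame(rows)


def cytokine_overlay(
    secretome_results: pd.DataFrame,
    registry: Iterable[str],
    time_h: float = 24.0,
) -> pd.DataFrame:
    """Restrict secretome differential results to cytokine-registry genes.

    Per registry gene detected in the secretome: the set of stimuli with a
    significant induction at ``time_h`` (default 24 h), and a
    ``constitutive`` flag when the gene is detected but never significant
    under any stimulus/time.
    """
    reg = {g.upper() for g in registry}
    df = secretome_results.copy()
    df["gene"] = df["feature"].map(_gene_of).str.upper()
    df = df[df["gene"].isin(reg)]
    if df.empty:
        warnings.warn("no registry genes detected in the secretome")
        return pd.DataFrame(columns=["gene", "stimuli", "constitutive"])
    rows = []
    for gene, sub in df.groupby("gene"):
        at_t = sub[(sub["time_h"] == time_h) & sub["significant"]]
        stimuli = sorted(at_t["condition"].unique())
        constitutive = not bool(sub["significant"].any())
        rows.append({"gene": gene, "stimuli": stimuli, "constitutive": constitutive})
    return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
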