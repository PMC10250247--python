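"""Ligand-target GRN inference from user-selected target genes.

Starting from the targets, the prior-knowledge database is traversed
backwards: transcription factors regulating the targets, receptors
signaling to those TFs, and finally ligands binding those receptors.
The result is a four-layer directed graph G = <V, E> with
V = V_L | V_R | V_TF | V_T and E = E_LR | E_RTF | E_TFT; edges only
connect adjacent layers.  Inference uses prior knowledge only — no
expression data enters at this stage.

Node identity is the pair ``(gene, role)`` with role in {L, R, TF, T},
so a gene recruited in two roles (say as both TF and target) appears as
two distinct nodes and layer semantics stay clean.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .db import LAYER_ROLES, LAYERS, SignalingDB
from .errors import EmptyNetworkError, ValidationError

logger = logging.getLogger(__name__)

ROLES = ("L", "R", "TF", "T")

Node = tuple[str, str]  # (gene symbol, role)


@dataclass
class LigandTargetGRN:
    """Four-layer directed graph linking ligands to target genes.

    ``graph`` holds ``(gene, role)`` nodes and edges annotated with a
    ``layer`` attribute; ``provenance`` maps each edge to the union of
    source labels of the database interactions supporting it.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    provenance: dict[tuple[Node, Node], frozenset[str]] = field(default_factory=dict)

    def layer_nodes(self, role: str) -> list[str]:
        """Lexicographically ordered genes holding ``role``."""
        if role not in ROLES:
            raise ValidationError(f"unknown role token {role!r}")
        return sorted(g for g, r in self.graph.nodes if r == role)

    def layer_edges(self, layer: str) -> set[tuple[Node, Node]]:
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer token {layer!r}")
        return {(u, v) for u, v, d in self.graph.edges(data=True)
                if d["layer"] == layer}

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


def infer_ltgrn(targets: Iterable[str], db: SignalingDB) -> LigandTargetGRN:
    """Infer the ligand-target GRN for ``targets`` by backward traversal.

    Targets with no upstream TF in the database are dropped with a
    warning; if none survives an :class:`EmptyNetworkError` is raised
    (distinct from a validation error — the inputs were well-formed but
    no network exists).
    """
    targets = set(targets)
    if not targets:
        raise ValidationError("targets must be non-empty")

    tft = db.layer_edges("TFT")
    rtf = db.layer_edges("RTF")
    lr = db.layer_edges("LR")

    regulated = {t for _, t in tft}
    v_t = targets & regulated
    dropped = targets - v_t
    if dropped:
        logger.warning("targets with no upstream TF dropped: %s", sorted(dropped))
    if not v_t:
        raise EmptyNetworkError(
            "no target gene has an upstream transcription factor in the database"
        )
    v_tf = {tf for tf, t in tft if t in v_t}
    v_r = {r for r, tf in rtf if tf in v_tf}
    v_l = {l for l, r in lr if r in v_r}

    grn = LigandTargetGRN()
    g = grn.graph
    recruited = {"LR": (v_l, v_r), "RTF": (v_r, v_tf), "TFT": (v_tf, v_t)}
    for layer, (src_set, dst_set) in recruited.items():
        from_role, to_role = LAYER_ROLES[layer]
        for ia in db.layer(layer):
            if ia.from_gene in src_set and ia.to_gene in dst_set:
                u, v = (ia.from_gene, from_role), (ia.to_gene, to_role)
                g.add_edge(u, v, layer=layer)
                grn.provenance[(u, v)] = (
                    grn.provenance.get((u, v), frozenset()) | ia.sources
                )
    return grn


def grn_layer_nodes(grn: LigandTargetGRN, role: str) -> list[str]:
    """Functional alias for :meth:`LigandTargetGRN.layer_nodes`."""
    return grn.layer_nodes(role)


def write_grn(grn: LigandTargetGRN, path: str | Path) -> None:
    """Export a GRN as an edge-list TSV with role/layer/source columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["from", "from_role", "to", "to_role", "layer", "sources"])
        for (u, v) in sorted(grn.graph.edges):
            layer = grn.graph.edges[u, v]["layer"]
            sources = ",".join(sorted(grn.provenance.get((u, v), frozenset())))
            w.writerow([u[0], u[1], v[0], v[1], layer, sources])


def read_grn(path: str | Path) -> LigandTargetGRN:
    """Read a GRN written by :func:`write_grn`."""
    grn = LigandTargetGRN()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            u: Node = (row["from"], row["from_role"])
            v: Node = (row["to"], row["to_role"])
            if row["layer"] not in LAYERS:
                raise ValidationError(f"unknown layer token {row['layer']!r}")
            grn.graph.add_edge(u, v, layer=row["layer"])
            srcs = frozenset(s for s in row["sources"].split(",") if s)
            grn.provenance[(u, v)] = srcs
    return grn


def write_graphml(grn: LigandTargetGRN, path: str | Path) -> None:
    """Export a GRN as GraphML with ``gene``/``role`` node attributes."""
    g = nx.DiGraph()
    for gene, role in grn.graph.nodes:
        g.add_node(f"{gene}|{role}", gene=gene, role=role)
    for (u, v), srcs in (
        ((e, grn.provenance.get(e, frozenset())) for e in grn.graph.edges)
    ):
        g.add_edge(f"{u[0]}|{u[1]}", f"{v[0]}|{v[1]}",
                   layer=grn.graph.edges[u, v]["layer"],
                   sources=",".join(sorted(srcs)))
    nx.write_graphml(g, path)
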