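"""Quantitative analysis of an exSigNet.

Edge strengths follow a mass-action (Michaelis–Menten-like) model: for
an edge between nodes with expression levels s_i and s_j,

    w_ij = s_i * s_j / (Kh + s_i * s_j),

with Kh the apparent dissociation (half-saturation) constant, default 2:
when the expression product equals Kh the strength is exactly half its
maximum.  Strengths lie in [0, 1) and serve as edge capacities for the
maximum-flow analysis that ranks critical signals and targets, as the
entries of the pair-strength matrix used for k-means clustering of
ligand-target pairs, and as the layer totals of the activation index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from networkx.algorithms.flow import preflow_push
import networkx as nx
from sklearn.cluster import KMeans

from .db import LAYERS
from .errors import StateError, ValidationError
from .expression import GroupExpression
from .grn import Node
from .network import ExSigNet, exsignet_for_pair

logger = logging.getLogger(__name__)

Edge = tuple[Node, Node]


@dataclass
class WeightedExSigNet:
    """An exSigNet with mass-action strengths on every edge."""

    net: ExSigNet
    edge_strength: dict[Edge, float]
    kh: float = 2.0

    @property
    def graph(self) -> nx.DiGraph:
        return self.net.graph

    def layer_total(self, layer: str) -> float:
        """Summed strength of one layer's edges."""
        return float(sum(self.edge_strength[e] for e in self.net.layer_edges(layer)))


@dataclass
class FlowResult:
    """Per-pair maximum flows and the criticality ranking they induce."""

    pair_flow: dict[tuple[str, str], float]
    total_outflow: dict[str, float]
    total_inflow: dict[str, float]
    critical_signal: str
    critical_target: str


@dataclass
class PairStrengthMatrix:
    """(ligand, target) pair x edge strength matrix W.

    Row ``p``, column ``e`` holds the strength of edge ``e`` if ``e``
    lies in pair ``p``'s sub-network and 0 otherwise; shape is exactly
    (|V_L| * |V_T|) x |E|.  Rows and columns are ordered
    lexicographically for determinism.
    """

    rows: list[tuple[str, str]]
    cols: list[Edge]
    W: np.ndarray
    normalized: bool = False


@dataclass
class GOTermProjection:
    """Projection of one GO term onto an exSigNet."""

    gene_proportion: float
    expression_proportion: float
    genes: set[str]


def assign_expression(
    net: ExSigNet,
    gexpr: GroupExpression,
    group: str | None = None,
    external_override: tuple[GroupExpression, str] | None = None,
) -> ExSigNet:
    """Populate node expression levels on a copy of ``net``.

    Receptors, TFs and targets receive their maximal average expression
    over all cell groups (signaling need not occur in every group), or
    the named ``group``'s mean when one is given.  External signals are
    set to 1 — they are unmeasured by definition, and a fixed unit level
    keeps them from dominating the strength prediction — unless
    ``external_override`` supplies an auxiliary dataset and group in
    which their expression was measured.
    """
    if group is not None and group not in gexpr.groups:
        raise ValidationError(f"unknown cell group {group!r}")
    if external_override is not None:
        ov_expr, ov_group = external_override
        if ov_group not in ov_expr.groups:
            raise ValidationError(f"unknown cell group {ov_group!r} in override data")

    node_expr: dict[Node, float] = {}
    for gene, role in net.graph.nodes:
        if role == "L" and gene in net.external_signals:
            if external_override is None:
                node_expr[(gene, role)] = 1.0
            else:
                node_expr[(gene, role)] = ov_expr.mean(gene, ov_group)
            continue
        if gene not in gexpr.genes:
            raise ValidationError(
                f"node {gene!r} has no expression data; only external signals "
                "may be unmeasured"
            )
        if group is None:
            node_expr[(gene, role)] = float(gexpr.means.loc[gene].max())
        else:
            node_expr[(gene, role)] = gexpr.mean(gene, group)
    out = ExSigNet(graph=net.graph.copy(),
                   external_signals=set(net.external_signals))
    out.node_expr = node_expr
    return out


def edge_strength(s_i: float, s_j: float, kh: float = 2.0) -> float:
    """Mass-action strength s_i*s_j / (Kh + s_i*s_j), in [0, 1)."""
    if s_i < 0 or s_j < 0:
        raise ValidationError("expression levels must be non-negative")
    if kh <= 0:
        raise ValidationError("half-saturation constant Kh must be positive")
    prod = s_i * s_j
    return prod / (kh + prod)


def weight_network(net: ExSigNet, kh: float = 2.0) -> WeightedExSigNet:
    """Apply the mass-action strength model to every edge of ``net``."""
    if kh <= 0:
        raise ValidationError("half-saturation constant Kh must be positive")
    missing = [n for n in net.graph.nodes if n not in net.node_expr]
    if missing:
        raise StateError(
            f"node expression not populated (e.g. {missing[0]}); "
            "call assign_expression first"
        )
    strengths = {
        (u, v): edge_strength(net.node_expr[u], net.node_expr[v], kh)
        for u, v in net.graph.edges
    }
    return WeightedExSigNet(net=net, edge_strength=strengths, kh=kh)


def _capacity_graph(wnet: WeightedExSigNet) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(wnet.graph.nodes)
    for (u, v), w in wnet.edge_strength.items():
        g.add_edge(u, v, capacity=w)
    return g


def max_signal_flow(wnet: WeightedExSigNet, source: str, sink: str) -> float:
    """Maximum flow from an external signal to a target gene.

    Edge strengths act as capacities; the push-relabel algorithm computes
    the exact maximum s-t flow.  A pair with no connecting network has
    flow zero.
    """
    if source not in wnet.net.external_signals:
        raise ValidationError(f"{source!r} is not an external signal")
    if source not in wnet.net.layer_nodes("L"):
        raise ValidationError(f"{source!r} is not a ligand node")
    if sink not in wnet.net.targets:
        raise ValidationError(f"{sink!r} is not a target gene")
    g = _capacity_graph(wnet)
    s: Node = (source, "L")
    t: Node = (sink, "T")
    if not nx.has_path(g, s, t):
        return 0.0
    return float(nx.maximum_flow_value(g, s, t, flow_func=preflow_push))


def flow_summary(wnet: WeightedExSigNet) -> FlowResult:
    """All pair flows plus total outflows/inflows and the critical nodes.

    The critical external signal maximizes the total signal outflow (sum
    of its pair flows over all targets); the critical target maximizes
    the total inflow.  Ties are broken lexicographically and logged.
    """
    ligands = sorted(wnet.net.external_signals)
    targets = wnet.net.targets
    pair_flow = {(l, t): max_signal_flow(wnet, l, t)
                 for l in ligands for t in targets}
    total_outflow = {l: sum(pair_flow[(l, t)] for t in targets) for l in ligands}
    total_inflow = {t: sum(pair_flow[(l, t)] for l in ligands) for t in targets}

    def _argmax(d: Mapping[str, float]) -> str:
        best = max(d.values())
        winners = sorted(k for k, v in d.items() if v == best)
        if len(winners) > 1:
            logger.info("tie for critical node among %s; choosing %s",
                        winners, winners[0])
        return winners[0]

    return FlowResult(pair_flow, total_outflow, total_inflow,
                      critical_signal=_argmax(total_outflow),
                      critical_target=_argmax(total_inflow))


def activation_index(
    wnet: WeightedExSigNet,
    k: Sequence[float] = (2.0, 2.0, 2.0, 2.0),
) -> float:
    """Activation index (AcI): saturating product of size and layer strengths.

    AcI = |V||E|/(K1+|V||E|) * prod over layers of w_layer/(K_i+w_layer),
    where w_layer is the summed strength of the layer's edges.  Each
    factor saturates toward 1, so AcI lies in [0, 1); it vanishes when
    any layer carries no strength and grows with network size and with
    every individual edge strength.
    """
    if len(k) != 4 or any(ki <= 0 for ki in k):
        raise ValidationError("AcI requires four positive constants K1..K4")
    n_nodes = wnet.graph.number_of_nodes()
    n_edges = wnet.graph.number_of_edges()
    size = n_nodes * n_edges
    aci = size / (k[0] + size)
    for ki, layer in zip(k[1:], LAYERS):
        w = wnet.layer_total(layer)
        aci *= w / (ki + w)
    return float(aci)


def build_pair_matrix(wnet: WeightedExSigNet) -> PairStrengthMatrix:
    """Strength matrix W over all (external signal, target) pairs.

    Each row is one pair's view of the network: the strengths of the
    edges belonging to that pair's sub-network, zeros elsewhere.
    """
    ligands = sorted(wnet.net.external_signals)
    targets = wnet.net.targets
    cols: list[Edge] = sorted(wnet.graph.edges)
    col_idx = {e: i for i, e in enumerate(cols)}
    rows = [(l, t) for l in ligands for t in targets]
    W = np.zeros((len(rows), len(cols)))
    for r, (l, t) in enumerate(rows):
        sub = exsignet_for_pair(wnet.net, l, t)
        for e in sub.graph.edges:
            W[r, col_idx[e]] = wnet.edge_strength[e]
    return PairStrengthMatrix(rows=rows, cols=cols, W=W)


def normalize_pair_matrix(
    pm: PairStrengthMatrix, method: str = "row-unit"
) -> PairStrengthMatrix:
    """Normalize W for clustering (noise reduction).

    ``row-unit`` scales each row to unit Euclidean norm so clustering
    compares the shape of a pair's strength profile, not its magnitude;
    all-zero rows are left as zero.  ``column-z`` standardizes columns;
    ``none`` is a no-op.
    """
    if method == "none":
        return PairStrengthMatrix(pm.rows, pm.cols, pm.W.copy(), normalized=False)
    W = pm.W.astype(float).copy()
    if method == "row-unit":
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        W = W / norms
    elif method == "column-z":
        sd = W.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        W = (W - W.mean(axis=0, keepdims=True)) / sd
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return PairStrengthMatrix(pm.rows, pm.cols, W, normalized=True)


def cluster_pairs(
    pm: PairStrengthMatrix,
    k: int,
    n_init: int = 20,
    seed: int = 0,
    normalize: str = "row-unit",
) -> dict[tuple[str, str], int]:
    """k-means clustering of (signal, target) pairs on the normalized W.

    The best of ``n_init`` random restarts (by within-cluster sum of
    squares) is kept; results are deterministic given ``seed``.
    """
    n_distinct = len(np.unique(pm.W, axis=0))
    if not 1 <= k <= n_distinct:
        raise ValidationError(
            f"k must be between 1 and the number of distinct rows ({n_distinct})"
        )
    norm = normalize_pair_matrix(pm, normalize)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(norm.W)
    return {pair: int(lab) for pair, lab in zip(pm.rows, labels)}


def go_projection(
    wnet: WeightedExSigNet,
    term_sets: Mapping[str, set[str]],
) -> dict[str, GOTermProjection]:
    """Project GO term gene sets onto the network's nodes and expression.

    For each term, the gene proportion is the fraction of network nodes
    whose gene belongs to the term, and the expression proportion is the
    fraction of total node expression those nodes carry.  Terms with
    large expression proportion may matter more than their enrichment
    rank alone suggests.
    """
    nodes = list(wnet.graph.nodes)
    if not nodes:
        raise StateError("cannot project GO terms onto an empty network")
    expr = wnet.net.node_expr
    total_expr = sum(abs(expr[n]) for n in nodes)
    out: dict[str, GOTermProjection] = {}
    for term, genes in term_sets.items():
        hit_nodes = [n for n in nodes if n[0] in genes]
        hit_expr = sum(abs(expr[n]) for n in hit_nodes)
        out[term] = GOTermProjection(
            gene_proportion=len(hit_nodes) / len(nodes),
            expression_proportion=(hit_expr / total_expr) if total_expr > 0 else 0.0,
            genes={n[0] for n in hit_nodes},
        )
    return out


def flow_table(result: FlowResult) -> pd.DataFrame:
    """Tidy per-pair flow table (ligand, target, flow)."""
    return pd.DataFrame(
        [(l, t, f) for (l, t), f in sorted(result.pair_flow.items())],
        columns=["ligand", "target", "flow"],
    )
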