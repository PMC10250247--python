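"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import pandas as pd
import pytest

from exsignet import (ExpressionCutoffs, ExSigNet, GroupExpression,
                      Interaction, SignalingDB)
from exsignet.quantify import WeightedExSigNet


def make_db(edges, species="human", source="src"):
    """Build a SignalingDB from (from, to, layer) triples."""
    return SignalingDB(
        [Interaction(a, b, layer, species, frozenset({source}))
         for a, b, layer in edges],
        species,
    )


def make_gexpr(values: dict[str, dict[str, float]]) -> GroupExpression:
    """GroupExpression from {gene: {group: mean}} (missing entries 0)."""
    return GroupExpression(pd.DataFrame(values).T.fillna(0.0))


def make_net(edges, node_expr=None, externals=None) -> ExSigNet:
    """Build an ExSigNet from ((gene, role), (gene, role), layer) triples."""
    net = ExSigNet()
    for u, v, layer in edges:
        net.graph.add_edge(u, v, layer=layer)
    if node_expr:
        net.node_expr = dict(node_expr)
    net.external_signals = (set(externals) if externals is not None
                            else {g for g, r in net.graph.nodes if r == "L"})
    return net


def make_weighted(edges_with_caps, externals=None) -> WeightedExSigNet:
    """WeightedExSigNet with explicitly assigned edge capacities."""
    net = make_net([(u, v, layer) for u, v, layer, _ in edges_with_caps],
                   externals=externals)
    net.node_expr = {n: 1.0 for n in net.graph.nodes}
    strengths = {(u, v): cap for u, v, _, cap in edges_with_caps}
    return WeightedExSigNet(net=net, edge_strength=strengths)


def min_cut_bruteforce(graph: nx.DiGraph, s, t) -> float:
    """Max-flow oracle: minimum s-t cut by exhaustive subset enumeration.

    By max-flow/min-cut duality the maximum flow equals the minimum,
    over all node partitions separating s from t, of the total capacity
    of edges crossing from the s-side to the t-side.
    """
    others = [n for n in graph.nodes if n not in (s, t)]
    best = float("inf")
    for r in range(len(others) + 1):
        for subset in itertools.combinations(others, r):
            side = set(subset) | {s}
            cap = sum(d["capacity"] for u, v, d in graph.edges(data=True)
                      if u in side and v not in side)
            best = min(best, cap)
    return best


def enumerate_grn_bruteforce(targets, db):
    """GRN oracle: exhaustive enumeration of target-anchored path suffixes.

    Enumerates every TF->T regulation into a target, every R->TF->T
    suffix and every complete L->R->TF->T path by brute force over the
    three layer tables, independent of the backward-traversal
    implementation.  Their union is the ligand-target GRN (upstream
    layers may be partially populated: a recruited TF need not have a
    known receptor).
    """
    lr, rtf, tft = (db.layer_edges(l) for l in ("LR", "RTF", "TFT"))
    nodes, edges = set(), set()
    for tf, t in tft:
        if t not in targets:
            continue
        nodes |= {(tf, "TF"), (t, "T")}
        edges.add(((tf, "TF"), (t, "T"), "TFT"))
        for r, tf2 in rtf:
            if tf2 != tf:
                continue
            nodes.add((r, "R"))
            edges.add(((r, "R"), (tf, "TF"), "RTF"))
            for l, r2 in lr:
                if r2 != r:
                    continue
                nodes.add((l, "L"))
                edges.add(((l, "L"), (r, "R"), "LR"))
    return nodes, edges


@pytest.fixture
def single_path_db():
    return make_db([("LigA", "RecA", "LR"), ("RecA", "TF1", "RTF"),
                    ("TF1", "T1", "TFT")])


@pytest.fixture
def toy_cutoffs():
    return ExpressionCutoffs(low_cutoff=1.0, high_cutoff=2.0,
                             per_group_p_low={}, per_group_p_high={})
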