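"""External-signal identification and exSigNet construction.

An *external signal* is a ligand the measured cells receive but do not
produce: it is lowly expressed (or unmeasured) in every cell group,
while its downstream receptor and transcription factor are highly
expressed — evidence that the pathway is active even though the ligand's
source lies outside the dataset.

The *exSigNet* is the subgraph of the ligand-target GRN spanned by the
complete external-signal → receptor → TF → target paths in which every
retained receptor and TF is highly expressed in at least one cell group.
Target genes are user-chosen and are not expression-filtered by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import EmptyNetworkError, ValidationError
from .expression import ExpressionCutoffs, GroupExpression, classify_gene
from .expression import potential_external_signals
from .grn import LigandTargetGRN, Node


@dataclass
class ExSigNet:
    """External-signal-to-target signaling network (a GRN subgraph).

    ``node_expr`` maps each ``(gene, role)`` node to its assigned
    expression level; it is empty until populated by
    :func:`exsignet.quantify.assign_expression`.  ``external_signals``
    is exactly the ligand layer of the graph.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    node_expr: dict[Node, float] = field(default_factory=dict)
    external_signals: set[str] = field(default_factory=set)

    def layer_nodes(self, role: str) -> list[str]:
        return sorted(g for g, r in self.graph.nodes if r == role)

    def layer_edges(self, layer: str) -> set[tuple[Node, Node]]:
        return {(u, v) for u, v, d in self.graph.edges(data=True)
                if d["layer"] == layer}

    @property
    def targets(self) -> list[str]:
        return self.layer_nodes("T")

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


def _high_in_any_group(
    gene: str, gexpr: GroupExpression, cutoffs: ExpressionCutoffs,
    group: str | None = None,
) -> bool:
    groups = [group] if group is not None else gexpr.groups
    return any(classify_gene(gexpr, cutoffs, gene, g) == "high" for g in groups)


def identify_external_signals(
    grn: LigandTargetGRN,
    gexpr: GroupExpression,
    cutoffs: ExpressionCutoffs,
    group: str | None = None,
) -> set[str]:
    """Ligands of ``grn`` that qualify as external signals.

    A ligand qualifies when (a) it is a potential external signal (low
    in all groups, or unmeasured) and (b) it binds a highly expressed
    receptor that signals to a highly expressed TF regulating one of the
    GRN's target genes.  ``group`` restricts the "highly expressed"
    requirement to one named cell group; by default high in any group
    counts.  May return the empty set.
    """
    if grn.is_empty:
        raise ValidationError("cannot identify external signals on an empty GRN")
    g = grn.graph
    target_genes = set(grn.layer_nodes("T"))
    potential = potential_external_signals(grn.layer_nodes("L"), gexpr, cutoffs)

    found: set[str] = set()
    for ligand in potential:
        node = (ligand, "L")
        for _, (rec, _) in g.out_edges(node):
            if not _high_in_any_group(rec, gexpr, cutoffs, group):
                continue
            for _, (tf, _) in g.out_edges((rec, "R")):
                if not _high_in_any_group(tf, gexpr, cutoffs, group):
                    continue
                if any(t in target_genes for _, (t, _) in g.out_edges((tf, "TF"))):
                    found.add(ligand)
                    break
            if ligand in found:
                break
    return found


def infer_exsignet(
    grn: LigandTargetGRN,
    gexpr: GroupExpression,
    cutoffs: ExpressionCutoffs,
    group: str | None = None,
    require_high_targets: bool = False,
) -> ExSigNet:
    """Build the exSigNet: paths from external signals to target genes.

    Retains exactly the nodes and edges lying on a complete 3-edge path
    external signal → high receptor → high TF → target.  With
    ``require_high_targets`` targets must additionally be classified
    high in some group (off by default: targets are user-validated).
    Raises :class:`EmptyNetworkError` when no external signal exists.
    """
    externals = identify_external_signals(grn, gexpr, cutoffs, group)
    if not externals:
        raise EmptyNetworkError("no external signals identified in the GRN")
    g = grn.graph
    target_genes = set(grn.layer_nodes("T"))

    # forward sweep: expression-qualified nodes reachable from the externals
    recs = {r for l in externals for _, (r, _) in g.out_edges((l, "L"))
            if _high_in_any_group(r, gexpr, cutoffs, group)}
    tfs = {tf for r in recs for _, (tf, _) in g.out_edges((r, "R"))
           if _high_in_any_group(tf, gexpr, cutoffs, group)}
    tgts = {t for tf in tfs for _, (t, _) in g.out_edges((tf, "TF"))
            if t in target_genes}
    if require_high_targets:
        tgts = {t for t in tgts if _high_in_any_group(t, gexpr, cutoffs, group)}

    # backward sweep: drop nodes with no live downstream continuation
    tfs = {tf for tf in tfs
           if any(t in tgts for _, (t, _) in g.out_edges((tf, "TF")))}
    recs = {r for r in recs
            if any(tf in tfs for _, (tf, _) in g.out_edges((r, "R")))}
    externals = {l for l in externals
                 if any(r in recs for _, (r, _) in g.out_edges((l, "L")))}

    net = ExSigNet(external_signals=externals)
    keep = [("L", externals), ("R", recs), ("TF", tfs), ("T", tgts)]
    kept_nodes = {(gene, role) for role, genes in keep for gene in genes}
    for u, v, d in g.edges(data=True):
        if u in kept_nodes and v in kept_nodes:
            net.graph.add_edge(u, v, layer=d["layer"])
    return net


def exsignet_for_pair(net: ExSigNet, ligand: str, target: str) -> ExSigNet:
    """Sub-network of ``net`` spanned by all paths from one ligand to one target.

    Returns an empty network (not an error) when no connecting path
    exists; raises a validation error when the ligand is not one of the
    network's external signals or the target is absent.
    """
    if ligand not in net.external_signals:
        raise ValidationError(f"{ligand!r} is not an external signal of this network")
    if target not in net.targets:
        raise ValidationError(f"{target!r} is not a target gene of this network")
    src: Node = (ligand, "L")
    dst: Node = (target, "T")
    forward = nx.descendants(net.graph, src) | {src}
    backward = nx.ancestors(net.graph, dst) | {dst}
    kept = forward & backward
    sub = ExSigNet()
    if dst not in kept or src not in kept:
        return sub
    for u, v, d in net.graph.edges(data=True):
        if u in kept and v in kept:
            sub.graph.add_edge(u, v, layer=d["layer"])
    sub.external_signals = {ligand}
    sub.node_expr = {n: net.node_expr[n] for n in sub.graph.nodes
                     if n in net.node_expr}
    return sub
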