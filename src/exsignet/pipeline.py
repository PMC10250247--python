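"""End-to-end pipeline orchestration.

``run_pipeline`` composes the full analysis — database loading, group
means and cutoffs, GRN inference, external-signal identification,
exSigNet construction, strength prediction, flows, activation index,
pair clustering and optional GO projection — and writes a report bundle
plus a machine-readable manifest.  The pipeline is a pure function of
(inputs, configuration, seed): identical manifests imply identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .db import load_db
from .errors import ValidationError
from .expression import group_means, percentile_cutoffs
from .grn import infer_ltgrn, write_grn
from .io import (read_cell_labels, read_expression_csv, read_expression_mtx,
                 read_gene_list, read_term_sets)
from .network import infer_exsignet
from .quantify import (activation_index, assign_expression, build_pair_matrix,
                       cluster_pairs, flow_summary, flow_table, go_projection,
                       weight_network)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and parameters of one pipeline run.

    Defaults follow the method's standard settings: 50th/90th percentile
    cutoffs, half-saturation constant Kh = 2, AcI constants K1..K4 = 2,
    and k-means with 20 random restarts.
    """

    db: str = ""
    matrix: str = ""           # dense CSV, or matrix.mtx with genes/barcodes
    genes: str = ""            # gene index for MTX input
    barcodes: str = ""         # barcode index for MTX input
    labels: str = ""
    targets: str = ""
    terms: str = ""            # optional GMT/TSV of GO term gene sets
    species: str = "synthetic"
    p_low: float = 50.0
    p_high: float = 90.0
    kh: float = 2.0
    aci_k: tuple[float, float, float, float] = (2.0, 2.0, 2.0, 2.0)
    n_clusters: int = 2
    n_init: int = 20
    seed: int = 0
    group: str | None = None          # restrict "high" calls to one group
    normalization: str = "row-unit"   # pair-matrix normalization

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "aci_k" in data:
            data["aci_k"] = tuple(data["aci_k"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("db", "matrix", "labels", "targets"):
            if not getattr(self, name):
                raise ValidationError(f"config field {name!r} is required")


def _load_expression(config: RunConfig) -> pd.DataFrame:
    if config.matrix.endswith(".mtx"):
        if not config.genes or not config.barcodes:
            raise ValidationError(
                "MTX input requires the 'genes' and 'barcodes' config fields")
        return read_expression_mtx(config.matrix, config.genes, config.barcodes)
    return read_expression_csv(config.matrix)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    Returns a dictionary with the in-memory results (exSigNet, flows,
    AcI, cluster labels, GO projection) keyed by stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    db = load_db(config.db, config.species)
    expr = _load_expression(config)
    labels = read_cell_labels(config.labels)
    targets = read_gene_list(config.targets)

    gexpr = group_means(expr, labels)
    cutoffs = percentile_cutoffs(gexpr, config.p_low, config.p_high)
    logger.info("expression: %d genes, %d groups; cutoffs low=%.4g high=%.4g",
                len(gexpr.genes), len(gexpr.groups),
                cutoffs.low_cutoff, cutoffs.high_cutoff)

    grn = infer_ltgrn(targets, db)
    logger.info("GRN: %d nodes, %d edges", grn.graph.number_of_nodes(),
                grn.graph.number_of_edges())
    write_grn(grn, outdir / "grn.tsv")

    net = infer_exsignet(grn, gexpr, cutoffs, group=config.group)
    net = assign_expression(net, gexpr)
    wnet = weight_network(net, kh=config.kh)
    logger.info("exSigNet: %d nodes, %d edges, %d external signals",
                net.graph.number_of_nodes(), net.graph.number_of_edges(),
                len(net.external_signals))

    rows = [
        (u[0], u[1], v[0], v[1], d["layer"], wnet.edge_strength[(u, v)])
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["from", "from_role", "to", "to_role",
                                "layer", "strength"]).to_csv(
        outdir / "exsignet.tsv", sep="\t", index=False)

    flows = flow_summary(wnet)
    flow_table(flows).to_csv(outdir / "flows.csv", index=False)
    aci = activation_index(wnet, config.aci_k)

    pm = build_pair_matrix(wnet)
    clusters = None
    n_distinct = len({tuple(r) for r in pm.W})
    if config.n_clusters <= n_distinct:
        clusters = cluster_pairs(pm, config.n_clusters, config.n_init,
                                 config.seed, config.normalization)
        pd.DataFrame(
            [(l, t, c) for (l, t), c in sorted(clusters.items())],
            columns=["ligand", "target", "cluster"],
        ).to_csv(outdir / "clusters.csv", index=False)
    else:
        logger.warning("skipping clustering: k=%d exceeds %d distinct pairs",
                       config.n_clusters, n_distinct)

    projection = None
    if config.terms:
        projection = go_projection(wnet, read_term_sets(config.terms))
        pd.DataFrame(
            [(term, p.gene_proportion, p.expression_proportion,
              ";".join(sorted(p.genes)))
             for term, p in sorted(projection.items())],
            columns=["term", "gene_proportion", "expression_proportion", "genes"],
        ).to_csv(outdir / "go_projection.csv", index=False)

    summary = {
        "external_signals": sorted(net.external_signals),
        "activation_index": aci,
        "critical_signal": flows.critical_signal,
        "critical_target": flows.critical_target,
        "total_outflow": dict(sorted(flows.total_outflow.items())),
        "total_inflow": dict(sorted(flows.total_inflow.items())),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    manifest = {"version": __version__, "config": asdict(config)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {"grn": grn, "exsignet": net, "weighted": wnet, "flows": flows,
            "aci": aci, "clusters": clusters, "go": projection,
            "summary": summary}
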