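"""Synthetic scenarios with planted ground truth.

Generates a layered prior-knowledge database plus a gene x cell
expression matrix in which a chosen subset of ligands is *external*:
their expression is zero in every cell group while a complete planted
receptor → TF → target cascade downstream of each is highly expressed
in one designated group.  All remaining (internal) ligands are highly
expressed in one group, so they can never be mistaken for external
signals, and each is wired to a cascade of a *different* group — which
makes leave-one-group-out benchmarking work: removing a ligand's only
high group turns it into an expected external signal whose downstream
cascade is still measured.

Expression regimes (designed group means, arbitrary normalized units):
zero for externals, ``high_mean`` (default 10) for cascade genes in
their group, and an intermediate background around 1 elsewhere.  The
high regime clears the 90th-percentile cutoff by a wide margin by
construction.  Per-cell values are the designed group mean plus
Gaussian noise truncated at zero; with ``noise_sd=0`` group means equal
their designed values exactly.  Only group means and percentiles are
consumed downstream, so this simple noise model exercises the whole
pipeline; it does not attempt realistic scRNA-seq artifacts (dropout,
batch effects, doublets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .db import Interaction, SignalingDB, write_db
from .errors import ValidationError

HIGH = "high"
MID = "mid"
ZERO = "zero"

_REGIME_MEANS = {ZERO: 0.0, MID: 1.0, HIGH: 10.0}


@dataclass
class SyntheticScenario:
    """A generated database + expression dataset with planted truth."""

    db: SignalingDB
    expr_matrix: pd.DataFrame          # genes x cells
    cell_labels: pd.Series             # cell -> group
    targets: list[str]                 # the user-supplied target gene list
    planted_externals: set[str]
    planted_internals: set[str]
    planted_paths: set[tuple[str, str, str, str]]   # (L, R, TF, T)
    regimes: pd.DataFrame              # genes x groups regime labels
    seed: int
    expected_externals: set[str] = field(default_factory=set)

    @property
    def groups(self) -> list[str]:
        return sorted(self.cell_labels.unique())


def _expected_externals(
    db: SignalingDB, regimes: pd.DataFrame, groups: list[str], targets: set[str]
) -> set[str]:
    """Ground-truth external signals, derived from regimes and the DB.

    A ligand is expected external iff it has no high-regime group among
    ``groups`` and some ligand→receptor→TF→target chain exists whose
    receptor and TF are high-regime in at least one of ``groups``.
    """
    def high_somewhere(gene: str) -> bool:
        return gene in regimes.index and (regimes.loc[gene, groups] == HIGH).any()

    lr = db.layer_edges("LR")
    rtf = db.layer_edges("RTF")
    tft = db.layer_edges("TFT")
    ligands = {l for l, _ in lr}
    expected = set()
    for lig in ligands:
        if high_somewhere(lig):
            continue
        for l, r in lr:
            if l != lig or not high_somewhere(r):
                continue
            for r2, tf in rtf:
                if r2 != r or not high_somewhere(tf):
                    continue
                if any(tf2 == tf and t in targets for tf2, t in tft):
                    expected.add(lig)
                    break
            if lig in expected:
                break
    return expected


def generate_scenario(
    n_ligands: int = 10,
    n_receptors: int = 8,
    n_tfs: int = 6,
    n_targets: int = 5,
    n_external: int = 3,
    n_groups: int = 3,
    cells_per_group: int = 30,
    edge_density: float = 0.15,
    noise_sd: float = 0.1,
    n_background: int = 40,
    seed: int = 0,
    species: str = "synthetic",
) -> SyntheticScenario:
    """Generate a reproducible scenario with planted external signals."""
    if min(n_ligands, n_receptors, n_tfs, n_targets, n_groups,
           cells_per_group) < 1:
        raise ValidationError("all counts must be >= 1")
    if not 0 <= n_external <= n_ligands:
        raise ValidationError("n_external must be between 0 and n_ligands")
    if not 0 < edge_density <= 1:
        raise ValidationError("edge_density must be in (0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    ligands = [f"LG{i:02d}" for i in range(n_ligands)]
    receptors = [f"RC{i:02d}" for i in range(n_receptors)]
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    targets = [f"TG{i:02d}" for i in range(n_targets)]
    background = [f"BG{i:03d}" for i in range(n_background)]
    groups = [f"G{i}" for i in range(n_groups)]

    externals = set(ligands[:n_external])
    internals = set(ligands[n_external:])

    edges: set[tuple[str, str, str]] = set()
    paths: set[tuple[str, str, str, str]] = set()
    cascade_group: dict[int, str] = {}
    for i, lig in enumerate(sorted(externals)):
        r, tf, t = (receptors[i % n_receptors], tfs[i % n_tfs],
                    targets[i % n_targets])
        edges |= {(lig, r, "LR"), (r, tf, "RTF"), (tf, t, "TFT")}
        paths.add((lig, r, tf, t))
        cascade_group[i] = groups[i % n_groups]

    # internal ligands: high in one group, wired to a cascade of another
    internal_high: dict[str, str] = {}
    for j, lig in enumerate(sorted(internals)):
        hg = groups[j % n_groups]
        internal_high[lig] = hg
        if externals:
            others = [i for i, g in cascade_group.items() if g != hg]
            i = others[j % len(others)] if others else j % len(cascade_group)
            edges.add((lig, receptors[i % n_receptors], "LR"))

    # random extra layer-respecting edges
    for pool_from, pool_to, layer in (
        (ligands, receptors, "LR"),
        (receptors, tfs, "RTF"),
        (tfs, targets, "TFT"),
    ):
        for a in pool_from:
            for b in pool_to:
                if rng.random() < edge_density:
                    edges.add((a, b, layer))

    db = SignalingDB(
        [Interaction(a, b, layer, species, frozenset({"planted"}))
         for a, b, layer in sorted(edges)],
        species,
    )

    # designed expression regimes
    genes = ligands + receptors + tfs + targets + background
    regimes = pd.DataFrame(MID, index=genes, columns=groups)
    for lig in externals:
        regimes.loc[lig, :] = ZERO
    for lig, hg in internal_high.items():
        # group-specific ligands: expressed only by their own group, so
        # removing that group makes them bona fide external signals
        regimes.loc[lig, :] = ZERO
        regimes.loc[lig, hg] = HIGH
    for i, (lig, r, tf, t) in enumerate(sorted(paths)):
        g = cascade_group[i]
        regimes.loc[[r, tf, t], g] = HIGH

    # designed means: fixed regime levels for network genes; background
    # genes get gene-specific variation so the percentile cutoffs sit in
    # a realistic band.  Only background genes (absent from the DB) may
    # straddle the 90th-percentile cutoff, so classification of every
    # network gene is unambiguous by construction.
    designed = np.array([[_REGIME_MEANS[regimes.at[g, grp]] for grp in groups]
                         for g in genes])
    jitter = rng.uniform(0.5, 2.0, size=n_background)
    designed[len(genes) - n_background:, :] = jitter[:, None]

    cells, labels, cols = [], [], []
    for gi, grp in enumerate(groups):
        mean_vec = designed[:, gi]
        noise = rng.normal(0.0, noise_sd, size=(len(genes), cells_per_group))
        block = np.clip(mean_vec[:, None] + noise, 0.0, None)
        cells.append(block)
        for ci in range(cells_per_group):
            cols.append(f"C_{grp}_{ci:03d}")
            labels.append(grp)
    expr = pd.DataFrame(np.hstack(cells), index=genes, columns=cols)
    cell_labels = pd.Series(labels, index=cols, name="group")

    scenario = SyntheticScenario(
        db=db, expr_matrix=expr, cell_labels=cell_labels, targets=targets,
        planted_externals=externals, planted_internals=internals,
        planted_paths=paths, regimes=regimes, seed=seed,
    )
    scenario.expected_externals = _expected_externals(
        db, regimes, groups, set(targets))
    return scenario


def leave_one_group_out(scenario: SyntheticScenario, group: str) -> SyntheticScenario:
    """Remove one cell group, making its cells 'external cells'.

    The database and planted truth are unchanged, but the expected
    external signals are recomputed: a ligand whose only high-expression
    group was removed is now unmeasurable by the remaining cells and —
    provided its downstream cascade is still highly expressed in a
    remaining group — becomes an expected external signal.
    """
    groups = scenario.groups
    if group not in groups:
        raise ValidationError(f"unknown cell group {group!r}")
    if len(groups) < 2:
        raise ValidationError("cannot remove the last cell group")
    keep = scenario.cell_labels != group
    remaining = [g for g in groups if g != group]
    out = replace(
        scenario,
        expr_matrix=scenario.expr_matrix.loc[:, keep.to_numpy()],
        cell_labels=scenario.cell_labels[keep],
    )
    out.expected_externals = _expected_externals(
        scenario.db, scenario.regimes, remaining, set(scenario.targets))
    return out


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> None:
    """Write a scenario to disk in the pipeline's input formats.

    Produces ``db.tsv``, ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``,
    ``labels.csv`` and ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_db(scenario.db, outdir / "db.tsv")
    sparse = scipy.sparse.csr_matrix(scenario.expr_matrix.to_numpy())
    scipy.io.mmwrite(outdir / "matrix.mtx", sparse)
    (outdir / "genes.tsv").write_text(
        "".join(f"{g}\n" for g in scenario.expr_matrix.index))
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in scenario.expr_matrix.columns))
    scenario.cell_labels.rename_axis("cell").to_csv(outdir / "labels.csv")
    (outdir / "targets.txt").write_text(
        "".join(f"{t}\n" for t in scenario.targets))
    truth = {
        "planted_externals": sorted(scenario.planted_externals),
        "planted_internals": sorted(scenario.planted_internals),
        "expected_externals": sorted(scenario.expected_externals),
        "planted_paths": sorted(map(list, scenario.planted_paths)),
        "targets": scenario.targets,
        "seed": scenario.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
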