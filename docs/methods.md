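# Methods

## Problem setting and model

Single-cell RNA-seq measures the transcriptomes of a set of cells, but the
signals those cells respond to may originate outside the dataset:
unmeasured cell populations, the extracellular environment, or inducers
added experimentally. The package infers such *external signals* for a
user-chosen set of target genes and quantifies the network connecting
them.

The signaling model is a fixed four-layer structure: ligand → receptor →
transcription factor → target gene. Prior knowledge enters as three edge
tables (`LR`, `RTF`, `TFT`), each edge carrying provenance labels naming
the curated resources supporting it. Databases are per-species; gene
symbols are matched case-sensitively after whitespace trimming and no
orthology mapping is attempted. Multi-subunit ligand/receptor complexes
are not modeled — every interaction is a single gene pair — and
self-loops are rejected at validation since the layered structure never
needs them. When several resources contribute the same `(from, to,
layer)` triple they are merged into one interaction with unioned source
labels; merging is commutative and idempotent, so the integrated database
is independent of the order resources are added.

### Ligand–target GRN

Given targets V_T, inference is a backward traversal using prior
knowledge only: V_TF is every TF with a `TFT` edge into V_T, V_R every
receptor with an `RTF` edge into V_TF, V_L every ligand with an `LR` edge
into V_R; E is the restriction of the three layers to the recruited
nodes. Targets with no upstream TF are dropped with a warning; if none
survives the result is an explicit empty-network error rather than a
validation error. Node identity is the pair (gene, role) so that a gene
recruited in two roles appears once per role and edges never skip
layers. Note the traversal keeps upstream-incomplete branches (a
recruited TF need not have a known receptor); completeness is only
enforced later, on the exSigNet.

### Expression cutoffs and classification

All expression decisions use per-group *mean* expression (zeros
included), computed from the provided matrix with no further
normalization or log transform — the input is assumed pre-normalized.
Per group, genes with zero mean are removed and the 50th and 90th
percentiles of the remaining means are computed with linear interpolation
between order statistics (the common default in scientific stacks; the
percentile method and both percentile levels are exposed as parameters).
The low cutoff is the maximum of the 50th percentiles over groups and the
high cutoff the minimum of the 90th; taking max/min across groups absorbs
large between-group differences. Classification uses strict
inequalities — high if mean > high cutoff, low if mean < low cutoff, ties
intermediate — and high takes precedence in the (possible) regime where
the cutoffs cross, which is logged. Genes absent from the matrix are
treated as zero everywhere, which is what makes entirely unmeasured
inducers identifiable. A ligand low in every group, or unmeasured, is a
*potential external signal*.

### exSigNet

A potential external signal is confirmed when some `LR` edge reaches a
receptor classified high in at least one group, that receptor reaches a
TF high in at least one group, and that TF regulates one of the targets.
"High in at least one group" is the default semantics (signaling need not
occur in all populations); a config flag restricts the requirement to a
named group. The exSigNet Ĝ is the subgraph spanned by all complete
signal → high receptor → high TF → target paths; forward and backward
sweeps guarantee every retained node lies on such a path. Targets are
not expression-filtered by default (they are user-validated input); a
flag can require them high as well.

## Quantification

Node expression ŝ is the maximal group mean (or a named group's mean);
external signals get ŝ = 1 since they are unmeasured — a fixed unit level
that keeps them from dominating the prediction — unless an auxiliary
dataset measuring them is supplied. Edge strength is the mass-action
form ŵ = ŝⁱŝʲ/(Kh + ŝⁱŝʲ) with half-saturation constant Kh = 2 by
default; ŵ ∈ [0, 1), equals 0.5 exactly at ŝⁱŝʲ = Kh, and is strictly
increasing in each expression level. Changing Kh rescales strengths
monotonically, so strength *ranks* for strictly ordered expression
products are Kh-invariant (tested for Kh ∈ {1..10}).

Per (signal, target) pair the maximal signal flow is the exact maximum
s–t flow with strengths as capacities, computed by push-relabel on the
full Ĝ (per-pair flows on full-graph capacities; exactness, not a
particular algorithm, is the contract — the implementation is verified
against a brute-force min-cut enumeration on small graphs, tolerance
1e-9). A disconnected pair has flow zero. Total outflow (per signal)
and inflow (per target) are sums of pair flows; their argmaxes are the
critical external signal and critical target gene, with lexicographic,
logged tie-breaking.

The activation index AcI multiplies four saturating terms — network size
|V̂||Ê| and the three per-layer total strengths — each of the form
x/(K+x) with K₁..K₄ = 2 by default. AcI ∈ [0, 1), vanishes when any
layer carries no strength, and is strictly monotone in every edge
strength.

The pair-strength matrix W has one row per (signal, target) pair
(|V̂_L|·|V̂_T| rows, lexicographic) and one column per edge of Ĝ; an
entry is the edge's strength when the edge lies in the pair's
sub-network, else zero, so the union of pair sub-networks reconstructs
Ĝ column-wise. For clustering, rows are scaled to unit Euclidean norm
(all-zero rows left zero): the clusters then compare the *shape* of a
pair's strength profile, not its magnitude. Column z-scoring and no
normalization are available alternatives. k-means runs 20 random
restarts, keeping the best within-cluster sum of squares, deterministic
given the seed; k is user-supplied — no automatic selection is silently
applied.

GO projection takes term → gene-set mappings as input (enrichment
testing itself is upstream) and reports, per term, |V_GO|/|V_Ĝ| — the
fraction of network nodes whose gene belongs to the term — and the
fraction of total node expression carried by those nodes. Expression
levels are non-negative, so the absolute values in the expression ratio
are a formal no-op.

## Synthetic scenarios

The generator emulates the leave-cells-out benchmarking design: plant
`n_external` ligands with zero designed expression in every group, each
with a guaranteed complete cascade whose receptor/TF/target are in the
high regime (designed mean 10) in one designated group; make all other
ligands *group-specific* (high in exactly one group, zero elsewhere) and
wire each to a cascade of a different group; add random layer-respecting
edges at `edge_density`. Defaults: 10 ligands (3 external), 8 receptors,
6 TFs, 5 targets, 3 groups × 30 cells, density 0.15, 40 background genes.

Designed group means use three regimes — 0, 1 (intermediate) and 10
(high) — with the high regime clearing the 90th-percentile cutoff by a
margin well above 2×, so tests are not threshold-fragile. Network genes
take their regime values exactly; only background genes, which appear in
no interaction, get gene-specific intermediate variation (uniform on
[0.5, 2]), so the percentile band is populated realistically without
ever making a pathway gene's classification ambiguous. Per-cell values
are the designed mean plus Gaussian noise truncated at zero
(`noise_sd = 0.1` by default; the method consumes only group means and
percentiles, so the exact per-cell distribution is a configuration
choice, and zero noise reproduces the designed means exactly).
Everything derives from one integer seed.

By this construction the planted external signals are recovered with
precision = recall = 1 at low noise, and `leave_one_group_out` removes
one group's cells so that its group-specific ligands become expected
external signals, computable exactly from the designed regimes and the
database. What passing these tests does *not* show: robustness to
dropout, batch effects, doublets, ambient RNA or continuous expression
gradients — none of which the generator models — nor anything about the
coverage of a real curated interaction database.

## Numerical and design notes

- Flow, strength and AcI comparisons in tests use absolute tolerance
  1e-9 (1e-12 for the closed-form AcI example).
- The pipeline is a pure function of (inputs, config, seed); the run
  manifest records every parameter and reruns are byte-identical.
- Problem sizes in the test suite are deliberately small (networks of
  tens of nodes, ≤ 8-node graphs for the exhaustive min-cut oracle, 20
  seeded scenarios of ~70 genes × 90 cells): every quantity checked is
  size-independent or holds by construction, so desk-scale instances
  exercise the same code paths as large datasets.
- The CLI exposes `db`, `expr`, `grn`, `simulate`, `run` and `quantify`
  subcommands; flows, AcI, clustering and GO projection are emitted by
  `run`/`quantify` as files of the report bundle rather than as separate
  subcommands, keeping every quantity one invocation away from raw
  inputs. Exit codes: 0 success, 2 validation error, 3 empty result.

## Known limitations

- Single-gene interactions only; no complexes, cofactors, agonists or
  antagonists, and no TF→TF cascades or path-length variants.
- External signals are assigned unit expression; comparisons of AcI or
  flows between networks with different numbers of external signals
  inherit that convention.
- The percentile cutoffs are global per dataset; very unbalanced group
  sizes shift group means but are otherwise uncorrected.
- k for pair clustering must be chosen by the user.
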