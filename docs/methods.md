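# Methods

## Pipeline model and assumptions

The package treats a multi-herb formula's mechanism as a chain of set and
graph operations over opaque, case-sensitive identifiers. No identifier
namespace mapping (gene symbol ↔ UniProt ↔ Entrez) is performed: all inputs
to one run must share a namespace, which is the caller's responsibility.
PPI data are modeled as an undirected, unweighted simple graph —
self-interactions are dropped and duplicate assertions (in either
orientation) collapse, regardless of source database or interaction type.

### ADME screening

A compound is a candidate iff (OB ≥ ob_min ∧ DL ≥ dl_min) ∨ whitelisted.
Defaults ob_min = 30 (%), dl_min = 0.18 (dimensionless), the conventional
TCMSP-style cutoffs. The comparison is **inclusive** at the boundary; the
screening convention does not specify strictness and inclusive is the
boundary-safe choice (a strict variant is available via
`ScreenConfig(inclusive=False)`). Both cutoffs must hold jointly. The
whitelist is an explicit input column, never a hard-coded compound list.

### Seed networks and the CPPI merge

Seed-network builders attached to PPI databases (e.g. BisoGenet) grow a
network around a seed list by rules that are tool-specific and generally
not recoverable from a methods section. Three bracketing modes are offered:

* `induced` — subgraph on the seeds only (smallest);
* `induced_plus_bridges` (default) — additionally admit any non-seed
  adjacent to ≥ 2 distinct seeds, then take all edges among admitted nodes.
  This is the smallest expansion that grows the node set at all, which is
  the behavior such tools exhibit;
* `first_neighbors` — seeds plus all neighbors, induced (largest).

The two seed networks merge into the CPPI by **node intersection** (default):
nodes present in both networks, with every edge of either network between
them. A `union` mode exists; intersection is the default because the core
network of interest is precisely the part reachable from *both* the drug
and the disease target sets, and published CPPI sizes (smaller than either
input network) are only consistent with intersection.

### Centralities

Six per-node scores, following the CytoNCA conventions:

| metric | definition | notes |
|---|---|---|
| DC | \|N(v)\| | integer |
| BC | Σ_{​{s,t}} σ_st(v)/σ_st | unnormalized, unordered pairs once, disconnected pairs contribute 0 |
| CC | (m−1)/Σ_u d(v,u) within v's m-node component | ∈ [0,1]; isolated node → 0 |
| EC | principal adjacency eigenvector, ‖·‖₂ = 1 | see below |
| NC | Σ_{u∈N(v)} z(v,u)/min(d_v−1, d_u−1) | z = common neighbors; zero denominator contributes 0 |
| LAC | 2·T(v)/d_v | T(v) = triangles through v; d_v = 0 → 0 |

DC, BC and CC are delegated to networkx
(`betweenness_centrality(normalized=False)`,
`closeness_centrality(wf_improved=False)`), which implement exactly these
contracts; the test suite verifies all of them against hand-rolled
brute-force oracles (explicit shortest-path enumeration, hand BFS) on a
library of ≥ 60 small graphs, so the delegation is checked, not assumed.
NC and LAC have no library implementation and are authored here.

EC is computed by power iteration on the full adjacency matrix
(tolerance 1e-10 on the max successive-iterate change, cap 1000
iterations). The iterate applies A + I rather than A: the shift leaves the
eigenvectors unchanged while making the principal eigenvalue strictly
dominant in magnitude, so the iteration also converges on bipartite graphs,
where plain power iteration oscillates between the ±λ₁ eigenvectors. On a
disconnected graph the mass concentrates on the component(s) with the
largest spectral radius; an edgeless graph yields all zeros with a warning.

### Hub selection

Medians are per-metric sample medians over the input table (even length →
mean of the two central order statistics). A hub must **strictly** exceed
all six medians; strictness matters because it caps the selection at
⌊n/2⌋ — strictly exceeding a median is impossible for half the sample on
any one metric. An inclusive option exists but is off by default. Ties are
not broken; selection is purely the six-way conjunction, output sorted.
Medians are always computed over the nodes of the network actually supplied
(for the pipeline: the CPPI), and the thresholds are recorded in the run
summary.

### Enrichment and grouping

The universe defaults to the union of all annotated genes (the convention
of ClueGO-style tools); an explicit universe can be supplied. The query is
restricted to the universe and terms with zero query overlap are omitted —
consequently BH adjustment runs over the terms actually tested. The
significance gate is on the **raw** P value (p ≤ 0.05) by default, matching
the practice this workflow descends from; the BH-adjusted value is always
reported alongside and can be made the gate (`gate_on="adjusted"`).

Kappa between two terms is Cohen's kappa of their membership indicator
vectors over the universe; the degenerate case pₑ = 1 returns 1 for equal
sets and 0 otherwise. Grouping links significant term pairs with
kappa ≥ 0.4 (the documented default of the cited tooling; it is a visible
config value) and takes **connected components** of that graph, rather than
the iterative group-merging heuristic of the original ClueGO tool: the
component rule is simpler, deterministic, and refines monotonically as the
threshold rises. Groups are numbered by their best P value; each group's
leading term is its minimum-P row (ties: larger K, then lexicographic id).

## Synthetic generator

The generator emulates the statistical structure of the database
extractions the pipeline consumes, at desk scale, with planted ground truth
recorded in a manifest. Defaults (all overridable in `SyntheticSpec`):

* **Compound table** — 260 ingredients over five herbs
  (20/55/15/20/150 for BGZ/BZ/FJ/WM/GC), 17 of them assigned to extra
  herbs; joint OB/DL pass probability 0.47 and whitelist probability 0.30
  among failures. These rates were chosen so the candidate accounting
  (~120 filter passes plus ~45 whitelist rescues out of ~260) has the shape
  such screens produce in practice. OB is exponential above/uniform below
  the cutoff, DL likewise; values are rounded to 4 decimals at a safe
  distance from the cutoffs so rounding can never flip a pass.
* **PPI** — Erdős–Rényi background on 300 proteins at edge probability
  0.02, chosen for analyzability (binomial degree expectations make the
  generator testable); a scale-free background would be more realistic for
  degree distributions but is not needed for what the tests measure. A
  20-node module is planted at internal density 0.9 — dense but not a
  literal clique, so hub recovery is a statistical success, not a
  definitional one.
* **Targets** — the drug-target pool is 150 PPI proteins containing the
  planted module; compound degrees follow a truncated Zipf law (exponent
  2.0). The disease set has 60 genes overlapping the drug targets in
  exactly 40, with the planted module inside the overlap: the module plays
  the role of the disease-relevant core that both target sets hit, which
  is what makes it survive the node-intersection merge into the CPPI.
* **Annotations** — 29 background terms of 10–50 random genes plus one
  planted 25-gene term containing 15 of the 20 planted hubs.

All randomness flows through `numpy.random.default_rng` seeded from
`spec.seed` (one independent stream per generator), so every output —
including the written file bundle — is a pure, byte-identical function of
the spec.

What passing tests on this generator do **not** show: robustness to real
PPI degree heterogeneity, to identifier mismatches across databases, to
annotation bias (real GO terms are nested and correlated, synthetic terms
are independent), or to the much larger scale of real interactomes. The
generator validates the machinery, not the biology.

## Problem sizes

The shipped experiments run on 300-node PPI graphs with 20 replicate seeds
for the recovery experiments and 1,000 random tables for the
hypergeometric/Fisher comparison — sizes at which every result is exact or
tightly estimated while the whole suite and the acceptance script each
complete in seconds.

## Numerical choices and degenerate inputs

* Hypergeometric tails go through `scipy.stats.hypergeom.sf` (log-space
  internally); k = 0 returns exactly 1 by construction.
* An empty centrality table raises; an edgeless graph yields zero EC with a
  warning; an empty node intersection during merging warns and returns the
  empty graph; a query disjoint from the universe warns and returns no rows.
* A pipeline stage failure writes a `FAILED` marker, retains partial
  outputs, and raises an error naming the stage.
* The run summary deliberately contains no wall-clock timestamp: reruns on
  identical inputs and config are bit-identical, which is worth more for
  reproducibility than a timing record. Versions and the full config echo
  are included instead.

## Known limitations

* OB/DL values are consumed, never computed; target prediction from
  chemistry is out of scope — the compound→target map is an input.
* No GO DAG structure, evidence codes or term redundancy pruning; the
  enrichment machinery is generic over any GMT.
* The exact expansion rule of seed-network builders attached to specific
  PPI databases is not reproducible; the three modes bracket plausible
  behaviors, and a study's own exported networks can be fed to the
  `topology`/`hubs` stages directly instead of being regenerated.
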