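# netpharm

Network-pharmacology inference for multi-herb formulas.

Traditional multi-herb prescriptions act through many compounds hitting many
protein targets at once, so explaining *how* a formula treats a disease is a
network problem, not a single-target one. `netpharm` implements the standard
network-pharmacology workflow used for this kind of analysis — built around a
five-herb formula (herb codes BGZ, BZ, FJ, WM, GC) studied for the
depigmentation disease vitiligo, but applicable to any formula/disease pair
whose inputs can be expressed as the same tables. It is aimed at
computational biologists who want the screening, network construction, hub
selection and enrichment steps as tested, scriptable library code instead of
a chain of GUI tools (Cytoscape, CytoNCA, ClueGO).

## The method

1. **ADME screen.** Each herb ingredient has an oral bioavailability OB (%)
   and a drug-likeness index DL ∈ [0, 1]. Candidates satisfy
   OB ≥ 30 ∧ DL ≥ 0.18, with an explicit whitelist override for compounds
   (e.g. psoralen, angelicin) that fail the cutoffs but have well-documented
   activity.
2. **Compound–target network.** Candidates link to their predicted protein
   targets in a bipartite graph; compound degree flags the pleiotropic
   ingredients, and the intersection of the predicted targets with known
   disease targets gives the directly disease-relevant subset.
3. **PPI seed networks and the CPPI.** From a background protein–protein
   interaction snapshot, seed networks are grown around the drug-target set
   and the disease-target set (default: seeds plus any protein bridging ≥ 2
   seeds) and merged by node intersection into the **core PPI (CPPI)**
   network.
4. **Six-centrality hub selection.** For every CPPI node six centralities
   are computed — degree (DC), unnormalized betweenness (BC),
   component-relative closeness (CC), eigenvector (EC, ‖·‖₂ = 1), network
   centrality (NC, the sum of edge clustering coefficients
   z(u,v)/min(d_u−1, d_v−1) over incident edges) and local average
   connectivity (LAC, = 2·triangles(v)/d_v). A **hub** is a node whose six
   values all *strictly* exceed the network-wide medians; with strict
   comparison at most ⌊n/2⌋ nodes can qualify.
5. **Enrichment.** The hub set is tested against term annotations with the
   upper-tail hypergeometric probability
   P(X ≥ k) = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n) (universe N, term size K,
   query size n, overlap k), Benjamini–Hochberg adjusted; significant terms
   are grouped ClueGO-style by linking term pairs whose membership kappa
   ≥ 0.4 and taking connected components, each led by its lowest-P term.

A seeded synthetic generator (`netpharm.synth`) produces the full input
bundle with planted ground truth — a known screening outcome, a dense
20-node module planted in the PPI (the true hubs), an exact disease overlap,
and one planted enriched term — so the pipeline is testable end to end
without any database access.

## Worked example

```sh
netpharm simulate --seed 5 --out demo/inputs
# wrote bundle to demo/inputs: 260 compounds, PPI 300/1062, 20 planted hubs

cat > demo/config.yaml <<EOF
inputs:
  compounds: demo/inputs/compounds.tsv
  compound_targets: demo/inputs/compound_targets.tsv
  disease_targets: demo/inputs/disease_targets.txt
  ppi: demo/inputs/ppi.sif
  annotations: demo/inputs/annotations.gmt
output:
  out_dir: demo/out
EOF

netpharm run-all --config demo/config.yaml
# done: 155 candidates, CPPI 137/465, 26 hubs, 1 significant terms in 1 groups
```

Reading the output: of 260 synthetic ingredients, 155 pass the OB/DL screen
(whitelist rescues included); their 150 predicted targets overlap the
60-gene disease set in 40 genes; the two seed networks intersect in a
137-node, 465-edge CPPI; 26 nodes strictly exceed all six centrality
medians (the planted 20-node module is recovered among them), and the
planted term is the single significant enrichment hit. Per-stage artifacts
(`candidates.tsv`, `cppi.sif`, `centrality.tsv`, `hubs.txt`,
`enrichment.tsv`, `run_summary.json`) land in `demo/out/`; the same stages
are runnable individually via the `screen`, `build-net`, `ppi`, `topology`,
`hubs` and `enrich` subcommands, so a study's own exported tables can be
substituted at any point.

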