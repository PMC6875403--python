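"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the database extractions a real study feeds into the
pipeline, with planted ground truth so every downstream stage can be scored:

* a five-herb compound table whose OB/DL values straddle the screening
  cutoffs, with a known pass fraction and a whitelisted subset of failures;
* a compound-target bipartite map with heavy-tailed (truncated power-law)
  compound degrees;
* a sparse background PPI graph (Erdos-Renyi by default) containing a
  planted densely connected module — the ground-truth hubs;
* a disease-target set overlapping the drug targets in an exact, known
  number of genes, with the planted module inside the overlap so it
  survives the node-intersection merge into the CPPI;
* term annotations containing one planted term over-representing the
  planted hubs among random background terms.

All randomness flows through seeded generators derived from ``spec.seed``;
every output is a pure function of the spec.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from netpharm.bipartite import CompoundTargetMap
from netpharm.ppi import PPIGraph, build_graph
from netpharm.screen import KBL_HERBS, CompoundRecord

_DEFAULT_PER_HERB = {"BGZ": 20, "BZ": 55, "FJ": 15, "WM": 20, "GC": 150}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults are scaled to the five-herb formula the pipeline was built
    around: ~260 raw ingredients across herbs with roughly half passing the
    joint OB/DL screen and ~30% of failures whitelisted (so candidate
    counts land near the 123 + 45 split such screens produce), a 300-node
    background PPI at edge probability 0.02 with a 20-node module planted
    at density 0.9, and a disease set of 60 genes overlapping the drug
    targets in exactly 40 (containing the planted module).
    """

    seed: int = 42
    n_compounds_per_herb: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PER_HERB)
    )
    n_multi_herb: int = 17
    ob_pass_fraction: float = 0.47
    whitelist_fraction: float = 0.30
    n_targets: int = 150
    target_degree_exponent: float = 2.0
    ppi_n_background: int = 300
    ppi_edge_prob: float = 0.02
    planted_hub_count: int = 20
    planted_density: float = 0.9
    disease_overlap_count: int = 40
    n_disease_targets: int = 60
    n_terms: int = 30
    planted_term_size: int = 25
    planted_term_hub_overlap: int = 15

    def __post_init__(self) -> None:
        for name in (
            "n_multi_herb",
            "n_targets",
            "ppi_n_background",
            "planted_hub_count",
            "disease_overlap_count",
            "n_disease_targets",
            "n_terms",
            "planted_term_size",
            "planted_term_hub_overlap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ob_pass_fraction", "whitelist_fraction", "ppi_edge_prob", "planted_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_degree_exponent <= 1.0:
            raise ValueError("target_degree_exponent must be > 1")
        if self.planted_hub_count and self.planted_density <= self.ppi_edge_prob:
            raise ValueError("planted_density must exceed ppi_edge_prob")
        if self.planted_hub_count >= self.ppi_n_background:
            raise ValueError("planted_hub_count must be < ppi_n_background")
        if self.n_targets > self.ppi_n_background:
            raise ValueError("n_targets cannot exceed ppi_n_background")
        if self.disease_overlap_count > self.n_disease_targets:
            raise ValueError("disease_overlap_count cannot exceed n_disease_targets")
        if self.planted_term_hub_overlap > min(self.planted_term_size, self.planted_hub_count):
            raise ValueError("planted_term_hub_overlap exceeds term or hub size")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _gen_compounds(spec: SyntheticSpec) -> tuple[list[CompoundRecord], dict]:
    rng = _rng(spec, 1)
    herbs = [h for h in KBL_HERBS if h in spec.n_compounds_per_herb]
    herbs += sorted(set(spec.n_compounds_per_herb) - set(KBL_HERBS))

    primary: list[str] = []
    for h in herbs:
        primary.extend([h] * spec.n_compounds_per_herb[h])
    n = len(primary)
    memberships: list[set[str]] = [{h} for h in primary]
    if n and spec.n_multi_herb:
        multi_idx = rng.choice(n, size=min(spec.n_multi_herb, n), replace=False)
        for i in multi_idx:
            extra_n = int(rng.integers(1, 3))
            pool = [h for h in herbs if h not in memberships[i]]
            for h in rng.choice(len(pool), size=min(extra_n, len(pool)), replace=False):
                memberships[i].add(pool[h])

    records: list[CompoundRecord] = []
    cand_flags: list[bool] = []
    n_pass = n_rescued = 0
    for i in range(n):
        passes = rng.random() < spec.ob_pass_fraction
        if passes:
            ob = 30.0 + float(rng.exponential(25.0))
            dl = min(1.0, 0.18 + float(rng.exponential(0.15)))
            whitelisted = False
            n_pass += 1
        else:
            mode = rng.choice(["ob", "dl", "both"])
            ob_low = float(rng.uniform(1.0, 29.9))
            dl_low = float(rng.uniform(0.01, 0.17))
            if mode == "ob":
                ob, dl = ob_low, min(1.0, 0.18 + float(rng.exponential(0.15)))
            elif mode == "dl":
                ob, dl = 30.0 + float(rng.exponential(25.0)), dl_low
            else:
                ob, dl = ob_low, dl_low
            whitelisted = bool(rng.random() < spec.whitelist_fraction)
            if whitelisted:
                n_rescued += 1
        records.append(
            CompoundRecord(
                compound_id=f"C{i + 1:04d}",
                name=f"compound-{i + 1:04d}",
                herbs=frozenset(memberships[i]),
                ob=round(ob, 4),
                dl=round(dl, 4),
                whitelisted=whitelisted,
            )
        )
        cand_flags.append(passes or whitelisted)

    candidate = [r for r, is_cand in zip(records, cand_flags) if is_cand]
    per_herb = {h: sum(1 for r in candidate if h in r.herbs) for h in herbs}
    truth = {
        "n_input": n,
        "n_pass_filter": n_pass,
        "n_whitelisted_rescues": n_rescued,
        "n_candidates": n_pass + n_rescued,
        "candidate_ids": sorted(r.compound_id for r in candidate),
        "per_herb_counts": per_herb,
        "n_shared": sum(1 for r in candidate if len(r.herbs) >= 2),
    }
    return records, truth


def gen_compound_table(spec: SyntheticSpec) -> list[CompoundRecord]:
    """Synthetic herb-ingredient table with known screening ground truth."""
    return _gen_compounds(spec)[0]


def gen_ppi(spec: SyntheticSpec) -> tuple[PPIGraph, frozenset[str]]:
    """Background PPI with a planted dense module; returns (graph, planted)."""
    rng = _rng(spec, 2)
    nodes = [f"G{i + 1:04d}" for i in range(spec.ppi_n_background)]
    planted = sorted(
        nodes[i] for i in rng.choice(spec.ppi_n_background, size=spec.planted_hub_count, replace=False)
    )
    planted_set = set(planted)

    iu, ju = np.triu_indices(spec.ppi_n_background, k=1)
    mask = rng.random(iu.shape[0]) < spec.ppi_edge_prob
    pairs = [(nodes[i], nodes[j]) for i, j in zip(iu[mask], ju[mask])]
    for a in range(len(planted)):
        for b in range(a + 1, len(planted)):
            if rng.random() < spec.planted_density:
                pairs.append((planted[a], planted[b]))
    graph = build_graph(pairs)
    # planted nodes missing every coin flip would vanish with the isolated
    # nodes; keep them so the ground truth is always part of the graph
    return (
        PPIGraph(nodes=graph.nodes | frozenset(planted_set), edges=graph.edges),
        frozenset(planted_set),
    )


def _target_pool(spec: SyntheticSpec) -> list[str]:
    rng = _rng(spec, 3)
    graph, planted = gen_ppi(spec)
    others = sorted(graph.nodes - planted)
    extra_n = max(0, spec.n_targets - len(planted))
    extra = [others[i] for i in rng.choice(len(others), size=min(extra_n, len(others)), replace=False)]
    return sorted(set(planted) | set(extra))


def gen_compound_target_map(spec: SyntheticSpec) -> CompoundTargetMap:
    """Bipartite map with truncated power-law compound degrees.

    Targets are drawn from a pool of PPI nodes that contains the planted
    module; every planted node is guaranteed at least one compound, and
    every candidate compound at least one target.
    """
    rng = _rng(spec, 4)
    _, truth = _gen_compounds(spec)
    cand_ids = truth["candidate_ids"]
    pool = _target_pool(spec)
    _, planted = gen_ppi(spec)

    edges: set[tuple[str, str]] = set()
    for cid in cand_ids:
        deg = int(min(rng.zipf(spec.target_degree_exponent), len(pool)))
        picks = rng.choice(len(pool), size=deg, replace=False)
        edges.update((cid, pool[i]) for i in picks)

    covered = {t for _, t in edges}
    for hub in sorted(planted - covered):
        if cand_ids:
            cid = cand_ids[int(rng.integers(len(cand_ids)))]
            edges.add((cid, hub))
    return CompoundTargetMap(edges=frozenset(edges))


def gen_disease_targets(spec: SyntheticSpec) -> frozenset[str]:
    """Disease set overlapping the drug targets in exactly the spec'd count.

    The planted module sits inside the overlap (the disease-relevant core
    hit by both target sets), padded with random drug targets up to the
    overlap count and with non-drug PPI genes up to the set size.
    """
    rng = _rng(spec, 5)
    graph, planted = gen_ppi(spec)
    drug_targets = set(gen_compound_target_map(spec).targets())

    core = sorted(planted & drug_targets)[: spec.disease_overlap_count]
    rest = sorted(drug_targets - set(core))
    pad_n = spec.disease_overlap_count - len(core)
    overlap = set(core)
    if pad_n > 0 and rest:
        overlap |= {rest[i] for i in rng.choice(len(rest), size=min(pad_n, len(rest)), replace=False)}

    non_drug = sorted(graph.nodes - drug_targets)
    out_n = spec.n_disease_targets - len(overlap)
    outside = set()
    if out_n > 0 and non_drug:
        outside = {non_drug[i] for i in rng.choice(len(non_drug), size=min(out_n, len(non_drug)), replace=False)}
    return frozenset(overlap | outside)


def gen_annotations(spec: SyntheticSpec):
    """Term annotations with one planted term enriched for the planted hubs."""
    from netpharm.io import GeneSetCollection

    rng = _rng(spec, 6)
    graph, planted = gen_ppi(spec)
    universe = sorted(graph.nodes)
    planted_l = sorted(planted)
    non_hub = sorted(graph.nodes - planted)

    entries = []
    for t in range(1, spec.n_terms):
        size = int(rng.integers(10, 51))
        size = min(size, len(universe))
        genes = frozenset(universe[i] for i in rng.choice(len(universe), size=size, replace=False))
        entries.append((f"SYN:{t:04d}", f"background term {t}", genes))

    k = min(spec.planted_term_hub_overlap, len(planted_l))
    hub_part = [planted_l[i] for i in rng.choice(len(planted_l), size=k, replace=False)]
    fill_n = min(spec.planted_term_size - k, len(non_hub))
    fill = [non_hub[i] for i in rng.choice(len(non_hub), size=fill_n, replace=False)]
    entries.append(("SYN:PLANTED", "planted enriched term", frozenset(hub_part) | frozenset(fill)))
    return GeneSetCollection(entries=tuple(entries))


def gen_all(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write the full input bundle plus a ground-truth manifest.

    Files: ``compounds.tsv``, ``compound_targets.tsv``, ``disease_targets.txt``,
    ``ppi.sif``, ``annotations.gmt``, ``universe.txt``, ``manifest.json``.
    Byte-identical across runs with the same spec.
    """
    from netpharm import io as npio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, truth = _gen_compounds(spec)
    graph, planted = gen_ppi(spec)
    ctmap = gen_compound_target_map(spec)
    disease = gen_disease_targets(spec)
    annotations = gen_annotations(spec)

    npio.write_compound_table(records, out / "compounds.tsv")
    with open(out / "compound_targets.tsv", "w", encoding="utf-8") as fh:
        fh.write("#compound_id\ttarget_id\n")
        for c, t in sorted(ctmap.edges):
            fh.write(f"{c}\t{t}\n")
    npio.write_id_list(disease, out / "disease_targets.txt")
    npio.write_network(graph, out / "ppi.sif", "sif")
    npio.write_gmt(annotations, out / "annotations.gmt")
    npio.write_id_list(graph.nodes, out / "universe.txt")

    manifest = {
        "spec": asdict(spec),
        "screen_truth": truth,
        "planted_hubs": sorted(planted),
        "planted_term": {
            "id": "SYN:PLANTED",
            "size": len(annotations.genes_of("SYN:PLANTED")),
            "hub_overlap": len(annotations.genes_of("SYN:PLANTED") & planted),
        },
        "n_drug_targets": len(ctmap.targets()),
        "disease_overlap_count": len(set(ctmap.targets()) & disease),
        "n_disease_targets": len(disease),
        "ppi": {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges},
        "files": {
            "compounds": "compounds.tsv",
            "compound_targets": "compound_targets.tsv",
            "disease_targets": "disease_targets.txt",
            "ppi": "ppi.sif",
            "annotations": "annotations.gmt",
            "universe": "universe.txt",
        },
    }
    npio.write_json(manifest, out / "manifest.json")
    return manifest


def bundle_digest(out_dir: str | Path) -> str:
    """SHA-256 over the bundle's files, for determinism checks."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
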