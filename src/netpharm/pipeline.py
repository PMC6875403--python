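"""End-to-end orchestration of the network-pharmacology workflow.

Stages run in order — ADME screen, compound-target network, disease
overlap, drug/disease seed PPI networks, CPPI merge, six-centrality hub
selection, enrichment with kappa grouping — communicating through files so
any stage's input can be substituted (e.g. with a study's own exported
tables).  Every run writes a machine-readable :class:`RunSummary`; reruns
with identical inputs and config are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from netpharm import __version__
from netpharm import io as npio
from netpharm.bipartite import (
    CompoundTargetMap,
    build_bipartite,
    compound_degrees,
    disease_overlap,
    herb_target_counts,
    high_degree_compounds,
)
from netpharm.enrichment import (
    EnrichmentConfig,
    enrich,
    group_terms,
    write_enrichment_table,
)
from netpharm.ppi import MergeConfig, SeedNetworkConfig, build_graph, merge_networks, seed_network
from netpharm.screen import ScreenConfig, screen_compounds, screen_summary
from netpharm.topology import centrality_table, median_thresholds, select_hubs

logger = logging.getLogger("netpharm")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths and per-stage settings of one pipeline run."""

    compounds: str
    compound_targets: str
    disease_targets: str
    ppi: str
    annotations: str
    out_dir: str
    universe: str | None = None
    ppi_format: str = "sif"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed_mode: SeedNetworkConfig = field(default_factory=SeedNetworkConfig)
    merge_mode: MergeConfig = field(default_factory=MergeConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    degree_threshold: int = 20
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a sectioned key-value config file.

        Sections: ``inputs`` (compounds, compound_targets, disease_targets,
        ppi, annotations, universe, ppi_format), ``screen`` (ob_min, dl_min,
        inclusive), ``network`` (seed_mode, merge_mode, degree_threshold),
        ``enrichment`` (p_cutoff, kappa_threshold, gate_on, universe_mode),
        ``output`` (out_dir, log_level, seed).
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        screen = raw.get("screen", {})
        net = raw.get("network", {})
        enr = raw.get("enrichment", {})
        out = raw.get("output", {})
        enr_kwargs = {
            k: enr[k]
            for k in ("p_cutoff", "kappa_threshold", "gate_on", "universe_mode")
            if k in enr
        }
        return cls(
            compounds=inputs["compounds"],
            compound_targets=inputs["compound_targets"],
            disease_targets=inputs["disease_targets"],
            ppi=inputs["ppi"],
            annotations=inputs["annotations"],
            universe=inputs.get("universe"),
            ppi_format=inputs.get("ppi_format", "sif"),
            screen=ScreenConfig(
                ob_min=float(screen.get("ob_min", 30.0)),
                dl_min=float(screen.get("dl_min", 0.18)),
                inclusive=bool(screen.get("inclusive", True)),
            ),
            seed_mode=SeedNetworkConfig(mode=net.get("seed_mode", "induced_plus_bridges")),
            merge_mode=MergeConfig(mode=net.get("merge_mode", "node_intersection")),
            enrichment=EnrichmentConfig(**enr_kwargs),
            degree_threshold=int(net.get("degree_threshold", 20)),
            out_dir=out.get("out_dir", "netpharm_out"),
            log_level=out.get("log_level", "INFO"),
            seed=int(out.get("seed", 0)),
        )


@dataclass(frozen=True)
class RunSummary:
    """Per-stage counts of a successful run, plus config echo and version."""

    n_input_compounds: int
    n_candidates: int
    n_whitelisted_rescues: int
    per_herb_counts: dict[str, int]
    n_shared_compounds: int
    n_potential_targets: int
    n_bipartite_nodes: int
    n_bipartite_edges: int
    n_high_degree_compounds: int
    herb_target_counts: dict[str, int]
    n_disease_targets: int
    n_overlap: int
    drug_net: dict[str, int]
    disease_net: dict[str, int]
    cppi: dict[str, int]
    medians: dict[str, float]
    n_hubs: int
    n_terms_tested: int
    n_significant_terms: int
    n_groups: int
    config: dict
    version: str

    def check_consistency(self) -> None:
        """Raise if the internal count constraints are violated."""
        assert self.n_candidates <= self.n_input_compounds
        assert self.n_overlap <= min(self.n_potential_targets, self.n_disease_targets)
        assert self.n_hubs <= self.cppi["n_nodes"]
        assert self.n_significant_terms <= self.n_terms_tested
        assert self.n_groups <= self.n_significant_terms or self.n_significant_terms == 0
        assert self.cppi["n_nodes"] <= min(
            self.drug_net["n_nodes"], self.disease_net["n_nodes"]
        ) or self.config["merge_mode"] == "union"


def _stage(name: str, out_dir: Path):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> RunSummary:
    """Execute the whole workflow and write all artifacts to ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    with _stage("screen", out):
        records = npio.read_compound_table(config.compounds)
        candidates, _rejected = screen_compounds(records, config.screen)
        herbs = tuple(sorted({h for r in records for h in r.herbs}))
        scr = screen_summary(records, candidates, config.screen, herbs)
        npio.write_compound_table(candidates, out / "candidates.tsv")
        npio.write_json(scr, out / "screen_summary.json")
        logger.info(
            "stage screen: %d compounds in, %d candidates (%d rescued)",
            scr["n_input"], scr["n_candidates"], scr["n_whitelisted_rescues"],
        )

    with _stage("bipartite", out):
        pairs = npio.read_edge_list(config.compound_targets, "tsv2")
        ctmap = CompoundTargetMap.from_pairs(pairs).restrict_to(
            {r.compound_id for r in candidates}
        )
        net = build_bipartite(candidates, ctmap)
        degrees = compound_degrees(net)
        high = high_degree_compounds(net, config.degree_threshold)
        htc = herb_target_counts(candidates, ctmap)
        with open(out / "compound_degrees.tsv", "w", encoding="utf-8") as fh:
            fh.write("compound_id\tdegree\n")
            for c in sorted(degrees):
                fh.write(f"{c}\t{degrees[c]}\n")
        with open(out / "bipartite.sif", "w", encoding="utf-8") as fh:
            for c, t in sorted(net.edges):
                fh.write(f"{c}\tct\t{t}\n")
        potential = set(net.target_nodes)
        logger.info(
            "stage bipartite: %d nodes, %d edges, %d potential targets",
            net.n_nodes, net.n_edges, len(potential),
        )

    with _stage("overlap", out):
        disease = npio.read_id_list(config.disease_targets)
        overlap = disease_overlap(potential, disease)
        npio.write_id_list(overlap, out / "overlap_targets.txt")
        logger.info(
            "stage overlap: %d potential vs %d disease -> %d shared",
            len(potential), len(disease), len(overlap),
        )

    with _stage("ppi", out):
        if config.ppi_format == "sif":
            ppi = npio.read_network(config.ppi, "sif")
        else:
            ppi = build_graph(npio.read_edge_list(config.ppi, config.ppi_format))
        drug_net = seed_network(ppi, potential, config.seed_mode)
        disease_net = seed_network(ppi, set(disease), config.seed_mode)
        cppi = merge_networks(drug_net, disease_net, config.merge_mode)
        npio.write_network(drug_net, out / "drug_net.sif", "sif")
        npio.write_network(disease_net, out / "disease_net.sif", "sif")
        npio.write_network(cppi, out / "cppi.sif", "sif")
        logger.info(
            "stage ppi: drug %d/%d, disease %d/%d, cppi %d/%d (merge=%s)",
            drug_net.n_nodes, drug_net.n_edges,
            disease_net.n_nodes, disease_net.n_edges,
            cppi.n_nodes, cppi.n_edges, config.merge_mode.mode,
        )

    with _stage("topology", out):
        table = centrality_table(cppi)
        npio.write_centrality_table(table, out / "centrality.tsv")
        thr = median_thresholds(table) if table else None
        hubs = select_hubs(table, thr) if thr else []
        medians = (
            {
                "dc": thr.dc_med, "bc": thr.bc_med, "cc": thr.cc_med,
                "ec": thr.ec_med, "nc": thr.nc_med, "lac": thr.lac_med,
            }
            if thr
            else {}
        )
        npio.write_json({"medians": medians, "strict": True}, out / "thresholds.json")
        npio.write_id_list(hubs, out / "hubs.txt")
        logger.info("stage topology: %d nodes scored, %d hubs", len(table), len(hubs))

    with _stage("enrich", out):
        annotations = npio.read_gmt(config.annotations)
        enr_config = config.enrichment
        if config.universe is not None:
            enr_config = EnrichmentConfig(
                p_cutoff=enr_config.p_cutoff,
                kappa_threshold=enr_config.kappa_threshold,
                universe_mode="explicit",
                universe=frozenset(npio.read_id_list(config.universe)),
                gate_on=enr_config.gate_on,
            )
        if hubs:
            rows = enrich(set(hubs), annotations, enr_config)
            rows = group_terms(rows, annotations, enr_config)
        else:
            rows = []
        write_enrichment_table(rows, out / "enrichment.tsv")
        sig = [r for r in rows if r.significant]
        groups = sorted({r.group_id for r in sig if r.group_id is not None})
        npio.write_json(
            {
                "n_tested": len(rows),
                "n_significant": len(sig),
                "n_groups": len(groups),
                "leading_terms": sorted(r.term_id for r in sig if r.leading),
            },
            out / "groups.json",
        )
        logger.info(
            "stage enrich: %d terms tested, %d significant in %d groups",
            len(rows), len(sig), len(groups),
        )

    summary = RunSummary(
        n_input_compounds=scr["n_input"],
        n_candidates=scr["n_candidates"],
        n_whitelisted_rescues=scr["n_whitelisted_rescues"],
        per_herb_counts=scr["per_herb_counts"],
        n_shared_compounds=scr["n_shared"],
        n_potential_targets=len(potential),
        n_bipartite_nodes=net.n_nodes,
        n_bipartite_edges=net.n_edges,
        n_high_degree_compounds=len(high),
        herb_target_counts=htc,
        n_disease_targets=len(disease),
        n_overlap=len(overlap),
        drug_net={"n_nodes": drug_net.n_nodes, "n_edges": drug_net.n_edges},
        disease_net={"n_nodes": disease_net.n_nodes, "n_edges": disease_net.n_edges},
        cppi={"n_nodes": cppi.n_nodes, "n_edges": cppi.n_edges},
        medians=medians,
        n_hubs=len(hubs),
        n_terms_tested=len(rows),
        n_significant_terms=len(sig),
        n_groups=len(groups),
        config={
            "screen": asdict(config.screen),
            "seed_mode": config.seed_mode.mode,
            "merge_mode": config.merge_mode.mode,
            "enrichment": {
                "p_cutoff": config.enrichment.p_cutoff,
                "kappa_threshold": config.enrichment.kappa_threshold,
                "gate_on": config.enrichment.gate_on,
            },
            "degree_threshold": config.degree_threshold,
            "seed": config.seed,
        },
        version=__version__,
    )
    summary.check_consistency()
    npio.write_json(asdict(summary), out / "run_summary.json")
    return summary
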