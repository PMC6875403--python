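"""Compound-target bipartite network and disease-target overlap.

Candidate compounds are linked to their predicted protein targets in a
bipartite graph; per-compound degrees identify the pleiotropic ingredients,
per-herb target unions summarize each herb's reach, and the intersection of
the predicted ("potential") targets with the known disease-associated
targets gives the directly disease-relevant subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from netpharm.screen import CompoundRecord


@dataclass(frozen=True)
class CompoundTargetMap:
    """Deduplicated set of (compound_id, target_id) assertions."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "CompoundTargetMap":
        return cls(edges=frozenset((c, t) for c, t in pairs))

    def compounds(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.edges)

    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    def restrict_to(self, compound_ids: set[str]) -> "CompoundTargetMap":
        return CompoundTargetMap(
            edges=frozenset(e for e in self.edges if e[0] in compound_ids)
        )


@dataclass(frozen=True)
class BipartiteNetwork:
    """Bipartite compound-target graph over two disjoint node sets."""

    compound_nodes: frozenset[str]
    target_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.compound_nodes & self.target_nodes:
            clash = sorted(self.compound_nodes & self.target_nodes)[:5]
            raise ValueError(f"compound and target node sets overlap: {clash}")
        for c, t in self.edges:
            if c not in self.compound_nodes or t not in self.target_nodes:
                raise ValueError(f"edge {(c, t)!r} has endpoint outside the node sets")

    @property
    def n_nodes(self) -> int:
        return len(self.compound_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_bipartite(
    candidates: list[CompoundRecord],
    ctmap: CompoundTargetMap,
    keep_isolated: bool = False,
) -> BipartiteNetwork:
    """Assemble the compound-target network from screened candidates.

    By default only compounds with at least one predicted target (and only
    targets with at least one edge) appear as nodes; ``keep_isolated=True``
    additionally declares every candidate compound as a node.

    Raises
    ------
    ValueError
        If the map references a compound that is not a candidate.
    """
    cand_ids = {r.compound_id for r in candidates}
    unknown = ctmap.compounds() - cand_ids
    if unknown:
        raise ValueError(
            f"compound-target map references non-candidate compound(s): {sorted(unknown)[:5]}"
        )
    compound_nodes = set(ctmap.compounds())
    if keep_isolated:
        compound_nodes |= cand_ids
    return BipartiteNetwork(
        compound_nodes=frozenset(compound_nodes),
        target_nodes=ctmap.targets(),
        edges=ctmap.edges,
    )


def compound_degrees(net: BipartiteNetwork) -> dict[str, int]:
    """Distinct-target count per compound (isolated compounds absent)."""
    deg: dict[str, int] = {}
    for c, _ in net.edges:
        deg[c] = deg.get(c, 0) + 1
    return deg


def high_degree_compounds(net: BipartiteNetwork, threshold: int = 20) -> list[str]:
    """Compounds with degree >= threshold, sorted by descending degree then id."""
    deg = compound_degrees(net)
    hits = [c for c, d in deg.items() if d >= threshold]
    return sorted(hits, key=lambda c: (-deg[c], c))


def herb_target_counts(
    candidates: list[CompoundRecord], ctmap: CompoundTargetMap
) -> dict[str, int]:
    """Per-herb count of distinct targets hit by the herb's candidates."""
    targets_by_compound: dict[str, set[str]] = {}
    for c, t in ctmap.edges:
        targets_by_compound.setdefault(c, set()).add(t)
    herb_targets: dict[str, set[str]] = {}
    for rec in candidates:
        tset = targets_by_compound.get(rec.compound_id, set())
        for h in rec.herbs:
            herb_targets.setdefault(h, set()).update(tset)
    return {h: len(ts) for h, ts in sorted(herb_targets.items())}


def disease_overlap(potential_targets: set[str], disease_targets: set[str]) -> list[str]:
    """Sorted intersection of predicted and disease-associated targets."""
    return sorted(potential_targets & disease_targets)
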