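"""Hypergeometric over-representation testing with kappa-statistic grouping.

A query gene set (here: the hub targets) is tested against each annotated
term: with a universe of N genes of which K carry the term and a query of n
genes, the enrichment P value is the upper tail P(X >= k) of the
hypergeometric distribution at the observed overlap k.  Significant terms
are then clustered ClueGO-style: two terms are linked when the
chance-corrected agreement (Cohen's kappa) of their gene memberships over
the universe reaches a threshold, and connected components of that term
graph form the functional groups, each represented by its lowest-P
("leading") term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from netpharm.io import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the enrichment and grouping steps.

    ``p_cutoff`` gates significance on the raw P value by default (set
    ``gate_on="adjusted"`` to gate on the Benjamini-Hochberg value instead).
    ``universe_mode="annotated_union"`` takes the universe as the union of
    all annotated genes; ``"explicit"`` requires ``universe``.
    ``kappa_threshold`` is the minimum kappa for linking two terms.
    """

    p_cutoff: float = 0.05
    kappa_threshold: float = 0.4
    universe_mode: Literal["annotated_union", "explicit"] = "annotated_union"
    universe: frozenset[str] | None = None
    gate_on: Literal["raw", "adjusted"] = "raw"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValueError(f"p_cutoff must be in (0, 1), got {self.p_cutoff}")
        if not 0.0 <= self.kappa_threshold <= 1.0:
            raise ValueError(f"kappa_threshold must be in [0, 1], got {self.kappa_threshold}")
        if self.universe_mode == "explicit" and not self.universe:
            raise ValueError("universe_mode='explicit' requires a universe")


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's test result (and, after grouping, its group assignment)."""

    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    adj_p: float
    significant: bool
    group_id: int | None = None
    leading: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValueError(
                f"{self.term_id}: inconsistent counts k={self.k} K={self.K} "
                f"n={self.n} N={self.N}"
            )


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed via the survival function for numerical stability; k = 0
    returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _resolve_universe(terms: GeneSetCollection, config: EnrichmentConfig) -> frozenset[str]:
    if config.universe_mode == "explicit":
        assert config.universe is not None
        return frozenset(config.universe)
    return terms.all_genes()


def enrich(
    query: set[str], terms: GeneSetCollection, config: EnrichmentConfig | None = None
) -> list[EnrichmentRow]:
    """Test every annotated term for over-representation in ``query``.

    The query is restricted to the universe; terms with no query overlap
    (k = 0) are omitted.  Benjamini-Hochberg adjusted P values are computed
    over all tested terms.  Rows are sorted by ascending P then term id.
    """
    if not query:
        raise ValueError("query gene set is empty")
    config = config or EnrichmentConfig()
    universe = _resolve_universe(terms, config)
    q = frozenset(query) & universe
    if not q:
        warnings.warn("query has no genes in the universe; nothing to test", stacklevel=2)
        return []
    n, big_n = len(q), len(universe)

    tested: list[tuple[str, str, int, int, float]] = []
    for set_id, desc, genes in terms.entries:
        gset = genes & universe
        k = len(q & gset)
        if k == 0 or not gset:
            continue
        p = hypergeom_upper_tail(k, len(gset), n, big_n)
        tested.append((set_id, desc, k, len(gset), p))
    if not tested:
        return []

    pvals = [t[4] for t in tested]
    adj = multipletests(pvals, method="fdr_bh")[1]
    rows = []
    for (set_id, desc, k, big_k, p), ap in zip(tested, adj):
        gate_p = p if config.gate_on == "raw" else float(ap)
        rows.append(
            EnrichmentRow(
                term_id=set_id,
                name=desc,
                k=k,
                K=big_k,
                n=n,
                N=big_n,
                p_value=p,
                adj_p=float(ap),
                significant=gate_p <= config.p_cutoff,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def kappa_score(a: set[str], b: set[str], universe: set[str]) -> float:
    """Cohen's kappa of two sets' membership indicators over a universe.

    Chance-corrected agreement of the 2x2 membership table; 1 for identical
    sets, <= 0 for independence or worse.  In the degenerate case of chance
    agreement 1 (both sets empty or both the full universe), returns 1.0
    when the sets are equal and 0.0 otherwise.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not (a <= universe and b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    both = len(a & b)
    neither = n - len(a | b)
    po = (both + neither) / n
    pe = (len(a) * len(b) + (n - len(a)) * (n - len(b))) / (n * n)
    if pe == 1.0:
        return 1.0 if a == b else 0.0
    return (po - pe) / (1.0 - pe)


def group_terms(
    rows: list[EnrichmentRow],
    terms: GeneSetCollection,
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentRow]:
    """Assign significant terms to kappa-similarity groups.

    A term graph links two significant terms when the kappa of their
    (universe-restricted) gene sets is >= ``kappa_threshold``; groups are
    the connected components, numbered from 1 in order of their best P value
    (ties broken by term id).  Within each group the leading term has the
    minimal P value (ties: larger K, then lexicographic term id).
    Non-significant rows pass through with no group.
    """
    config = config or EnrichmentConfig()
    universe = _resolve_universe(terms, config)
    sig = [r for r in rows if r.significant]
    if not sig:
        return list(rows)

    gsets = {r.term_id: terms.genes_of(r.term_id) & universe for r in sig}
    tg = nx.Graph()
    tg.add_nodes_from(gsets)
    ids = sorted(gsets)
    for i, t1 in enumerate(ids):
        for t2 in ids[i + 1 :]:
            if kappa_score(set(gsets[t1]), set(gsets[t2]), set(universe)) >= config.kappa_threshold:
                tg.add_edge(t1, t2)

    by_id = {r.term_id: r for r in sig}
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(tg)),
        key=lambda comp: min((by_id[t].p_value, t) for t in comp),
    )
    assignment: dict[str, tuple[int, bool]] = {}
    for gid, comp in enumerate(components, start=1):
        lead = min(comp, key=lambda t: (by_id[t].p_value, -by_id[t].K, t))
        for t in comp:
            assignment[t] = (gid, t == lead)

    out = []
    for r in rows:
        if r.term_id in assignment:
            gid, lead = assignment[r.term_id]
            out.append(replace(r, group_id=gid, leading=lead))
        else:
            out.append(r)
    return out


def write_enrichment_table(rows: list[EnrichmentRow], path) -> None:
    """TSV export: term_id, name, k, K, n, N, p, adj_p, significant, group, leading."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tname\tk\tK\tn\tN\tp_value\tadj_p\tsignificant\tgroup\tleading\n")
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_value:.10g}\t{r.adj_p:.10g}"
                f"\t{'true' if r.significant else 'false'}"
                f"\t{r.group_id if r.group_id is not None else ''}"
                f"\t{'true' if r.leading else 'false'}\n"
            )
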