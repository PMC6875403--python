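"""Readers and writers for the external formats the pipeline touches.

Tabular inputs (compound tables, compound-target maps, centrality tables)
are TSV; networks travel as SIF or GraphML; term annotations as GMT; run
summaries as JSON.  Identifiers are treated as opaque, case-sensitive
strings throughout — no symbol/accession mapping is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx

from netpharm.ppi import PPIGraph, build_graph
from netpharm.screen import CompoundRecord
from netpharm.topology import CentralityRecord


class FormatError(ValueError):
    """A file does not conform to its declared format/dialect."""


@dataclass(frozen=True)
class TableDialect:
    """Dialect of a delimited text table.

    The default matches common Cytoscape exports: tab-delimited, ``#``
    comment lines, header row required.
    """

    delimiter: str = "\t"
    has_header: bool = True
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be exactly one character")
        if not self.comment_prefix:
            raise ValueError("comment_prefix must be non-empty")


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class GeneSetCollection:
    """Term -> gene annotations, as read from a GMT file."""

    entries: tuple[tuple[str, str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set id(s): {dupes}")
        for set_id, _, genes in self.entries:
            if not genes:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def genes_of(self, set_id: str) -> frozenset[str]:
        for sid, _, genes in self.entries:
            if sid == set_id:
                return genes
        raise KeyError(set_id)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, genes in self.entries:
            out |= genes
        return frozenset(out)


def _data_lines(path: str | Path, dialect: TableDialect) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping blanks and comments."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(dialect.comment_prefix):
                continue
            yield lineno, line


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}

_COMPOUND_COLUMNS = ("compound_id", "name", "herbs", "ob", "dl")


def read_compound_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[CompoundRecord]:
    """Read a compound table into records.

    Required columns: ``compound_id``, ``name``, ``herbs`` (semicolon-
    separated herb codes), ``ob``, ``dl``.  An optional ``whitelist`` column
    (true/false) defaults to false.

    Raises
    ------
    FormatError
        On a missing required column (named in the message), a non-numeric
        OB/DL value (with its line number), or duplicated compound ids.
    """
    rows = list(_data_lines(path, dialect))
    if not rows:
        raise FormatError(f"{path}: empty file (header row required)")
    header_no, header_line = rows[0]
    header = header_line.split(dialect.delimiter)
    col = {name: i for i, name in enumerate(header)}
    for required in _COMPOUND_COLUMNS:
        if required not in col:
            raise FormatError(f"{path}: missing required column {required!r}")
    wl_idx = col.get("whitelist")

    records: list[CompoundRecord] = []
    seen: dict[str, int] = {}
    for lineno, line in rows[1:]:
        fields = line.split(dialect.delimiter)
        if len(fields) < len(_COMPOUND_COLUMNS):
            raise FormatError(f"{path}:{lineno}: expected >= {len(_COMPOUND_COLUMNS)} fields")
        cid = fields[col["compound_id"]].strip()
        if cid in seen:
            raise FormatError(
                f"{path}:{lineno}: duplicate compound_id {cid!r} "
                f"(first seen on line {seen[cid]})"
            )
        seen[cid] = lineno
        try:
            ob = float(fields[col["ob"]])
            dl = float(fields[col["dl"]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric OB/DL value: {exc}") from None
        herbs = frozenset(h.strip() for h in fields[col["herbs"]].split(";") if h.strip())
        whitelisted = False
        if wl_idx is not None and wl_idx < len(fields):
            token = fields[wl_idx].strip().lower()
            if token in _TRUE:
                whitelisted = True
            elif token in _FALSE:
                whitelisted = False
            else:
                raise FormatError(f"{path}:{lineno}: bad whitelist flag {token!r}")
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=fields[col["name"]].strip(),
                herbs=herbs,
                ob=ob,
                dl=dl,
                whitelisted=whitelisted,
            )
        )
    return records


def write_compound_table(
    records: list[CompoundRecord], path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    d = dialect.delimiter
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(d.join((*_COMPOUND_COLUMNS, "whitelist")) + "\n")
        for r in records:
            fh.write(
                d.join(
                    (
                        r.compound_id,
                        r.name,
                        ";".join(sorted(r.herbs)),
                        repr(r.ob),
                        repr(r.dl),
                        "true" if r.whitelisted else "false",
                    )
                )
                + "\n"
            )


def read_edge_list(
    path: str | Path, format_name: Literal["sif", "tsv2"]
) -> list[tuple[str, str]]:
    """Read raw interaction pairs from a SIF or a two-column TSV file.

    SIF rows are ``A interaction_type B [B2 ...]`` (whitespace-delimited;
    the interaction type is discarded and a row fans out to one pair per
    trailing node).  ``tsv2`` rows are ``A<TAB>B``.  Pairs are returned in
    file order with duplicates and self-pairs intact — deduplication is the
    graph builder's job.
    """
    if format_name not in ("sif", "tsv2"):
        raise ValueError(f"unknown edge-list format {format_name!r}")
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path, DEFAULT_DIALECT):
        if format_name == "sif":
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: SIF row needs >= 3 fields")
            src = fields[0]
            for tgt in fields[2:]:
                pairs.append((src, tgt))
        else:
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: tsv2 row needs 2 fields")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT annotation file (``id<TAB>description<TAB>gene...``).

    Genes are deduplicated per set; row order is irrelevant to the result's
    set semantics.  Rows with fewer than three fields and duplicated set ids
    raise :class:`FormatError`.
    """
    entries: list[tuple[str, str, frozenset[str]]] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path, DEFAULT_DIALECT):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT row needs >= 3 fields")
        set_id, desc = fields[0], fields[1]
        if set_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        seen.add(set_id)
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {set_id!r} is empty")
        entries.append((set_id, desc, genes))
    return GeneSetCollection(entries=tuple(entries))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, desc, genes in collection.entries:
            fh.write("\t".join([set_id, desc, *sorted(genes)]) + "\n")


def write_network(
    graph: PPIGraph, path: str | Path, format_name: Literal["sif", "graphml"]
) -> None:
    """Write a graph so that :func:`read_network` round-trips it exactly.

    SIF output uses the untyped interaction label ``pp``; isolated nodes are
    written as single-field rows (standard SIF convention).
    """
    if format_name == "sif":
        isolated = graph.nodes - {n for e in graph.edges for n in e}
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(graph.edges):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(isolated):
                fh.write(f"{n}\n")
    elif format_name == "graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    else:
        raise ValueError(f"unknown network format {format_name!r}")


def read_network(path: str | Path, format_name: Literal["sif", "graphml"]) -> PPIGraph:
    """Read a network written by :func:`write_network` (or any SIF/GraphML)."""
    if format_name == "sif":
        pairs: list[tuple[str, str]] = []
        singletons: set[str] = set()
        for lineno, line in _data_lines(path, DEFAULT_DIALECT):
            fields = line.split()
            if len(fields) == 1:
                singletons.add(fields[0])
            elif len(fields) >= 3:
                for tgt in fields[2:]:
                    pairs.append((fields[0], tgt))
            else:
                raise FormatError(f"{path}:{lineno}: SIF row needs 1 or >= 3 fields")
        g = build_graph(pairs)
        return PPIGraph(nodes=g.nodes | frozenset(singletons), edges=g.edges)
    if format_name == "graphml":
        return PPIGraph.from_networkx(nx.read_graphml(str(path)))
    raise ValueError(f"unknown network format {format_name!r}")


def read_id_list(path: str | Path) -> set[str]:
    """Read one identifier per line (blank lines and ``#`` comments skipped)."""
    return {line.strip() for _, line in _data_lines(path, DEFAULT_DIALECT)}


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in sorted(set(ids)):
            fh.write(f"{i}\n")


def write_centrality_table(records: list[CentralityRecord], path: str | Path) -> None:
    """Write the six-centrality table, values at 10 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tdc\tbc\tcc\tec\tnc\tlac\n")
        for r in sorted(records, key=lambda r: r.node):
            fh.write(
                f"{r.node}\t{r.dc:d}\t{r.bc:.10g}\t{r.cc:.10g}"
                f"\t{r.ec:.10g}\t{r.nc:.10g}\t{r.lac:.10g}\n"
            )


def read_centrality_table(path: str | Path) -> list[CentralityRecord]:
    records: list[CentralityRecord] = []
    rows = list(_data_lines(path, DEFAULT_DIALECT))
    if not rows:
        raise FormatError(f"{path}: empty centrality table")
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 fields")
        records.append(
            CentralityRecord(
                node=fields[0],
                dc=int(fields[1]),
                bc=float(fields[2]),
                cc=float(fields[3]),
                ec=float(fields[4]),
                nc=float(fields[5]),
                lac=float(fields[6]),
            )
        )
    return records


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
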