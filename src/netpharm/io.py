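"""Readers and writers for every external file the pipeline touches.

All tabular formats are tab-separated UTF-8 with a header row.  Writers
sort their output canonically so identical inputs produce identical
bytes, which keeps round-trip and regression tests exact.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from .model import (
    AnnotationCollection,
    AnnotationTerm,
    CentralityRecord,
    CompoundTargetTable,
    DiseaseTargetSet,
    FormatError,
    HerbCompoundTable,
    PharmEfficacyRow,
    PharmEfficacyTable,
    SchemaError,
    ScoredInteraction,
    TypedNetwork,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# generic relation tables
# ---------------------------------------------------------------------------

def read_relation_table(
    path: PathLike, schema: Sequence[str]
) -> list[tuple[str, ...]]:
    """Read a tab-separated relation table with a header row.

    Returns rows in file order as tuples of whitespace-trimmed strings,
    with the columns selected and ordered per *schema*.  Empty lines are
    skipped.  A missing schema column raises :class:`SchemaError`; a
    duplicated header name raises :class:`FormatError`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: missing header row")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise FormatError(f"{path}: duplicate header column(s) {dupes}")
        try:
            indices = [header.index(col) for col in schema]
        except ValueError:
            missing = [col for col in schema if col not in header]
            raise SchemaError(
                f"{path}: missing column(s) {missing}; header was {header}"
            ) from None
        rows: list[tuple[str, ...]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) <= max(indices):
                raise FormatError(
                    f"{path}:{lineno}: expected at least {max(indices) + 1} "
                    f"columns, got {len(fields)}"
                )
            rows.append(tuple(fields[i] for i in indices))
    return rows


def write_relation_table(
    rows: Iterable[Sequence[str]], path: PathLike, schema: Sequence[str]
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(schema) + "\n")
        for row in rows:
            fh.write("\t".join(str(f) for f in row) + "\n")


# convenience loaders for the three relation tables of the pipeline

def read_herb_compound_table(path: PathLike) -> HerbCompoundTable:
    return HerbCompoundTable(
        read_relation_table(path, ("herb_id", "compound_id"))  # type: ignore[arg-type]
    )


def read_compound_target_table(path: PathLike) -> CompoundTargetTable:
    return CompoundTargetTable(
        read_relation_table(path, ("compound_id", "target_id"))  # type: ignore[arg-type]
    )


def read_disease_targets(path: PathLike) -> DiseaseTargetSet:
    rows = read_relation_table(path, ("target_id",))
    return DiseaseTargetSet(t for (t,) in rows)


def read_pharm_efficacy_table(path: PathLike) -> PharmEfficacyTable:
    rows = read_relation_table(
        path, ("compound_id", "pharmacology_statement", "traditional_effect")
    )
    return PharmEfficacyTable(PharmEfficacyRow(*r) for r in rows)


def write_pharm_efficacy_table(tbl: PharmEfficacyTable, path: PathLike) -> None:
    write_relation_table(
        [
            (r.compound_id, r.pharmacology_statement, r.traditional_effect)
            for r in tbl.rows
        ],
        path,
        ("compound_id", "pharmacology_statement", "traditional_effect"),
    )


# ---------------------------------------------------------------------------
# scored interactions
# ---------------------------------------------------------------------------

def canonicalize_interactions(
    interactions: Iterable[ScoredInteraction],
) -> list[ScoredInteraction]:
    """Collapse duplicate unordered pairs, keeping the maximum score.

    Idempotent: applying it twice changes nothing.
    """
    best: dict[tuple[str, str], ScoredInteraction] = {}
    for it in interactions:
        prev = best.get(it.pair)
        if prev is None or it.score > prev.score:
            best[it.pair] = it
    return sorted(best.values())


def read_scored_interactions(
    path: PathLike, min_score: float = 0.4
) -> list[ScoredInteraction]:
    """Read a String-style scored edge list and apply the confidence filter.

    The file has a header row with at least three columns; the first two
    are the protein symbols and the score is taken from a column named
    ``combined_score`` if present, else from the third column.  Only
    interactions with score strictly greater than *min_score* are kept
    (the therapeutic-target literature's ``>0.4`` convention).  Pairs are
    canonicalized, duplicates collapsed to the maximum score, and
    self-interactions dropped with a logged count.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: missing header row")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        if len(header) < 3:
            raise FormatError(f"{path}: expected at least 3 columns, got {header}")
        score_col = (
            header.index("combined_score") if "combined_score" in header else 2
        )
        kept: list[ScoredInteraction] = []
        n_self = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) <= score_col:
                raise FormatError(f"{path}:{lineno}: too few columns")
            try:
                score = float(fields[score_col])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparseable score {fields[score_col]!r}"
                ) from None
            a, b = fields[0], fields[1]
            if a.upper() == b.upper():
                n_self += 1
                continue
            if score > min_score:
                kept.append(ScoredInteraction(a, b, score))
    if n_self:
        logger.info("%s: dropped %d self-interaction(s)", path, n_self)
    return canonicalize_interactions(kept)


def write_scored_interactions(
    interactions: Iterable[ScoredInteraction], path: PathLike
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for it in sorted(interactions):
            fh.write(f"{it.protein_a}\t{it.protein_b}\t{_fmt(it.score, 6)}\n")


# ---------------------------------------------------------------------------
# network exports
# ---------------------------------------------------------------------------

def write_sif(net: TypedNetwork, path: PathLike) -> None:
    """Write a simple-interaction-format file (Cytoscape dialect).

    One line per edge ``source<TAB>relation<TAB>target``; isolated nodes
    are emitted as single-column lines.  Edges are sorted canonically so
    identical networks produce byte-identical files.
    """
    path = Path(path)
    g = net.graph
    lines: list[str] = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((u, v))
        lines.append(f"{a}\t{data.get('relation') or 'pp'}\t{b}")
    for node in g.nodes:
        if g.degree(node) == 0:
            lines.append(str(node))
    lines.sort()
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_sif(path: PathLike) -> nx.Graph:
    """Read a SIF file back into a plain graph (roles live elsewhere)."""
    g = nx.Graph()
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            g.add_node(fields[0])
        elif len(fields) == 3:
            g.add_edge(fields[0], fields[2], relation=fields[1])
        else:
            raise FormatError(f"{path}:{lineno}: expected 1 or 3 fields")
    return g


def write_graphml(net: TypedNetwork, path: PathLike) -> None:
    """GraphML export preserving role labels as node attributes."""
    g = nx.Graph(name=net.name)
    for node in sorted(net.graph.nodes):
        g.add_node(node, role=net.role_of(node))
    for u, v, data in sorted(net.graph.edges(data=True), key=lambda e: sorted(e[:2])):
        g.add_edge(u, v, relation=data.get("relation") or "pp")
    nx.write_graphml(g, str(path))


def read_graphml(path: PathLike) -> TypedNetwork:
    g = nx.read_graphml(str(path))
    return TypedNetwork.from_graph(g, name=g.graph.get("name", ""))


def _fmt(value: float, places: int) -> str:
    """Fixed-point decimal formatting with round-half-even."""
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(float(value))).quantize(q, ROUND_HALF_EVEN))


def write_node_attributes(
    records: Sequence[CentralityRecord], path: PathLike
) -> None:
    """Write the per-node topology table (degree, betweenness, closeness).

    Real-valued columns use fixed 6-decimal round-half-even formatting;
    rows are sorted by descending degree, ties broken by node id.
    """
    if not records:
        raise FormatError("no centrality records to write")
    path = Path(path)
    ordered = sorted(records, key=lambda r: (-r.degree, r.node))
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\trole\tdegree\tbetweenness\tcloseness\tis_main\n")
        for r in ordered:
            fh.write(
                f"{r.node}\t{r.role}\t{r.degree}\t{_fmt(r.betweenness, 6)}"
                f"\t{_fmt(r.closeness, 6)}\t{str(r.is_main).lower()}\n"
            )


# ---------------------------------------------------------------------------
# GMT annotation sets
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> AnnotationCollection:
    """Read a GMT file (term, description, members; tab-separated)."""
    terms: list[AnnotationTerm] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
            )
        term_id, name, *members = fields
        members = [m.strip().upper() for m in members if m.strip()]
        terms.append(
            AnnotationTerm(
                term_id=term_id.strip(), name=name.strip(), members=frozenset(members)
            )
        )
    return AnnotationCollection(terms)


def write_gmt(annotations: AnnotationCollection, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(annotations, key=lambda t: t.term_id):
            members = "\t".join(sorted(term.members))
            fh.write(f"{term.term_id}\t{term.name}\t{members}\n")
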