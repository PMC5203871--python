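"""Domain types for the network-pharmacology pipeline.

The pipeline relates a multi-herb formula to a disease through typed
relation tables: herbs contain active compounds, compounds hit predicted
protein targets, a therapeutic-target database contributes disease
targets, and a scored protein-protein interaction (PPI) catalogue links
all of them to the rest of the human proteome.  Every table here is a
thin validated container over plain Python data so that readers, writers
and generators can be tested byte-exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "NetpharmError",
    "SchemaError",
    "FormatError",
    "ConfigError",
    "ValidationError",
    "ROLES",
    "TRADITIONAL_EFFECTS",
    "HerbCompoundTable",
    "CompoundTargetTable",
    "DiseaseTargetSet",
    "ScoredInteraction",
    "AnnotationTerm",
    "AnnotationCollection",
    "PharmEfficacyRow",
    "PharmEfficacyTable",
    "TypedNetwork",
    "CentralityRecord",
    "MainNodeThresholds",
    "EnrichmentResult",
    "ModulePartition",
]


class NetpharmError(Exception):
    """Base class for every error raised by this package."""


class SchemaError(NetpharmError):
    """A table is missing a required column."""


class FormatError(NetpharmError):
    """A file is syntactically malformed (bad header, unparseable field)."""


class ConfigError(NetpharmError):
    """A generator or pipeline configuration is infeasible."""


class ValidationError(NetpharmError):
    """An in-memory object violates a domain invariant."""


#: Closed set of node roles used by every typed network.
ROLES = frozenset(
    {
        "herb",
        "compound",
        "compound_target",
        "infertility_target",
        "shared_target",
        "other_protein",
        "pharmacology",
        "effect",
    }
)

#: Closed set of traditional-effect labels for the formula studied here:
#: dispersing stagnated liver Qi, nourishing blood, invigorating the spleen.
TRADITIONAL_EFFECTS = frozenset(
    {"qi_dispersing", "blood_nourishing", "spleen_invigorating"}
)


def _require_token(value: str, what: str) -> str:
    value = value.strip()
    if not value:
        raise ValidationError(f"empty {what}")
    return value


@dataclass(frozen=True)
class HerbCompoundTable:
    """Herb -> active-compound membership (one row per pair).

    A compound may belong to several herbs; duplicate pairs are invalid.
    """

    rows: tuple[tuple[str, str], ...]

    def __init__(self, rows: Iterable[tuple[str, str]]):
        clean = tuple(
            (_require_token(h, "herb_id"), _require_token(c, "compound_id"))
            for h, c in rows
        )
        if len(set(clean)) != len(clean):
            dupes = [p for p, n in Counter(clean).items() if n > 1]
            raise ValidationError(f"duplicate herb/compound pairs: {dupes}")
        object.__setattr__(self, "rows", clean)

    @property
    def herbs(self) -> set[str]:
        return {h for h, _ in self.rows}

    @property
    def compounds(self) -> set[str]:
        return {c for _, c in self.rows}

    def compounds_of(self, herb: str) -> set[str]:
        return {c for h, c in self.rows if h == herb}

    def herbs_of(self, compound: str) -> set[str]:
        return {h for h, c in self.rows if c == compound}

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CompoundTargetTable:
    """Compound -> predicted protein target relation (bipartite).

    Target symbols are uppercase-normalized on construction.
    """

    rows: tuple[tuple[str, str], ...]

    def __init__(self, rows: Iterable[tuple[str, str]]):
        clean = tuple(
            (_require_token(c, "compound_id"), _require_token(t, "target_id").upper())
            for c, t in rows
        )
        if len(set(clean)) != len(clean):
            dupes = [p for p, n in Counter(clean).items() if n > 1]
            raise ValidationError(f"duplicate compound/target pairs: {dupes}")
        object.__setattr__(self, "rows", clean)

    @property
    def compounds(self) -> set[str]:
        return {c for c, _ in self.rows}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.rows}

    def targets_of(self, compound: str) -> set[str]:
        return {t for c, t in self.rows if c == compound}

    def compounds_of(self, target: str) -> set[str]:
        return {c for c, t in self.rows if t == target}

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class DiseaseTargetSet:
    """Uppercase-normalized, deduplicated set of disease-target symbols."""

    targets: frozenset[str]

    def __init__(self, targets: Iterable[str]):
        clean = frozenset(_require_token(t, "target_id").upper() for t in targets)
        if not clean:
            raise ValidationError("disease target set is empty")
        object.__setattr__(self, "targets", clean)

    def __contains__(self, item: str) -> bool:
        return item in self.targets

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.targets))

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True, order=True)
class ScoredInteraction:
    """One undirected PPI edge with a confidence score in [0, 1].

    The unordered pair is stored canonically (protein_a < protein_b
    lexicographically); self-interactions are rejected.
    """

    protein_a: str
    protein_b: str
    score: float

    def __init__(self, protein_a: str, protein_b: str, score: float):
        a = _require_token(protein_a, "protein_a").upper()
        b = _require_token(protein_b, "protein_b").upper()
        if a == b:
            raise ValidationError(f"self-interaction {a!r}")
        if a > b:
            a, b = b, a
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"score {score} outside [0, 1] for ({a}, {b})")
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        object.__setattr__(self, "score", score)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    members: frozenset[str]
    category: str = "biological_process"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"term {self.term_id!r} has no members")


class AnnotationCollection:
    """Map term_id -> annotation term (a GMT file in memory)."""

    def __init__(self, terms: Iterable[AnnotationTerm]):
        self._terms: dict[str, AnnotationTerm] = {}
        for term in terms:
            if term.term_id in self._terms:
                raise ValidationError(f"duplicate term id {term.term_id!r}")
            self._terms[term.term_id] = term

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        return self._terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[AnnotationTerm]:
        return iter(self._terms.values())

    def __len__(self) -> int:
        return len(self._terms)

    @property
    def term_ids(self) -> list[str]:
        return list(self._terms)

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for term in self._terms.values():
            out |= term.members
        return out


@dataclass(frozen=True)
class PharmEfficacyRow:
    compound_id: str
    pharmacology_statement: str
    traditional_effect: str

    def __post_init__(self) -> None:
        _require_token(self.compound_id, "compound_id")
        _require_token(self.pharmacology_statement, "pharmacology_statement")
        if self.traditional_effect not in TRADITIONAL_EFFECTS:
            raise ValidationError(
                f"unknown traditional effect {self.traditional_effect!r}; "
                f"expected one of {sorted(TRADITIONAL_EFFECTS)}"
            )


@dataclass(frozen=True)
class PharmEfficacyTable:
    """Curated compound -> pharmacology -> traditional-effect relations.

    Compounds with no established pharmacology simply have no rows.
    """

    rows: tuple[PharmEfficacyRow, ...]

    def __init__(self, rows: Iterable[PharmEfficacyRow]):
        object.__setattr__(self, "rows", tuple(rows))

    @property
    def compounds(self) -> set[str]:
        return {r.compound_id for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)


class TypedNetwork:
    """Undirected simple graph whose nodes carry a role label.

    Thin wrapper over :class:`networkx.Graph` enforcing the domain
    invariants: no self-loops, no parallel edges, every edge endpoint
    declared beforehand, roles drawn from :data:`ROLES`.
    """

    def __init__(self, name: str = ""):
        self._g = nx.Graph(name=name)

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, role: str) -> None:
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r} for node {node_id!r}")
        existing = self._g.nodes.get(node_id)
        if existing is not None and existing["role"] != role:
            raise ValidationError(
                f"node {node_id!r} already has role {existing['role']!r}, "
                f"cannot relabel to {role!r}"
            )
        self._g.add_node(node_id, role=role)

    def add_edge(self, u: str, v: str, relation: Optional[str] = None) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        for end in (u, v):
            if end not in self._g:
                raise ValidationError(f"edge endpoint {end!r} is not a declared node")
        self._g.add_edge(u, v, relation=relation if relation is not None else "pp")

    # -- inspection ---------------------------------------------------
    @property
    def name(self) -> str:
        return self._g.graph.get("name", "")

    @property
    def graph(self) -> nx.Graph:
        return self._g

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self._g.edges]

    def role_of(self, node_id: str) -> str:
        return self._g.nodes[node_id]["role"]

    def role_census(self) -> dict[str, int]:
        return dict(Counter(role for _, role in self._g.nodes(data="role")))

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TypedNetwork({self.name!r}, nodes={self.number_of_nodes()}, "
            f"edges={self.number_of_edges()})"
        )

    @classmethod
    def from_graph(cls, g: nx.Graph, name: str = "") -> "TypedNetwork":
        net = cls(name=name or g.graph.get("name", ""))
        for node, data in g.nodes(data=True):
            net.add_node(str(node), data["role"])
        for u, v, data in g.edges(data=True):
            net.add_edge(str(u), str(v), data.get("relation"))
        return net


@dataclass(frozen=True)
class CentralityRecord:
    """Degree, betweenness and closeness of one node, plus the hub flag."""

    node: str
    role: str
    degree: int
    betweenness: float
    closeness: float
    is_main: bool = False


@dataclass(frozen=True)
class MainNodeThresholds:
    """Network-wide arithmetic means of the three indices."""

    mean_degree: float
    mean_betweenness: float
    mean_closeness: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one annotation term in a gene list.

    fold_enrichment = (k/n) / (K/N); p_raw is the hypergeometric upper
    tail P(X >= k); q_bh the Benjamini-Hochberg adjusted value.
    """

    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_raw: float
    q_bh: float
    module: str = ""

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValidationError(
                f"term {self.term_id!r}: k={self.k} exceeds min(n={self.n}, K={self.K})"
            )


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of analyzed genes to representative functional modules."""

    modules: Mapping[str, frozenset[str]]

    def __init__(self, modules: Mapping[str, Iterable[str]]):
        object.__setattr__(
            self,
            "modules",
            {label: frozenset(genes) for label, genes in modules.items()},
        )

    @property
    def labels(self) -> list[str]:
        return list(self.modules)

    def module_of(self, gene: str) -> Optional[str]:
        for label, members in self.modules.items():
            if gene in members:
                return label
        return None

    def __len__(self) -> int:
        return len(self.modules)
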