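"""SBO is-a graph, EC numbers, and the persistent EC -> SBO mapping store.

The Systems Biology Ontology (SBO) is a controlled vocabulary whose terms are
rendered as ``SBO:`` followed by seven digits.  Only the is-a backbone is
needed here: it lets the annotator reason about ancestry (is term X a kind of
"biochemical reaction"?) and pick the deepest common ancestor when several
enzymes with different functions catalyse one reaction.

The mapping store links Enzyme Commission (EC) patterns to SBO terms.  An EC
number classifies an enzymatic function with four dot-separated fields
(class.subclass.sub-subclass.serial); patterns may leave a suffix of fields as
wildcards, so ``2.6.1.-`` covers every aminotransferase.  Mappings fall into
three categories: *one_to_one* (a whole class/subclass/sub-subclass maps to a
single term, e.g. transamination), *one_to_few* (a handful of explicit EC
numbers, e.g. myristoylation) and *one_to_many* (a larger explicit subset of
one sub-subclass, e.g. acetylation).
"""

from __future__ import annotations

import importlib.resources
import sqlite3
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import obonet

from .errors import ConfigurationError, OntologyError

__all__ = [
    "ECNumber",
    "SBOTerm",
    "OntologyGraph",
    "MappingEntry",
    "MappingStore",
    "load_ontology",
    "default_ontology_path",
    "default_seed_path",
    "lookup",
    "resolve_reaction_term",
    "enzymatic_class_count",
    "GENERIC_BIOCHEMICAL_ID",
]

#: Numeric id of the generic "biochemical reaction" term, the fallback for
#: reactions whose enzymatic function cannot be resolved.
GENERIC_BIOCHEMICAL_ID = 176

WILDCARD = None


@dataclass(frozen=True, order=True)
class ECNumber:
    """A four-field EC number or prefix pattern.

    A ``None`` field is a wildcard; the invariant is that wildcards form a
    suffix (patterns are prefixes of full EC numbers).
    """

    d1: int
    d2: Optional[int] = WILDCARD
    d3: Optional[int] = WILDCARD
    d4: Optional[int] = WILDCARD

    def __post_init__(self):
        if self.d1 < 1:
            raise ValueError(f"EC class must be a positive integer, got {self.d1}")
        fields = (self.d2, self.d3, self.d4)
        seen_wild = False
        for f in fields:
            if f is WILDCARD:
                seen_wild = True
            elif seen_wild:
                raise ValueError(f"wildcards must form a suffix: {fields}")
            elif f < 1:
                raise ValueError(f"EC fields must be positive integers, got {f}")

    @property
    def depth(self) -> int:
        """Number of specified (non-wildcard) fields, 1-4."""
        return sum(f is not WILDCARD for f in (self.d1, self.d2, self.d3, self.d4))

    def prefix(self, depth: int) -> "ECNumber":
        """Return this EC truncated to ``depth`` specified fields."""
        fields = [self.d1, self.d2, self.d3, self.d4][:depth]
        return ECNumber(*fields)

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        """Parse ``"2.6.1.1"`` or a prefix pattern such as ``"2.6.1.-"``.

        Accepts an optional ``EC `` / ``ec-code:`` prefix and fewer than four
        fields (missing fields are wildcards).
        """
        s = text.strip()
        for pre in ("EC ", "EC:", "ec-code:", "ec-code/"):
            if s.startswith(pre):
                s = s[len(pre):]
        parts = s.split(".")
        if not 1 <= len(parts) <= 4:
            raise ValueError(f"not an EC number: {text!r}")
        fields = []
        for p in parts:
            p = p.strip()
            if p in ("-", "", "n"):
                fields.append(WILDCARD)
            else:
                # tolerate preliminary serials like "n1"
                if p.startswith("n") and p[1:].isdigit():
                    p = p[1:]
                if not p.isdigit():
                    raise ValueError(f"not an EC number: {text!r}")
                fields.append(int(p))
        while len(fields) < 4:
            fields.append(WILDCARD)
        if fields[0] is WILDCARD:
            raise ValueError(f"EC class field may not be a wildcard: {text!r}")
        return cls(*fields)

    def __str__(self) -> str:
        return ".".join(
            "-" if f is WILDCARD else str(f) for f in (self.d1, self.d2, self.d3, self.d4)
        )


def render_sbo(sbo_id: int) -> str:
    """Render a numeric id in the canonical ``SBO:0000xxx`` form."""
    if not 0 <= sbo_id <= 9_999_999:
        raise ValueError(f"SBO id out of range: {sbo_id}")
    return f"SBO:{sbo_id:07d}"


def parse_sbo(text: str) -> int:
    s = text.strip()
    if s.upper().startswith("SBO:"):
        s = s[4:]
    return int(s)


@dataclass(frozen=True)
class SBOTerm:
    """One ontology term: numeric id, human-readable label, parent ids."""

    id: int
    label: str
    parents: frozenset

    def __str__(self) -> str:
        return f"{render_sbo(self.id)} ({self.label})"


class OntologyGraph:
    """The SBO is-a DAG with ancestor/depth reasoning.

    Edges run child -> parent in the underlying :class:`networkx.DiGraph`, so
    graph-theoretic descendants of a node are its ontological ancestors.
    """

    def __init__(self, terms: dict):
        self.terms = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise OntologyError(
                        f"term {render_sbo(t.id)} references unknown parent {render_sbo(p)}"
                    )
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join(
                render_sbo(u) for u, _ in nx.find_cycle(g)
            )
            raise OntologyError(f"is-a graph contains a cycle: {cycle}")
        self._g = g
        self.roots = {t.id for t in self.terms.values() if not t.parents}
        self._by_label = {}
        for t in self.terms.values():
            self._by_label.setdefault(t.label.lower(), t.id)
        self._depth_cache = {}

    def __contains__(self, sbo_id: int) -> bool:
        return sbo_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def label_of(self, sbo_id: int) -> str:
        return self.terms[sbo_id].label

    def id_for_label(self, label: str) -> Optional[int]:
        return self._by_label.get(label.lower())

    def ancestors(self, sbo_id: int, include_self: bool = True) -> set:
        """All is-a ancestors of a term (optionally including itself)."""
        anc = nx.descendants(self._g, sbo_id)
        if include_self:
            anc = anc | {sbo_id}
        return anc

    def is_a(self, sbo_id: int, ancestor_id: int) -> bool:
        """True if ``sbo_id`` is ``ancestor_id`` or one of its descendants."""
        return ancestor_id in self.ancestors(sbo_id)

    def depth(self, sbo_id: int) -> int:
        """Length of the longest parent chain from the term up to a root."""
        cached = self._depth_cache.get(sbo_id)
        if cached is not None:
            return cached
        parents = self.terms[sbo_id].parents
        d = 0 if not parents else 1 + max(self.depth(p) for p in parents)
        self._depth_cache[sbo_id] = d
        return d

    def deepest_common_ancestor(self, sbo_ids: Iterable[int]) -> Optional[int]:
        """Deepest term that is an ancestor-or-self of every input term.

        Ties at equal depth are broken by the smaller numeric id, for
        determinism.  Returns ``None`` for an empty input.
        """
        ids = list(sbo_ids)
        if not ids:
            return None
        common = self.ancestors(ids[0])
        for i in ids[1:]:
            common &= self.ancestors(i)
        if not common:
            return None
        return min(common, key=lambda t: (-self.depth(t), t))


def load_ontology(path: Union[str, Path]) -> OntologyGraph:
    """Read an OBO file into an :class:`OntologyGraph`.

    Only ``is_a`` edges are kept; obsolete terms are excluded.  A cyclic is-a
    graph raises :class:`OntologyError` naming the cycle.
    """
    multigraph = obonet.read_obo(str(path), ignore_obsolete=True)
    terms = {}
    for node, data in multigraph.nodes(data=True):
        sbo_id = parse_sbo(node)
        parents = frozenset(
            parse_sbo(v)
            for _, v, key in multigraph.out_edges(node, keys=True)
            if key == "is_a"
        )
        terms[sbo_id] = SBOTerm(id=sbo_id, label=data.get("name", ""), parents=parents)
    return OntologyGraph(terms)


def default_ontology_path() -> Path:
    return Path(importlib.resources.files("sbokit") / "data" / "sbo_mini.obo")


def default_seed_path() -> Path:
    return Path(importlib.resources.files("sbokit") / "data" / "ec_sbo_seed.tsv")


@lru_cache(maxsize=1)
def default_ontology() -> OntologyGraph:
    """The miniature SBO subset shipped with the package, loaded once."""
    return load_ontology(default_ontology_path())


@dataclass(frozen=True)
class MappingEntry:
    """One row of the EC -> SBO mapping store."""

    ec_pattern: ECNumber
    sbo_id: int
    category: str  # one_to_one | one_to_few | one_to_many
    class_label: str

    CATEGORIES = ("one_to_one", "one_to_few", "one_to_many")

    def __post_init__(self):
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown mapping category: {self.category!r}")


_SCHEMA = """
CREATE TABLE IF NOT EXISTS ec_sbo (
    ec_pattern TEXT PRIMARY KEY,
    sbo_label  TEXT NOT NULL,
    sbo_id     INTEGER NOT NULL,
    category   TEXT NOT NULL,
    class_label TEXT NOT NULL
);
"""


class MappingStore:
    """Relational EC -> SBO mapping store (SQLite, file-backed or in-memory).

    The canonical content ships as a human-editable tab-separated seed with
    columns ``ec_pattern, sbo_label, sbo_id, category, class_label``; the
    relational table mirrors those columns.
    """

    def __init__(self, db_path: Union[str, Path] = ":memory:"):
        self._conn = sqlite3.connect(str(db_path))
        self._conn.execute(_SCHEMA)

    # -- construction -------------------------------------------------

    @classmethod
    def from_seed(cls, seed_path: Union[str, Path, None] = None,
                  db_path: Union[str, Path] = ":memory:") -> "MappingStore":
        """Build a store from a seed TSV (default: the shipped table)."""
        store = cls(db_path)
        path = Path(seed_path) if seed_path else default_seed_path()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("ec_pattern"):
                    continue
                pattern, label, sbo_id, category, class_label = line.split("\t")
                store.add(
                    MappingEntry(
                        ec_pattern=ECNumber.parse(pattern),
                        sbo_id=int(sbo_id),
                        category=category,
                        class_label=class_label,
                    ),
                    sbo_label=label,
                )
        return store

    @classmethod
    def default(cls) -> "MappingStore":
        store = cls.from_seed()
        store.validate_against(default_ontology())
        return store

    def add(self, entry: MappingEntry, sbo_label: str = "") -> None:
        if entry.category == "one_to_one" and entry.ec_pattern.depth > 3:
            raise ValueError(
                f"one_to_one entries must be class/subclass/sub-subclass patterns "
                f"(depth <= 3): {entry.ec_pattern}"
            )
        if entry.category in ("one_to_few", "one_to_many") and entry.ec_pattern.depth != 4:
            raise ValueError(
                f"{entry.category} entries must list explicit EC numbers "
                f"(depth 4): {entry.ec_pattern}"
            )
        try:
            self._conn.execute(
                "INSERT INTO ec_sbo VALUES (?, ?, ?, ?, ?)",
                (str(entry.ec_pattern), sbo_label, entry.sbo_id,
                 entry.category, entry.class_label),
            )
        except sqlite3.IntegrityError as exc:
            raise ValueError(f"duplicate ec_pattern {entry.ec_pattern}") from exc
        self._conn.commit()

    # -- queries ------------------------------------------------------

    def _get(self, pattern: str) -> Optional[MappingEntry]:
        row = self._conn.execute(
            "SELECT ec_pattern, sbo_id, category, class_label FROM ec_sbo "
            "WHERE ec_pattern = ?", (pattern,)
        ).fetchone()
        if row is None:
            return None
        return MappingEntry(ECNumber.parse(row[0]), row[1], row[2], row[3])

    def lookup(self, ec: ECNumber) -> Optional[MappingEntry]:
        """Most specific match wins: exact, then depth-3, -2, -1 prefixes."""
        for depth in range(ec.depth, 0, -1):
            hit = self._get(str(ec.prefix(depth)))
            if hit is not None:
                return hit
        return None

    def entries(self) -> list:
        rows = self._conn.execute(
            "SELECT ec_pattern, sbo_id, category, class_label FROM ec_sbo "
            "ORDER BY ec_pattern"
        ).fetchall()
        return [MappingEntry(ECNumber.parse(r[0]), r[1], r[2], r[3]) for r in rows]

    def labelled_entries(self) -> list:
        rows = self._conn.execute(
            "SELECT ec_pattern, sbo_label, sbo_id FROM ec_sbo ORDER BY ec_pattern"
        ).fetchall()
        return rows

    def validate_against(self, graph: OntologyGraph) -> None:
        """Assert every (label, id) pair resolves in the pinned ontology.

        Guards against invented ids: a seed row whose label does not match the
        ontology's label for that id is a configuration error.
        """
        problems = []
        for pattern, label, sbo_id in self.labelled_entries():
            if sbo_id not in graph:
                problems.append(f"{pattern}: {render_sbo(sbo_id)} absent from ontology")
            elif label and graph.label_of(sbo_id).lower() != label.lower():
                problems.append(
                    f"{pattern}: label {label!r} does not match ontology label "
                    f"{graph.label_of(sbo_id)!r} for {render_sbo(sbo_id)}"
                )
        if problems:
            raise ConfigurationError("; ".join(problems))

    def close(self) -> None:
        self._conn.close()


def lookup(ec: ECNumber, store: MappingStore) -> Optional[MappingEntry]:
    """Module-level convenience wrapper around :meth:`MappingStore.lookup`."""
    return store.lookup(ec)


def resolve_reaction_term(ecs, graph: OntologyGraph, store: MappingStore,
                          generic_id: int = GENERIC_BIOCHEMICAL_ID):
    """Resolve a reaction's EC annotations to a single SBO term.

    Policy: no ECs or no hits -> the generic biochemical-reaction term; a
    unanimous mapping -> that term; disagreeing mappings -> the deepest common
    ancestor in the is-a graph, clamped so the result is never above the
    generic biochemical-reaction term.

    Returns ``(term, categories)`` where ``categories`` is the tuple of
    mapping categories that contributed (empty for the generic fallback).
    """
    hits = []
    for ec in ecs:
        entry = store.lookup(ec)
        if entry is not None:
            hits.append(entry)
    if generic_id not in graph:
        raise ConfigurationError(
            f"generic biochemical term {render_sbo(generic_id)} absent from ontology"
        )
    if not hits:
        return graph.terms[generic_id], ()
    mapped_ids = []
    for entry in hits:
        if entry.sbo_id not in graph:
            raise ConfigurationError(
                f"mapped term {render_sbo(entry.sbo_id)} (pattern {entry.ec_pattern}) "
                f"absent from ontology"
            )
        if entry.sbo_id not in mapped_ids:
            mapped_ids.append(entry.sbo_id)
    categories = tuple(e.category for e in hits)
    if len(mapped_ids) == 1:
        return graph.terms[mapped_ids[0]], categories
    dca = graph.deepest_common_ancestor(mapped_ids)
    if dca is None or not graph.is_a(dca, generic_id):
        return graph.terms[generic_id], categories
    return graph.terms[dca], categories


def enzymatic_class_count(store: MappingStore,
                          generic_id: int = GENERIC_BIOCHEMICAL_ID) -> int:
    """Number of distinct specific SBO terms reachable by biochemical lookup."""
    ids = {e.sbo_id for e in store.entries()}
    ids.discard(generic_id)
    return len(ids)
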