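"""Orchestrate the annotation pipeline and compute coverage reports.

The pipeline: (1) triage every reaction into its class; (2) give
pseudo-reactions their subtype terms; (3) type transport reactions by
mechanism; (4) resolve biochemical reactions through the EC -> SBO mapping
store, falling back to the generic biochemical-reaction term; (5) annotate
species, genes and enzymatic-catalyst modifiers; (6) report coverage — in
particular the fraction of reactions left with only the generic term, the
quantity that measures how much specificity the annotation added.

All SBO ids are configured as (label, id) pairs and asserted against the
pinned ontology before any assignment is made, so an invented id can never
silently reach a model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import importlib.resources

from .errors import ConfigurationError, ReportError
from .reaction_triage import ReactionClass, partition_model
from .sbml_gateway import Assignment, ModelDocument, ReactionRecord
from .sbo_knowledge import (
    GENERIC_BIOCHEMICAL_ID,
    MappingStore,
    OntologyGraph,
    render_sbo,
    resolve_reaction_term,
)
from .transport_typing import TransportType, classify_transport

log = logging.getLogger(__name__)

__all__ = ["TermRef", "AnnotatorConfig", "AnnotationReport",
           "annotate_model", "annotate_modifiers", "coverage_report",
           "load_default_config"]


@dataclass(frozen=True)
class TermRef:
    """A configured SBO term: human label plus the id it must resolve to."""

    label: str
    id: int


_CLASS_TO_ROLE = {
    ReactionClass.EXCHANGE: "exchange",
    ReactionClass.DEMAND: "demand",
    ReactionClass.SINK: "sink",
    ReactionClass.BIOMASS: "biomass",
}

_TRANSPORT_TO_ROLE = {
    TransportType.PASSIVE: "transport_passive",
    TransportType.ACTIVE_ATP: "transport_active",
    TransportType.ACTIVE_PEP: "transport_active",
    TransportType.SYMPORT: "transport_symport",
    TransportType.ANTIPORT: "transport_antiport",
    TransportType.GENERIC: "transport_generic",
}


@dataclass
class AnnotatorConfig:
    """Label-keyed term table plus the small mechanism tables."""

    terms: Dict[str, TermRef]
    energetic_moieties: Dict[str, str]
    pts_sugar_pairs: Dict[str, str]
    macromolecule_id_patterns: List[str] = field(default_factory=list)
    annotate_macromolecule_species: bool = False

    REQUIRED_ROLES = (
        "biochemical_generic", "transport_top", "exchange", "demand", "sink",
        "biomass", "transport_generic", "transport_active", "transport_passive",
        "transport_symport", "transport_antiport", "species",
        "species_macromolecule", "gene", "modifier_enzymatic_catalyst",
    )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AnnotatorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        terms = {role: TermRef(d["label"], int(d["id"]))
                 for role, d in raw["terms"].items()}
        return cls(
            terms=terms,
            energetic_moieties=dict(raw.get("energetic_moieties", {})),
            pts_sugar_pairs=dict(raw.get("pts_sugar_pairs", {})),
            macromolecule_id_patterns=list(raw.get("macromolecule_id_patterns", [])),
            annotate_macromolecule_species=bool(
                raw.get("annotate_macromolecule_species", False)
            ),
        )

    def validate_against(self, graph: OntologyGraph) -> None:
        """Resolve every configured label against the pinned ontology.

        Raises :class:`ConfigurationError` listing all mismatches before any
        assignment is attempted.
        """
        problems = []
        for role in self.REQUIRED_ROLES:
            if role not in self.terms:
                problems.append(f"missing term role {role!r}")
        for role, ref in self.terms.items():
            if ref.id not in graph:
                problems.append(
                    f"{role}: {render_sbo(ref.id)} absent from ontology"
                )
            elif graph.label_of(ref.id).lower() != ref.label.lower():
                problems.append(
                    f"{role}: label {ref.label!r} does not match ontology label "
                    f"{graph.label_of(ref.id)!r} for {render_sbo(ref.id)}"
                )
        if problems:
            raise ConfigurationError("; ".join(problems))

    def term_id(self, role: str) -> int:
        return self.terms[role].id


def load_default_config(graph: Optional[OntologyGraph] = None) -> AnnotatorConfig:
    """The packaged default configuration, validated if a graph is given."""
    path = importlib.resources.files("sbokit") / "data" / "default_config.json"
    config = AnnotatorConfig.from_json(str(path))
    if graph is not None:
        config.validate_against(graph)
    return config


@dataclass
class AnnotationReport:
    """Per-kind histogram of assigned terms plus coverage fractions.

    ``generic_reaction_fraction`` is the share of (sbo-bearing) reactions
    carrying only the generic biochemical-reaction term — the lower it is
    after annotation, the more specific the model's reaction semantics.
    """

    histogram: Dict[Tuple[str, int], int]
    generic_reaction_fraction: Optional[float]
    class_counts: Dict[ReactionClass, int] = field(default_factory=dict)
    generic_reaction_fraction_before: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "histogram": [
                {"entity_kind": kind, "sbo": render_sbo(sbo), "count": count}
                for (kind, sbo), count in sorted(self.histogram.items())
            ],
            "generic_reaction_fraction": self.generic_reaction_fraction,
            "generic_reaction_fraction_before": self.generic_reaction_fraction_before,
            "class_counts": {
                cls.value: n for cls, n in sorted(
                    self.class_counts.items(), key=lambda kv: kv[0].value
                )
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        lines = ["entity_kind\tsbo\tcount"]
        for (kind, sbo), count in sorted(self.histogram.items()):
            lines.append(f"{kind}\t{render_sbo(sbo)}\t{count}")
        if self.class_counts:
            lines.append("")
            lines.append("reaction_class\tcount")
            for cls, n in sorted(self.class_counts.items(), key=lambda kv: kv[0].value):
                lines.append(f"{cls.value}\t{n}")
        lines.append("")
        lines.append(f"generic_reaction_fraction\t{self.generic_reaction_fraction}")
        if self.generic_reaction_fraction_before is not None:
            lines.append(
                "generic_reaction_fraction_before\t"
                f"{self.generic_reaction_fraction_before}"
            )
        return "\n".join(lines) + "\n"


def annotate_modifiers(rxn: ReactionRecord, config: AnnotatorConfig
                       ) -> List[Assignment]:
    """Enzymatic-catalyst terms for modifiers of EC-annotated reactions.

    A modifier on a reaction that carries at least one EC number is, by that
    evidence, an enzyme; it gets the "enzymatic catalyst" role term.
    Modifiers of EC-less reactions are left untouched (they could equally be
    inhibitors or other stimulators).
    """
    if not rxn.modifiers or not rxn.ec_numbers:
        return []
    sbo_id = config.term_id("modifier_enzymatic_catalyst")
    return [
        Assignment(
            entity_id=f"{rxn.id}::{sp_id}",
            entity_kind="modifier",
            sbo_id=sbo_id,
            rule="modifier-enzymatic-catalyst",
        )
        for sp_id in rxn.modifiers
    ]


def _keep_existing(existing: Optional[int], proposed: int,
                   graph: OntologyGraph, force: bool) -> bool:
    """Preserve a pre-existing strictly more specific term unless forced."""
    if force or existing is None or existing == proposed:
        return False
    if existing not in graph:
        return False
    return graph.is_a(existing, proposed)


def _biochemical_assignment(rxn: ReactionRecord, graph: OntologyGraph,
                            store: MappingStore, generic_id: int) -> Assignment:
    term, categories = resolve_reaction_term(
        rxn.ec_numbers, graph, store, generic_id=generic_id
    )
    if not categories:
        rule = "biochemical-generic"
    elif len(set(categories)) == 1:
        rule = "ec-" + categories[0]
    else:
        rule = "ec-ancestor"
    return Assignment(rxn.id, "reaction", term.id, rule)


def annotate_model(doc: ModelDocument, config: AnnotatorConfig,
                   store: MappingStore, graph: OntologyGraph,
                   force: bool = False
                   ) -> Tuple[List[Assignment], AnnotationReport]:
    """Run the whole pipeline on one model.

    Returns the full assignment list (deterministic: model order) and the
    coverage report over the final state.  With ``force`` false, pre-existing
    terms that are strictly more specific than the rule outcome are kept.
    """
    config.validate_against(graph)
    store.validate_against(graph)
    generic_id = config.term_id("biochemical_generic")

    assignments: List[Assignment] = []
    buckets = partition_model(doc)
    class_of = {rid: cls for cls, rids in buckets.items() for rid in rids}

    for rxn in doc.reactions:
        cls = class_of[rxn.id]
        if cls in _CLASS_TO_ROLE:
            role = _CLASS_TO_ROLE[cls]
            a = Assignment(rxn.id, "reaction", config.term_id(role),
                           f"pseudo-{role}")
        elif cls is ReactionClass.TRANSPORT:
            ttype = classify_transport(
                rxn, doc,
                moieties=config.energetic_moieties or None,
                pts_pairs=config.pts_sugar_pairs or None,
            )
            a = Assignment(rxn.id, "reaction",
                           config.term_id(_TRANSPORT_TO_ROLE[ttype]),
                           f"transport-{ttype.value}")
        else:
            a = _biochemical_assignment(rxn, graph, store, generic_id)
        if _keep_existing(rxn.existing_sbo, a.sbo_id, graph, force):
            a = Assignment(rxn.id, "reaction", rxn.existing_sbo,
                           "preserved-existing")
        assignments.append(a)
        log.info("assigned %s to %s via %s", a.sbo_string, a.entity_id, a.rule)

    species_term = config.term_id("species")
    macro_term = config.term_id("species_macromolecule")
    for sp in doc.species:
        sbo_id, rule = species_term, "species-default"
        if config.annotate_macromolecule_species and any(
            pat.lower() in sp.id.lower() or pat.lower() in sp.name.lower()
            for pat in config.macromolecule_id_patterns
        ):
            sbo_id, rule = macro_term, "species-macromolecule"
        if _keep_existing(sp.existing_sbo, sbo_id, graph, force):
            sbo_id, rule = sp.existing_sbo, "preserved-existing"
        assignments.append(Assignment(sp.id, "species", sbo_id, rule))

    gene_term = config.term_id("gene")
    for gene in doc.genes:
        sbo_id, rule = gene_term, "gene-default"
        if _keep_existing(gene.existing_sbo, sbo_id, graph, force):
            sbo_id, rule = gene.existing_sbo, "preserved-existing"
        assignments.append(Assignment(gene.id, "gene", sbo_id, rule))

    for rxn in doc.reactions:
        assignments.extend(annotate_modifiers(rxn, config))

    histogram: Dict[Tuple[str, int], int] = {}
    for a in assignments:
        key = (a.entity_kind, a.sbo_id)
        histogram[key] = histogram.get(key, 0) + 1
    reaction_terms = [a for a in assignments if a.entity_kind == "reaction"]
    generic_fraction = (
        sum(a.sbo_id == generic_id for a in reaction_terms) / len(reaction_terms)
        if reaction_terms else None
    )
    report = AnnotationReport(
        histogram=histogram,
        generic_reaction_fraction=generic_fraction,
        class_counts={cls: len(rids) for cls, rids in buckets.items()},
    )
    return assignments, report


def _generic_fraction(doc: ModelDocument, generic_id: int) -> Optional[float]:
    """Generic-term share among sbo-bearing reactions; None if no terms."""
    with_terms = [r for r in doc.reactions if r.existing_sbo is not None]
    if not with_terms:
        return None
    return sum(r.existing_sbo == generic_id for r in with_terms) / len(with_terms)


def coverage_report(doc_before: ModelDocument, doc_after: ModelDocument,
                    generic_id: int = GENERIC_BIOCHEMICAL_ID) -> AnnotationReport:
    """Compare generic-term coverage before and after annotation.

    Both documents must describe the same entity sets.  The histogram covers
    the after-state; the generic fractions are reported as a (before, after)
    pair via ``generic_reaction_fraction_before`` / ``generic_reaction_fraction``.
    """
    for kind, before, after in (
        ("reaction", {r.id for r in doc_before.reactions},
         {r.id for r in doc_after.reactions}),
        ("species", {s.id for s in doc_before.species},
         {s.id for s in doc_after.species}),
        ("gene", {g.id for g in doc_before.genes},
         {g.id for g in doc_after.genes}),
    ):
        if before != after:
            raise ReportError(
                f"{kind} sets differ between documents: "
                f"only-before={sorted(before - after)} only-after={sorted(after - before)}"
            )

    histogram: Dict[Tuple[str, int], int] = {}
    for r in doc_after.reactions:
        if r.existing_sbo is not None:
            key = ("reaction", r.existing_sbo)
            histogram[key] = histogram.get(key, 0) + 1
    for s in doc_after.species:
        if s.existing_sbo is not None:
            key = ("species", s.existing_sbo)
            histogram[key] = histogram.get(key, 0) + 1
    for g in doc_after.genes:
        if g.existing_sbo is not None:
            key = ("gene", g.existing_sbo)
            histogram[key] = histogram.get(key, 0) + 1

    return AnnotationReport(
        histogram=histogram,
        generic_reaction_fraction=_generic_fraction(doc_after, generic_id),
        generic_reaction_fraction_before=_generic_fraction(doc_before, generic_id),
    )
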