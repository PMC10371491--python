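"""Partition reactions into exchange / demand / sink / biomass / transport /
biochemical classes.

Genome-scale constraint-based models mix three very different kinds of
reaction: physical conversions confined to one compartment, transport events
that move molecules between compartments, and pseudo-reactions (boundary
exchanges, demands, sinks and the biomass objective) that exist only for
modelling purposes.  Every reaction receives exactly one class; the classes
partition the reaction set.

Decision order: biomass first (a biomass function often spans compartments
and must not be mistaken for transport), then one-sided pseudo-reactions,
then the compartment-span test for transport, and biochemical as the default.
"""

from __future__ import annotations

from enum import Enum
from typing import Dict, List, Optional

from .errors import TriageError
from .sbml_gateway import ModelDocument, ReactionRecord

__all__ = ["ReactionClass", "triage_reaction", "partition_model",
           "extracellular_compartment"]


class ReactionClass(Enum):
    EXCHANGE = "EXCHANGE"
    DEMAND = "DEMAND"
    SINK = "SINK"
    BIOMASS = "BIOMASS"
    TRANSPORT = "TRANSPORT"
    BIOCHEMICAL = "BIOCHEMICAL"


_EXCHANGE_PREFIXES = ("EX_",)
_SINK_PREFIXES = ("SK_", "sink_")
_DEMAND_PREFIXES = ("DM_",)


def extracellular_compartment(doc: ModelDocument) -> Optional[str]:
    """Best-effort identification of the extracellular compartment.

    Preference order: the compartment whose species participate in
    ``EX_``-prefixed one-sided reactions; a compartment with id ``e``; a
    compartment whose id or name contains "extracellular".
    """
    for r in doc.reactions:
        if r.id.startswith(_EXCHANGE_PREFIXES) and (not r.reactants or not r.products):
            side = r.reactants or r.products
            if side:
                return doc.species_record(side[0][0]).compartment
    comp_ids = {c for c, _ in doc.compartments}
    if "e" in comp_ids:
        return "e"
    for cid, cname in doc.compartments:
        if "extracellular" in cid.lower() or "extracellular" in cname.lower():
            return cid
    return None


def _is_biomass(rxn: ReactionRecord) -> bool:
    haystack = (rxn.id + " " + rxn.name).lower()
    return rxn.is_objective or "biomass" in haystack


def triage_reaction(rxn: ReactionRecord, doc: ModelDocument,
                    extracellular: Optional[str] = None) -> ReactionClass:
    """Classify one reaction; raises :class:`TriageError` on a degenerate
    reaction with no participants at all."""
    if not rxn.reactants and not rxn.products:
        raise TriageError(f"reaction {rxn.id} has no participants")

    if _is_biomass(rxn):
        return ReactionClass.BIOMASS

    if not rxn.reactants or not rxn.products:
        # One-sided: a pseudo-reaction. Conventional id prefixes win; the
        # structural fallback looks at where the sole participants live.
        if rxn.id.startswith(_EXCHANGE_PREFIXES):
            return ReactionClass.EXCHANGE
        if rxn.id.startswith(_SINK_PREFIXES):
            return ReactionClass.SINK
        if rxn.id.startswith(_DEMAND_PREFIXES):
            return ReactionClass.DEMAND
        if extracellular is None:
            extracellular = extracellular_compartment(doc)
        side = rxn.reactants or rxn.products
        records = [doc.species_record(sid) for sid, _ in side]
        if all(s.is_boundary or s.compartment == extracellular for s in records):
            return ReactionClass.EXCHANGE
        # Sink vs demand: sinks are conventionally reversible drains,
        # demands irreversible.
        return ReactionClass.SINK if rxn.reversible else ReactionClass.DEMAND

    compartments = {
        doc.species_record(sid).compartment for sid in rxn.participant_ids()
    }
    if len(compartments) >= 2:
        return ReactionClass.TRANSPORT
    return ReactionClass.BIOCHEMICAL


def partition_model(doc: ModelDocument) -> Dict[ReactionClass, List[str]]:
    """Classify every reaction; buckets follow model order and partition the
    reaction set."""
    buckets: Dict[ReactionClass, List[str]] = {cls: [] for cls in ReactionClass}
    extracellular = extracellular_compartment(doc)
    for rxn in doc.reactions:
        try:
            cls = triage_reaction(rxn, doc, extracellular=extracellular)
        except TriageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context
            raise TriageError(f"while classifying {rxn.id}: {exc}") from exc
        buckets[cls].append(rxn.id)
    return buckets
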