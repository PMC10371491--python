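"""Sub-classify transport reactions by mechanism.

A transport reaction moves molecules between compartments.  The mechanism
decides the ontology term: passive diffusion of a single species, primary
active transport coupled to ATP hydrolysis (ABC-style), group translocation
via the phosphoenolpyruvate (PEP) phosphotransferase system (PTS, where the
sugar is phosphorylated in transit and so changes identity), and secondary
co-transport (symport when the co-transported species move the same way,
antiport when they move in opposite directions).

Detection is by BiGG base identifiers: the energetic moieties are
``atp/adp/pi`` and ``pep/pyr`` regardless of compartment, and a translocation
event is the same base id appearing as reactant in one compartment and
product in another.  Precedence: ACTIVE_ATP > ACTIVE_PEP > SYMPORT/ANTIPORT >
PASSIVE > GENERIC — energy coupling is the strongest signal, multi-species
co-transport is more informative than the single-species default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional

from .errors import ContractViolationError
from .reaction_triage import ReactionClass, triage_reaction
from .sbml_gateway import ModelDocument, ReactionRecord

__all__ = ["TransportType", "TranslocationEvent", "translocation_events",
           "classify_transport", "DEFAULT_MOIETIES", "DEFAULT_PTS_PAIRS"]


class TransportType(Enum):
    PASSIVE = "PASSIVE"
    ACTIVE_ATP = "ACTIVE_ATP"
    ACTIVE_PEP = "ACTIVE_PEP"
    SYMPORT = "SYMPORT"
    ANTIPORT = "ANTIPORT"
    GENERIC = "GENERIC"


#: Energetic-moiety base ids (compartment ignored).
DEFAULT_MOIETIES = {"atp": "atp", "adp": "adp", "phosphate": "pi",
                    "pep": "pep", "pyruvate": "pyr"}

#: PTS sugar -> phosphorylated-product base-id pairs (identity change in transit).
DEFAULT_PTS_PAIRS = {"glc__D": "g6p", "fru": "f6p", "man": "man6p",
                     "mnl": "mnl1p", "acgam": "acgam6p"}


@dataclass(frozen=True)
class TranslocationEvent:
    """One base id crossing between compartments within a reaction."""

    base_id: str
    from_compartment: str
    to_compartment: str

    def __post_init__(self):
        if self.from_compartment == self.to_compartment:
            raise ValueError("translocation requires distinct compartments")

    @property
    def direction(self):
        return (self.from_compartment, self.to_compartment)


def _side_bases(rxn: ReactionRecord, doc: ModelDocument, side) -> Dict[str, List[str]]:
    """Map base id -> compartments on one side, preserving order."""
    out: Dict[str, List[str]] = {}
    for sid, _ in side:
        rec = doc.species_record(sid)
        out.setdefault(rec.base_id, []).append(rec.compartment)
    return out


def translocation_events(rxn: ReactionRecord, doc: ModelDocument
                         ) -> List[TranslocationEvent]:
    """Base ids consumed in one compartment and produced in another.

    One event per base id, in reactant order.  Group-translocated species
    (e.g. PTS sugars) change identity and therefore yield no event here.
    """
    product_bases = _side_bases(rxn, doc, rxn.products)
    events: List[TranslocationEvent] = []
    seen = set()
    for sid, _ in rxn.reactants:
        rec = doc.species_record(sid)
        if rec.base_id in seen:
            continue
        for comp in product_bases.get(rec.base_id, []):
            if comp != rec.compartment:
                events.append(TranslocationEvent(rec.base_id, rec.compartment, comp))
                seen.add(rec.base_id)
                break
    return events


def _pts_crossing(rxn: ReactionRecord, doc: ModelDocument,
                  pts_pairs: Dict[str, str]) -> bool:
    """A sugar from the PTS table crosses compartments, identity change allowed."""
    product_bases = _side_bases(rxn, doc, rxn.products)
    for sid, _ in rxn.reactants:
        rec = doc.species_record(sid)
        phospho = pts_pairs.get(rec.base_id)
        if phospho is None:
            continue
        for target in (phospho, rec.base_id):
            for comp in product_bases.get(target, []):
                if comp != rec.compartment:
                    return True
    return False


def classify_transport(rxn: ReactionRecord, doc: ModelDocument,
                       moieties: Optional[Dict[str, str]] = None,
                       pts_pairs: Optional[Dict[str, str]] = None) -> TransportType:
    """Assign one mechanism to a reaction already triaged TRANSPORT."""
    if triage_reaction(rxn, doc) is not ReactionClass.TRANSPORT:
        raise ContractViolationError(
            f"classify_transport called on non-transport reaction {rxn.id}"
        )
    m = dict(DEFAULT_MOIETIES if moieties is None else moieties)
    pts = dict(DEFAULT_PTS_PAIRS if pts_pairs is None else pts_pairs)
    atp, adp, pi = m["atp"], m["adp"], m["phosphate"]
    pep, pyr = m["pep"], m["pyruvate"]
    moiety_bases = {atp, adp, pi, pep, pyr}

    reactant_bases = _side_bases(rxn, doc, rxn.reactants)
    product_bases = _side_bases(rxn, doc, rxn.products)
    events = translocation_events(rxn, doc)

    # (1) ABC-style primary active transport: ATP hydrolysed to ADP + Pi
    # (water optional — requiring both products separates transport from
    # compartment-spanning kinases) while some substrate crosses.
    if atp in reactant_bases and adp in product_bases and pi in product_bases:
        substrate_crosses = bool(events) or _pts_crossing(rxn, doc, pts)
        if not substrate_crosses:
            atp_comp = reactant_bases[atp][0]
            substrate_crosses = any(
                base not in moiety_bases and base != "h2o" and comp != atp_comp
                for base, comps in list(reactant_bases.items()) + list(product_bases.items())
                for comp in comps
            )
        if substrate_crosses:
            return TransportType.ACTIVE_ATP

    # (2) PTS group translocation: PEP -> pyruvate drives sugar import with
    # phosphorylation in transit.
    if pep in reactant_bases and pyr in product_bases and _pts_crossing(rxn, doc, pts):
        return TransportType.ACTIVE_PEP

    # (3) Co-transport of two or more species.
    if len(events) >= 2:
        directions = {e.direction for e in events}
        if any((t, f) in directions for f, t in directions):
            return TransportType.ANTIPORT
        if len(directions) == 1:
            return TransportType.SYMPORT

    # (4) Uniport: exactly one crossing species and nothing else involved.
    if len(events) == 1:
        participant_bases = set(reactant_bases) | set(product_bases)
        if participant_bases == {events[0].base_id}:
            return TransportType.PASSIVE

    return TransportType.GENERIC
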