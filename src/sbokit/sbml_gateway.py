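"""Read and write SBML models; normalize entities into plain records.

The gateway is the only module that touches libsbml.  It loads an SBML Level 3
model (with or without the flux-balance-constraints package), exposes a
normalized :class:`ModelDocument` view, extracts EC numbers from MIRIAM-style
controlled-vocabulary annotations, and writes ``sboTerm`` attributes back onto
the original libsbml document so that everything else in the file round-trips
untouched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple, Union

import libsbml

from .errors import AssignmentTargetError, ModelParseError, SbokitError
from .sbo_knowledge import ECNumber, render_sbo

log = logging.getLogger(__name__)

__all__ = [
    "SpeciesRecord",
    "ReactionRecord",
    "GeneRecord",
    "ModelDocument",
    "Assignment",
    "load_model",
    "extract_ec_numbers",
    "ec_numbers_from_uris",
    "apply_and_save",
    "OUTPUT_TAG",
]

#: Suffix appended to the input file stem for the annotated output.
OUTPUT_TAG = "_SBOannotated"

# Both identifiers.org dialects (path-style and prefixed), plus urn:miriam.
_EC_URI_RE = re.compile(r"(?:^|[/:])ec-code[/:]([^/:]+)$")


@dataclass(frozen=True)
class SpeciesRecord:
    """Normalized view of one SBML species.

    ``compartment`` always comes from the species element's compartment
    attribute; the BiGG id suffix is used only to derive ``base_id`` (the
    compartment-independent metabolite identity, e.g. ``glc__D`` from
    ``glc__D_e``).
    """

    id: str
    base_id: str
    compartment: str
    is_boundary: bool = False
    existing_sbo: Optional[int] = None
    name: str = ""


@dataclass(frozen=True)
class ReactionRecord:
    """Normalized view of one SBML reaction.

    Stoichiometries are strictly positive; direction is encoded by the side a
    species appears on.
    """

    id: str
    reversible: bool
    reactants: Tuple[Tuple[str, float], ...]
    products: Tuple[Tuple[str, float], ...]
    modifiers: Tuple[str, ...] = ()
    ec_numbers: Tuple[ECNumber, ...] = ()
    existing_sbo: Optional[int] = None
    is_objective: bool = False
    name: str = ""

    def participant_ids(self) -> List[str]:
        return [s for s, _ in self.reactants] + [s for s, _ in self.products]


@dataclass(frozen=True)
class GeneRecord:
    id: str
    label: str = ""
    existing_sbo: Optional[int] = None


@dataclass
class ModelDocument:
    """A whole model, normalized; keeps the libsbml document for round-trips."""

    model_id: str
    compartments: List[Tuple[str, str]]
    species: List[SpeciesRecord]
    reactions: List[ReactionRecord]
    genes: List[GeneRecord]
    objective_reaction_ids: Set[str]
    source_path: Optional[Path] = None
    sbml_document: Optional[libsbml.SBMLDocument] = field(default=None, repr=False)

    def __post_init__(self):
        comp_ids = {c for c, _ in self.compartments}
        sp_ids = {s.id for s in self.species}
        rxn_ids = {r.id for r in self.reactions}
        for s in self.species:
            if s.compartment not in comp_ids:
                raise SbokitError(
                    f"species {s.id} references unknown compartment {s.compartment}"
                )
        for r in self.reactions:
            for sid in r.participant_ids() + list(r.modifiers):
                if sid not in sp_ids:
                    raise SbokitError(
                        f"reaction {r.id} references unknown species {sid}"
                    )
        if not self.objective_reaction_ids <= rxn_ids:
            raise SbokitError("objective_reaction_ids is not a subset of reactions")
        self._species_by_id = {s.id: s for s in self.species}
        self._reactions_by_id = {r.id: r for r in self.reactions}

    def species_record(self, species_id: str) -> SpeciesRecord:
        return self._species_by_id[species_id]

    def reaction_record(self, reaction_id: str) -> ReactionRecord:
        return self._reactions_by_id[reaction_id]


@dataclass(frozen=True)
class Assignment:
    """One (entity, SBO term, rule) annotation decision.

    ``entity_kind`` is one of reaction/species/gene/modifier/model.  Modifier
    assignments target a specific modifier slot inside a reaction, so their
    ``entity_id`` is ``"<reaction id>::<species id>"``.
    """

    entity_id: str
    entity_kind: str
    sbo_id: int
    rule: str

    KINDS = ("reaction", "species", "gene", "modifier", "model")

    def __post_init__(self):
        if self.entity_kind not in self.KINDS:
            raise ValueError(f"unknown entity kind {self.entity_kind!r}")
        if not 0 < self.sbo_id <= 9_999_999:
            raise ValueError(f"SBO id out of range: {self.sbo_id}")
        if not self.rule:
            raise ValueError("rule tag must be non-empty")

    @property
    def sbo_string(self) -> str:
        return render_sbo(self.sbo_id)


def _strip_base_id(species_id: str, compartment: str) -> str:
    """Strip one trailing ``_<compartment>`` only when it matches exactly."""
    suffix = "_" + compartment
    if compartment and species_id.endswith(suffix) and len(species_id) > len(suffix):
        return species_id[: -len(suffix)]
    return species_id


def ec_numbers_from_uris(uris: Sequence[str]) -> List[ECNumber]:
    """EC numbers cited by ec-code resource URIs, deduplicated, in order.

    Malformed EC strings are skipped with a warning, never fatal.
    """
    out: List[ECNumber] = []
    for uri in uris:
        m = _EC_URI_RE.search(uri)
        if not m:
            continue
        try:
            ec = ECNumber.parse(m.group(1))
        except ValueError:
            log.warning("skipping malformed EC number in annotation URI: %s", uri)
            continue
        if ec not in out:
            out.append(ec)
    return out


def _cvterm_uris(sbase: libsbml.SBase) -> List[str]:
    uris = []
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for j in range(term.getNumResources()):
            uris.append(term.getResourceURI(j))
    return uris


def extract_ec_numbers(sbase: libsbml.SBase) -> List[ECNumber]:
    """All EC numbers cited in an element's controlled-vocabulary annotations."""
    return ec_numbers_from_uris(_cvterm_uris(sbase))


def add_ec_annotations(doc: ModelDocument, reaction_id: str,
                       ecs: Sequence[ECNumber]) -> None:
    """Write EC numbers into a reaction's annotation block as bqbiol:is CVTerms."""
    reaction = _require_sbml(doc).getModel().getReaction(reaction_id)
    if reaction is None:
        raise AssignmentTargetError([reaction_id])
    if not reaction.isSetMetaId():
        reaction.setMetaId(f"meta_{reaction.getId()}")
    existing = set(map(str, extract_ec_numbers(reaction)))
    for ec in ecs:
        if str(ec) in existing:
            continue
        cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(libsbml.BQB_IS)
        cv.addResource(f"https://identifiers.org/ec-code/{ec}")
        reaction.addCVTerm(cv)


def _sbo_or_none(sbase: libsbml.SBase) -> Optional[int]:
    return sbase.getSBOTerm() if sbase.isSetSBOTerm() else None


def load_model(path: Union[str, Path]) -> ModelDocument:
    """Load an SBML Level 3 file into a :class:`ModelDocument`.

    Unknown or extra SBML content stays opaque inside the retained libsbml
    document and survives :func:`apply_and_save` round-trips.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sbml_doc = libsbml.readSBMLFromFile(str(path))
    if sbml_doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0 \
            or sbml_doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) > 0:
        first = sbml_doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR) \
            or sbml_doc.getError(0)
        raise ModelParseError(f"{path.name}: {first.getMessage().strip()}")
    model = sbml_doc.getModel()
    if model is None:
        raise ModelParseError(f"{path.name}: no <model> element")
    if sbml_doc.getLevel() < 3:
        raise ModelParseError(
            f"{path.name}: SBML Level {sbml_doc.getLevel()} unsupported (need Level 3)"
        )

    compartments = [
        (c.getId(), c.getName() or "") for c in model.getListOfCompartments()
    ]
    species = []
    for s in model.getListOfSpecies():
        comp = s.getCompartment()
        species.append(
            SpeciesRecord(
                id=s.getId(),
                base_id=_strip_base_id(s.getId(), comp),
                compartment=comp,
                is_boundary=bool(s.getBoundaryCondition()),
                existing_sbo=_sbo_or_none(s),
                name=s.getName() or "",
            )
        )

    objective_ids: Set[str] = set()
    fbc = model.getPlugin("fbc")
    if fbc is not None:
        objective = fbc.getActiveObjective()
        if objective is None and fbc.getNumObjectives() > 0:
            objective = fbc.getObjective(0)
        if objective is not None:
            for fo in objective.getListOfFluxObjectives():
                if fo.getCoefficient() != 0.0:
                    objective_ids.add(fo.getReaction())

    reactions = []
    for r in model.getListOfReactions():
        reactants = tuple(
            (sr.getSpecies(), abs(sr.getStoichiometry()))
            for sr in r.getListOfReactants()
        )
        products = tuple(
            (sr.getSpecies(), abs(sr.getStoichiometry()))
            for sr in r.getListOfProducts()
        )
        reactions.append(
            ReactionRecord(
                id=r.getId(),
                reversible=bool(r.getReversible()),
                reactants=reactants,
                products=products,
                modifiers=tuple(m.getSpecies() for m in r.getListOfModifiers()),
                ec_numbers=tuple(extract_ec_numbers(r)),
                existing_sbo=_sbo_or_none(r),
                is_objective=r.getId() in objective_ids,
                name=r.getName() or "",
            )
        )

    genes = []
    if fbc is not None:
        for gp in fbc.getListOfGeneProducts():
            genes.append(
                GeneRecord(
                    id=gp.getId(),
                    label=gp.getLabel() or "",
                    existing_sbo=_sbo_or_none(gp),
                )
            )

    return ModelDocument(
        model_id=model.getId() or path.stem,
        compartments=compartments,
        species=species,
        reactions=reactions,
        genes=genes,
        objective_reaction_ids=objective_ids,
        source_path=path,
        sbml_document=sbml_doc,
    )


def _require_sbml(doc: ModelDocument) -> libsbml.SBMLDocument:
    if doc.sbml_document is None:
        raise SbokitError("ModelDocument carries no libsbml document handle")
    return doc.sbml_document


def _resolve_target(model: libsbml.Model, a: Assignment):
    if a.entity_kind == "reaction":
        return model.getReaction(a.entity_id)
    if a.entity_kind == "species":
        return model.getSpecies(a.entity_id)
    if a.entity_kind == "gene":
        fbc = model.getPlugin("fbc")
        return None if fbc is None else fbc.getGeneProduct(a.entity_id)
    if a.entity_kind == "modifier":
        rxn_id, _, sp_id = a.entity_id.partition("::")
        reaction = model.getReaction(rxn_id)
        return None if reaction is None else reaction.getModifier(sp_id)
    if a.entity_kind == "model":
        return model
    return None


def apply_and_save(doc: ModelDocument, assignments: Sequence[Assignment],
                   out_dir: Union[str, Path] = ".") -> Path:
    """Set ``sboTerm`` attributes and write ``<stem>_SBOannotated.xml``.

    Every assignment must reference an existing entity; all non-annotation
    content is written back unchanged (canonical libsbml serialization).
    """
    sbml_doc = _require_sbml(doc)
    model = sbml_doc.getModel()

    targets = []
    unknown = []
    for a in assignments:
        target = _resolve_target(model, a)
        if target is None:
            unknown.append(f"{a.entity_kind}:{a.entity_id}")
        else:
            targets.append((target, a))
    if unknown:
        raise AssignmentTargetError(unknown)

    for target, a in targets:
        target.setSBOTerm(a.sbo_id)

    stem = doc.source_path.stem if doc.source_path else doc.model_id
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / f"{stem}{OUTPUT_TAG}.xml"
    if not libsbml.writeSBMLToFile(sbml_doc, str(out_path)):
        raise SbokitError(f"could not write {out_path}")
    return out_path
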