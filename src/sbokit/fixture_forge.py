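"""Deterministic miniature SBML models covering every classification branch.

Real genome-scale models are too large to ship and too slow to annotate in a
test loop, so this module forges tiny BiGG-style models in which each
requested rule branch — every reaction class, every transport mechanism,
every EC-mapping category, the no-EC fallback — is represented by at least
one reaction with a known expected outcome.  Each generated model gets a
sidecar expectations table (reaction_id, expected_class, expected_term_label)
so tests and demos can check the annotator against ground truth.

The same spec always produces byte-identical files: construction is fully
deterministic and branches are laid down in sorted order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Tuple, Union

import libsbml

from .errors import SbokitError
from .sbml_gateway import (
    GeneRecord,
    ModelDocument,
    ReactionRecord,
    SpeciesRecord,
    load_model,
)

__all__ = ["FixtureSpec", "build_fixture", "load_expectations",
           "BRANCH_TAGS", "FULL_BRANCH", "random_document"]


class _ModelBuilder:
    """Thin deterministic wrapper over libsbml for L3V1 + fbc v2 documents."""

    def __init__(self, model_id: str):
        ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
        self.doc = libsbml.SBMLDocument(ns)
        self.doc.setPackageRequired("fbc", False)
        self.model = self.doc.createModel()
        self.model.setId(model_id)
        mplug = self.model.getPlugin("fbc")
        mplug.setStrict(False)
        self._fbc = mplug
        self._compartments = set()
        self._species = set()
        self._objective = None

    def compartment(self, cid: str) -> None:
        if cid in self._compartments:
            return
        c = self.model.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(1.0)
        self._compartments.add(cid)

    def species(self, sid: str, compartment: str, boundary: bool = False) -> None:
        if sid in self._species:
            return
        self.compartment(compartment)
        s = self.model.createSpecies()
        if s.setId(sid) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise SbokitError(f"invalid SBML species id {sid!r}")
        s.setCompartment(compartment)
        s.setBoundaryCondition(boundary)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
        s.setInitialConcentration(1.0)
        self._species.add(sid)

    def reaction(self, rid: str, reactants: Dict[str, float],
                 products: Dict[str, float], reversible: bool = False,
                 modifiers: Iterable[str] = (), ecs: Iterable[str] = (),
                 objective: bool = False, name: str = "") -> None:
        r = self.model.createReaction()
        r.setId(rid)
        if name:
            r.setName(name)
        r.setReversible(reversible)
        r.setFast(False)
        for sid, stoich in reactants.items():
            sr = r.createReactant()
            sr.setSpecies(sid)
            sr.setStoichiometry(stoich)
            sr.setConstant(True)
        for sid, stoich in products.items():
            sr = r.createProduct()
            sr.setSpecies(sid)
            sr.setStoichiometry(stoich)
            sr.setConstant(True)
        for sid in modifiers:
            mod = r.createModifier()
            mod.setSpecies(sid)
        ecs = list(ecs)
        if ecs:
            r.setMetaId(f"meta_{rid}")
            for ec in ecs:
                cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
                cv.setBiologicalQualifierType(libsbml.BQB_IS)
                cv.addResource(f"https://identifiers.org/ec-code/{ec}")
                r.addCVTerm(cv)
        if objective:
            if self._objective is None:
                obj = self._fbc.createObjective()
                obj.setId("obj")
                obj.setType("maximize")
                self._fbc.setActiveObjectiveId("obj")
                self._objective = obj
            fo = self._objective.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(1.0)

    def gene(self, gid: str, label: str = "") -> None:
        gp = self._fbc.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(label or gid)

    def to_string(self) -> str:
        return libsbml.writeSBMLToString(self.doc)


Expectation = Tuple[str, str, str]  # reaction_id, expected_class, expected_term_label


def _branch_exchange(b: _ModelBuilder) -> List[Expectation]:
    b.species("o2_e", "e")
    b.reaction("EX_o2_e", {"o2_e": 1}, {}, reversible=True)
    return [("EX_o2_e", "EXCHANGE", "exchange reaction")]


def _branch_demand(b: _ModelBuilder) -> List[Expectation]:
    b.species("amob_c", "c")
    b.reaction("DM_amob_c", {"amob_c": 1}, {}, reversible=False)
    return [("DM_amob_c", "DEMAND", "demand reaction")]


def _branch_sink(b: _ModelBuilder) -> List[Expectation]:
    b.species("pqq_c", "c")
    b.reaction("SK_pqq_c", {"pqq_c": 1}, {}, reversible=True)
    return [("SK_pqq_c", "SINK", "sink reaction")]


def _branch_biomass(b: _ModelBuilder) -> List[Expectation]:
    for sid in ("glc__D_c", "atp_c", "adp_c", "pi_c"):
        b.species(sid, "c")
    b.reaction("BIOMASS_core", {"glc__D_c": 1, "atp_c": 10},
               {"adp_c": 10, "pi_c": 10}, objective=True)
    return [("BIOMASS_core", "BIOMASS", "biomass production")]


def _branch_passive(b: _ModelBuilder) -> List[Expectation]:
    b.species("o2_e", "e")
    b.species("o2_c", "c")
    b.reaction("O2t", {"o2_e": 1}, {"o2_c": 1}, reversible=True)
    return [("O2t", "TRANSPORT", "passive transport")]


def _branch_active_atp(b: _ModelBuilder) -> List[Expectation]:
    for sid, comp in (("atp_c", "c"), ("h2o_c", "c"), ("glc__D_e", "e"),
                      ("adp_c", "c"), ("pi_c", "c"), ("h_c", "c"),
                      ("glc__D_c", "c")):
        b.species(sid, comp)
    b.reaction("GLCabc", {"atp_c": 1, "h2o_c": 1, "glc__D_e": 1},
               {"adp_c": 1, "pi_c": 1, "h_c": 1, "glc__D_c": 1})
    return [("GLCabc", "TRANSPORT", "active transport")]


def _branch_active_pep(b: _ModelBuilder) -> List[Expectation]:
    for sid, comp in (("glc__D_e", "e"), ("pep_c", "c"),
                      ("g6p_c", "c"), ("pyr_c", "c")):
        b.species(sid, comp)
    b.reaction("GLCpts", {"glc__D_e": 1, "pep_c": 1}, {"g6p_c": 1, "pyr_c": 1})
    return [("GLCpts", "TRANSPORT", "active transport")]


def _branch_symport(b: _ModelBuilder) -> List[Expectation]:
    for sid, comp in (("na1_e", "e"), ("pro__L_e", "e"),
                      ("na1_c", "c"), ("pro__L_c", "c")):
        b.species(sid, comp)
    b.reaction("PROt4", {"na1_e": 1, "pro__L_e": 1}, {"na1_c": 1, "pro__L_c": 1})
    return [("PROt4", "TRANSPORT", "symporter-mediated transport")]


def _branch_antiport(b: _ModelBuilder) -> List[Expectation]:
    for sid, comp in (("ca2_c", "c"), ("h_e", "e"),
                      ("ca2_e", "e"), ("h_c", "c")):
        b.species(sid, comp)
    b.reaction("CAt6", {"ca2_c": 1, "h_e": 1}, {"ca2_e": 1, "h_c": 1})
    return [("CAt6", "TRANSPORT", "antiporter-mediated transport")]


def _branch_generic_transport(b: _ModelBuilder) -> List[Expectation]:
    # Spans compartments but no base id crosses and no energetic coupling.
    b.species("glyc_e", "e")
    b.species("dha_c", "c")
    b.reaction("GLYCDHAt", {"glyc_e": 1}, {"dha_c": 1})
    return [("GLYCDHAt", "TRANSPORT", "transport reaction")]


def _branch_ec_one_to_one(b: _ModelBuilder) -> List[Expectation]:
    for sid in ("asp__L_c", "akg_c", "oaa_c", "glu__L_c"):
        b.species(sid, "c")
    b.reaction("ASPTA", {"asp__L_c": 1, "akg_c": 1},
               {"oaa_c": 1, "glu__L_c": 1}, reversible=True,
               ecs=["2.6.1.1"])
    return [("ASPTA", "BIOCHEMICAL", "transamination")]


def _branch_ec_one_to_few(b: _ModelBuilder) -> List[Expectation]:
    for sid in ("ttdca_c", "prot_c", "myrprot_c", "coa_c"):
        b.species(sid, "c")
    b.reaction("PMYR", {"ttdca_c": 1, "prot_c": 1},
               {"myrprot_c": 1, "coa_c": 1}, ecs=["2.3.1.97"])
    return [("PMYR", "BIOCHEMICAL", "myristoylation")]


def _branch_ec_one_to_many(b: _ModelBuilder) -> List[Expectation]:
    for sid in ("accoa_c", "glu__L_c", "acglu_c", "coa_c"):
        b.species(sid, "c")
    b.reaction("ACGS", {"accoa_c": 1, "glu__L_c": 1},
               {"acglu_c": 1, "coa_c": 1}, ecs=["2.3.1.1"])
    return [("ACGS", "BIOCHEMICAL", "acetylation")]


def _branch_ec_ligase(b: _ModelBuilder) -> List[Expectation]:
    for sid in ("glu__L_c", "cys__L_c", "atp_c", "glucys_c",
                "adp_c", "pi_c", "h_c"):
        b.species(sid, "c")
    b.reaction("GLUCYS", {"glu__L_c": 1, "cys__L_c": 1, "atp_c": 1},
               {"glucys_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1},
               ecs=["6.3.2.4"])
    return [("GLUCYS", "BIOCHEMICAL", "formation of a covalent bond")]


def _branch_ec_ancestor(b: _ModelBuilder) -> List[Expectation]:
    # Two ECs mapping to sibling terms (myristoylation, acetylation); the
    # annotator should settle on their common ancestor.
    for sid in ("ttdca_c", "accoa_c", "prot_c", "acylprot_c"):
        b.species(sid, "c")
    b.reaction("NACYL", {"ttdca_c": 1, "accoa_c": 1, "prot_c": 1},
               {"acylprot_c": 1}, ecs=["2.3.1.97", "2.3.1.5"])
    return [("NACYL", "BIOCHEMICAL", "addition of a chemical group")]


def _branch_no_ec(b: _ModelBuilder) -> List[Expectation]:
    b.species("g6p_c", "c")
    b.species("f6p_c", "c")
    b.reaction("PGI", {"g6p_c": 1}, {"f6p_c": 1}, reversible=True)
    return [("PGI", "BIOCHEMICAL", "biochemical reaction")]


def _branch_modifier(b: _ModelBuilder) -> List[Expectation]:
    for sid in ("pg2_c", "pep_c", "h2o_c", "eno_mod_c"):
        b.species(sid, "c")
    b.reaction("ENO", {"pg2_c": 1}, {"pep_c": 1, "h2o_c": 1},
               reversible=True, modifiers=["eno_mod_c"], ecs=["4.2.1.11"])
    return [("ENO", "BIOCHEMICAL", "cleavage")]


def _branch_genes(b: _ModelBuilder) -> List[Expectation]:
    b.gene("G_b0001", "thrA")
    b.gene("G_b0002", "thrB")
    return []


_BRANCH_BUILDERS = {
    "EXCHANGE": _branch_exchange,
    "DEMAND": _branch_demand,
    "SINK": _branch_sink,
    "BIOMASS": _branch_biomass,
    "PASSIVE": _branch_passive,
    "ACTIVE_ATP": _branch_active_atp,
    "ACTIVE_PEP": _branch_active_pep,
    "SYMPORT": _branch_symport,
    "ANTIPORT": _branch_antiport,
    "GENERIC_TRANSPORT": _branch_generic_transport,
    "EC_ONE_TO_ONE": _branch_ec_one_to_one,
    "EC_ONE_TO_FEW": _branch_ec_one_to_few,
    "EC_ONE_TO_MANY": _branch_ec_one_to_many,
    "EC_LIGASE": _branch_ec_ligase,
    "EC_ANCESTOR": _branch_ec_ancestor,
    "NO_EC": _branch_no_ec,
    "MODIFIER": _branch_modifier,
    "GENES": _branch_genes,
}

BRANCH_TAGS = frozenset(_BRANCH_BUILDERS)
FULL_BRANCH = BRANCH_TAGS


@dataclass(frozen=True)
class FixtureSpec:
    """Which rule branches a forged model must exercise."""

    name: str
    branches: FrozenSet[str]
    seed: int = 0

    def __post_init__(self):
        if not self.branches:
            raise ValueError("branches must be non-empty")


def build_fixture(spec: FixtureSpec, out_dir: Union[str, Path]) -> Path:
    """Forge the SBML file and its expectations sidecar; returns the SBML path."""
    unknown = sorted(set(spec.branches) - BRANCH_TAGS)
    if unknown:
        raise SbokitError(
            f"unknown branch tags {unknown}; known: {sorted(BRANCH_TAGS)}"
        )
    builder = _ModelBuilder(spec.name)
    expectations: List[Expectation] = []
    for tag in sorted(spec.branches):
        expectations.extend(_BRANCH_BUILDERS[tag](builder))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sbml_path = out_dir / f"{spec.name}.xml"
    sbml_path.write_text(builder.to_string(), encoding="utf-8")
    sidecar = out_dir / f"{spec.name}.expectations.tsv"
    lines = ["reaction_id\texpected_class\texpected_term_label"]
    lines += [f"{rid}\t{cls}\t{label}" for rid, cls, label in expectations]
    sidecar.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return sbml_path


def load_expectations(sbml_path: Union[str, Path]) -> List[Expectation]:
    sidecar = Path(sbml_path).with_suffix(".expectations.tsv")
    rows: List[Expectation] = []
    for line in sidecar.read_text(encoding="utf-8").splitlines()[1:]:
        rid, cls, label = line.split("\t")
        rows.append((rid, cls, label))
    return rows


# ---------------------------------------------------------------------------
# Randomized in-memory models (for partition/property testing)
# ---------------------------------------------------------------------------

_COMPARTMENTS = ("c", "e", "p")


def random_document(seed: int, n_reactions: int = 12) -> ModelDocument:
    """A random in-memory model mixing all six reaction shapes.

    Useful for property tests: every generated reaction is valid (non-empty,
    consistent species references) but ids, shapes and compartments vary with
    the seed.
    """
    rng = random.Random(seed)
    species: Dict[str, SpeciesRecord] = {}

    def sp(base: str, comp: str) -> str:
        sid = f"{base}_{comp}"
        if sid not in species:
            species[sid] = SpeciesRecord(
                id=sid, base_id=base, compartment=comp,
                is_boundary=False,
            )
        return sid

    reactions: List[ReactionRecord] = []
    objective_ids = set()
    for i in range(n_reactions):
        shape = rng.choice(
            ["exchange", "demand", "sink", "biomass", "transport", "biochemical"]
        )
        base_a = f"m{rng.randrange(40)}"
        base_b = f"m{rng.randrange(40)}x"
        if shape == "exchange":
            prefix = rng.choice(["EX_", ""])
            rid = f"{prefix}r{i}_e"
            reactions.append(ReactionRecord(
                id=rid, reversible=True,
                reactants=((sp(base_a, "e"), 1.0),), products=(),
            ))
        elif shape == "demand":
            reactions.append(ReactionRecord(
                id=rng.choice(["DM_", ""]) + f"r{i}", reversible=False,
                reactants=((sp(base_a, "c"), 1.0),), products=(),
            ))
        elif shape == "sink":
            reactions.append(ReactionRecord(
                id=rng.choice(["SK_", "sink_", ""]) + f"r{i}", reversible=True,
                reactants=((sp(base_a, "c"), 1.0),), products=(),
            ))
        elif shape == "biomass":
            rid = f"r{i}_biomass" if rng.random() < 0.5 else f"r{i}"
            is_obj = rid == f"r{i}"  # objective membership marks the plain id
            reactions.append(ReactionRecord(
                id=rid, reversible=False,
                reactants=((sp(base_a, "c"), 1.0),),
                products=((sp(base_b, "c"), 1.0),),
                is_objective=is_obj,
            ))
            if is_obj:
                objective_ids.add(rid)
        elif shape == "transport":
            c1, c2 = rng.sample(_COMPARTMENTS, 2)
            reactions.append(ReactionRecord(
                id=f"r{i}t", reversible=rng.random() < 0.5,
                reactants=((sp(base_a, c1), 1.0),),
                products=((sp(base_a, c2), 1.0),),
            ))
        else:
            comp = rng.choice(_COMPARTMENTS)
            reactions.append(ReactionRecord(
                id=f"r{i}b", reversible=rng.random() < 0.5,
                reactants=((sp(base_a, comp), 1.0),),
                products=((sp(base_b, comp), 1.0),),
            ))

    return ModelDocument(
        model_id=f"random_{seed}",
        compartments=[(c, c) for c in _COMPARTMENTS],
        species=list(species.values()),
        reactions=reactions,
        genes=[GeneRecord(id=f"G_{seed}_1")],
        objective_reaction_ids=objective_ids,
    )
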