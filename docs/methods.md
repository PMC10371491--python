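# Methods

## Scope and model of the problem

sbokit annotates SBML Level 3 constraint-based models (optionally with the
flux-balance-constraints package) whose species follow the BiGG identifier
convention: a compartment-independent base id plus a compartment suffix
(`glc__D_e`, `atp_c`). The annotation problem is treated as deterministic
rule application, not inference: every decision is a function of reaction
structure (participants, compartments, reversibility, objective membership),
of embedded controlled-vocabulary EC annotations, and of two knowledge
artefacts — the SBO is-a graph and an EC → SBO mapping table.

## Reaction triage

Classes partition the reaction set; precedence is biomass > one-sided
pseudo-reaction > transport > biochemical. Rationale for the order: a biomass
function frequently spans compartments and consumes energy, so any later
rule would misfile it; one-sidedness is unambiguous; the compartment-span
test then cleanly separates transport from conversion chemistry.

* **Biomass**: membership in the active flux objective, or the
  case-insensitive substring `biomass` in the reaction id or name. The
  id-pattern fallback exists because many published models mark biomass only
  by id; recognizing an inactive biomass function is otherwise impossible
  from structure alone.
* **One-sided reactions** (empty reactant or product side) are
  pseudo-reactions. Conventional prefixes win when present (`EX_`, `SK_` /
  `sink_`, `DM_`); structurally, a drain on a boundary or extracellular
  species is an exchange, and prefix-less intracellular drains are
  disambiguated by reversibility — sinks reversible, demands irreversible —
  the stated convention of the constraint-based modelling community.
* **Extracellular compartment**: the compartment serving `EX_`-prefixed
  one-sided reactions; failing that, the compartment with id `e` or with
  "extracellular" in its id or name. Computed once per model.
* A reaction with no participants at all is a hard error rather than a
  silent class: it indicates a broken model.

## Transport typing

A translocation event is one base id consumed in one compartment and
produced in another. Mechanism precedence is
`ACTIVE_ATP > ACTIVE_PEP > SYMPORT/ANTIPORT > PASSIVE > GENERIC`:
energy coupling is the strongest mechanistic signal, and multi-species rules
carry more information than the single-species default.

* **ACTIVE_ATP** requires ATP consumed *and* both ADP and Pᵢ produced
  (water optional). Requiring both hydrolysis products distinguishes
  ABC-style transport from kinases that happen to span compartments; an ATP
  molecule merely crossing a membrane does not trigger the rule.
* **ACTIVE_PEP** (PTS) requires PEP → pyruvate conversion while a sugar
  crosses compartments. The sugar may change identity in transit
  (`glc__D` → `g6p`); the permitted (sugar, phospho-product) pairs are a
  small configurable table, because PTS chemistry phosphorylates the
  substrate during import.
* **SYMPORT / ANTIPORT** need ≥ 2 translocation events; antiport fires when
  at least two events run in opposite directions, symport when all share one
  direction. A co-transported proton counts as an ordinary event, so
  substrate-plus-proton importers classify as symport.
* **PASSIVE** is a strict uniport: exactly one event and no other
  participant of any kind. A proton-only uniport is therefore passive.
* Everything else — identity-changing crossings without energy coupling,
  mixed-direction multi-compartment reactions — is **GENERIC** transport.
* Energetic moieties are recognized by base id (`atp`, `adp`, `pi`, `pep`,
  `pyr`) with compartment ignored; BiGG universal ids are stable enough that
  formula parsing would add risk without benefit.

Term mapping: passive → passive transport (SBO:0000658); both active forms →
active transport (SBO:0000657); symport/antiport → the symporter-/
antiporter-mediated transport terms (659/660); generic → transport reaction
(655). EC class 7 (translocases) is deliberately absent from the biochemical
mapping table: translocase-annotated reactions are handled by this
structural path.

## EC → SBO resolution

The store is a small relational table (SQLite, in-memory by default,
file-backed on request) seeded from a human-editable TSV with columns
`ec_pattern, sbo_label, sbo_id, category, class_label`. Lookup is
most-specific-first: exact four-field entry, then depth-3/-2/-1 prefixes.
Categories encode curation breadth — `one_to_one` patterns are whole
classes/subclasses/sub-subclasses (depth ≤ 3); `one_to_few` and
`one_to_many` are explicit depth-4 EC lists. The seed distinguishes 18
enzymatic-function classes; the ligase class maps EC 6 to SBO:0000695
(formation of a covalent bond), the term introduced for exactly this gap.

Multi-enzyme reactions: if all ECs resolve to one term, that term wins;
otherwise the deepest common ancestor in the is-a graph is taken, with ties
at equal depth broken by the smaller numeric id (determinism), and the
result clamped to never rise above the generic biochemical-reaction term —
if the only shared ancestry lies above it, the generic term is returned.
Reactions with no (matching) EC annotation get the generic term.

## Anti-hallucination rule for term ids

Except where a term id is structurally forced (the ligase term), every SBO
id used anywhere — entity role terms, transport terms, every seed row — is
stored as a *(label, id)* pair and asserted against the pinned ontology at
load time; a mismatch aborts before any assignment. The pinned ontology
shipped with the package (`data/sbo_mini.obo`) is a hand-curated miniature
subset (synthetic fixture) containing only the ~45 referenced terms plus
their ancestor chains, not a full SBO release; swapping in a full release
via `--obo` subjects the configuration to the same assertions.

## Other entities and preservation policy

Species receive `simple chemical` (SBO:0000247); an optional, default-off
pattern table can route macromolecule-like species (protein/biomass
pseudo-metabolites) to `macromolecule` (245) — off by default because id
patterns are heuristic. Genes receive `gene` (243). A reaction modifier is
annotated `enzymatic catalyst` (460) only when its reaction carries at least
one EC number — the EC evidence is what identifies the modifier as an
enzyme rather than an inhibitor or other stimulator.

Pre-existing terms that are strict is-a descendants of the rule outcome are
preserved (do no harm to curated models); `--force` overwrites. Annotation
is idempotent: re-annotating an annotated model is byte-identical.

## Coverage report

The report counts assigned terms per entity kind and computes the generic
reaction fraction — among sbo-bearing reactions, the share carrying only the
generic biochemical term — before and after annotation. This is the
tool-level quality metric: a specific annotation run should push it down.
Corpus-scale values depend on the corpus and are not asserted by the tests;
the fixtures verify the computation and the direction of change.

## Fixture forge and what the tests show

Shipping real genome-scale models is impractical, so the test bed forges
miniature BiGG-style SBML models in which each rule branch is represented by
a hand-built reaction with a known expected class and term, recorded in a
sidecar expectations table. Construction is fully deterministic (sorted
branch order, no randomness), so identical specs yield byte-identical files.
Randomized in-memory models (seeded `random.Random`) cover the partition
property across shapes the forge templates do not enumerate.

What this does *not* show: behaviour on models with non-BiGG identifiers,
exotic compartment topologies (> 3 compartments, nested membranes),
light-/redox-driven transporters, or curation errors in real EC annotations.
The forge also builds chemically minimal reactions (no mass balance), which
is irrelevant to classification but means fixtures are not simulatable.

## Numerical and degenerate-input choices

There is no floating-point computation beyond coverage fractions (exact
ratios of small integers). Determinism everywhere: model order drives
assignment order; ancestor ties break by smaller id; SQLite iteration is
ordered. Degenerate inputs: participant-less reactions raise; malformed EC
strings inside annotations are skipped with a warning; a missing mapped term
or a label/id mismatch is a configuration error raised before any
assignment; offline BiGG lookups return an absent result and the annotation
falls back to the generic term rather than aborting.

## Problem sizes

The shipped test suite and the acceptance script run on forged models of
1-17 reactions, 200 randomized 10-15-reaction models for the partition
property, and ≥ 50 randomized ontologies of 4-15 terms for the
ancestor-resolution oracle — sizes chosen because every rule branch is
exercised at full coverage while the whole suite stays interactive
(seconds). The pipeline itself is linear in model size and has no
per-model-size constants that the fixtures would hide.

## Known limitations

* BiGG identifier conventions are assumed for base-id matching; models using
  other namespaces will classify transport poorly (everything becomes
  GENERIC) though triage and pseudo-reaction handling still work.
* The PTS sugar table is small and configurable; unlisted
  phosphotransferase substrates fall back to GENERIC transport.
* The shipped ontology subset is not a full SBO release; analyses that need
  terms outside the configured set must supply a full OBO via `--obo`.
* Primary vs secondary active transport beyond the ATP/PEP signals, membrane
  topology, and thermodynamics are out of scope.
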