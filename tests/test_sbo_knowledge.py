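"""Ontology graph, EC -> SBO lookup, and the ancestor-resolution policy."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbokit import (
    ConfigurationError,
    ECNumber,
    MappingEntry,
    MappingStore,
    OntologyError,
    enzymatic_class_count,
    load_ontology,
    resolve_reaction_term,
)
from sbokit.sbo_knowledge import GENERIC_BIOCHEMICAL_ID, OntologyGraph, SBOTerm

FIXTURE_OBO = """\
format-version: 1.2

[Term]
id: SBO:0000001
name: root

[Term]
id: SBO:0000002
name: left
is_a: SBO:0000001 ! root

[Term]
id: SBO:0000003
name: right
is_a: SBO:0000001 ! root

[Term]
id: SBO:0000004
name: left-child
is_a: SBO:0000002 ! left

[Term]
id: SBO:0000005
name: gone
is_obsolete: true
"""


class TestLoadOntology:
    def test_parse_terms_and_edges(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text(FIXTURE_OBO)
        g = load_ontology(p)
        assert len(g) == 4
        assert g.terms[4].parents == frozenset({2})
        assert g.roots == {1}

    def test_obsolete_terms_excluded(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text(FIXTURE_OBO)
        assert 5 not in load_ontology(p)

    def test_cycle_raises_naming_cycle(self, tmp_path):
        p = tmp_path / "cyclic.obo"
        p.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: SBO:0000001\nname: a\nis_a: SBO:0000002\n\n"
            "[Term]\nid: SBO:0000002\nname: b\nis_a: SBO:0000001\n"
        )
        with pytest.raises(OntologyError, match="cycle"):
            load_ontology(p)

    def test_shipped_ontology_is_dag_rooted_and_labelled(self, graph):
        assert graph.roots == {0}
        assert graph.label_of(176) == "biochemical reaction"
        assert graph.label_of(695) == "formation of a covalent bond"
        # every non-root reaches a root
        for t in graph.terms.values():
            assert graph.ancestors(t.id) & graph.roots


class TestLookup:
    @pytest.mark.parametrize(
        "ec, expected_id, expected_label",
        [
            ("6.3.2.4", 695, "formation of a covalent bond"),
            ("2.6.1.1", 403, "transamination"),
            ("2.6.1.2", 403, "transamination"),
            ("2.3.1.97", 218, "myristoylation"),
            ("2.3.1.5", 215, "acetylation"),
            ("1.1.1.1", 200, "redox reaction"),
            ("3.1.3.9", 376, "hydrolysis"),
        ],
    )
    def test_default_store_examples(self, store, graph, ec, expected_id,
                                    expected_label):
        entry = store.lookup(ECNumber.parse(ec))
        assert entry.sbo_id == expected_id
        assert graph.label_of(entry.sbo_id) == expected_label

    def test_unmatched_class_returns_none(self, store):
        assert store.lookup(ECNumber.parse("9.9.9.9")) is None

    def test_translocase_class_not_in_biochemical_map(self, store):
        # EC class 7 is routed through transport typing, not the store
        assert store.lookup(ECNumber.parse("7.1.1.1")) is None

    def test_exact_beats_prefix(self):
        s = MappingStore()
        s.add(MappingEntry(ECNumber.parse("2.3.1.-"), 100, "one_to_one", "x"))
        s.add(MappingEntry(ECNumber.parse("2.3.1.5"), 200, "one_to_few", "y"))
        assert s.lookup(ECNumber.parse("2.3.1.5")).sbo_id == 200
        assert s.lookup(ECNumber.parse("2.3.1.6")).sbo_id == 100

    @settings(derandomize=True, max_examples=50)
    @given(
        ec=st.tuples(st.integers(1, 7), st.integers(1, 20),
                     st.integers(1, 20), st.integers(1, 200)),
        depths=st.sets(st.integers(1, 4), min_size=1),
    )
    def test_most_specific_entry_always_wins(self, ec, depths):
        """Property: among entries at several depths matching one EC, lookup
        returns the deepest."""
        full = ECNumber(*ec)
        s = MappingStore()
        for d in depths:
            s.add(MappingEntry(full.prefix(d), sbo_id=d,
                               category="one_to_one" if d <= 3 else "one_to_few",
                               class_label="c"))
        assert s.lookup(full).sbo_id == max(depths)

    def test_duplicate_pattern_rejected(self):
        s = MappingStore()
        s.add(MappingEntry(ECNumber.parse("1.-.-.-"), 1, "one_to_one", "a"))
        with pytest.raises(ValueError, match="duplicate"):
            s.add(MappingEntry(ECNumber.parse("1.-.-.-"), 2, "one_to_one", "b"))

    def test_category_depth_contract(self):
        s = MappingStore()
        with pytest.raises(ValueError):
            s.add(MappingEntry(ECNumber.parse("1.1.1.1"), 1, "one_to_one", "a"))
        with pytest.raises(ValueError):
            s.add(MappingEntry(ECNumber.parse("1.1.1.-"), 1, "one_to_many", "a"))


class TestStoreValidation:
    def test_default_store_resolves_against_pinned_ontology(self, store, graph):
        store.validate_against(graph)  # must not raise

    def test_mislabelled_entry_is_configuration_error(self, graph, tmp_path):
        seed = tmp_path / "seed.tsv"
        seed.write_text(
            "ec_pattern\tsbo_label\tsbo_id\tcategory\tclass_label\n"
            "1.-.-.-\tnot the real label\t200\tone_to_one\tx\n"
        )
        s = MappingStore.from_seed(seed)
        with pytest.raises(ConfigurationError, match="label"):
            s.validate_against(graph)

    def test_every_mapped_term_descends_from_generic(self, store, graph):
        for entry in store.entries():
            assert graph.is_a(entry.sbo_id, GENERIC_BIOCHEMICAL_ID), entry


class TestEnzymaticClassCount:
    def test_default_store_has_18_classes(self, store):
        assert enzymatic_class_count(store) == 18

    def test_empty_store(self):
        assert enzymatic_class_count(MappingStore()) == 0

    def test_shared_sbo_id_counted_once(self):
        s = MappingStore()
        s.add(MappingEntry(ECNumber.parse("2.3.1.5"), 215, "one_to_many", "a"))
        s.add(MappingEntry(ECNumber.parse("2.3.1.6"), 215, "one_to_many", "a"))
        assert enzymatic_class_count(s) == 1


# ---------------------------------------------------------------------------
# resolve_reaction_term and its brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_resolution(mapped_ids, parents, generic_id):
    """Independent oracle: enumerate each term's full ancestor set by direct
    parent-chasing, intersect, keep only descendants-or-self of the generic
    term, and take maximal depth (ties -> smaller id)."""

    def ancestor_set(t):
        out = {t}
        frontier = [t]
        while frontier:
            n = frontier.pop()
            for p in parents.get(n, ()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    def depth(t):
        ps = parents.get(t, ())
        return 0 if not ps else 1 + max(depth(p) for p in ps)

    common = ancestor_set(mapped_ids[0])
    for t in mapped_ids[1:]:
        common &= ancestor_set(t)
    candidates = [t for t in common if generic_id in ancestor_set(t)]
    if not candidates:
        return generic_id
    return min(candidates, key=lambda t: (-depth(t), t))


def random_dag(rng, n_terms):
    """Random ontology: generic term 176 under root 0, the rest hang below
    176 with 1-2 random parents each (acyclic by construction)."""
    parents = {0: (), 176: (0,)}
    ids = [176]
    for k in range(n_terms):
        tid = 1000 + k
        n_parents = 1 if len(ids) < 2 or rng.random() < 0.6 else 2
        parents[tid] = tuple(rng.sample(ids, n_parents))
        ids.append(tid)
    terms = {
        t: SBOTerm(id=t, label=f"term {t}", parents=frozenset(ps))
        for t, ps in parents.items()
    }
    return OntologyGraph(terms), parents


def test_resolution_matches_brute_force_on_random_dags(store):
    """resolve_reaction_term equals independent ancestor enumeration on >= 50
    randomized DAGs with randomized EC -> term stores."""
    rng = random.Random(20240917)
    for trial in range(60):
        graph, parents = random_dag(rng, n_terms=rng.randint(3, 12))
        specific = [t for t in parents if t >= 1000]
        s = MappingStore()
        ecs = []
        for j, target in enumerate(rng.sample(specific, rng.randint(1, len(specific)))):
            ec = ECNumber(rng.randint(1, 6), rng.randint(1, 9), rng.randint(1, 9), j + 1)
            s.add(MappingEntry(ec, target, "one_to_few", "r"))
            ecs.append(ec)
        term, _ = resolve_reaction_term(ecs, graph, s, generic_id=176)
        mapped = []
        for ec in ecs:
            hit = s.lookup(ec)
            if hit.sbo_id not in mapped:
                mapped.append(hit.sbo_id)
        if len(mapped) == 1:
            assert term.id == mapped[0]
        else:
            assert term.id == brute_force_resolution(mapped, parents, 176)


class TestResolveReactionTerm:
    def test_empty_ec_list_gives_generic(self, store, graph):
        term, cats = resolve_reaction_term([], graph, store)
        assert term.id == GENERIC_BIOCHEMICAL_ID
        assert cats == ()

    def test_unanimous_mapping(self, store, graph):
        term, _ = resolve_reaction_term(
            [ECNumber.parse("2.6.1.1"), ECNumber.parse("2.6.1.2")], graph, store
        )
        assert graph.label_of(term.id) == "transamination"

    def test_sibling_terms_resolve_to_common_parent(self, store, graph):
        # myristoylation and acetylation are siblings under "addition of a
        # chemical group" in the pinned ontology
        term, _ = resolve_reaction_term(
            [ECNumber.parse("2.3.1.97"), ECNumber.parse("2.3.1.5")], graph, store
        )
        assert graph.label_of(term.id) == "addition of a chemical group"

    def test_never_resolves_above_generic(self, graph):
        # one term under the generic, one outside the biochemical subtree:
        # the common ancestor would sit above "biochemical reaction", so the
        # generic term is returned instead
        s = MappingStore()
        s.add(MappingEntry(ECNumber.parse("2.6.1.1"), 403, "one_to_few", "a"))
        s.add(MappingEntry(ECNumber.parse("1.1.1.1"), 655, "one_to_few", "b"))
        term, _ = resolve_reaction_term(
            [ECNumber.parse("2.6.1.1"), ECNumber.parse("1.1.1.1")], graph, s
        )
        assert term.id == GENERIC_BIOCHEMICAL_ID

    def test_mapped_term_missing_from_graph_is_config_error(self, graph):
        s = MappingStore()
        s.add(MappingEntry(ECNumber.parse("2.6.1.1"), 9999991, "one_to_few", "a"))
        with pytest.raises(ConfigurationError):
            resolve_reaction_term([ECNumber.parse("2.6.1.1")], graph, s)

    def test_tie_broken_by_smaller_id(self):
        # two parents at equal depth over both mapped terms
        parents = {0: (), 176: (0,), 1001: (176,), 1002: (176,),
                   2001: (1001, 1002), 2002: (1001, 1002)}
        terms = {t: SBOTerm(t, f"t{t}", frozenset(ps)) for t, ps in parents.items()}
        graph = OntologyGraph(terms)
        s = MappingStore()
        s.add(MappingEntry(ECNumber.parse("2.1.1.1"), 2001, "one_to_few", "a"))
        s.add(MappingEntry(ECNumber.parse("2.1.1.2"), 2002, "one_to_few", "b"))
        term, _ = resolve_reaction_term(
            [ECNumber.parse("2.1.1.1"), ECNumber.parse("2.1.1.2")], graph, s,
            generic_id=176,
        )
        assert term.id == 1001
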