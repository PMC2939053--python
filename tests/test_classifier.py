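"""Rule engine, census and taxon aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrcensus.annotation_io import ProteinRecord, SpeciesTaxonomy, ValidationError
from lrrcensus.classifier import (
    CensusTable,
    TMConstraint,
    architecture_order_check,
    builtin_rules,
    census,
    classify,
    classify_all,
    rules_from_yaml,
    rules_to_yaml,
    summarize,
    validate_nesting,
)

from _oracles import brute_force_labels


class TestBuiltinRules:
    def test_receptor_requires_exactly_one_tm(self, rules):
        rule = rules["LRR_RECEPTOR"]
        assert rule.tm == TMConstraint.exactly(1)
        assert rule.required_groups == (frozenset({"PF00560", "PF07723", "PF07725"}),)

    def test_tlr_is_receptor_plus_tir(self, rules):
        tlr = rules["TLR"]
        assert tlr.tm == TMConstraint.exactly(1)
        assert frozenset({"PF01582"}) in tlr.required_groups

    def test_secreted_lrr_needs_sp_and_zero_tm(self, rules):
        rule = rules["SECRETED_LRR"]
        assert rule.tm == TMConstraint.exactly(0)
        assert rule.signal_peptide == "required"

    def test_kinase_group_accepts_either_accession(self, rules):
        assert frozenset({"PF07714", "PF00069"}) in rules["LRR_RK"].required_groups

    def test_stand_and_lysm_omitted_without_accessory_config(self):
        bare = builtin_rules()
        assert "STAND" not in bare and "LYSM_RK" not in bare
        assert "NACHT_PROTEIN" in bare


class TestClassify:
    def test_lrr_with_one_tm_is_receptor(self, rules, arch_factory):
        arch = arch_factory(
            domains=[("PF00560", 5, 28), ("PF00560", 40, 63)], helices=[(100, 122)]
        )
        assert classify(arch, rules).labels == {"LRR_PROTEIN", "LRR_RECEPTOR"}

    def test_kinase_effector_adds_lrr_rk(self, rules, arch_factory):
        arch = arch_factory(
            domains=[("PF00560", 5, 28), ("PF00069", 200, 450)], helices=[(100, 122)]
        )
        assert classify(arch, rules).labels == {"LRR_PROTEIN", "LRR_RECEPTOR", "LRR_RK"}

    def test_two_tm_is_not_a_receptor(self, rules, arch_factory):
        arch = arch_factory(
            domains=[("PF00560", 5, 28)], helices=[(100, 122), (300, 322)]
        )
        assert classify(arch, rules).labels == {"LRR_PROTEIN"}

    def test_tm_constraints_read_corrected_helices(self, rules, arch_factory):
        # raw 2 helices, one removed by the SP overlap -> counted as receptor
        arch = arch_factory(
            domains=[("PF00560", 50, 73)], helices=[(5, 21), (100, 122)], sp_end=22
        )
        assert len(arch.tm_raw) == 2 and len(arch.tm_corrected) == 1
        assert "LRR_RECEPTOR" in classify(arch, rules).labels

    @settings(deadline=None, max_examples=200)
    @given(data=st.data())
    def test_agrees_with_clause_by_clause_oracle(self, rules, data):
        """Random small architectures classify identically to an independent
        evaluator that checks each rule clause separately."""
        from conftest import make_arch as arch_factory
        pool = [
            "PF00560", "PF07723", "PF07725", "PF01582", "PF00069", "PF07714",
            "PF00211", "PF00931", "PF05729", "PF06985", "PF00400", "PF01476",
            "PF00047", "PF02189",
        ]
        n_domains = data.draw(st.integers(0, 6))
        accs = data.draw(
            st.lists(st.sampled_from(pool), min_size=n_domains, max_size=n_domains)
        )
        n_tm = data.draw(st.integers(0, 3))
        has_sp = data.draw(st.booleans())
        domains = [(acc, 30 + 40 * i, 50 + 40 * i) for i, acc in enumerate(accs)]
        helices = [(400 + 30 * i, 420 + 30 * i) for i in range(n_tm)]
        arch = arch_factory(domains=domains, helices=helices,
                            sp_end=20 if has_sp else None)
        assert classify(arch, rules).labels == brute_force_labels(arch, rules)


class TestCensus:
    def _proteins(self, spec):
        return [ProteinRecord(pid, sid, 500) for pid, sid in spec]

    def test_counts_per_species_and_class(self, rules, arch_factory):
        archs = [
            arch_factory(pid=f"p{i}", domains=[("PF00560", 5, 28)]) for i in range(6)
        ]
        proteins = self._proteins((f"p{i}", "s1") for i in range(6))
        table = census(classify_all(archs, rules), proteins, rules)
        assert table.count("s1", "LRR_PROTEIN") == 6
        assert table.count("s1", "TLR") == 0  # explicit zero

    def test_empty_dataset_gives_empty_table(self, rules):
        table = census([], [], rules)
        assert table.species == () and all(v == 0 for v in table.counts.values())

    def test_multilabel_protein_increments_both(self, rules, arch_factory):
        arch = arch_factory(domains=[("PF00560", 5, 28), ("PF00211", 200, 380)])
        table = census(
            classify_all([arch], rules), self._proteins([("p1", "s1")]), rules
        )
        assert table.count("s1", "LRR_PROTEIN") == 1
        assert table.count("s1", "LRR_AC") == 1

    def test_permutation_invariance(self, rules, arch_factory):
        archs = [
            arch_factory(pid="pa", domains=[("PF00560", 5, 28)], helices=[(99, 120)]),
            arch_factory(pid="pb", domains=[("PF01582", 5, 140)]),
            arch_factory(pid="pc", domains=[("PF00560", 5, 28)]),
        ]
        proteins = self._proteins([("pa", "s2"), ("pb", "s1"), ("pc", "s2")])
        fwd = census(classify_all(archs, rules), proteins, rules)
        rev = census(classify_all(archs[::-1], rules), proteins[::-1], rules)
        assert fwd.counts == rev.counts and fwd.species == rev.species

    def test_nesting_laws_validated(self):
        bad = CensusTable(
            species=("s1",), classes=("TLR", "LRR_RECEPTOR", "LRR_PROTEIN"),
            counts={("s1", "TLR"): 3, ("s1", "LRR_RECEPTOR"): 1, ("s1", "LRR_PROTEIN"): 5},
        )
        with pytest.raises(AssertionError, match="TLR"):
            validate_nesting(bad)


class TestSummarize:
    def _table(self, lrr_counts, receptor_counts=None):
        species = tuple(sorted(lrr_counts))
        receptor_counts = receptor_counts or {s: 0 for s in species}
        counts = {}
        for s in species:
            counts[(s, "LRR_PROTEIN")] = lrr_counts[s]
            counts[(s, "LRR_RECEPTOR")] = receptor_counts[s]
        return CensusTable(species=species, classes=("LRR_PROTEIN", "LRR_RECEPTOR"),
                           counts=counts)

    def test_threshold_arithmetic(self):
        table = self._table({"a": 6, "b": 12, "c": 25})
        taxa = [SpeciesTaxonomy(s, ("fungi",)) for s in "abc"]
        [summary] = summarize(table, taxa).values()
        assert summary.n_species == 3
        assert summary.n_high_lrr == 1   # >= 20
        assert summary.n_low_lrr == 1    # < 10
        assert summary.n_receptor_free == 3
        assert summary.class_max["LRR_PROTEIN"] == ("c", 25)

    def test_unknown_species_is_error(self):
        table = self._table({"a": 6})
        with pytest.raises(ValidationError, match="a"):
            summarize(table, [SpeciesTaxonomy("other", ("fungi",))])

    def test_groups_split_by_taxon_level(self):
        table = self._table({"a": 25, "b": 3}, {"a": 1, "b": 0})
        taxa = [
            SpeciesTaxonomy("a", ("fungi", "ascomycota")),
            SpeciesTaxonomy("b", ("metazoa", "chordata")),
        ]
        out = summarize(table, taxa)
        assert set(out) == {"fungi", "metazoa"}
        assert out["fungi"].n_high_lrr == 1
        assert out["metazoa"].n_receptor_free == 1


class TestArchitectureOrderCheck:
    ORDER = ["PF08509", "PF00560", "PF00211"]

    def test_conserved_order_passes(self, arch_factory):
        arch = arch_factory(
            domains=[("PF08509", 10, 120), ("PF00560", 300, 323), ("PF00211", 900, 980)]
        )
        assert architecture_order_check(arch, self.ORDER)

    def test_inversion_fails(self, arch_factory):
        arch = arch_factory(domains=[("PF00211", 10, 120), ("PF08509", 900, 950)])
        assert not architecture_order_check(arch, self.ORDER)

    def test_missing_optional_domain_still_passes(self, arch_factory):
        # some family members lack the N-terminal G-alpha binding domain
        arch = arch_factory(domains=[("PF00560", 300, 323), ("PF00211", 900, 980)])
        assert architecture_order_check(arch, self.ORDER)

    def test_untracked_domains_ignored(self, arch_factory):
        arch = arch_factory(
            domains=[("PF08509", 10, 120), ("PF00400", 200, 240), ("PF00211", 900, 980)]
        )
        assert architecture_order_check(arch, self.ORDER)


def test_rule_set_yaml_round_trip(rules):
    text = rules_to_yaml(rules)
    again = rules_from_yaml(text)
    assert again == rules


def test_rules_from_yaml_rejects_duplicates():
    text = rules_to_yaml(builtin_rules())
    doubled = text + text
    with pytest.raises(ValueError, match="duplicate"):
        rules_from_yaml(doubled)
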