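"""Diplotype calling, haplotype support, rule evaluation, realization."""

from collections import Counter

import numpy as np
import pytest

from pgxcds import fixtures
from pgxcds.genotype_io import PatientGenotype
from pgxcds.inference import (
    Diplotype,
    call_diplotypes,
    evaluate_expression,
    haplotype_support,
    realize_patient,
    zygosity_profile,
)
from pgxcds.kb_model import (
    HaplotypeDefinition,
    HaplotypeTaxonomy,
    KbError,
    KnowledgeBase,
    SnpDefinition,
    parse_expression,
)


class TestZygosityProfile:
    def test_heterozygous_and_homozygous_counts(self):
        g = PatientGenotype(calls={"rs1057910": ("A", "C"), "rs2": ("A", "A")})
        profile = zygosity_profile(g)
        assert profile["rs1057910"] == Counter({"A": 1, "C": 1})
        assert profile["rs2"] == Counter({"A": 2})

    def test_empty_genotype(self):
        assert zygosity_profile(PatientGenotype()) == {}

    def test_missing_rsids_omitted(self):
        g = PatientGenotype(calls={"rs1": ("A", "A")}, missing={"rs2"})
        assert set(zygosity_profile(g)) == {"rs1"}


def _panel_kb(rows, gene="G1"):
    # the caller consults only the haplotype panel, not the SNP registry
    defs = [
        HaplotypeDefinition(gene=gene, name=n, allele_map=dict(m))
        for n, m in rows.items()
    ]
    return KnowledgeBase(haplotypes={gene: defs})


class TestCallDiplotypes:
    def test_published_heterozygote_walkthrough(self, cyp2c9_kb):
        profile = {
            "rs1057910": Counter({"A": 1, "C": 1}),
            "rs1057911": Counter({"A": 2}),
            "rs1799853": Counter({"C": 2}),
            "rs2256871": Counter({"A": 2}),
        }
        call = call_diplotypes(profile, cyp2c9_kb, "CYP2C9")
        assert [d.pair for d in call.diplotypes] == [("CYP2C9*1", "CYP2C9*3")]
        assert not call.diplotypes[0].homozygous
        assert not call.ambiguous

    def test_reference_homozygote(self, cyp2c9_kb):
        profile = {
            "rs1057910": Counter({"A": 2}),
            "rs1057911": Counter({"A": 2}),
            "rs1799853": Counter({"C": 2}),
            "rs2256871": Counter({"A": 2}),
        }
        call = call_diplotypes(profile, cyp2c9_kb, "CYP2C9")
        assert [d.pair for d in call.diplotypes] == [("CYP2C9*1", "CYP2C9*1")]
        assert call.diplotypes[0].homozygous

    def test_strict_mode_missing_panel_snp_is_no_call(self, cyp2c9_kb):
        profile = {
            "rs1057910": Counter({"A": 1, "C": 1}),
            "rs1057911": Counter({"A": 2}),
            "rs1799853": Counter({"C": 2}),
        }
        call = call_diplotypes(profile, cyp2c9_kb, "CYP2C9")
        assert not call.called
        assert call.missing == ("rs2256871",)

    def test_lenient_mode_calls_on_observed_subset(self, cyp2c9_kb):
        profile = {
            "rs1057910": Counter({"A": 1, "C": 1}),
            "rs1057911": Counter({"A": 2}),
            "rs1799853": Counter({"C": 2}),
        }
        call = call_diplotypes(profile, cyp2c9_kb, "CYP2C9", strict=False)
        assert [d.pair for d in call.diplotypes] == [("CYP2C9*1", "CYP2C9*3")]

    def test_unphased_cis_trans_ambiguity(self):
        kb = _panel_kb({
            "A": {"s1": "G", "s2": "T"},
            "B": {"s1": "C", "s2": "A"},
            "C": {"s1": "G", "s2": "A"},
            "D": {"s1": "C", "s2": "T"},
        })
        profile = {"s1": Counter({"G": 1, "C": 1}), "s2": Counter({"T": 1, "A": 1})}
        call = call_diplotypes(profile, kb, "G1")
        assert {d.pair for d in call.diplotypes} == {("A", "B"), ("C", "D")}
        assert call.ambiguous

    def test_unknown_gene_rejected(self, cyp2c9_kb):
        with pytest.raises(KbError):
            call_diplotypes({}, cyp2c9_kb, "NOPE")

    def test_oracle_equivalence_random_panels(self):
        """Calling agrees with exhaustive pair enumeration, >=200 seeded cases."""
        rng = np.random.default_rng(42)
        bases = "ACGT"
        for case in range(220):
            n_hap = int(rng.integers(2, 13))
            n_snp = int(rng.integers(1, 5))
            rsids = [f"s{k}" for k in range(n_snp)]
            rows = {}
            for h in range(n_hap):
                rows[f"H*{h + 1}"] = {
                    r: bases[rng.integers(0, 4)] for r in rsids
                }
            kb = _panel_kb(rows)
            names = sorted(rows)
            i1, i2 = rng.integers(0, n_hap), rng.integers(0, n_hap)
            truth = tuple(sorted((names[i1], names[i2])))
            profile = {
                r: Counter((rows[truth[0]][r], rows[truth[1]][r])) for r in rsids
            }
            # independent oracle: compare genotype signatures of every pair
            signature = {r: tuple(sorted(profile[r].elements())) for r in rsids}
            expected = {
                (names[i], names[j])
                for i in range(n_hap)
                for j in range(i, n_hap)
                if all(
                    tuple(sorted((rows[names[i]][r], rows[names[j]][r])))
                    == signature[r]
                    for r in rsids
                )
            }
            got = {d.pair for d in call_diplotypes(profile, kb, "G1").diplotypes}
            assert got == expected, f"case {case}"
            assert truth in got

    def test_monotone_refinement(self):
        """Observing one more SNP never enlarges the consistent set."""
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for _ in range(40):
            rsids = [f"s{k}" for k in range(3)]
            rows = {
                f"H*{h + 1}": {r: bases[rng.integers(0, 4)] for r in rsids}
                for h in range(5)
            }
            kb = _panel_kb(rows)
            names = sorted(rows)
            t = tuple(sorted(rng.choice(names, size=2)))
            full = {r: Counter((rows[t[0]][r], rows[t[1]][r])) for r in rsids}
            prev = None
            for k in range(1, len(rsids) + 1):
                sub = {r: full[r] for r in rsids[:k]}
                got = {
                    d.pair
                    for d in call_diplotypes(sub, kb, "G1", strict=False).diplotypes
                }
                if prev is not None:
                    assert got <= prev
                prev = got

    def test_indistinguishable_pair_never_separated(self):
        kb = _panel_kb({
            "X": {"s1": "A"}, "Y": {"s1": "A"}, "Z": {"s1": "G"},
        })
        profile = {"s1": Counter({"A": 2})}
        got = {d.pair for d in call_diplotypes(profile, kb, "G1").diplotypes}
        # X and Y are interchangeable: every combination appears, none is unique
        assert got == {("X", "X"), ("X", "Y"), ("Y", "Y")}


class TestHaplotypeSupport:
    def test_heterozygote_support(self):
        d = Diplotype("CYP2C9", ("CYP2C9*1", "CYP2C9*3"))
        assert haplotype_support([d], HaplotypeTaxonomy()) == {
            "CYP2C9*1": 1, "CYP2C9*3": 1,
        }

    def test_taxonomy_closure(self):
        tax = HaplotypeTaxonomy({"TPMT*3A": "TPMT*3"})
        d = Diplotype("TPMT", ("TPMT*1", "TPMT*3A"))
        support = haplotype_support([d], tax)
        assert support["TPMT*3"] == 1 and support["TPMT*3A"] == 1

    def test_homozygote_counts_two(self):
        d = Diplotype("G", ("G*1", "G*1"))
        assert haplotype_support([d], HaplotypeTaxonomy()) == {"G*1": 2}

    def test_two_subtypes_give_parent_two_copies(self):
        tax = HaplotypeTaxonomy({"T*3A": "T*3", "T*3B": "T*3"})
        d = Diplotype("T", ("T*3A", "T*3B"))
        assert haplotype_support([d], tax)["T*3"] == 2


RULE27 = parse_expression({
    "and": [
        {"hap": "TPMT*1", "min": 1},
        {"or": [{"hap": n, "min": 1}
                for n in ("TPMT*2", "TPMT*3A", "TPMT*3B", "TPMT*3C", "TPMT*4")]},
    ]
})
RULE35_VIA_PARENT = parse_expression({
    "and": [
        {"hap": "TPMT*1", "min": 1},
        {"or": [{"hap": "TPMT*2", "min": 1}, {"hap": "TPMT*3", "min": 1},
                {"hap": "TPMT*4", "min": 1}]},
    ]
})


class TestEvaluateExpression:
    def test_deficient_carrier_triggers_cpic_rule(self):
        support = {"TPMT*1": 1, "TPMT*3A": 1, "TPMT*3": 1}
        assert evaluate_expression(RULE27, support)

    def test_parent_atom_satisfied_via_subtype(self):
        support = {"TPMT*1": 1, "TPMT*3A": 1, "TPMT*3": 1}
        assert evaluate_expression(RULE35_VIA_PARENT, support)

    def test_wild_type_homozygote_triggers_nothing(self):
        assert not evaluate_expression(RULE27, {"TPMT*1": 2})

    def test_warfarin_rule_with_variant_atom(self, cyp2c9_kb):
        expr = cyp2c9_kb.cds_rules[0].expression
        support = {"CYP2C9*1": 1, "CYP2C9*3": 1}
        profile = {"rs9923231": Counter({"T": 2})}
        assert evaluate_expression(expr, support, profile)
        assert not evaluate_expression(
            expr, support, {"rs9923231": Counter({"C": 1, "T": 1})}
        )

    def test_exactly_two_requires_true_homozygote(self):
        # two copies of the parent via two different subtypes is not homozygous
        expr = parse_expression({"hap": "T*3", "exactly": 2})
        support = {"T*3": 2, "T*3A": 1, "T*3B": 1}
        assert not evaluate_expression(expr, support, homozygotes=frozenset())
        assert evaluate_expression(
            expr, support, homozygotes=frozenset({"T*3", "T*3A"})
        )

    def test_atom_over_missing_snp_is_false(self):
        expr = parse_expression({"snp": "rs9923231", "allele": "T", "min": 1})
        assert not evaluate_expression(expr, {}, {})


class TestRealizePatient:
    def test_walkthrough_triggers_single_warfarin_message(
        self, demo_kb, warfarin_patient
    ):
        result = realize_patient(warfarin_patient, demo_kb)
        pairs = [d.pair for d in result.calls["CYP2C9"].diplotypes]
        assert pairs == [("CYP2C9*1", "CYP2C9*3")]
        assert [r.id for r in result.triggered] == ["warfarin_1"]
        assert result.triggered[0].message == fixtures.WARFARIN_MESSAGE
        # TPMT panel is entirely unobserved: no-call, not an error
        assert not result.calls["TPMT"].called
        assert result.stats == {"matched_snps": 5, "triggered_rules": 1}

    def test_empty_genotype_all_no_call(self, demo_kb):
        result = realize_patient(PatientGenotype(), demo_kb)
        assert all(not c.called for c in result.calls.values())
        assert not result.triggered
        assert result.matched_snps == 0

    def test_simulated_ground_truth_recovered(self):
        from pgxcds.simkit import SimConfig, simulate_panel

        config = SimConfig(seed=9, genes=2, n_patients=1)
        kb, _ = simulate_panel(config)
        gene = kb.genes()[0]
        names = kb.haplotype_names(gene)
        h1 = kb.haplotype(names[0])
        h2 = kb.haplotype(names[1])
        g = PatientGenotype(patient_id="truth")
        for kb_gene in kb.genes():
            a, b = (h1, h2) if kb_gene == gene else (
                kb.haplotypes[kb_gene][0], kb.haplotypes[kb_gene][0]
            )
            for rsid in kb.gene_panel(kb_gene):
                g.add_call(rsid, a.allele_map[rsid], b.allele_map[rsid])
        result = realize_patient(g, kb)
        assert (names[0], names[1]) in {
            d.pair for d in result.calls[gene].diplotypes
        }

    def test_recommendations_ordered_by_importance_then_id(self, tpmt_kb):
        from pgxcds.kb_model import CdsRule

        tpmt_kb.cds_rules.append(
            CdsRule(
                id="00_standard", drug="azathioprine",
                expression=parse_expression({"hap": "TPMT*1", "min": 1}),
                message="standard dosing", importance="standard",
            )
        )
        result = realize_patient(fixtures.tpmt_patient(kb=tpmt_kb), tpmt_kb)
        assert [r.id for r in result.triggered] == ["27", "35", "00_standard"]

    def test_json_serialization_shape(self, demo_kb, warfarin_patient):
        js = realize_patient(warfarin_patient, demo_kb).to_json()
        assert js["diplotypes"]["CYP2C9"] == ["CYP2C9*1/CYP2C9*3"]
        assert js["ambiguity"]["CYP2C9"] is False
        assert "TPMT" in js["no_call"]
        assert js["recommendations"][0]["drug"] == "warfarin"

    def test_phenotype_rules_feed_cds_rules(self, tpmt_kb):
        from pgxcds.kb_model import CdsRule, PhenotypeRule

        tpmt_kb.phenotype_rules.append(
            PhenotypeRule(
                id="ph1", phenotype_label="TPMT intermediate metabolizer",
                expression=RULE27,
            )
        )
        tpmt_kb.cds_rules = [
            CdsRule(
                id="via_phenotype", drug="azathioprine",
                expression=parse_expression(
                    {"phenotype": "TPMT intermediate metabolizer"}
                ),
                message="reduce dose",
            )
        ]
        result = realize_patient(fixtures.tpmt_patient(kb=tpmt_kb), tpmt_kb)
        assert result.phenotypes == ("TPMT intermediate metabolizer",)
        assert [r.id for r in result.triggered] == ["via_phenotype"]
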