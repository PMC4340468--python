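"""Rule-population semantics: decomposition, enumeration, subsumption, audit."""

import itertools

import numpy as np
import pytest

from pgxcds.kb_model import (
    And,
    CdsRule,
    HaplotypeAtom,
    HaplotypeDefinition,
    KbError,
    KnowledgeBase,
    Or,
    SnpDefinition,
    parse_expression,
)
from pgxcds.rule_logic import (
    NonDecomposableError,
    audit_conflicts,
    audit_to_tsv,
    compare_rules,
    gene_domain,
    per_gene_decompose,
    satisfying_diplotypes,
)


def _two_gene_kb():
    snps = {}
    haplotypes = {}
    for gi, gene in enumerate(("GA", "GB")):
        rsid = f"rs{100 + gi}"
        snps[rsid] = SnpDefinition(rsid, gene, "forward", frozenset({"A", "G"}))
        haplotypes[gene] = [
            HaplotypeDefinition(gene, f"{gene}*1", {rsid: "A"}),
            HaplotypeDefinition(gene, f"{gene}*2", {rsid: "G"}),
        ]
    return KnowledgeBase(snps=snps, haplotypes=haplotypes)


class TestDecompose:
    def test_single_gene_rule_stays_whole(self, tpmt_kb):
        expr = tpmt_kb.rule_by_id("27").expression
        parts = per_gene_decompose(expr, tpmt_kb)
        assert set(parts) == {"TPMT"}
        assert parts["TPMT"] == expr

    def test_two_gene_conjunction_splits(self, cyp2c9_kb):
        expr = cyp2c9_kb.cds_rules[0].expression  # CYP2C9 haps AND VKORC1 SNP
        parts = per_gene_decompose(expr, cyp2c9_kb)
        assert set(parts) == {"CYP2C9", "VKORC1"}

    def test_cross_gene_disjunction_rejected(self):
        kb = _two_gene_kb()
        expr = Or((HaplotypeAtom("GA*1"), HaplotypeAtom("GB*1")))
        with pytest.raises(NonDecomposableError):
            per_gene_decompose(expr, kb)


class TestSatisfyingDiplotypes:
    def test_min_one_atom_over_two_haplotypes(self):
        kb = _two_gene_kb()
        got = satisfying_diplotypes(HaplotypeAtom("GA*1"), "GA", kb)
        assert got == frozenset({
            ("pair", ("GA*1", "GA*1")), ("pair", ("GA*1", "GA*2")),
        })

    def test_cpic_rule_population(self, tpmt_kb):
        """*1 plus one deficient allele: only the *1-het carrier pairs."""
        expr = tpmt_kb.rule_by_id("27").expression
        got = satisfying_diplotypes(expr, "TPMT", tpmt_kb)
        expected = frozenset(
            ("pair", tuple(sorted(("TPMT*1", d))))
            for d in ("TPMT*2", "TPMT*3A", "TPMT*3B", "TPMT*3C", "TPMT*4")
        )
        assert got == expected

    def test_unsatisfiable_expression_empty(self):
        kb = _two_gene_kb()
        expr = And((
            HaplotypeAtom("GA*1", 2, "exactly"),
            HaplotypeAtom("GA*2", 1, "at_least"),
        ))
        assert satisfying_diplotypes(expr, "GA", kb) == frozenset()

    def test_snp_only_gene_domain(self, cyp2c9_kb):
        # VKORC1 has a registry SNP but no haplotype panel
        dom = gene_domain(cyp2c9_kb, "VKORC1")
        assert len(dom) == 3  # CC, CT, TT
        expr = parse_expression({"snp": "rs9923231", "allele": "T", "exactly": 2})
        got = satisfying_diplotypes(expr, "VKORC1", cyp2c9_kb)
        assert got == frozenset({("snps", (("rs9923231", ("T", "T")),))})


class TestCompareRules:
    def test_published_azathioprine_pair_nested_with_conflict(self, tpmt_kb):
        finding = compare_rules(
            tpmt_kb.rule_by_id("27"), tpmt_kb.rule_by_id("35"), tpmt_kb
        )
        assert finding.relation == "A_subsumed_by_B"
        assert finding.conflict
        assert finding.drug == "azathioprine"
        # a witness the broader Dutch rule admits but the CPIC rule excludes
        assert "TPMT" in finding.witnesses

    def test_rule_compared_with_itself_equivalent(self, tpmt_kb):
        r = tpmt_kb.rule_by_id("27")
        clone = CdsRule(id="27bis", drug=r.drug, expression=r.expression,
                        message=r.message, source=r.source,
                        importance=r.importance)
        finding = compare_rules(r, clone, tpmt_kb)
        assert finding.relation == "equivalent"
        assert not finding.conflict  # identical message: no conflict

    def test_disjoint_populations(self, tpmt_kb):
        a = CdsRule(id="a", drug="d",
                    expression=parse_expression({"hap": "TPMT*1", "exactly": 2}),
                    message="m1")
        b = CdsRule(id="b", drug="d",
                    expression=parse_expression({"hap": "TPMT*2", "exactly": 2}),
                    message="m2")
        assert compare_rules(a, b, tpmt_kb).relation == "disjoint"

    def test_random_pairs_agree_with_product_space_oracle(self):
        """Componentwise classification matches full truth-table enumeration."""
        rng = np.random.default_rng(17)
        from pgxcds.simkit import SimConfig, simulate_panel

        disagreements = 0
        cases = 0
        for seed in range(12):
            config = SimConfig(seed=seed, genes=int(rng.integers(1, 4)),
                               snps_per_gene=3,
                               haplotypes_per_gene=int(rng.integers(2, 7)))
            kb, _ = simulate_panel(config)
            genes = kb.genes()
            for _ in range(10):
                exprs = []
                for _ in range(2):
                    n_atoms = int(rng.integers(1, 4))
                    atoms = []
                    for _ in range(n_atoms):
                        gene = genes[rng.integers(len(genes))]
                        names = kb.haplotype_names(gene)
                        atoms.append(HaplotypeAtom(
                            names[rng.integers(len(names))],
                            int(rng.integers(1, 3)),
                            "exactly" if rng.random() < 0.25 else "at_least",
                        ))
                    exprs.append(
                        And(tuple(atoms)) if rng.random() < 0.7
                        else Or(tuple(atoms))
                    )
                a = CdsRule(id="a", drug="d", expression=exprs[0], message="ma")
                b = CdsRule(id="b", drug="d", expression=exprs[1], message="mb")
                got = compare_rules(a, b, kb).relation
                expected = _oracle_relation(exprs[0], exprs[1], kb)
                cases += 1
                if got != expected:
                    disagreements += 1
        assert cases >= 100
        assert disagreements == 0

    def test_subsumption_transitive_on_nested_disjunctions(self, tpmt_kb):
        def rule(rid, subtypes):
            return CdsRule(
                id=rid, drug="d",
                expression=And((
                    HaplotypeAtom("TPMT*1"),
                    Or(tuple(HaplotypeAtom(s) for s in subtypes)),
                )),
                message=rid,
            )

        r1 = rule("r1", ["TPMT*2"])
        r2 = rule("r2", ["TPMT*2", "TPMT*3A"])
        r3 = rule("r3", ["TPMT*2", "TPMT*3A", "TPMT*4"])
        assert compare_rules(r1, r2, tpmt_kb).relation == "A_subsumed_by_B"
        assert compare_rules(r2, r3, tpmt_kb).relation == "A_subsumed_by_B"
        assert compare_rules(r1, r3, tpmt_kb).relation == "A_subsumed_by_B"

    def test_taxonomy_closure_monotone(self, tpmt_kb):
        """Adding a parent link never shrinks a satisfying set."""
        expr = parse_expression({"hap": "TPMT*3", "min": 1})
        before = satisfying_diplotypes(expr, "TPMT", tpmt_kb)
        import copy

        wider_kb = copy.deepcopy(tpmt_kb)
        wider_kb.taxonomy.parent["TPMT*5"] = "TPMT*3"
        after = satisfying_diplotypes(expr, "TPMT", wider_kb)
        assert before <= after and len(after) > len(before)


def _oracle_relation(expr_a, expr_b, kb):
    """Truth-table oracle over the full product of per-gene diplotype states."""
    from collections import Counter

    genes = kb.genes()
    per_gene = []
    for gene in genes:
        names = kb.haplotype_names(gene)
        per_gene.append([
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i, len(names))
        ])

    def holds(expr, assignment):
        counts = Counter()
        homozygote = set()
        for pair in assignment:
            for member in pair:
                for nm in kb.taxonomy.self_and_ancestors(member):
                    counts[nm] += 1
            if pair[0] == pair[1]:
                homozygote.update(kb.taxonomy.self_and_ancestors(pair[0]))
        def rec(e):
            if isinstance(e, And):
                return all(rec(c) for c in e.children)
            if isinstance(e, Or):
                return any(rec(c) for c in e.children)
            if e.mode == "at_least":
                return counts.get(e.name, 0) >= e.cardinality
            if e.cardinality == 2:
                return e.name in homozygote
            return counts.get(e.name, 0) == 1
        return rec(expr)

    pop_a, pop_b = set(), set()
    for assignment in itertools.product(*per_gene):
        if holds(expr_a, assignment):
            pop_a.add(assignment)
        if holds(expr_b, assignment):
            pop_b.add(assignment)
    if pop_a == pop_b:
        return "equivalent"
    if pop_a <= pop_b:
        return "A_subsumed_by_B"
    if pop_b <= pop_a:
        return "B_subsumed_by_A"
    if pop_a & pop_b:
        return "overlapping"
    return "disjoint"


class TestAudit:
    def test_two_rule_fixture_counts(self, tpmt_kb):
        result = audit_conflicts(tpmt_kb)
        assert len(result.findings) == 1
        assert result.findings[0].relation == "A_subsumed_by_B"
        assert result.findings[0].conflict
        # narrower-or-equal convention: only the CPIC rule is the narrow side
        assert result.summary["narrower_or_equal_rules"] == 1
        assert result.summary["participating_rules"] == 2
        assert result.summary["conflicting_pairs"] == 1

    def test_disjoint_rules_no_findings(self, tpmt_kb):
        tpmt_kb.cds_rules = [
            CdsRule(id="a", drug="d",
                    expression=parse_expression({"hap": "TPMT*1", "exactly": 2}),
                    message="m1"),
            CdsRule(id="b", drug="d",
                    expression=parse_expression({"hap": "TPMT*2", "exactly": 2}),
                    message="m2"),
        ]
        result = audit_conflicts(tpmt_kb)
        assert result.findings == []
        assert result.summary["narrower_or_equal_rules"] == 0

    def test_duplicated_rule_under_two_sources_conflicts(self, tpmt_kb):
        r = tpmt_kb.rule_by_id("27")
        tpmt_kb.cds_rules = [
            r,
            CdsRule(id="27_dup", drug=r.drug, expression=r.expression,
                    message="different wording", source="other group",
                    importance=r.importance),
        ]
        result = audit_conflicts(tpmt_kb)
        assert result.findings[0].relation == "equivalent"
        assert result.findings[0].conflict
        assert result.summary["narrower_or_equal_rules"] == 2

    def test_tsv_report_shape(self, tpmt_kb):
        text = audit_to_tsv(audit_conflicts(tpmt_kb))
        lines = text.strip().split("\n")
        assert lines[0].split("\t") == [
            "ruleA", "ruleB", "relation", "drug", "conflict", "witness",
        ]
        assert lines[1].startswith("27\t35\tA_subsumed_by_B\tazathioprine\ttrue")
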