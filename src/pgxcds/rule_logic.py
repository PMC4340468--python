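"""Population semantics for rules: model enumeration, subsumption, conflicts.

A rule's target population is the set of complete diplotype assignments
(every constrained gene carries an unordered pair of star alleles; SNP-only
genes carry an unordered allele pair per SNP) that satisfy its expression.
Because the space is finite, description-logic subsumption between rule
populations reduces to explicit set containment over enumerated models —
two rules target nested populations exactly when one's satisfying set is
contained in the other's, taxonomy closure included.

The practically important product of this machinery is the conflict audit:
pairs of rules whose populations are equivalent or nested, for the same
drug, but with different recommendation texts — the situation where two
guideline sources would tell the same patient different things.

For tractability, expressions are first decomposed into per-gene
conjuncts (AND distributes over genes; an OR must stay within one gene);
population comparison is then componentwise.  Genuinely cross-gene
disjunctions fall back to bounded enumeration over the product space and
report an explicit "undecided" outcome if the model count limit is hit.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .kb_model import (
    And,
    CdsRule,
    Expression,
    HaplotypeAtom,
    KbError,
    KnowledgeBase,
    Or,
    PhenotypeAtom,
    VariantAtom,
)
from .inference import EvalContext, _closed_counts, _eval

__all__ = [
    "NonDecomposableError",
    "ModelLimitError",
    "RelationFinding",
    "AuditResult",
    "per_gene_decompose",
    "gene_domain",
    "satisfying_diplotypes",
    "is_satisfiable",
    "compare_rules",
    "audit_conflicts",
    "audit_to_tsv",
]

DEFAULT_MODEL_LIMIT = 10**6


class NonDecomposableError(KbError):
    """An OR mixes genes; per-gene decomposition is impossible."""


class ModelLimitError(KbError):
    """Product-space enumeration would exceed the configured model count."""


# --------------------------------------------------------------------------
# Decomposition


def inline_phenotypes(expr: Expression, kb: KnowledgeBase) -> Expression:
    """Replace phenotype atoms by the disjunction of their defining expressions."""
    if isinstance(expr, And):
        return And(tuple(inline_phenotypes(c, kb) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(inline_phenotypes(c, kb) for c in expr.children))
    if isinstance(expr, PhenotypeAtom):
        defs = [
            r.expression for r in kb.phenotype_rules if r.phenotype_label == expr.label
        ]
        if not defs:
            raise KbError(f"phenotype {expr.label!r} has no defining rule")
        inlined = [inline_phenotypes(e, kb) for e in defs]
        return inlined[0] if len(inlined) == 1 else Or(tuple(inlined))
    return expr


def _atom_gene(atom, kb: KnowledgeBase) -> str:
    if isinstance(atom, HaplotypeAtom):
        return kb.gene_of_star(atom.name)
    if isinstance(atom, VariantAtom):
        snp = kb.snps.get(atom.rsid)
        if snp is None:
            raise KbError(f"unknown rsID {atom.rsid!r} in rule atom")
        return snp.gene
    raise KbError(f"atom without a gene: {atom!r}")


def per_gene_decompose(expr: Expression, kb: KnowledgeBase) -> dict:
    """Rewrite a monotone expression into a conjunction of per-gene parts.

    Atoms carry their own gene; AND merges children's maps (conjoining parts
    that share a gene); an OR is decomposable only when all of its children
    constrain the same single gene.  Raises :class:`NonDecomposableError`
    for cross-gene disjunctions, directing the caller to full product
    enumeration.
    """
    if isinstance(expr, (HaplotypeAtom, VariantAtom)):
        return {_atom_gene(expr, kb): expr}
    if isinstance(expr, PhenotypeAtom):
        raise KbError("phenotype atoms must be inlined before decomposition")
    if isinstance(expr, And):
        merged: dict = {}
        for child in expr.children:
            for gene, sub in per_gene_decompose(child, kb).items():
                if gene in merged:
                    prev = merged[gene]
                    parts = prev.children if isinstance(prev, And) else (prev,)
                    merged[gene] = And(parts + (sub,))
                else:
                    merged[gene] = sub
        return merged
    if isinstance(expr, Or):
        parts = [per_gene_decompose(c, kb) for c in expr.children]
        genes = {g for p in parts for g in p}
        if any(len(p) != 1 for p in parts) or len(genes) != 1:
            raise NonDecomposableError(
                f"disjunction spans genes {sorted(genes)}: use product enumeration"
            )
        gene = genes.pop()
        return {gene: Or(tuple(p[gene] for p in parts))}
    raise KbError(f"cannot decompose node {expr!r}")


# --------------------------------------------------------------------------
# Per-gene model domains


def gene_domain(kb: KnowledgeBase, gene: str) -> tuple:
    """All candidate states for a gene, as hashable labels, sorted.

    For a gene with a star-allele panel the states are the unordered
    haplotype-name pairs.  For a registry-only gene (no panel) they are the
    assignments of an unordered allele pair to each of the gene's SNPs.
    """
    if gene in kb.haplotypes and kb.haplotypes[gene]:
        names = kb.haplotype_names(gene)
        return tuple(
            ("pair", (names[i], names[j]))
            for i in range(len(names))
            for j in range(i, len(names))
        )
    rsids = sorted(r for r, s in kb.snps.items() if s.gene == gene)
    if not rsids:
        raise KbError(f"gene {gene!r} has neither haplotypes nor registry SNPs")
    per_snp = []
    for r in rsids:
        alleles = sorted(kb.snps[r].alleles)
        pairs = [
            (alleles[i], alleles[j])
            for i in range(len(alleles))
            for j in range(i, len(alleles))
        ]
        per_snp.append([(r, p) for p in pairs])
    return tuple(("snps", combo) for combo in itertools.product(*per_snp))


def _state_evidence(kb: KnowledgeBase, gene: str, label) -> tuple:
    """(counts, profile, homozygotes) evidence implied by one gene state."""
    kind, payload = label
    if kind == "pair":
        h1 = kb.haplotype(payload[0])
        h2 = kb.haplotype(payload[1])
        counts = _closed_counts(payload, kb.taxonomy)
        profile = {
            r: Counter((h1.allele_map[r], h2.allele_map[r])) for r in h1.allele_map
        }
        homozygotes = (
            frozenset(kb.taxonomy.self_and_ancestors(payload[0]))
            if payload[0] == payload[1]
            else frozenset()
        )
        return counts, profile, homozygotes
    profile = {r: Counter(p) for r, p in payload}
    return Counter(), profile, frozenset()


def _state_ctx(kb: KnowledgeBase, states) -> EvalContext:
    """Merge one state per gene into a single evaluation context."""
    support: Counter = Counter()
    profile: dict = {}
    homozygotes: set = set()
    for gene, label in states:
        counts, prof, homo = _state_evidence(kb, gene, label)
        support.update(counts)
        profile.update(prof)
        homozygotes.update(homo)
    return EvalContext(
        support=support,
        profile=profile,
        phenotypes=frozenset(),
        homozygotes=frozenset(homozygotes),
        counts_list=(support,),
    )


def satisfying_diplotypes(
    sub_expr: Expression, gene: str, kb: KnowledgeBase
) -> frozenset:
    """States of one gene whose implied evidence satisfies ``sub_expr``."""
    return frozenset(
        label
        for label in gene_domain(kb, gene)
        if _eval(sub_expr, _state_ctx(kb, [(gene, label)]))
    )


def is_satisfiable(
    expr: Expression, kb: KnowledgeBase, limit: int = DEFAULT_MODEL_LIMIT
) -> bool:
    """Does any complete diplotype assignment satisfy the expression?

    Uses per-gene decomposition when possible (satisfiable iff every per-gene
    component admits a state); otherwise bounded product enumeration.
    """
    expr = inline_phenotypes(expr, kb)
    try:
        parts = per_gene_decompose(expr, kb)
    except NonDecomposableError:
        genes = sorted({_atom_gene(a, kb) for a in _atoms(expr)})
        for states in _bounded_product(kb, genes, limit):
            if _eval(expr, _state_ctx(kb, states)):
                return True
        return False
    return all(
        satisfying_diplotypes(sub, gene, kb) for gene, sub in parts.items()
    )


def _atoms(expr: Expression):
    if isinstance(expr, (And, Or)):
        for c in expr.children:
            yield from _atoms(c)
    else:
        yield expr


def _bounded_product(kb: KnowledgeBase, genes, limit: int):
    domains = [gene_domain(kb, g) for g in genes]
    total = 1
    for d in domains:
        total *= len(d)
    if total > limit:
        raise ModelLimitError(
            f"product space has {total} models, exceeding limit {limit}"
        )
    for combo in itertools.product(*domains):
        yield tuple(zip(genes, combo))


# --------------------------------------------------------------------------
# Pairwise comparison


@dataclass(frozen=True)
class RelationFinding:
    """How two rules' target populations relate, with witnesses.

    ``relation`` is one of equivalent / A_subsumed_by_B / B_subsumed_by_A /
    overlapping / disjoint / undecided.  ``conflict`` is set when the
    populations are nested or equal, both rules concern the same drug, and
    the recommendation texts differ — the clinically interesting case.
    """

    rule_a: str
    rule_b: str
    relation: str
    witnesses: dict = field(default_factory=dict)
    conflict: bool = False
    drug: Optional[str] = None


def _conflict(a, b, relation: str) -> bool:
    if relation not in ("equivalent", "A_subsumed_by_B", "B_subsumed_by_A"):
        return False
    if not (isinstance(a, CdsRule) and isinstance(b, CdsRule)):
        return False
    return a.drug == b.drug and a.message != b.message


def compare_rules(
    a, b, kb: KnowledgeBase, limit: int = DEFAULT_MODEL_LIMIT
) -> RelationFinding:
    """Classify the relation between two rules' target populations.

    Componentwise over per-gene satisfying sets when both expressions
    decompose: A is subsumed by B iff, for every gene B constrains, A
    constrains it too and A's set is contained in B's (an empty component
    also subsumes trivially — the population is empty).  ``overlapping``
    requires a non-empty intersection at every constrained gene without
    containment either way.  Non-decomposable pairs fall back to bounded
    product enumeration; exceeding the limit yields relation ``undecided``,
    never a silent truncation.
    """
    drug = a.drug if isinstance(a, CdsRule) and isinstance(b, CdsRule) and a.drug == b.drug else None
    try:
        ea = inline_phenotypes(a.expression, kb)
        eb = inline_phenotypes(b.expression, kb)
        da = per_gene_decompose(ea, kb)
        db = per_gene_decompose(eb, kb)
    except NonDecomposableError:
        return _compare_product(a, b, kb, limit, drug)

    sat_a = {g: satisfying_diplotypes(sub, g, kb) for g, sub in da.items()}
    sat_b = {g: satisfying_diplotypes(sub, g, kb) for g, sub in db.items()}
    empty_a = any(not s for s in sat_a.values())
    empty_b = any(not s for s in sat_b.values())

    genes = sorted(set(sat_a) | set(sat_b))
    full = {g: frozenset(gene_domain(kb, g)) for g in genes}
    # an unconstrained gene admits its full domain, so componentwise
    # containment over the union of genes is exactly population containment
    sub_ab = empty_a or all(
        sat_a.get(g, full[g]) <= sat_b.get(g, full[g]) for g in genes
    )
    sub_ba = empty_b or all(
        sat_b.get(g, full[g]) <= sat_a.get(g, full[g]) for g in genes
    )

    inter = {g: sat_a.get(g, full[g]) & sat_b.get(g, full[g]) for g in genes}
    overlapping = (not empty_a) and (not empty_b) and all(inter.values())

    witnesses: dict = {}
    if sub_ab and sub_ba:
        relation = "equivalent"
    elif sub_ab:
        relation = "A_subsumed_by_B"
        witnesses = _strict_witness(sat_b, sat_a, kb)
    elif sub_ba:
        relation = "B_subsumed_by_A"
        witnesses = _strict_witness(sat_a, sat_b, kb)
    elif overlapping:
        relation = "overlapping"
        witnesses = {g: {"both": min(inter[g])} for g in genes if inter[g]}
    else:
        relation = "disjoint"
    return RelationFinding(
        rule_a=a.id,
        rule_b=b.id,
        relation=relation,
        witnesses=witnesses,
        conflict=_conflict(a, b, relation),
        drug=drug,
    )


def _strict_witness(wider: dict, narrower: dict, kb: KnowledgeBase) -> dict:
    """Per-gene states the wider rule admits that the narrower one excludes."""
    out = {}
    genes = sorted(set(wider) | set(narrower))
    for g in genes:
        full = frozenset(gene_domain(kb, g))
        extra = wider.get(g, full) - narrower.get(g, full)
        if extra:
            out[g] = {"wider_only": min(extra)}
    return out


def _compare_product(a, b, kb, limit, drug) -> RelationFinding:
    ea = inline_phenotypes(a.expression, kb)
    eb = inline_phenotypes(b.expression, kb)
    genes = sorted(
        {_atom_gene(x, kb) for x in _atoms(ea)}
        | {_atom_gene(x, kb) for x in _atoms(eb)}
    )
    try:
        models = list(_bounded_product(kb, genes, limit))
    except ModelLimitError:
        return RelationFinding(a.id, b.id, "undecided", {}, False, drug)
    pop_a = set()
    pop_b = set()
    for states in models:
        ctx = _state_ctx(kb, states)
        if _eval(ea, ctx):
            pop_a.add(states)
        if _eval(eb, ctx):
            pop_b.add(states)
    if pop_a == pop_b:
        relation = "equivalent"
    elif pop_a <= pop_b:
        relation = "A_subsumed_by_B"
    elif pop_b <= pop_a:
        relation = "B_subsumed_by_A"
    elif pop_a & pop_b:
        relation = "overlapping"
    else:
        relation = "disjoint"
    witnesses = {}
    both = pop_a & pop_b
    if both and relation == "overlapping":
        witnesses["model"] = {"both": min(both)}
    return RelationFinding(a.id, b.id, relation, witnesses,
                           _conflict(a, b, relation), drug)


# --------------------------------------------------------------------------
# Knowledge-base-wide audit


@dataclass
class AuditResult:
    findings: list
    summary: dict


def audit_conflicts(kb: KnowledgeBase, limit: int = DEFAULT_MODEL_LIMIT) -> AuditResult:
    """Compare every unordered rule pair; summarise overlap and conflict counts.

    The summary reports two conventions for "rules with equivalent or
    subsumed populations": ``narrower_or_equal_rules`` counts a rule when its
    population is equal to, or strictly contained in, some other rule's
    (equivalent pairs count both members, strict subsumption only the
    narrower side); ``participating_rules`` counts any rule on either side of
    an equivalence/subsumption.
    """
    rules = sorted(kb.all_rules(), key=lambda r: r.id)
    findings = []
    narrower: set = set()
    participating: set = set()
    conflicted: set = set()
    for i in range(len(rules)):
        for j in range(i + 1, len(rules)):
            f = compare_rules(rules[i], rules[j], kb, limit=limit)
            if f.relation == "disjoint":
                continue
            findings.append(f)
            if f.relation == "equivalent":
                narrower.update((f.rule_a, f.rule_b))
                participating.update((f.rule_a, f.rule_b))
            elif f.relation == "A_subsumed_by_B":
                narrower.add(f.rule_a)
                participating.update((f.rule_a, f.rule_b))
            elif f.relation == "B_subsumed_by_A":
                narrower.add(f.rule_b)
                participating.update((f.rule_a, f.rule_b))
            if f.conflict:
                conflicted.update((f.rule_a, f.rule_b))
    summary = {
        "n_rules": len(rules),
        "n_pairs": len(rules) * (len(rules) - 1) // 2,
        "n_findings": len(findings),
        "narrower_or_equal_rules": len(narrower),
        "participating_rules": len(participating),
        "conflicting_rules": len(conflicted),
        "conflicting_pairs": sum(1 for f in findings if f.conflict),
    }
    return AuditResult(findings=findings, summary=summary)


def audit_to_tsv(result: AuditResult) -> str:
    lines = ["ruleA\truleB\trelation\tdrug\tconflict\twitness"]
    for f in result.findings:
        lines.append(
            "\t".join(
                [
                    f.rule_a,
                    f.rule_b,
                    f.relation,
                    f.drug or "",
                    str(f.conflict).lower(),
                    repr(f.witnesses) if f.witnesses else "",
                ]
            )
        )
    return "\n".join(lines) + "\n"
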