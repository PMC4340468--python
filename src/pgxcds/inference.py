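"""Diplotype calling, phenotype inference, and CDS rule matching.

The reasoning pipeline mirrors how a description-logic reasoner realises a
patient against star-allele class definitions, re-implemented natively over
the finite diplotype space:

1. the genotype is condensed to a per-SNP zygosity profile (allele counts
   summing to two);
2. for each gene with a haplotype panel, every unordered pair of star
   alleles whose combined allele multiset reproduces the observed profile at
   every panel SNP is a consistent diplotype — calling is strict by default:
   any panel SNP missing from the profile yields a no-call rather than a
   guess, which trades recall for precision exactly as conservative
   necessary-and-sufficient allele definitions do;
3. haplotype support is read off the consistent diplotypes under
   union-entailment semantics and closed upward through the star-allele
   taxonomy (a *3A carrier supports *3);
4. phenotype rules, then CDS rules, are evaluated as monotone boolean
   expressions over cardinality atoms; triggered recommendations are ordered
   by clinical importance, then rule id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .kb_model import (
    And,
    CdsRule,
    Expression,
    HaplotypeAtom,
    HaplotypeTaxonomy,
    KbError,
    KnowledgeBase,
    Or,
    PhenotypeAtom,
    VariantAtom,
)
from .genotype_io import PatientGenotype

__all__ = [
    "Diplotype",
    "GeneCall",
    "InferenceResult",
    "zygosity_profile",
    "call_diplotypes",
    "haplotype_support",
    "evaluate_expression",
    "realize_patient",
]

_IMPORTANCE_RANK = {"important_modification": 0, "minor_deviation": 1, "standard": 2}


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of star alleles carried by one individual at a gene."""

    gene: str
    pair: tuple  # (name, name), sorted

    def __post_init__(self):
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        if len(self.pair) != 2:
            raise KbError("a diplotype is exactly two haplotype names")

    @property
    def homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]

    def __str__(self) -> str:
        return f"{self.pair[0]}/{self.pair[1]}"


@dataclass
class GeneCall:
    """Outcome of diplotype calling for one gene."""

    gene: str
    diplotypes: tuple = ()  # sorted tuple of Diplotype
    missing: tuple = ()  # panel rsIDs absent from the profile (no-call reason)

    @property
    def called(self) -> bool:
        return bool(self.diplotypes)

    @property
    def ambiguous(self) -> bool:
        return len(self.diplotypes) > 1


def zygosity_profile(genotype: PatientGenotype) -> dict:
    """Per-SNP allele counts (summing to 2); missing rsIDs are simply absent."""
    return {rsid: Counter(pair) for rsid, pair in genotype.calls.items()}


def call_diplotypes(
    profile: Mapping[str, Counter],
    kb: KnowledgeBase,
    gene: str,
    strict: bool = True,
) -> GeneCall:
    """All star-allele pairs consistent with the observed zygosity at a gene.

    A pair ``{h1, h2}`` is consistent when, at every panel SNP, the multiset
    of the two haplotypes' defining alleles equals the observed allele
    counts.  In strict mode (default) any panel SNP absent from the profile
    aborts with a no-call listing the missing rsIDs; in lenient mode the
    consistency check is restricted to the observed panel SNPs, trading
    precision for recall.
    """
    defs = kb.haplotypes.get(gene)
    if not defs:
        raise KbError(f"unknown gene {gene!r}")
    panel = kb.gene_panel(gene)
    missing = tuple(r for r in panel if r not in profile)
    if strict and missing:
        return GeneCall(gene=gene, missing=missing)
    check = [r for r in panel if r in profile]
    if not check:
        return GeneCall(gene=gene, missing=missing)
    ordered = sorted(defs, key=lambda h: h.name)
    found = []
    for i in range(len(ordered)):
        for j in range(i, len(ordered)):
            h1, h2 = ordered[i], ordered[j]
            if all(
                Counter((h1.allele_map[r], h2.allele_map[r])) == profile[r]
                for r in check
            ):
                found.append(Diplotype(gene=gene, pair=(h1.name, h2.name)))
    if not found:
        # covered but inconsistent with every pair: report as uncalled with
        # no missing SNPs, distinguishing "no data" from "no match"
        return GeneCall(gene=gene, missing=missing)
    return GeneCall(gene=gene, diplotypes=tuple(sorted(found, key=lambda d: d.pair)),
                    missing=missing)


def _closed_counts(pair: Sequence[str], taxonomy: HaplotypeTaxonomy) -> Counter:
    """Copy counts per star-allele name, closed upward through the taxonomy."""
    counts = Counter()
    for member in pair:
        for name in taxonomy.self_and_ancestors(member):
            counts[name] += 1
    return counts


def haplotype_support(
    diplotypes: Iterable[Diplotype], taxonomy: HaplotypeTaxonomy
) -> dict:
    """Union-entailment support: name -> max copy count over consistent diplotypes.

    Every consistent diplotype contributes its haplotypes (and their taxonomy
    ancestors); a name's support is the largest copy count any single
    diplotype gives it.  Under ambiguity this is deliberately permissive —
    callers can consult the ambiguity flag to suppress recommendations.
    """
    support: dict = {}
    for d in diplotypes:
        for name, c in _closed_counts(d.pair, taxonomy).items():
            support[name] = max(support.get(name, 0), c)
    return support


@dataclass(frozen=True)
class EvalContext:
    """Evidence against which rule atoms are evaluated."""

    support: Mapping[str, int]
    profile: Mapping[str, Counter]
    phenotypes: frozenset
    homozygotes: frozenset  # taxonomy-closed names with a homozygous diplotype
    counts_list: Optional[tuple] = None  # per-diplotype closed Counters


def _eval(expr: Expression, ctx: EvalContext) -> bool:
    if isinstance(expr, And):
        return all(_eval(c, ctx) for c in expr.children)
    if isinstance(expr, Or):
        return any(_eval(c, ctx) for c in expr.children)
    if isinstance(expr, HaplotypeAtom):
        if expr.mode == "at_least":
            return ctx.support.get(expr.name, 0) >= expr.cardinality
        if expr.cardinality == 2:
            return expr.name in ctx.homozygotes
        if ctx.counts_list is not None:
            return any(c.get(expr.name, 0) == 1 for c in ctx.counts_list)
        return ctx.support.get(expr.name, 0) == 1
    if isinstance(expr, VariantAtom):
        count = ctx.profile.get(expr.rsid, Counter()).get(expr.allele, 0)
        if expr.mode == "at_least":
            return count >= expr.cardinality
        return count == expr.cardinality
    if isinstance(expr, PhenotypeAtom):
        return expr.label in ctx.phenotypes
    raise KbError(f"cannot evaluate node {expr!r}")


def evaluate_expression(
    expr: Expression,
    support: Mapping[str, int],
    profile: Optional[Mapping[str, Counter]] = None,
    phenotypes: Iterable[str] = (),
    homozygotes: Optional[Iterable[str]] = None,
    counts_list: Optional[Sequence[Counter]] = None,
) -> bool:
    """Evaluate a monotone rule expression against patient evidence.

    ``HaplotypeAtom(at_least c)`` holds when support reaches ``c``;
    ``HaplotypeAtom(exactly 2)`` holds only for a homozygous consistent
    diplotype of that star allele (or a taxonomy descendant) — two copies via
    two different subtypes do not count as a homozygote.  Variant atoms count
    alleles in the zygosity profile; atoms over missing SNPs or no-call genes
    are simply false (a rule never fires on absent evidence).

    ``homozygotes`` and ``counts_list`` carry per-diplotype evidence for the
    "exactly" modes; when omitted they are approximated from aggregated
    support (sufficient for at_least-only expressions).
    """
    if homozygotes is None:
        homozygotes = {n for n, c in support.items() if c >= 2}
    return _eval(
        expr,
        EvalContext(
            support=support,
            profile=profile or {},
            phenotypes=frozenset(phenotypes),
            homozygotes=frozenset(homozygotes),
            counts_list=tuple(counts_list) if counts_list is not None else None,
        ),
    )


@dataclass
class InferenceResult:
    """Everything inferred for one patient: calls, phenotypes, recommendations."""

    patient_id: str
    calls: dict = field(default_factory=dict)  # gene -> GeneCall
    phenotypes: tuple = ()
    triggered: tuple = ()  # CdsRule, ordered by importance then id
    matched_snps: int = 0

    @property
    def stats(self) -> dict:
        return {"matched_snps": self.matched_snps,
                "triggered_rules": len(self.triggered)}

    def to_json(self) -> dict:
        return {
            "patient": self.patient_id,
            "diplotypes": {
                g: [str(d) for d in c.diplotypes]
                for g, c in sorted(self.calls.items())
            },
            "ambiguity": {g: c.ambiguous for g, c in sorted(self.calls.items())},
            "no_call": {
                g: list(c.missing)
                for g, c in sorted(self.calls.items())
                if not c.called
            },
            "phenotypes": list(self.phenotypes),
            "recommendations": [
                {
                    "rule": r.id,
                    "drug": r.drug,
                    "importance": r.importance,
                    "source": r.source,
                    "message": r.message,
                }
                for r in self.triggered
            ],
            "stats": self.stats,
        }


def realize_patient(
    genotype: PatientGenotype, kb: KnowledgeBase, strict: bool = True
) -> InferenceResult:
    """Run the full pipeline: zygosity -> diplotypes -> phenotypes -> CDS rules."""
    profile = zygosity_profile(genotype)
    calls = {g: call_diplotypes(profile, kb, g, strict=strict) for g in kb.genes()}

    all_diplotypes = [d for c in calls.values() for d in c.diplotypes]
    support = haplotype_support(all_diplotypes, kb.taxonomy)
    counts_list = tuple(_closed_counts(d.pair, kb.taxonomy) for d in all_diplotypes)
    homozygotes = frozenset(
        name
        for d in all_diplotypes
        if d.homozygous
        for name in kb.taxonomy.self_and_ancestors(d.pair[0])
    )

    def holds(expr: Expression, phenotypes: frozenset) -> bool:
        return _eval(
            expr,
            EvalContext(
                support=support,
                profile=profile,
                phenotypes=phenotypes,
                homozygotes=homozygotes,
                counts_list=counts_list,
            ),
        )

    # phenotype rules may reference other phenotype labels: iterate to fixpoint
    phenotypes: frozenset = frozenset()
    for _ in range(max(1, len(kb.phenotype_rules))):
        new = frozenset(
            r.phenotype_label
            for r in kb.phenotype_rules
            if holds(r.expression, phenotypes)
        )
        if new == phenotypes:
            break
        phenotypes = new

    triggered = [r for r in kb.cds_rules if holds(r.expression, phenotypes)]
    triggered.sort(key=lambda r: (_IMPORTANCE_RANK[r.importance], r.id))

    matched = sum(1 for rsid in genotype.calls if rsid in kb.snps)
    return InferenceResult(
        patient_id=genotype.patient_id,
        calls=calls,
        phenotypes=tuple(sorted(phenotypes)),
        triggered=tuple(triggered),
        matched_snps=matched,
    )
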