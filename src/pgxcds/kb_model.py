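"""Knowledge-base model: SNPs, star-allele haplotypes, rules, and static validation.

A pharmacogenomic knowledge base relates three layers of description:

* polymorphisms (SNPs and small indels, identified by dbSNP rsIDs) and the
  alleles observable at each of them;
* star alleles (named haplotypes such as ``CYP2C9*3``), each defined as a
  total map from the gene's SNP panel to one allele per SNP, following the
  layout of PharmGKB haplotype translation tables;
* rules — phenotype-inference rules and clinical decision support (CDS)
  rules — written as monotone boolean expressions over haplotype, variant
  and phenotype atoms with qualified cardinalities ("has at least 1 copy of
  TPMT*1", "has exactly 2 copies of the T allele of rs9923231").

This module provides the domain types, the haplotype-table compiler, and the
static audits that catch the classic curation defects of such tables:
haplotypes whose defining SNP sets make them indistinguishable, references to
unknown rsIDs or alleles, and rules no diploid genotype can ever satisfy.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "KbError",
    "SnpDefinition",
    "HaplotypeDefinition",
    "HaplotypeTaxonomy",
    "HaplotypeAtom",
    "VariantAtom",
    "PhenotypeAtom",
    "And",
    "Or",
    "Expression",
    "PhenotypeRule",
    "CdsRule",
    "Finding",
    "ValidationReport",
    "KnowledgeBase",
    "parse_expression",
    "expression_to_json",
    "parse_haplotype_table",
    "serialize_haplotype_table",
    "check_distinguishability",
    "check_rule_satisfiability",
    "validate_kb",
]

_RSID_RE = re.compile(r"^rs\d+$")

IMPORTANCE_LEVELS = ("standard", "minor_deviation", "important_modification")


class KbError(ValueError):
    """Raised for structural defects in knowledge-base content."""


@dataclass(frozen=True)
class SnpDefinition:
    """One polymorphism: rsID, owning gene, strand orientation, allele set.

    ``orientation`` is the strand, relative to the reference genome, on which
    the defining alleles are reported; calls read from forward-genome assay
    output must be complemented for reverse-orientation SNPs before they are
    compared with these alleles.  Indels are carried as literal tokens
    ("INS"/"DEL" or multi-base strings) without left-normalisation.
    """

    rsid: str
    gene: str
    orientation: str = "forward"
    alleles: frozenset = frozenset()
    assays: frozenset = frozenset()
    see_also: Optional[str] = None

    def __post_init__(self):
        if not _RSID_RE.match(self.rsid):
            raise KbError(f"invalid rsID {self.rsid!r}: expected 'rs' + digits")
        if self.orientation not in ("forward", "reverse"):
            raise KbError(f"{self.rsid}: orientation must be forward/reverse")
        if not self.alleles:
            raise KbError(f"{self.rsid}: allele set must be non-empty")
        for a in self.alleles:
            if not a or a != a.upper():
                raise KbError(f"{self.rsid}: allele {a!r} must be non-empty uppercase")


@dataclass
class HaplotypeDefinition:
    """A named star allele: total map rsID -> allele over its gene's panel."""

    gene: str
    name: str
    allele_map: dict

    def __eq__(self, other):
        if not isinstance(other, HaplotypeDefinition):
            return NotImplemented
        return (self.gene, self.name, self.allele_map) == (
            other.gene,
            other.name,
            other.allele_map,
        )


@dataclass
class HaplotypeTaxonomy:
    """Broader/narrower relation between star-allele names (e.g. *3A under *3).

    ``parent`` maps a star-allele name to its (single) broader name.  Parent
    names need not carry allele maps of their own — an abstract parent exists
    only so that rules may refer to the whole family.
    """

    parent: dict = field(default_factory=dict)

    def __post_init__(self):
        # cycle check via repeated parent hops
        for start in self.parent:
            seen = {start}
            cur = start
            while cur in self.parent:
                cur = self.parent[cur]
                if cur in seen:
                    raise KbError(f"taxonomy cycle through {cur!r}")
                seen.add(cur)

    def ancestors(self, name: str) -> list:
        """Strict ancestors of ``name``, nearest first."""
        out = []
        cur = name
        while cur in self.parent:
            cur = self.parent[cur]
            out.append(cur)
        return out

    def self_and_ancestors(self, name: str) -> list:
        return [name] + self.ancestors(name)

    def is_or_descends_from(self, name: str, target: str) -> bool:
        return target in self.self_and_ancestors(name)


# --------------------------------------------------------------------------
# Rule expressions: a monotone (negation-free) boolean grammar over atoms.


@dataclass(frozen=True)
class HaplotypeAtom:
    """Cardinality condition on copies of a star allele in the diplotype."""

    name: str
    cardinality: int = 1
    mode: str = "at_least"  # or "exactly"

    def __post_init__(self):
        if self.cardinality not in (1, 2):
            raise KbError(f"haplotype atom cardinality must be 1 or 2")
        if self.mode not in ("at_least", "exactly"):
            raise KbError("haplotype atom mode must be at_least/exactly")


@dataclass(frozen=True)
class VariantAtom:
    """Cardinality condition on copies of one allele of one SNP."""

    rsid: str
    allele: str
    cardinality: int = 1
    mode: str = "at_least"

    def __post_init__(self):
        if self.cardinality not in (1, 2):
            raise KbError("variant atom cardinality must be 1 or 2")
        if self.mode not in ("at_least", "exactly"):
            raise KbError("variant atom mode must be at_least/exactly")


@dataclass(frozen=True)
class PhenotypeAtom:
    label: str


@dataclass(frozen=True)
class And:
    children: tuple

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))


@dataclass(frozen=True)
class Or:
    children: tuple

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))


Expression = Union[And, Or, HaplotypeAtom, VariantAtom, PhenotypeAtom]


def parse_expression(obj) -> Expression:
    """Parse the JSON/YAML expression grammar into an expression tree.

    Grammar: ``{"and": [...]}``, ``{"or": [...]}``,
    ``{"hap": "TPMT*1", "min": 1}``, ``{"hap": "CYP2C9*3", "exactly": 2}``,
    ``{"snp": "rs9923231", "allele": "T", "exactly": 2}`` (or ``"min"``),
    ``{"phenotype": "..."}``.  ``min``/``exactly`` default to ``min: 1``.
    """
    if not isinstance(obj, Mapping):
        raise KbError(f"expression node must be a mapping, got {obj!r}")
    if "and" in obj:
        return And(tuple(parse_expression(c) for c in obj["and"]))
    if "or" in obj:
        return Or(tuple(parse_expression(c) for c in obj["or"]))
    if "hap" in obj:
        card, mode = _card_mode(obj)
        return HaplotypeAtom(obj["hap"], card, mode)
    if "snp" in obj:
        card, mode = _card_mode(obj)
        return VariantAtom(obj["snp"], str(obj["allele"]).upper(), card, mode)
    if "phenotype" in obj:
        return PhenotypeAtom(obj["phenotype"])
    raise KbError(f"unrecognised expression node {obj!r}")


def _card_mode(obj) -> tuple:
    if "exactly" in obj:
        return int(obj["exactly"]), "exactly"
    return int(obj.get("min", 1)), "at_least"


def expression_to_json(expr: Expression):
    """Inverse of :func:`parse_expression`."""
    if isinstance(expr, And):
        return {"and": [expression_to_json(c) for c in expr.children]}
    if isinstance(expr, Or):
        return {"or": [expression_to_json(c) for c in expr.children]}
    if isinstance(expr, HaplotypeAtom):
        key = "exactly" if expr.mode == "exactly" else "min"
        return {"hap": expr.name, key: expr.cardinality}
    if isinstance(expr, VariantAtom):
        key = "exactly" if expr.mode == "exactly" else "min"
        return {"snp": expr.rsid, "allele": expr.allele, key: expr.cardinality}
    if isinstance(expr, PhenotypeAtom):
        return {"phenotype": expr.label}
    raise KbError(f"not an expression node: {expr!r}")


def iter_atoms(expr: Expression):
    if isinstance(expr, (And, Or)):
        for c in expr.children:
            yield from iter_atoms(c)
    else:
        yield expr


@dataclass(frozen=True)
class PhenotypeRule:
    id: str
    phenotype_label: str
    expression: Expression
    source: str = ""


@dataclass(frozen=True)
class CdsRule:
    """A drug-specific recommendation attached to a genotype-defined population."""

    id: str
    drug: str
    expression: Expression
    message: str
    source: str = ""
    importance: str = "standard"

    def __post_init__(self):
        if not self.message:
            raise KbError(f"rule {self.id}: message must be non-empty")
        if self.importance not in IMPORTANCE_LEVELS:
            raise KbError(
                f"rule {self.id}: importance must be one of {IMPORTANCE_LEVELS}"
            )


# --------------------------------------------------------------------------
# Validation reporting


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    category: str  # indistinguishable_haplotypes | unknown_rsid | unknown_allele
    #                | unsatisfiable_rule | dangling_reference
    identifiers: tuple
    message: str = ""


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    def add(self, severity: str, category: str, identifiers: Iterable, message: str = ""):
        self.findings.append(Finding(severity, category, tuple(identifiers), message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def errors(self) -> list:
        return [f for f in self.findings if f.severity == "error"]

    def warnings(self) -> list:
        return [f for f in self.findings if f.severity == "warning"]

    def extend(self, other: "ValidationReport"):
        self.findings.extend(other.findings)


# --------------------------------------------------------------------------
# The knowledge base


@dataclass
class KnowledgeBase:
    """SNP registry, per-gene star-allele panels, taxonomy, and rules."""

    snps: dict = field(default_factory=dict)  # rsid -> SnpDefinition
    haplotypes: dict = field(default_factory=dict)  # gene -> [HaplotypeDefinition]
    taxonomy: HaplotypeTaxonomy = field(default_factory=HaplotypeTaxonomy)
    phenotype_rules: list = field(default_factory=list)
    cds_rules: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    def genes(self) -> list:
        return sorted(self.haplotypes)

    def gene_panel(self, gene: str) -> tuple:
        """The rsIDs over which the gene's haplotypes are defined, sorted."""
        defs = self.haplotypes.get(gene)
        if not defs:
            raise KbError(f"unknown gene {gene!r}")
        return tuple(sorted(defs[0].allele_map))

    def haplotype(self, name: str) -> HaplotypeDefinition:
        for defs in self.haplotypes.values():
            for h in defs:
                if h.name == name:
                    return h
        raise KbError(f"unknown haplotype {name!r}")

    def haplotype_names(self, gene: str) -> list:
        return sorted(h.name for h in self.haplotypes.get(gene, []))

    def star_names(self) -> set:
        """All star-allele names: concrete definitions plus abstract taxonomy names."""
        names = {h.name for defs in self.haplotypes.values() for h in defs}
        names.update(self.taxonomy.parent)
        names.update(self.taxonomy.parent.values())
        return names

    def gene_of_star(self, name: str) -> str:
        """Gene owning a star-allele name, resolving abstract names via children."""
        for gene, defs in self.haplotypes.items():
            for h in defs:
                if h.name == name:
                    return gene
        # abstract name: any taxonomy descendant that is concrete decides it
        for child, parent in self.taxonomy.parent.items():
            if self.taxonomy.is_or_descends_from(child, name):
                for gene, defs in self.haplotypes.items():
                    if any(h.name == child for h in defs):
                        return gene
        raise KbError(f"cannot resolve gene of star allele {name!r}")

    def all_rules(self) -> list:
        return list(self.phenotype_rules) + list(self.cds_rules)

    def rule_by_id(self, rule_id: str):
        for r in self.all_rules():
            if r.id == rule_id:
                return r
        raise KbError(f"unknown rule {rule_id!r}")

    def merge(self, other: "KnowledgeBase") -> "KnowledgeBase":
        """Union of two knowledge bases; duplicate rsIDs/genes/rule ids are errors."""
        dup = set(self.snps) & set(other.snps)
        if dup:
            raise KbError(f"duplicate rsIDs on merge: {sorted(dup)}")
        dupg = set(self.haplotypes) & set(other.haplotypes)
        if dupg:
            raise KbError(f"duplicate genes on merge: {sorted(dupg)}")
        ids = {r.id for r in self.all_rules()} & {r.id for r in other.all_rules()}
        if ids:
            raise KbError(f"duplicate rule ids on merge: {sorted(ids)}")
        return KnowledgeBase(
            snps={**self.snps, **other.snps},
            haplotypes={**self.haplotypes, **other.haplotypes},
            taxonomy=HaplotypeTaxonomy(
                {**self.taxonomy.parent, **other.taxonomy.parent}
            ),
            phenotype_rules=self.phenotype_rules + other.phenotype_rules,
            cds_rules=self.cds_rules + other.cds_rules,
            metadata={**self.metadata, **other.metadata},
        )


# --------------------------------------------------------------------------
# Haplotype-table compiler


def parse_haplotype_table(
    table: str,
    gene: str,
    snp_registry: Mapping[str, SnpDefinition],
    report: Optional[ValidationReport] = None,
) -> list:
    """Compile a TSV haplotype translation table into star-allele definitions.

    The table layout follows PharmGKB convention: the first column
    ("Haplotype") lists star-allele names, remaining columns are rsIDs, and
    cells carry the allele each haplotype bears at that SNP.  The first data
    row is the reference haplotype; a blank cell means "same as reference".

    When ``report`` is given, unknown rsIDs and alleles are recorded there as
    findings and parsing continues best-effort; otherwise they raise
    :class:`KbError`.  Duplicate haplotype names always raise.
    """
    df = pd.read_csv(io.StringIO(table), sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise KbError("haplotype table has no columns")
    rsids = [c.strip() for c in df.columns[1:]]

    def flag(category: str, identifiers: tuple, msg: str):
        if report is not None:
            report.add("error", category, identifiers, msg)
        else:
            raise KbError(msg)

    for r in rsids:
        if r not in snp_registry:
            flag("unknown_rsid", (gene, r), f"{gene}: rsID {r} absent from registry")

    defs: list = []
    seen = set()
    reference: Optional[dict] = None
    for _, row in df.iterrows():
        name = str(row.iloc[0]).strip()
        if not name:
            raise KbError(f"{gene}: blank haplotype name")
        if name in seen:
            raise KbError(f"{gene}: duplicate haplotype name {name!r}")
        seen.add(name)
        allele_map = {}
        for r, cell in zip(rsids, row.iloc[1:]):
            allele = str(cell).strip().upper()
            if not allele:
                if reference is None:
                    raise KbError(
                        f"{gene}: reference haplotype {name!r} has a blank cell at {r}"
                    )
                allele = reference[r]
            if "/" in allele:
                raise KbError(
                    f"{gene} {name}: ambiguous cell {allele!r} at {r} not supported"
                )
            snp = snp_registry.get(r)
            if snp is not None and allele not in snp.alleles:
                flag(
                    "unknown_allele",
                    (gene, name, r, allele),
                    f"{gene} {name}: allele {allele!r} not in {r}'s allele set",
                )
            allele_map[r] = allele
        if reference is None:
            reference = allele_map
        defs.append(HaplotypeDefinition(gene=gene, name=name, allele_map=allele_map))
    return defs


def serialize_haplotype_table(defs: Sequence[HaplotypeDefinition]) -> str:
    """Write star-allele definitions back to the TSV table layout (no blanks)."""
    if not defs:
        return "Haplotype\n"
    rsids = sorted(defs[0].allele_map)
    lines = ["\t".join(["Haplotype"] + rsids)]
    for h in defs:
        lines.append("\t".join([h.name] + [h.allele_map[r] for r in rsids]))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Static audits


def check_distinguishability(kb: KnowledgeBase) -> ValidationReport:
    """Flag same-gene haplotype pairs whose allele maps are identical.

    Two star alleles with identical maps over the panel can never be told
    apart by genotype data — the classic "underspecified haplotype" curation
    defect in translation tables.
    """
    report = ValidationReport()
    for gene in sorted(kb.haplotypes):
        defs = kb.haplotypes[gene]
        for i in range(len(defs)):
            for j in range(i + 1, len(defs)):
                if defs[i].allele_map == defs[j].allele_map:
                    report.add(
                        "warning",
                        "indistinguishable_haplotypes",
                        (gene, defs[i].name, defs[j].name),
                        f"{gene}: {defs[i].name} and {defs[j].name} have "
                        "identical allele maps",
                    )
    return report


def check_rule_satisfiability(kb: KnowledgeBase) -> ValidationReport:
    """Flag rules no diploid genotype can satisfy.

    Decided by finite model enumeration over the diplotype space (at most two
    haplotype copies per gene, exactly two alleles per SNP) — see
    :mod:`pgxcds.rule_logic`.
    """
    from . import rule_logic  # deferred: rule_logic imports this module

    report = ValidationReport()
    for rule in kb.all_rules():
        try:
            sat = rule_logic.is_satisfiable(rule.expression, kb)
        except rule_logic.ModelLimitError:
            continue  # undecided, never a silent finding
        except KbError as exc:
            report.add("error", "dangling_reference", (rule.id,), str(exc))
            continue
        if not sat:
            report.add(
                "error",
                "unsatisfiable_rule",
                (rule.id,),
                f"rule {rule.id}: no diplotype satisfies the expression",
            )
    return report


def _check_references(kb: KnowledgeBase) -> ValidationReport:
    report = ValidationReport()
    star = kb.star_names()
    # panel consistency
    for gene, defs in kb.haplotypes.items():
        if not defs:
            continue
        panel = set(defs[0].allele_map)
        for h in defs:
            if set(h.allele_map) != panel:
                report.add(
                    "error",
                    "dangling_reference",
                    (gene, h.name),
                    f"{gene} {h.name}: allele map keys differ from the gene panel",
                )
            for r, a in h.allele_map.items():
                snp = kb.snps.get(r)
                if snp is None:
                    report.add(
                        "error", "unknown_rsid", (gene, r), f"{gene}: {r} not in registry"
                    )
                elif a not in snp.alleles:
                    report.add(
                        "error",
                        "unknown_allele",
                        (gene, h.name, r, a),
                        f"{gene} {h.name}: allele {a!r} not among {r}'s alleles",
                    )
    # taxonomy endpoints share a gene
    for child, parent in kb.taxonomy.parent.items():
        try:
            gc, gp = kb.gene_of_star(child), kb.gene_of_star(parent)
        except KbError:
            report.add(
                "error",
                "dangling_reference",
                (child, parent),
                f"taxonomy link {child} -> {parent} references unknown names",
            )
            continue
        if gc != gp:
            report.add(
                "error",
                "dangling_reference",
                (child, parent),
                f"taxonomy link {child} -> {parent} crosses genes ({gc} vs {gp})",
            )
    # rule atom references
    labels = {r.phenotype_label for r in kb.phenotype_rules}
    for rule in kb.all_rules():
        for atom in iter_atoms(rule.expression):
            if isinstance(atom, HaplotypeAtom) and atom.name not in star:
                report.add(
                    "error",
                    "dangling_reference",
                    (rule.id, atom.name),
                    f"rule {rule.id}: unknown haplotype {atom.name!r}",
                )
            elif isinstance(atom, VariantAtom):
                snp = kb.snps.get(atom.rsid)
                if snp is None:
                    report.add(
                        "error",
                        "unknown_rsid",
                        (rule.id, atom.rsid),
                        f"rule {rule.id}: unknown rsID {atom.rsid}",
                    )
                elif atom.allele not in snp.alleles:
                    report.add(
                        "error",
                        "unknown_allele",
                        (rule.id, atom.rsid, atom.allele),
                        f"rule {rule.id}: {atom.allele!r} not among "
                        f"{atom.rsid}'s alleles",
                    )
            elif isinstance(atom, PhenotypeAtom) and atom.label not in labels:
                report.add(
                    "error",
                    "dangling_reference",
                    (rule.id, atom.label),
                    f"rule {rule.id}: phenotype {atom.label!r} has no defining rule",
                )
    return report


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Run every static audit: references, distinguishability, satisfiability."""
    report = _check_references(kb)
    report.extend(check_distinguishability(kb))
    if not report.errors():  # satisfiability needs resolvable references
        report.extend(check_rule_satisfiability(kb))
    return report
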