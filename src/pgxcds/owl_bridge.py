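"""OWL 2 export of the knowledge base and patients, and entity counting.

The export reproduces the qualified-cardinality modelling patterns the
rest of the package reasons over natively:

* each SNP is a class under ``polymorphism`` annotated with its rsID, gene
  (``relevant_for``), covering assays (``can_be_tested_with``) and strand
  orientation; each observable allele is a subclass of its SNP;
* each star allele is a class under ``haplotype``; for every unordered
  haplotype pair of a gene, a "human with ..." class carries an
  EquivalentClasses definition built from qualified cardinalities over
  allele classes — ``exactly 1`` of each allele where the two haplotypes
  differ, ``exactly 2`` where they agree — plus SubClassOf assertions of
  haplotype possession (``exactly 2`` of the haplotype for homozygotes);
* each rule is a class of humans annotated with ``CDS_message``, ``source``
  and ``recommendations_importance``, its expression translated to a class
  expression;
* a patient is an OWL individual with one anonymous "copy" individual per
  chromosome per called SNP, typed by the allele class it instantiates.

Two syntaxes are emitted: Turtle (via rdflib, with deterministic blank-node
labels so output is byte-stable) and OWL functional-style syntax (a direct
text emitter).  Entity counting parses any standard RDF serialization and
counts by annotation signature, with a configurable property mapping so it
can also be pointed at externally produced ontologies whose IRIs differ.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Optional, Union

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef, XSD
from rdflib.namespace import OWL

from .kb_model import (
    And,
    Expression,
    HaplotypeAtom,
    KbError,
    KnowledgeBase,
    Or,
    PhenotypeAtom,
    VariantAtom,
    validate_kb,
)
from .genotype_io import PatientGenotype

__all__ = ["PGX", "export_kb", "export_patient", "count_ontology_entities"]

BASE_IRI = "http://example.org/pgx#"
PGX = Namespace(BASE_IRI)

ANNOTATIONS = (
    "rsid",
    "relevant_for",
    "can_be_tested_with",
    "dbsnp_orientation_on_reference_genome",
    "CDS_message",
    "source",
    "recommendations_importance",
    "phenotype_label",
)

DEFAULT_MAPPING = {
    "rsid": str(PGX.rsid),
    "relevant_for": str(PGX.relevant_for),
    "cds_message": str(PGX.CDS_message),
    "phenotype": str(PGX.phenotype_label),
    "haplotype_root": str(PGX.haplotype),
}


def sanitize(name: str) -> str:
    """IRI-safe fragment: the star convention becomes ``_star_``."""
    out = name.replace("*", "_star_")
    return re.sub(r"[^A-Za-z0-9_.-]", "_", out)


class _BNodes:
    """Deterministic blank-node factory (rdflib's default labels are random)."""

    def __init__(self):
        self.n = 0

    def __call__(self) -> BNode:
        self.n += 1
        return BNode(f"b{self.n}")


def _rdf_list(g: Graph, items, bn: _BNodes):
    head = RDF.nil
    for item in reversed(items):
        node = bn()
        g.add((node, RDF.first, item))
        g.add((node, RDF.rest, head))
        head = node
    return head


def _qcr(g: Graph, bn: _BNodes, n: int, onclass, exact: bool = True):
    b = bn()
    g.add((b, RDF.type, OWL.Restriction))
    g.add((b, OWL.onProperty, PGX.has))
    prop = OWL.qualifiedCardinality if exact else OWL.minQualifiedCardinality
    g.add((b, prop, Literal(n, datatype=XSD.nonNegativeInteger)))
    g.add((b, OWL.onClass, onclass))
    return b


def _intersection(g: Graph, bn: _BNodes, members):
    b = bn()
    g.add((b, RDF.type, OWL.Class))
    g.add((b, OWL.intersectionOf, _rdf_list(g, members, bn)))
    return b


def _union(g: Graph, bn: _BNodes, members):
    b = bn()
    g.add((b, RDF.type, OWL.Class))
    g.add((b, OWL.unionOf, _rdf_list(g, members, bn)))
    return b


def _class_expr(g: Graph, bn: _BNodes, expr: Expression):
    if isinstance(expr, And):
        return _intersection(g, bn, [_class_expr(g, bn, c) for c in expr.children])
    if isinstance(expr, Or):
        return _union(g, bn, [_class_expr(g, bn, c) for c in expr.children])
    if isinstance(expr, HaplotypeAtom):
        return _qcr(g, bn, expr.cardinality, PGX[sanitize(expr.name)],
                    exact=expr.mode == "exactly")
    if isinstance(expr, VariantAtom):
        return _qcr(g, bn, expr.cardinality,
                    PGX[f"{expr.rsid}_{sanitize(expr.allele)}"],
                    exact=expr.mode == "exactly")
    if isinstance(expr, PhenotypeAtom):
        return PGX[f"phenotype_{sanitize(expr.label)}"]
    raise KbError(f"cannot translate node {expr!r}")


def _build_graph(kb: KnowledgeBase) -> Graph:
    g = Graph()
    g.bind("pgx", PGX)
    g.bind("owl", OWL)
    bn = _BNodes()
    ont = URIRef(BASE_IRI.rstrip("#"))
    g.add((ont, RDF.type, OWL.Ontology))
    for name in ("polymorphism", "haplotype", "human"):
        g.add((PGX[name], RDF.type, OWL.Class))
    for name in ANNOTATIONS:
        g.add((PGX[name], RDF.type, OWL.AnnotationProperty))
    g.add((PGX.has, RDF.type, OWL.ObjectProperty))

    # SNPs and their allele subclasses
    for rsid in sorted(kb.snps):
        snp = kb.snps[rsid]
        cls = PGX[rsid]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, PGX.polymorphism))
        g.add((cls, PGX.rsid, Literal(rsid)))
        g.add((cls, PGX.relevant_for, Literal(snp.gene)))
        g.add((cls, PGX.dbsnp_orientation_on_reference_genome,
               Literal(snp.orientation)))
        for assay in sorted(snp.assays):
            g.add((cls, PGX.can_be_tested_with, Literal(assay)))
        if snp.see_also:
            g.add((cls, RDFS.seeAlso, URIRef(snp.see_also)))
        for allele in sorted(snp.alleles):
            acls = PGX[f"{rsid}_{sanitize(allele)}"]
            g.add((acls, RDF.type, OWL.Class))
            g.add((acls, RDFS.subClassOf, cls))

    # star alleles, taxonomy, and human-with-diplotype classes
    star_names = sorted(kb.star_names())
    for name in star_names:
        cls = PGX[sanitize(name)]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, PGX.haplotype))
        try:
            g.add((cls, PGX.relevant_for, Literal(kb.gene_of_star(name))))
        except KbError:
            pass
    for child in sorted(kb.taxonomy.parent):
        g.add((PGX[sanitize(child)], RDFS.subClassOf,
               PGX[sanitize(kb.taxonomy.parent[child])]))

    for gene in kb.genes():
        names = kb.haplotype_names(gene)
        defs = {h.name: h for h in kb.haplotypes[gene]}
        panel = kb.gene_panel(gene)
        for i in range(len(names)):
            for j in range(i, len(names)):
                h1, h2 = defs[names[i]], defs[names[j]]
                cls = PGX[f"human_with_{sanitize(h1.name)}_{sanitize(h2.name)}"]
                g.add((cls, RDF.type, OWL.Class))
                g.add((cls, RDFS.subClassOf, PGX.human))
                members = [PGX.human]
                for r in panel:
                    a1, a2 = h1.allele_map[r], h2.allele_map[r]
                    if a1 == a2:
                        members.append(
                            _qcr(g, bn, 2, PGX[f"{r}_{sanitize(a1)}"])
                        )
                    else:
                        for a in sorted((a1, a2)):
                            members.append(
                                _qcr(g, bn, 1, PGX[f"{r}_{sanitize(a)}"])
                            )
                g.add((cls, OWL.equivalentClass, _intersection(g, bn, members)))
                if h1.name == h2.name:
                    g.add((cls, RDFS.subClassOf,
                           _qcr(g, bn, 2, PGX[sanitize(h1.name)])))
                else:
                    for h in (h1, h2):
                        g.add((cls, RDFS.subClassOf,
                               _qcr(g, bn, 1, PGX[sanitize(h.name)], exact=False)))

    # rules
    for rule in sorted(kb.phenotype_rules, key=lambda r: r.id):
        cls = PGX[f"rule_{sanitize(rule.id)}"]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, PGX.human))
        g.add((cls, PGX.phenotype_label, Literal(rule.phenotype_label)))
        if rule.source:
            g.add((cls, PGX.source, Literal(rule.source)))
        g.add((cls, OWL.equivalentClass, _intersection(
            g, bn, [PGX.human, _class_expr(g, bn, rule.expression)])))
        pcls = PGX[f"phenotype_{sanitize(rule.phenotype_label)}"]
        g.add((pcls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, pcls))
    for rule in sorted(kb.cds_rules, key=lambda r: r.id):
        cls = PGX[f"rule_{sanitize(rule.id)}"]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, PGX.human))
        g.add((cls, PGX.CDS_message, Literal(rule.message)))
        g.add((cls, PGX.relevant_for, Literal(rule.drug)))
        g.add((cls, PGX.recommendations_importance, Literal(rule.importance)))
        if rule.source:
            g.add((cls, PGX.source, Literal(rule.source)))
        g.add((cls, OWL.equivalentClass, _intersection(
            g, bn, [PGX.human, _class_expr(g, bn, rule.expression)])))
    return g


def export_kb(kb: KnowledgeBase, syntax: str = "turtle") -> str:
    """Serialize a validated knowledge base as OWL 2 (``turtle``/``functional``).

    Raises :class:`KbError` if static validation reports errors (warnings,
    e.g. indistinguishable haplotypes, do not block export).
    """
    report = validate_kb(kb)
    if report.errors():
        msgs = "; ".join(f.message for f in report.errors()[:5])
        raise KbError(f"knowledge base fails validation: {msgs}")
    if syntax == "turtle":
        return _build_graph(kb).serialize(format="turtle")
    if syntax == "functional":
        return _functional_kb(kb)
    raise ValueError(f"unknown syntax {syntax!r}")


def export_patient(genotype: PatientGenotype, syntax: str = "turtle") -> str:
    """Serialize a patient as an OWL individual with allele-possession assertions.

    Each called SNP contributes exactly two anonymous chromosome-copy
    individuals (two for a homozygote, one per allele for a heterozygote),
    each linked from the patient by ``has`` and typed by its allele class —
    four triples per called SNP, plus two typing triples for the patient.
    """
    if syntax == "functional":
        return _functional_patient(genotype)
    if syntax != "turtle":
        raise ValueError(f"unknown syntax {syntax!r}")
    g = Graph()
    g.bind("pgx", PGX)
    g.bind("owl", OWL)
    bn = _BNodes()
    ind = PGX[f"patient_{sanitize(genotype.patient_id)}"]
    g.add((ind, RDF.type, OWL.NamedIndividual))
    g.add((ind, RDF.type, PGX.human))
    for rsid in sorted(genotype.calls):
        for allele in genotype.calls[rsid]:
            copy = bn()
            g.add((ind, PGX.has, copy))
            g.add((copy, RDF.type, PGX[f"{rsid}_{sanitize(allele)}"]))
    return g.serialize(format="turtle")


# --------------------------------------------------------------------------
# Functional-style syntax (text emitter; rdflib has no writer for it)


def _f_expr(expr: Expression) -> str:
    if isinstance(expr, And):
        return "ObjectIntersectionOf(" + " ".join(
            _f_expr(c) for c in expr.children) + ")"
    if isinstance(expr, Or):
        return "ObjectUnionOf(" + " ".join(_f_expr(c) for c in expr.children) + ")"
    if isinstance(expr, HaplotypeAtom):
        kw = "ObjectExactCardinality" if expr.mode == "exactly" else "ObjectMinCardinality"
        return f"{kw}({expr.cardinality} :has :{sanitize(expr.name)})"
    if isinstance(expr, VariantAtom):
        kw = "ObjectExactCardinality" if expr.mode == "exactly" else "ObjectMinCardinality"
        return f"{kw}({expr.cardinality} :has :{expr.rsid}_{sanitize(expr.allele)})"
    if isinstance(expr, PhenotypeAtom):
        return f":phenotype_{sanitize(expr.label)}"
    raise KbError(f"cannot translate node {expr!r}")


def _f_lit(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _functional_kb(kb: KnowledgeBase) -> str:
    out = [
        f"Prefix(:=<{BASE_IRI}>)",
        "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
        "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
        "Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)",
        f"Ontology(<{BASE_IRI.rstrip('#')}>",
    ]
    for name in ("polymorphism", "haplotype", "human"):
        out.append(f"Declaration(Class(:{name}))")
    for name in ANNOTATIONS:
        out.append(f"Declaration(AnnotationProperty(:{name}))")
    out.append("Declaration(ObjectProperty(:has))")
    for rsid in sorted(kb.snps):
        snp = kb.snps[rsid]
        out.append(f"Declaration(Class(:{rsid}))")
        out.append(f"SubClassOf(:{rsid} :polymorphism)")
        out.append(f"AnnotationAssertion(:rsid :{rsid} {_f_lit(rsid)})")
        out.append(f"AnnotationAssertion(:relevant_for :{rsid} {_f_lit(snp.gene)})")
        out.append(
            "AnnotationAssertion(:dbsnp_orientation_on_reference_genome "
            f":{rsid} {_f_lit(snp.orientation)})"
        )
        for assay in sorted(snp.assays):
            out.append(
                f"AnnotationAssertion(:can_be_tested_with :{rsid} {_f_lit(assay)})"
            )
        if snp.see_also:
            out.append(
                f"AnnotationAssertion(rdfs:seeAlso :{rsid} <{snp.see_also}>)"
            )
        for allele in sorted(snp.alleles):
            out.append(f"Declaration(Class(:{rsid}_{sanitize(allele)}))")
            out.append(f"SubClassOf(:{rsid}_{sanitize(allele)} :{rsid})")
    for name in sorted(kb.star_names()):
        out.append(f"Declaration(Class(:{sanitize(name)}))")
        out.append(f"SubClassOf(:{sanitize(name)} :haplotype)")
    for child in sorted(kb.taxonomy.parent):
        out.append(
            f"SubClassOf(:{sanitize(child)} "
            f":{sanitize(kb.taxonomy.parent[child])})"
        )
    for gene in kb.genes():
        names = kb.haplotype_names(gene)
        defs = {h.name: h for h in kb.haplotypes[gene]}
        panel = kb.gene_panel(gene)
        for i in range(len(names)):
            for j in range(i, len(names)):
                h1, h2 = defs[names[i]], defs[names[j]]
                cname = f"human_with_{sanitize(h1.name)}_{sanitize(h2.name)}"
                out.append(f"Declaration(Class(:{cname}))")
                out.append(f"SubClassOf(:{cname} :human)")
                parts = [":human"]
                for r in panel:
                    a1, a2 = h1.allele_map[r], h2.allele_map[r]
                    if a1 == a2:
                        parts.append(
                            f"ObjectExactCardinality(2 :has :{r}_{sanitize(a1)})"
                        )
                    else:
                        for a in sorted((a1, a2)):
                            parts.append(
                                f"ObjectExactCardinality(1 :has :{r}_{sanitize(a)})"
                            )
                out.append(
                    f"EquivalentClasses(:{cname} ObjectIntersectionOf("
                    + " ".join(parts) + "))"
                )
                if h1.name == h2.name:
                    out.append(
                        f"SubClassOf(:{cname} ObjectExactCardinality("
                        f"2 :has :{sanitize(h1.name)}))"
                    )
                else:
                    for h in (h1, h2):
                        out.append(
                            f"SubClassOf(:{cname} ObjectMinCardinality("
                            f"1 :has :{sanitize(h.name)}))"
                        )
    for rule in sorted(kb.phenotype_rules, key=lambda r: r.id):
        cname = f"rule_{sanitize(rule.id)}"
        out.append(f"Declaration(Class(:{cname}))")
        out.append(f"SubClassOf(:{cname} :human)")
        out.append(
            f"AnnotationAssertion(:phenotype_label :{cname} "
            f"{_f_lit(rule.phenotype_label)})"
        )
        out.append(
            f"EquivalentClasses(:{cname} ObjectIntersectionOf(:human "
            f"{_f_expr(rule.expression)}))"
        )
    for rule in sorted(kb.cds_rules, key=lambda r: r.id):
        cname = f"rule_{sanitize(rule.id)}"
        out.append(f"Declaration(Class(:{cname}))")
        out.append(f"SubClassOf(:{cname} :human)")
        out.append(f"AnnotationAssertion(:CDS_message :{cname} {_f_lit(rule.message)})")
        out.append(f"AnnotationAssertion(:relevant_for :{cname} {_f_lit(rule.drug)})")
        out.append(
            f"AnnotationAssertion(:recommendations_importance :{cname} "
            f"{_f_lit(rule.importance)})"
        )
        if rule.source:
            out.append(
                f"AnnotationAssertion(:source :{cname} {_f_lit(rule.source)})"
            )
        out.append(
            f"EquivalentClasses(:{cname} ObjectIntersectionOf(:human "
            f"{_f_expr(rule.expression)}))"
        )
    out.append(")")
    return "\n".join(out) + "\n"


def _functional_patient(genotype: PatientGenotype) -> str:
    out = [
        f"Prefix(:=<{BASE_IRI}>)",
        "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
        f"Ontology(<{BASE_IRI.rstrip('#')}/patients>",
    ]
    ind = f":patient_{sanitize(genotype.patient_id)}"
    out.append(f"Declaration(NamedIndividual({ind}))")
    out.append(f"ClassAssertion(:human {ind})")
    n = 0
    for rsid in sorted(genotype.calls):
        for allele in genotype.calls[rsid]:
            n += 1
            copy = f"_:copy{n}"
            out.append(f"ObjectPropertyAssertion(:has {ind} {copy})")
            out.append(f"ClassAssertion(:{rsid}_{sanitize(allele)} {copy})")
    out.append(")")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Entity counting


def count_ontology_entities(
    source: Union[str, Path, Graph],
    mapping: Optional[Mapping[str, str]] = None,
    fmt: Optional[str] = None,
) -> dict:
    """Count SNP/variant/haplotype/gene/rule entities in an RDF/OWL document.

    ``source`` is a file path, serialized RDF text, or an rdflib Graph.
    Counting is annotation-driven: classes bearing the rsID annotation are
    SNPs, their subclasses are variants, classes bearing a CDS message are
    CDS rules, and so on.  ``mapping`` overrides the annotation/class IRIs
    (keys: ``rsid``, ``relevant_for``, ``cds_message``, ``phenotype``,
    ``haplotype_root``) for ontologies built with a different vocabulary.
    """
    m = dict(DEFAULT_MAPPING)
    if mapping:
        m.update(mapping)
    if isinstance(source, Graph):
        g = source
    else:
        g = Graph()
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            g.parse(str(source), format=fmt)
        else:
            parsed = False
            for candidate in ([fmt] if fmt else ["turtle", "xml", "nt"]):
                try:
                    g.parse(data=str(source), format=candidate)
                    parsed = True
                    break
                except Exception:
                    continue
            if not parsed:
                raise ValueError("could not parse RDF input")
    rsid_p = URIRef(m["rsid"])
    relevant_p = URIRef(m["relevant_for"])
    message_p = URIRef(m["cds_message"])
    phenotype_p = URIRef(m["phenotype"])
    hap_root = URIRef(m["haplotype_root"])

    snp_classes = set(g.subjects(rsid_p, None))
    variant_classes = {
        s for snp in snp_classes for s in g.subjects(RDFS.subClassOf, snp)
    }
    haplotype_classes = set(g.subjects(RDFS.subClassOf, hap_root))
    genes = {str(o) for s in snp_classes for o in g.objects(s, relevant_p)}
    cds_rules = set(g.subjects(message_p, None))
    phenotype_rules = set(g.subjects(phenotype_p, None))
    return {
        "snp_classes": len(snp_classes),
        "variant_classes": len(variant_classes),
        "haplotype_classes": len(haplotype_classes),
        "genes": len(genes),
        "phenotype_rules": len(phenotype_rules),
        "cds_rules": len(cds_rules),
    }
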