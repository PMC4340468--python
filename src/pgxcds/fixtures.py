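"""Built-in example knowledge-base content.

This module ships the worked examples used throughout the documentation and
tests: the published CYP2C9 translation-table excerpt, the warfarin dosing
rule over CYP2C9 star alleles and the VKORC1 promoter SNP rs9923231, and the
two azathioprine rules (CPIC and Dutch Pharmacogenomics Working Group) whose
TPMT target populations are nested — the canonical demonstration of the
rule-overlap audit.

The TPMT panel here is *synthetic*: the star-allele names and the
*3A/*3B/*3C-under-*3 taxonomy are real nomenclature, but each non-reference
haplotype is distinguished by one private tag SNP with invented rsIDs, which
guarantees pairwise distinguishability and unambiguous diplotype calls.
Registry strand orientations are likewise synthetic defaults (forward).
"""

from __future__ import annotations

from .genotype_io import PatientGenotype
from .kb_model import (
    CdsRule,
    HaplotypeTaxonomy,
    KnowledgeBase,
    SnpDefinition,
    parse_expression,
    parse_haplotype_table,
)

__all__ = [
    "CYP2C9_TABLE_TSV",
    "WARFARIN_MESSAGE",
    "AZATHIOPRINE_CPIC_MESSAGE",
    "AZATHIOPRINE_DPWG_MESSAGE",
    "cyp2c9_kb",
    "tpmt_kb",
    "demo_kb",
    "warfarin_patient",
    "tpmt_patient",
    "genotype_to_23andme",
]

CYP2C9_TABLE_TSV = (
    "Haplotype\trs1057910\trs1057911\trs1799853\trs2256871\n"
    "CYP2C9*1\tA\tA\tC\tA\n"
    "CYP2C9*3\tC\tA\tC\tA\n"
)

WARFARIN_MESSAGE = (
    "0.5-2 mg warfarin per day should be considered as a starting dose range "
    "for a patient with this genotype according to the warfarin drug label"
)

AZATHIOPRINE_CPIC_MESSAGE = (
    "If disease treatment normally starts at the “full dose”, "
    "consider starting at 30-70% of target dose (e.g., 1–1.5 mg/kg/d), "
    "and titrate based on tolerance. Allow 2–4 weeks to reach steady "
    "state after each dose adjustment."
)

AZATHIOPRINE_DPWG_MESSAGE = (
    "Select alternative drug or reduce dose by 50%. Increase dose in "
    "response of hematologic monitoring and efficacy."
)

_CYP2C9_SNPS = [
    # dbSNP's well-known allele pairs for these markers
    SnpDefinition("rs1057910", "CYP2C9", "forward", frozenset({"A", "C"}),
                  frozenset({"23andMe v3"}),
                  see_also="http://bio2rdf.org/dbsnp:rs1057910"),
    SnpDefinition("rs1057911", "CYP2C9", "forward", frozenset({"A", "T"}),
                  frozenset({"23andMe v3"})),
    SnpDefinition("rs1799853", "CYP2C9", "forward", frozenset({"C", "T"}),
                  frozenset({"23andMe v3"})),
    SnpDefinition("rs2256871", "CYP2C9", "forward", frozenset({"A", "G"}),
                  frozenset({"23andMe v3"})),
]

_VKORC1_SNP = SnpDefinition(
    "rs9923231", "VKORC1", "forward", frozenset({"C", "T"}),
    frozenset({"23andMe v3"}),
)


def cyp2c9_kb() -> KnowledgeBase:
    """CYP2C9 *1/*3 panel, the VKORC1 SNP, and the warfarin dosing rule."""
    registry = {s.rsid: s for s in _CYP2C9_SNPS}
    registry[_VKORC1_SNP.rsid] = _VKORC1_SNP
    haplotypes = parse_haplotype_table(CYP2C9_TABLE_TSV, "CYP2C9", registry)
    warfarin = CdsRule(
        id="warfarin_1",
        drug="warfarin",
        expression=parse_expression(
            {
                "and": [
                    {"hap": "CYP2C9*1", "min": 1},
                    {"hap": "CYP2C9*3", "min": 1},
                    {"snp": "rs9923231", "allele": "T", "exactly": 2},
                ]
            }
        ),
        message=WARFARIN_MESSAGE,
        source="warfarin drug label (FDA)",
        importance="important_modification",
    )
    return KnowledgeBase(
        snps=registry,
        haplotypes={"CYP2C9": haplotypes},
        cds_rules=[warfarin],
        metadata={"version": "fixtures-1", "provenance": "built-in examples"},
    )


# TPMT star alleles beyond the *1 reference; each gets one private tag SNP.
_TPMT_ALTS = (
    ["TPMT*2", "TPMT*3A", "TPMT*3B", "TPMT*3C"]
    + [f"TPMT*{i}" for i in range(4, 19)]
)


def tpmt_kb() -> KnowledgeBase:
    """Synthetic distinguishable TPMT panel with both azathioprine rules.

    20 concrete star alleles (*1, *2, *3A, *3B, *3C, *4-*18) over 19 tag
    SNPs (reference allele A, variant G; one private variant per
    non-reference haplotype), plus the abstract parent *3 with
    *3A/*3B/*3C as taxonomy children.
    """
    snps = {}
    rsids = []
    for i in range(len(_TPMT_ALTS)):
        rsid = f"rs{77000001 + i}"
        rsids.append(rsid)
        snps[rsid] = SnpDefinition(rsid, "TPMT", "forward", frozenset({"A", "G"}))
    rows = ["Haplotype\t" + "\t".join(rsids), "TPMT*1\t" + "\t".join("A" * len(rsids))]
    for i, name in enumerate(_TPMT_ALTS):
        alleles = ["A"] * len(rsids)
        alleles[i] = "G"
        rows.append(name + "\t" + "\t".join(alleles))
    haplotypes = parse_haplotype_table("\n".join(rows) + "\n", "TPMT", snps)
    taxonomy = HaplotypeTaxonomy(
        {"TPMT*3A": "TPMT*3", "TPMT*3B": "TPMT*3", "TPMT*3C": "TPMT*3"}
    )
    rule27 = CdsRule(
        id="27",
        drug="azathioprine",
        expression=parse_expression(
            {
                "and": [
                    {"hap": "TPMT*1", "min": 1},
                    {"or": [{"hap": n, "min": 1}
                            for n in ("TPMT*2", "TPMT*3A", "TPMT*3B",
                                      "TPMT*3C", "TPMT*4")]},
                ]
            }
        ),
        message=AZATHIOPRINE_CPIC_MESSAGE,
        source="CPIC",
        importance="important_modification",
    )
    rule35 = CdsRule(
        id="35",
        drug="azathioprine",
        expression=parse_expression(
            {
                "and": [
                    {"hap": "TPMT*1", "min": 1},
                    {"or": [{"hap": n, "min": 1}
                            for n in ["TPMT*2", "TPMT*3"]
                            + [f"TPMT*{i}" for i in range(4, 19)]]},
                ]
            }
        ),
        message=AZATHIOPRINE_DPWG_MESSAGE,
        source="Dutch Pharmacogenomics Working Group",
        importance="important_modification",
    )
    return KnowledgeBase(
        snps=snps,
        haplotypes={"TPMT": haplotypes},
        taxonomy=taxonomy,
        cds_rules=[rule27, rule35],
        metadata={"version": "fixtures-1"},
    )


def demo_kb() -> KnowledgeBase:
    """CYP2C9 + VKORC1 + TPMT content merged into one knowledge base."""
    return cyp2c9_kb().merge(tpmt_kb())


def warfarin_patient(patient_id: str = "demo_patient") -> PatientGenotype:
    """The walkthrough patient: CYP2C9 *1/*3 heterozygote, rs9923231 T/T."""
    g = PatientGenotype(patient_id=patient_id)
    g.add_call("rs1057910", "A", "C")
    g.add_call("rs1057911", "A", "A")
    g.add_call("rs1799853", "C", "C")
    g.add_call("rs2256871", "A", "A")
    g.add_call("rs9923231", "T", "T")
    return g


def tpmt_patient(
    pair=("TPMT*1", "TPMT*3A"), kb: KnowledgeBase = None,
    patient_id: str = "tpmt_patient",
) -> PatientGenotype:
    """A patient whose TPMT genotype is the given star-allele pair."""
    kb = kb or tpmt_kb()
    h1, h2 = kb.haplotype(pair[0]), kb.haplotype(pair[1])
    g = PatientGenotype(patient_id=patient_id)
    for rsid in kb.gene_panel("TPMT"):
        g.add_call(rsid, h1.allele_map[rsid], h2.allele_map[rsid])
    return g


def genotype_to_23andme(genotype: PatientGenotype, kb: KnowledgeBase) -> str:
    """Render a genotype as 23andMe raw-file text (forward-genome alleles)."""
    from .genotype_io import complement

    lines = ["# rsid\tchromosome\tposition\tgenotype"]
    rsids = sorted(set(genotype.calls) | genotype.missing)
    for pos, rsid in enumerate(rsids, start=1):
        if rsid in genotype.missing:
            geno = "--"
        else:
            pair = genotype.calls[rsid]
            snp = kb.snps.get(rsid)
            if snp is not None and snp.orientation == "reverse":
                pair = tuple(complement(a) for a in pair)
            geno = "".join(pair)
        lines.append(f"{rsid}\t1\t{pos}\t{geno}")
    return "\n".join(lines) + "\n"
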