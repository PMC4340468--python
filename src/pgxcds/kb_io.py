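"""Load and save knowledge-base archives.

An archive is a plain-text directory: a ``manifest.json``, the SNP registry
as TSV, one haplotype translation table per gene under ``haplotypes/``, the
taxonomy as JSON, and rule files in the JSON/YAML expression grammar (see
:func:`pgxcds.kb_model.parse_expression`).  Everything round-trips: an
archive saved from a knowledge base reloads to an equal knowledge base.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .kb_model import (
    CdsRule,
    HaplotypeTaxonomy,
    KbError,
    KnowledgeBase,
    PhenotypeRule,
    SnpDefinition,
    expression_to_json,
    parse_expression,
    parse_haplotype_table,
    serialize_haplotype_table,
)

__all__ = ["save_kb", "load_kb", "load_snp_registry", "load_rules"]

_REGISTRY_COLUMNS = ("rsid", "gene", "orientation", "alleles", "assays", "seeAlso")


def save_kb(kb: KnowledgeBase, directory) -> Path:
    directory = Path(directory)
    (directory / "haplotypes").mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(_REGISTRY_COLUMNS)]
    for rsid in sorted(kb.snps):
        s = kb.snps[rsid]
        lines.append(
            "\t".join(
                [
                    s.rsid,
                    s.gene,
                    s.orientation,
                    ",".join(sorted(s.alleles)),
                    ",".join(sorted(s.assays)),
                    s.see_also or "",
                ]
            )
        )
    (directory / "snps.tsv").write_text("\n".join(lines) + "\n")
    for gene in kb.genes():
        (directory / "haplotypes" / f"{gene}.tsv").write_text(
            serialize_haplotype_table(kb.haplotypes[gene])
        )
    (directory / "taxonomy.json").write_text(
        json.dumps({"parent": kb.taxonomy.parent}, indent=2) + "\n"
    )
    (directory / "phenotype_rules.json").write_text(
        json.dumps(
            [
                {
                    "id": r.id,
                    "phenotype": r.phenotype_label,
                    "expression": expression_to_json(r.expression),
                    "source": r.source,
                }
                for r in kb.phenotype_rules
            ],
            indent=2,
        )
        + "\n"
    )
    (directory / "cds_rules.json").write_text(
        json.dumps(
            [
                {
                    "id": r.id,
                    "drug": r.drug,
                    "expression": expression_to_json(r.expression),
                    "message": r.message,
                    "source": r.source,
                    "importance": r.importance,
                }
                for r in kb.cds_rules
            ],
            indent=2,
            ensure_ascii=False,
        )
        + "\n"
    )
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "format": "pgxcds-kb-1",
                "metadata": kb.metadata,
                "genes": kb.genes(),
            },
            indent=2,
        )
        + "\n"
    )
    return directory


def load_snp_registry(path) -> dict:
    """SNP registry from TSV (or JSON list of objects with the same fields)."""
    path = Path(path)
    registry = {}
    if path.suffix == ".json":
        for row in json.loads(path.read_text()):
            registry[row["rsid"]] = _snp_from_fields(
                row["rsid"], row["gene"], row.get("orientation", "forward"),
                row.get("alleles", ""), row.get("assays", ""),
                row.get("seeAlso", ""),
            )
        return registry
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    if tuple(header) != _REGISTRY_COLUMNS:
        raise KbError(f"unexpected registry header {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        fields += [""] * (len(_REGISTRY_COLUMNS) - len(fields))
        registry[fields[0]] = _snp_from_fields(*fields[:6])
    return registry


def _snp_from_fields(rsid, gene, orientation, alleles, assays, see_also):
    def split(v):
        if isinstance(v, (list, tuple, set, frozenset)):
            return frozenset(v)
        return frozenset(x.strip() for x in str(v).split(",") if x.strip())

    return SnpDefinition(
        rsid=rsid,
        gene=gene,
        orientation=orientation,
        alleles=split(alleles),
        assays=split(assays),
        see_also=see_also or None,
    )


def load_rules(path) -> tuple:
    """(phenotype_rules, cds_rules) from a JSON or YAML rule file.

    A rule with a ``phenotype`` field is a phenotype-inference rule; one with
    ``drug`` and ``message`` is a CDS rule.  A file may mix both.
    """
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return [], []
    if isinstance(data, dict):  # allow {"rules": [...]}
        data = data.get("rules", [])
    phenotype, cds = [], []
    for row in data:
        expr = parse_expression(row["expression"])
        if "phenotype" in row:
            phenotype.append(
                PhenotypeRule(
                    id=str(row["id"]),
                    phenotype_label=row["phenotype"],
                    expression=expr,
                    source=row.get("source", ""),
                )
            )
        elif "drug" in row:
            cds.append(
                CdsRule(
                    id=str(row["id"]),
                    drug=row["drug"],
                    expression=expr,
                    message=row["message"],
                    source=row.get("source", ""),
                    importance=row.get("importance", "standard"),
                )
            )
        else:
            raise KbError(f"rule {row.get('id')!r}: neither phenotype nor drug")
    return phenotype, cds


def load_kb(directory) -> KnowledgeBase:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    registry = load_snp_registry(directory / "snps.tsv")
    haplotypes = {}
    for table in sorted((directory / "haplotypes").glob("*.tsv")):
        gene = table.stem
        haplotypes[gene] = parse_haplotype_table(
            table.read_text(), gene, registry
        )
    taxonomy = HaplotypeTaxonomy({})
    tax_path = directory / "taxonomy.json"
    if tax_path.exists():
        taxonomy = HaplotypeTaxonomy(json.loads(tax_path.read_text())["parent"])
    phenotype_rules, cds_rules = [], []
    for name in ("phenotype_rules.json", "cds_rules.json", "rules.yaml"):
        path = directory / name
        if path.exists():
            p, c = load_rules(path)
            phenotype_rules += p
            cds_rules += c
    return KnowledgeBase(
        snps=registry,
        haplotypes=haplotypes,
        taxonomy=taxonomy,
        phenotype_rules=phenotype_rules,
        cds_rules=cds_rules,
        metadata=manifest.get("metadata", {}),
    )
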