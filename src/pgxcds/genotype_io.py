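"""Patient genotype input: 23andMe raw files and VCF.

Both readers produce the same in-memory representation: unordered diploid
allele pairs keyed by rsID, normalised to each SNP's defining strand
orientation.  Direct-to-consumer raw files and VCF both report alleles on
the forward strand of the reference genome, so calls at SNPs whose registry
entry is reverse-oriented are complement-flipped on ingest; downstream
haplotype matching then never needs to think about strand again.

Phase is discarded everywhere (pairs are unordered): star-allele calling
works from unphased zygosity, and cis/trans ambiguity is surfaced by the
inference layer instead.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pysam

from .kb_model import SnpDefinition

logger = logging.getLogger(__name__)

__all__ = ["PatientGenotype", "complement", "read_23andme", "read_vcf"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# tokens kept verbatim through strand flips; 23andMe "I"/"D" map onto these
INDEL_TOKENS = frozenset({"INS", "DEL"})


@dataclass
class PatientGenotype:
    """Unordered diploid calls per rsID, plus explicitly reported no-calls."""

    patient_id: str = "patient"
    calls: dict = field(default_factory=dict)  # rsid -> (allele, allele) sorted
    missing: set = field(default_factory=set)

    def add_call(self, rsid: str, a1: str, a2: str):
        if rsid in self.missing:
            self.missing.discard(rsid)
        self.calls[rsid] = tuple(sorted((a1, a2)))

    def to_json(self) -> dict:
        return {
            "patient": self.patient_id,
            "calls": {r: list(p) for r, p in sorted(self.calls.items())},
            "missing": sorted(self.missing),
        }


def complement(allele: str) -> str:
    """Reverse-complement of an allele string; indel tokens pass through.

    Multi-base alleles are complemented base-wise and reversed, so that a
    reverse-strand report of an inserted segment maps onto the defining
    strand's sequence.  The map is an involution: ``complement(complement(x))
    == x`` for every valid input.
    """
    if allele in INDEL_TOKENS:
        return allele
    try:
        return "".join(_COMP[b] for b in reversed(allele))
    except KeyError as exc:
        raise ValueError(f"cannot complement allele {allele!r}: {exc.args[0]!r}")


def _orient(allele: str, snp: SnpDefinition) -> str:
    return complement(allele) if snp.orientation == "reverse" else allele


def read_23andme(
    stream,
    snp_registry: Mapping[str, SnpDefinition],
    patient_id: str = "patient",
) -> PatientGenotype:
    """Read a 23andMe raw-data file (rsid / chromosome / position / genotype).

    Lines starting with ``#`` are comments.  A genotype of ``--`` records the
    rsID as an explicit no-call; single-letter (hemizygous X/Y/MT) genotypes
    are recorded as missing because calling is strictly diploid here.
    Identifiers absent from the registry (including 23andMe-internal ``i``
    ids) are skipped with a log entry.  ``I``/``D`` genotype characters are
    mapped to the INS/DEL tokens and logged, since their exact sequence is
    not recoverable from the raw file.
    """
    if isinstance(stream, (str, Path)):
        stream = open(stream, "r", encoding="utf-8")
    genotype = PatientGenotype(patient_id=patient_id)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        rsid, _chrom, _pos, geno = (f.strip() for f in fields)
        snp = snp_registry.get(rsid)
        if snp is None:
            logger.debug("line %d: %s not in registry, skipped", lineno, rsid)
            continue
        if geno == "--":
            genotype.missing.add(rsid)
            continue
        if len(geno) == 1:
            logger.info("line %d: %s hemizygous call %r recorded as missing",
                        lineno, rsid, geno)
            genotype.missing.add(rsid)
            continue
        if len(geno) != 2:
            raise ValueError(f"line {lineno}: genotype {geno!r} is not diploid")
        alleles = []
        for ch in geno.upper():
            if ch == "I":
                logger.info("line %d: %s insertion character mapped to INS",
                            lineno, rsid)
                alleles.append("INS")
            elif ch == "D":
                logger.info("line %d: %s deletion character mapped to DEL",
                            lineno, rsid)
                alleles.append("DEL")
            else:
                alleles.append(ch)
        genotype.add_call(rsid, _orient(alleles[0], snp), _orient(alleles[1], snp))
    return genotype


def read_vcf(
    source,
    snp_registry: Mapping[str, SnpDefinition],
    sample: Optional[str] = None,
    patient_id: Optional[str] = None,
) -> PatientGenotype:
    """Read one sample's genotypes from a VCF (v4.x, plain or bgzipped).

    Records are matched to the registry by the ID field only — the knowledge
    base is rsID-keyed.  GT indices are resolved against REF/ALT; both ``/``
    and ``|`` separators are accepted and phase is discarded.  ``./.`` or any
    half-missing genotype records the rsID as a no-call.  A multi-sample file
    needs an explicit ``sample``; a single-sample file uses its only sample.
    """
    path, tmp = _as_path(source)
    try:
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            if not samples:
                raise ValueError("VCF has no sample column")
            if sample is None:
                if len(samples) > 1:
                    raise ValueError(
                        f"multi-sample VCF ({len(samples)} samples): select one "
                        "with sample="
                    )
                sample = samples[0]
            elif sample not in samples:
                raise ValueError(f"sample {sample!r} not in VCF")
            genotype = PatientGenotype(patient_id=patient_id or sample)
            for rec in vcf:
                rsid = rec.id
                if rsid is None or rsid not in snp_registry:
                    continue
                snp = snp_registry[rsid]
                gt = rec.samples[sample].get("GT")
                if gt is None or len(gt) != 2 or any(i is None for i in gt):
                    genotype.missing.add(rsid)
                    continue
                alleles = []
                for idx in gt:
                    if idx >= len(rec.alleles):
                        raise ValueError(
                            f"{rsid}: GT index {idx} out of range of REF/ALT"
                        )
                    alleles.append(rec.alleles[idx].upper())
                genotype.add_call(
                    rsid, _orient(alleles[0], snp), _orient(alleles[1], snp)
                )
            return genotype
    finally:
        if tmp is not None:
            tmp.unlink(missing_ok=True)


def _as_path(source) -> tuple:
    """Accept a filesystem path or a text/binary stream (spooled to a temp file)."""
    if isinstance(source, (str, Path)):
        return Path(source), None
    data = source.read()
    if isinstance(data, str):
        data = data.encode()
    tmp = tempfile.NamedTemporaryFile(suffix=".vcf", delete=False)
    tmp.write(data)
    tmp.close()
    return Path(tmp.name), Path(tmp.name)
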