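"""Synthetic cohorts with ground truth, and the batch calling pipeline.

The simulator stands in for a public collection of direct-to-consumer
profiles: it draws a random, pairwise-distinguishable star-allele panel per
gene, samples each patient's two haplotypes independently from the panel's
frequency vector (Hardy-Weinberg — the minimal diploid population model, no
linkage or mutation), writes 23andMe-style or VCF profile files, and keeps
a truth record per patient for end-to-end recovery checks.

Missingness uses a coupled design: one uniform number is drawn per genotype
call and the call is dropped when it falls below the missingness
probability.  At a fixed seed the set of dropped calls therefore grows
monotonically with the missingness parameter, so the strict-mode call rate
is non-increasing in missingness exactly, not just in expectation.

All randomness flows from ``SimConfig.seed``; identical configurations give
byte-identical output files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .genotype_io import complement, read_23andme, read_vcf
from .inference import InferenceResult, realize_patient
from .kb_model import HaplotypeDefinition, KbError, KnowledgeBase, SnpDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "BatchResult",
    "simulate_panel",
    "simulate_patients",
    "batch_process",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults model a small pharmacogene screen: a handful of genes, a few
    defining SNPs each, biallelic markers, and fully observed genotypes
    unless a per-call missingness probability is set.
    """

    seed: int = 0
    genes: int = 3
    snps_per_gene: int = 4
    haplotypes_per_gene: int = 4
    haplotype_frequencies: Optional[dict] = None  # gene -> probability vector
    missingness: float = 0.0
    n_patients: int = 100
    output_format: str = "23andme"  # or "vcf"

    def __post_init__(self):
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must be in [0, 1]")
        if self.output_format not in ("23andme", "vcf"):
            raise ValueError("output_format must be 23andme or vcf")
        if self.haplotype_frequencies is not None:
            for gene, freq in self.haplotype_frequencies.items():
                arr = np.asarray(freq, dtype=float)
                if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{gene}: frequencies must sum to 1")


@dataclass
class TruthRecord:
    patient_id: str
    diplotypes: dict  # gene -> (name, name) sorted
    dropped: tuple  # rsIDs whose calls were masked to no-calls

    def to_json(self) -> dict:
        return {
            "patient": self.patient_id,
            "diplotypes": {g: list(p) for g, p in sorted(self.diplotypes.items())},
            "dropped": list(self.dropped),
        }


def simulate_panel(config: SimConfig) -> tuple:
    """Random distinguishable star-allele panel: (KnowledgeBase, frequencies).

    Per gene, biallelic SNPs with random allele pairs and random strand
    orientations; haplotype allele maps are rejection-sampled until pairwise
    distinct, so the panel always passes the distinguishability audit.
    Frequencies come from the config or a flat Dirichlet draw.
    """
    if config.haplotypes_per_gene > 2**config.snps_per_gene:
        raise KbError(
            f"cannot build {config.haplotypes_per_gene} distinct haplotypes "
            f"over {config.snps_per_gene} biallelic SNPs"
        )
    rng = np.random.default_rng(config.seed)
    snps: dict = {}
    haplotypes: dict = {}
    freqs: dict = {}
    for gi in range(config.genes):
        gene = f"GENE{gi + 1}"
        rsids = []
        alleles_by_rsid = {}
        for si in range(config.snps_per_gene):
            rsid = f"rs{90000000 + gi * 1000 + si}"
            pair = tuple(rng.choice(len(_BASES), size=2, replace=False))
            alleles = tuple(_BASES[k] for k in sorted(pair))
            orientation = "reverse" if rng.random() < 0.5 else "forward"
            snps[rsid] = SnpDefinition(
                rsid, gene, orientation, frozenset(alleles)
            )
            rsids.append(rsid)
            alleles_by_rsid[rsid] = alleles
        seen = set()
        defs = []
        attempts = 0
        while len(defs) < config.haplotypes_per_gene:
            attempts += 1
            if attempts > 1000 * config.haplotypes_per_gene:
                raise KbError(f"{gene}: could not sample distinct haplotypes")
            vec = tuple(
                alleles_by_rsid[r][rng.integers(0, 2)] for r in rsids
            )
            if vec in seen:
                continue
            seen.add(vec)
            defs.append(
                HaplotypeDefinition(
                    gene=gene,
                    name=f"{gene}*{len(defs) + 1}",
                    allele_map=dict(zip(rsids, vec)),
                )
            )
        haplotypes[gene] = defs
        if config.haplotype_frequencies and gene in config.haplotype_frequencies:
            freqs[gene] = np.asarray(config.haplotype_frequencies[gene], float)
        else:
            freqs[gene] = rng.dirichlet(np.ones(config.haplotypes_per_gene))
    kb = KnowledgeBase(
        snps=snps,
        haplotypes=haplotypes,
        metadata={"version": f"sim-seed{config.seed}"},
    )
    return kb, freqs


def simulate_patients(kb: KnowledgeBase, freqs: dict, config: SimConfig,
                      outdir) -> list:
    """Write one profile file per patient under ``outdir``; return truth records.

    Two haplotypes per gene are drawn independently from the gene's
    frequency vector; each panel SNP's genotype is the unordered allele
    pair, written on the forward genome strand (reverse-oriented registry
    SNPs are complemented on output, mirroring what assays report).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 7])
    genes = kb.genes()
    truths = []
    for pi in range(config.n_patients):
        pid = f"sim_{pi:04d}"
        diplotypes = {}
        calls = []  # (gene_idx, pos, rsid, pair-or-None)
        dropped = []
        for gi, gene in enumerate(genes):
            names = [h.name for h in kb.haplotypes[gene]]
            freq = freqs[gene]
            i1 = int(rng.choice(len(names), p=freq))
            i2 = int(rng.choice(len(names), p=freq))
            h1 = kb.haplotypes[gene][i1]
            h2 = kb.haplotypes[gene][i2]
            diplotypes[gene] = tuple(sorted((h1.name, h2.name)))
            for pos, rsid in enumerate(kb.gene_panel(gene), start=1):
                pair = (h1.allele_map[rsid], h2.allele_map[rsid])
                if rng.random() < config.missingness:
                    dropped.append(rsid)
                    pair = None
                calls.append((gi + 1, pos, rsid, pair))
        if config.output_format == "23andme":
            _write_23andme(outdir / f"{pid}.txt", kb, calls)
        else:
            _write_vcf(outdir / f"{pid}.vcf", kb, pid, calls)
        truths.append(TruthRecord(pid, diplotypes, tuple(dropped)))
    return truths


def _forward(pair, snp: SnpDefinition):
    if snp.orientation == "reverse":
        return tuple(complement(a) for a in pair)
    return pair


def _write_23andme(path: Path, kb: KnowledgeBase, calls):
    lines = ["# rsid\tchromosome\tposition\tgenotype"]
    for chrom, pos, rsid, pair in calls:
        if pair is None:
            geno = "--"
        else:
            geno = "".join(sorted(_forward(pair, kb.snps[rsid])))
        lines.append(f"{rsid}\t{chrom}\t{pos}\t{geno}")
    path.write_text("\n".join(lines) + "\n")


def _write_vcf(path: Path, kb: KnowledgeBase, sample: str, calls):
    contigs = sorted({chrom for chrom, *_ in calls})
    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID={c}>" for c in contigs),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for chrom, pos, rsid, pair in calls:
        snp = kb.snps[rsid]
        file_alleles = sorted(_forward(tuple(sorted(snp.alleles)), snp))
        ref, alts = file_alleles[0], file_alleles[1:]
        if pair is None:
            gt = "./."
        else:
            fpair = _forward(pair, snp)
            idx = [file_alleles.index(a) for a in fpair]
            gt = f"{min(idx)}/{max(idx)}"
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t{gt}"
        )
    path.write_text("\n".join(lines) + "\n")


@dataclass
class BatchResult:
    """Aggregate of realizing every profile in a directory."""

    n_profiles: int = 0
    n_failures: int = 0
    results: list = field(default_factory=list)  # InferenceResult, file order
    mean_matched_snps: Optional[float] = None
    mean_triggered_rules: Optional[float] = None
    gene_rates: dict = field(default_factory=dict)
    diplotype_frequencies: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "n_profiles": self.n_profiles,
            "n_failures": self.n_failures,
            "mean_matched_snps": self.mean_matched_snps,
            "mean_triggered_rules": self.mean_triggered_rules,
            "gene_rates": self.gene_rates,
            "diplotype_frequencies": {
                g: dict(sorted(c.items())) for g, c in
                sorted(self.diplotype_frequencies.items())
            },
        }


def batch_process(profile_dir, kb: KnowledgeBase, strict: bool = True) -> BatchResult:
    """Realize every profile file in a directory and aggregate statistics.

    ``.txt``/``.tsv`` files are read as 23andMe raw data, ``.vcf`` as VCF.
    Unreadable profiles are logged, skipped, and counted as failures.  The
    diplotype frequency table counts unambiguous calls only.
    """
    profile_dir = Path(profile_dir)
    out = BatchResult()
    files = sorted(
        p for p in profile_dir.iterdir()
        if p.suffix in (".txt", ".tsv", ".vcf") and not p.name.startswith("truth")
    )
    counts: dict = {g: Counter() for g in kb.genes()}
    dipfreq: dict = {g: Counter() for g in kb.genes()}
    for path in files:
        try:
            if path.suffix == ".vcf":
                genotype = read_vcf(path, kb.snps, patient_id=path.stem)
            else:
                genotype = read_23andme(path, kb.snps, patient_id=path.stem)
            result = realize_patient(genotype, kb, strict=strict)
        except Exception:
            logger.exception("failed to process %s", path)
            out.n_failures += 1
            continue
        out.n_profiles += 1
        out.results.append(result)
        for gene, call in result.calls.items():
            if not call.called:
                counts[gene]["no_call"] += 1
            elif call.ambiguous:
                counts[gene]["ambiguous"] += 1
            else:
                counts[gene]["called"] += 1
                dipfreq[gene][str(call.diplotypes[0])] += 1
    if out.n_profiles:
        out.mean_matched_snps = (
            sum(r.matched_snps for r in out.results) / out.n_profiles
        )
        out.mean_triggered_rules = (
            sum(len(r.triggered) for r in out.results) / out.n_profiles
        )
        out.gene_rates = {
            g: {
                "call_rate": (c["called"] + c["ambiguous"]) / out.n_profiles,
                "ambiguity_rate": c["ambiguous"] / out.n_profiles,
                "no_call_rate": c["no_call"] / out.n_profiles,
            }
            for g, c in counts.items()
        }
        out.diplotype_frequencies = {g: dict(c) for g, c in dipfreq.items() if c}
    return out
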