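# pgxcds

Star-allele calling and pharmacogenomic clinical decision support from
unphased genotypes, with static auditing of the underlying knowledge base.

Pharmacogenomic knowledge is conventionally curated as *haplotype
translation tables* (rows = star alleles such as `CYP2C9*3`, columns =
dbSNP rsIDs, cells = the allele each haplotype carries) and as dosing
guidelines that target genotype-defined patient populations ("a patient
carrying TPMT\*1 and one non-functional TPMT allele should start
azathioprine at 30–70% of target dose"). `pgxcds` compiles this content
into a small logical knowledge base and provides:

- **diplotype calling** — given a patient's unphased diploid genotype
  (23andMe raw file or VCF), find every unordered pair of star alleles
  {h₁, h₂} such that at every panel SNP *r* the multiset
  {h₁(r), h₂(r)} equals the observed allele counts. Calling is *strict* by
  default: if any defining SNP is unobserved, the gene is reported as a
  no-call rather than guessed, trading recall for precision;
- **rule matching** — phenotype-inference and clinical-decision-support
  (CDS) rules are monotone boolean expressions over qualified-cardinality
  atoms (`≥1 copy of TPMT*1`, `exactly 2 copies of the T allele of
  rs9923231`), evaluated against the called diplotypes with support closed
  upward through the star-allele taxonomy (a \*3A carrier satisfies a \*3
  atom);
- **knowledge-base audits** — detection of *indistinguishable haplotypes*
  (identical rows, the classic translation-table defect), of rules no
  diploid genotype can satisfy, and — via exhaustive model enumeration over
  the finite diplotype space — of rule pairs whose target populations are
  **equivalent or nested for the same drug but carry different
  recommendations**;
- **OWL 2 export** (Turtle and functional syntax) of the same content as
  equivalent-class definitions built from qualified cardinality
  restrictions, plus annotation-driven entity counting of any RDF ontology;
- a **simulator** that generates distinguishable panels and Hardy–Weinberg
  cohorts with ground truth, and a **batch pipeline** with population
  statistics.

## Worked example

The built-in fixtures carry the CYP2C9 \*1/\*3 translation-table excerpt,
the VKORC1 promoter SNP rs9923231, and a warfarin label rule requiring
haplotypes \*1 and \*3 plus homozygous T at rs9923231:

```python
from pgxcds import fixtures, realize_patient

kb = fixtures.demo_kb()
patient = fixtures.warfarin_patient()   # rs1057910 A/C, rs9923231 T/T, ...
result = realize_patient(patient, kb)
print(result.to_json())
```

prints (abridged):

```json
{
  "patient": "demo_patient",
  "diplotypes": {"CYP2C9": ["CYP2C9*1/CYP2C9*3"], "TPMT": []},
  "ambiguity": {"CYP2C9": false, "TPMT": false},
  "no_call": {"TPMT": ["rs77000001", "..."]},
  "recommendations": [
    {
      "rule": "warfarin_1",
      "drug": "warfarin",
      "importance": "important_modification",
      "source": "warfarin drug label (FDA)",
      "message": "0.5-2 mg warfarin per day should be considered as a starting dose range for a patient with this genotype according to the warfarin drug label"
    }
  ],
  "stats": {"matched_snps": 5, "triggered_rules": 1}
}
```

The heterozygous A/C call at rs1057910 (all other CYP2C9 panel SNPs
homozygous reference) admits exactly one consistent diplotype, \*1/\*3; the
homozygous T/T at rs9923231 then satisfies the warfarin rule's
exactly-2-copies atom, so its message is the single triggered
recommendation. The TPMT panel is entirely unobserved, so that gene is a
no-call and neither azathioprine rule fires.

The conflict audit on the two azathioprine rules reports that the CPIC
population (one \*1 plus one of \*2/\*3A/\*3B/\*3C/\*4) is strictly
contained in the Dutch working group's (one \*1 plus one of \*2–\*18, where
\*3A/\*3B/\*3C are subtypes of \*3), with the conflict flag set because the
two recommendation texts differ for the same drug:

```sh
$ pgxcds audit demo
{ "summary": { "n_rules": 3, ..., "narrower_or_equal_rules": 1,
               "conflicting_pairs": 1 }, ... }
```

The same workflows are available from the shell: `pgxcds compile`,
`validate`, `call`, `recommend`, `audit`, `export-owl`, `count-owl`,
`simulate`, `batch` (see `pgxcds --help`).

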