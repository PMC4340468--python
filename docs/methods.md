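# Methods

## The knowledge model

A knowledge base has four layers:

1. **SNP registry.** Each polymorphism carries a dbSNP-style rsID, its gene,
   the set of observable alleles (uppercase; indels are carried as literal
   `INS`/`DEL` tokens without left-normalisation), optional assay coverage,
   and a strand orientation (`forward`/`reverse`) relative to the reference
   genome. Orientation is metadata about how the *defining* alleles in the
   translation tables are written; assay output (23andMe raw data, VCF) is
   always forward-genome, so reverse-oriented calls are reverse-complemented
   on ingest and strand never reappears downstream.
2. **Star-allele panels.** A gene's haplotypes are compiled from a TSV
   translation table (first column `Haplotype`, remaining columns rsIDs).
   The first data row is the reference haplotype (conventionally \*1) and a
   blank cell means "same allele as the reference row" — the PharmGKB
   table convention. Every haplotype's allele map is total over the gene
   panel after compilation. Cells with ambiguity codes (`A/C`) are rejected
   rather than interpreted. Star-allele names are opaque strings; the `*`
   convention is not parsed.
3. **Taxonomy.** A partial child → parent map between star-allele names
   (e.g. TPMT\*3A under TPMT\*3), acyclic, within one gene. Parents may be
   *abstract* — taxonomy-only names with no allele map — so rules can refer
   to a whole allele family. Abstract names are excluded from the diplotype
   enumeration domain.
4. **Rules.** Phenotype-inference rules (label + expression) and CDS rules
   (drug, message, source, importance ∈ {standard, minor_deviation,
   important_modification}). Expressions are monotone (negation-free) trees
   of AND/OR over three atom kinds: haplotype cardinality (`≥c` or
   `exactly c` copies, c ∈ {1,2}), variant cardinality (copies of one
   allele of one SNP), and phenotype labels. The on-disk grammar is small
   JSON/YAML (`{"and": [...]}`, `{"hap": "TPMT*1", "min": 1}`,
   `{"snp": "rs9923231", "allele": "T", "exactly": 2}`,
   `{"phenotype": "..."}`). Published rule sets do not print their atom
   structure exhaustively, so the grammar is deliberately a small superset
   of what the shipped fixtures need.

## Calling and realization

Genotype calls are unordered diploid allele pairs per rsID (phase
discarded; haploid loci are recorded as missing — the cardinality patterns
are strictly diploid). The zygosity profile maps each observed rsID to
allele counts summing to 2.

A diplotype {h₁, h₂} is *consistent* with the profile when, at every panel
SNP r, the multiset {h₁(r), h₂(r)} equals the observed counts. The default
**strict** policy requires every panel SNP to be observed and otherwise
returns a no-call naming the missing rsIDs; this mirrors conservative
allele definitions that include rare distinguishing SNPs to avoid calling
a common haplotype incorrectly, at the cost of recall on sparse consumer
arrays. A **lenient** mode restricts the consistency check to the observed
panel subset for exploring that precision/recall trade-off.

Several diplotypes can be simultaneously consistent (unphased cis/trans
ambiguity). Haplotype *support* uses union-entailment semantics: every
consistent diplotype contributes its members and their taxonomy ancestors,
and a name's support is the maximum copy count any single diplotype gives
it. This matches monotone entailment from asserted class memberships; the
ambiguity is additionally surfaced as a flag so callers can suppress
recommendations when more than one diplotype fits.

Atom evaluation: `at_least c` compares against support; `exactly 2` of H
requires a consistent diplotype that is a true homozygote {d, d} with
d ⊑ H (two copies of a parent via two *different* subtypes do not count);
`exactly 1` requires a consistent diplotype with exactly one copy.
Variant atoms count alleles in the profile. Atoms over unobserved SNPs or
no-call genes are false — a rule never fires on absent evidence.
Phenotype rules are iterated to a fixpoint (monotone, hence convergent)
before CDS rules are evaluated. Triggered recommendations are ordered by
importance (important_modification first), then rule id; all other
orderings are lexicographic so outputs are byte-reproducible.

## Population semantics and the conflict audit

A rule's target population is modelled over *complete* assignments: every
constrained gene carries an unordered haplotype pair (or, for
registry-only genes without a panel, an unordered allele pair per SNP).
This matches class-level subsumption over fully specified individuals and
makes nesting judgements exact. Because the state space is finite,
subsumption reduces to set containment over enumerated models.

Expressions are first decomposed into per-gene conjuncts (AND distributes
across genes; an OR must stay within one gene). The comparison is then
componentwise over the union of constrained genes, with an unconstrained
gene defaulting to its full domain — this is exactly containment of the
product populations. If either rule has an empty component its population
is empty and is subsumed trivially. Cross-gene disjunctions (none occur in
the shipped content, which is per-gene conjunctive) fall back to bounded
product enumeration with a default limit of 10⁶ models; exceeding the
limit yields an explicit `undecided` relation, never a silent truncation.

The audit compares all unordered rule pairs and flags a *conflict* when
the populations are equivalent or nested, the drug matches, and the
message differs. Because published overlap statistics can be counted under
two conventions, the summary reports both: `narrower_or_equal_rules`
(a rule counts when its population is equal to, or strictly inside, some
other rule's — equivalent pairs count both members, strict subsumption
only the narrower side) and `participating_rules` (either side).

## OWL export

The OWL view re-expresses the same semantics in standard syntax: SNPs are
classes under `polymorphism` with rsid/gene/assay/orientation annotations,
alleles are subclasses of their SNP, and for every unordered haplotype
pair a "human with ..." class carries an EquivalentClasses definition of
qualified cardinality restrictions over allele classes — `exactly 1` of
each allele where the pair is heterozygous, `exactly 2` where it is
homozygous — plus SubClassOf assertions of haplotype possession. Rules are
classes of humans with their expressions translated directly.

IRIs use a single base namespace with sanitized fragments (`*` →
`_star_`); blank-node labels come from a local counter so serialization is
deterministic. Patients are exported as individuals with one anonymous
chromosome-copy node per allele instance (two per called SNP), which keeps
homozygous assertions distinct in the RDF graph and makes triple counts an
exact linear function of the number of calls. Entity counting is
annotation-driven (classes bearing the rsID annotation are SNPs, etc.)
with a configurable property mapping so it can be pointed at externally
produced ontologies whose vocabulary differs; the export targets
structural interoperability, not bit-identity with any particular released
artifact. The native engine, not an external DL reasoner, is authoritative
for inference.

## The simulator

The simulator emulates the inputs a public profile collection would
provide, with known truth. Per gene it draws biallelic SNPs with random
allele pairs and orientations and rejection-samples haplotype allele maps
until pairwise distinct, so generated panels always pass the
distinguishability audit. Patients draw two haplotypes per gene
independently from the panel's frequency vector (Hardy–Weinberg — the
minimal diploid model; no linkage disequilibrium, mutation, or
relatedness), and profiles are written as 23andMe-style text or VCF with
forward-genome alleles. Frequency vectors default to a flat Dirichlet
draw per gene when not supplied.

Missingness is applied with a *coupled* design: one uniform number is
drawn per genotype call and compared against the missingness probability,
so at a fixed seed the set of dropped calls grows monotonically in the
parameter and the strict-mode call rate is non-increasing in missingness
exactly, per seed, not merely in expectation. All randomness flows from
the single config seed; identical configs give byte-identical files.

What passing simulated tests does **not** show: real translation tables
contain underspecified (indistinguishable) haplotypes, deprecated rsIDs,
multi-allelic and indel markers, and array panels whose coverage is far
sparser than the simulated one; population structure and linkage are
absent. The simulator establishes correctness of the calling and auditing
machinery, not real-world call rates.

## Problem sizes and numerics

The shipped fixtures are intentionally small (a 2-haplotype CYP2C9
excerpt; a 20-haplotype TPMT panel over 19 synthetic tag SNPs). Default
test and verification runs use panels of ≤12 haplotypes, cohorts of up to
500 patients, and ≥200 randomized oracle comparisons for calling plus
≥100 for rule comparison — sizes at which the exhaustive oracles
(enumeration of all n(n+1)/2 pairs, full product truth tables) remain
cheap, which is what makes zero-disagreement checks meaningful. All
arithmetic is exact integer/set computation; there are no tolerances to
tune. Degenerate inputs have defined behaviour: empty genotypes yield
all-gene no-calls and no triggered rules, empty tables yield empty panels,
and an observed-but-matchless profile is distinguished from a
missing-data no-call by an empty missing list.

## Known limitations

- Calling is purely combinatorial: no likelihoods, no use of allele
  frequencies, no ranking of ambiguous diplotypes (frequencies exist only
  in the simulator).
- The union-entailment treatment of ambiguity is permissive by design;
  consumers should gate recommendations on the ambiguity flag in clinical
  settings.
- Structural variation (e.g. CYP2D6 copy-number hybrids) is out of scope;
  markers are point variants and token-level indels.
- 23andMe insertion/deletion genotype characters (`I`/`D`) are mapped to
  `INS`/`DEL` tokens and logged; the sequence-level identity of the indel
  is not recoverable from the raw file.
- VCF records are matched by the ID column only (the knowledge base is
  rsID-keyed); positional matching is not attempted.
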