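# cpg-mutspec

Tools for characterizing de novo point mutations in clonal genomes, with a
focus on C>T transitions at CpG sites:

* **filtering** — read-metric SNV identification filters (central/surrounding
  base quality, window gap+mismatch, depth, parental and sister allele
  counts, known-variant/simple-repeat/homopolymer exclusions, VAF band) as
  composable predicates with a per-filter removal report;
* **spectrum** — strand-collapsed 24-category mutation classification
  (6 classes × 4 3'-neighbors), genomic dinucleotide abundance counting on
  both strands, per-10⁹ normalized rates, CpG / non-CpG C>T partition and
  its correlation with total SNV load across clones;
* **sister** — shared-SNV detection across sister-clone call sets and
  reference-swap concordance;
* **enrichment** — compartment assignment (CDS > intron > intergenic),
  retrotransposon class percentages with a two-proportion Z-test, SINE
  subfamily enrichment relative to a germline comparator (AluJ-scaled),
  DMR in/out rate ratios normalized by CpG / other-C site abundance,
  CGI and CGI-shore (±5 kb) counts, nearest-TSS distance profiles;
* **coding** — codon-level consequence annotation and an exhaustive census
  of codon changes reachable by CpG-context C>T substitutions;
* **synthetic** — a fully seeded generator for genomes with controlled GC
  content and CpG observed/expected ratio (first-order Markov chain with
  exact stationary targets), annotation tracks, context-weighted mutation
  sets, and sister-clone families with designed shared/private/pre-existing
  structure plus a complete truth ledger — so every downstream statistic
  can be verified against a known ground truth.

## Command-line usage

All functionality is reachable through the `cpg-mutspec` entry point:

```sh
# generate a synthetic dataset (FASTA + BED tracks + per-clone VCFs + truth)
cpg-mutspec simulate --length 200000 --n-clones 3 --seed 1 --out data/

# apply the identification filters
cpg-mutspec filter --vcf data/clone1.vcf --genome data/genome.fa \
    --out-vcf calls1.vcf --report report1.tsv

# 24-category normalized spectrum
cpg-mutspec spectrum --vcf calls1.vcf --genome data/genome.fa --out spectrum.tsv

# shared SNVs across clones (filter with --no-sisters first)
cpg-mutspec sister --vcf calls1.vcf --vcf calls2.vcf --mode shared --out shared.tsv

# regional enrichment statistics
cpg-mutspec enrich --vcf calls1.vcf --genome data/genome.fa \
    --repeats data/repeats.bed --cgi data/cgi.bed --tss data/tss.bed \
    --dmr data/dmr.bed --out-prefix enrich

# codon-level consequences + CpG C>T codon census
cpg-mutspec coding --vcf calls1.vcf --genome data/genome.fa \
    --cds data/cds.gff --out effects.tsv --census census.tsv

# full staged pipeline from a YAML config (filter → spectrum → sister →
# enrich → coding), reproducible from config + seed
cpg-mutspec run --config config.yaml --seed 1 --out results/
```

Candidate VCFs carry the filter metrics as INFO tags (`DP`, `VAC`, `CQ`,
`SQ`, `GM`, plus optional `PAC`, `SAC`, `KNOWN`, `SRP`, `HPR`); the five
required tags must be declared and present, and a missing metric needed by
an enabled filter is a hard error — records never silently pass. Variant
positions are 1-based (VCF convention); interval tracks are 0-based
half-open (BED convention).

## Layout

```
src/cpg_mutspec/
  core.py         domain types, coordinate conventions, strand collapse
  intervals.py    interval tracks with exact stabbing queries
  annotations.py  repeat/CGI/TSS/DMR tracks and CDS transcript models
  io.py           FASTA / VCF / BED / GFF readers and writers
  filtering.py    identification filters + homopolymer detection
  spectrum.py     24-category spectrum, abundances, CpG partition
  sister.py       shared SNVs and reference-swap concordance
  enrichment.py   regional statistics and the two-proportion Z-test
  coding.py       codon effects and the CpG C>T codon census
  synthetic.py    seeded generators for genomes/tracks/mutations/families
  pipeline.py     staged orchestration with manifest + conservation checks
  cli.py          click-based CLI
```
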