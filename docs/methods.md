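# Methods

## Cross and inheritance model

The simulator (`geckomap.simulate`) emulates the mapping cross: one affected
father (*mss/mss*), two carrier mothers (*mss/+*), and offspring sorted by
genotype into a homozygous pool (n = 12) and a heterozygous pool (n = 14).
Phenotype equals genotype with complete penetrance — the wild-type allele is
incompletely dominant, so heterozygotes are visually distinguishable and
pools can be formed by phenotype.

Each mother carries one complete **mss-line haplotype** (alternate allele at
every informative site, genome-wide, in phase with the causal allele) and one
wild haplotype. This is the minimal structure that makes cosegregation decay
with genetic distance: an informative variant far from the locus ends up on
the "wrong" maternal haplotype only through recombination. Meiosis follows
the **Haldane model**: crossover count per chromosome is Poisson with mean
`length_Mb × rate / 100` Morgans (default rate 1 cM/Mb), breakpoint positions
uniform, no interference. A configurable **crossover-free core**
(`linked_core_bp`, default 1.3 Mb, centred on the locus) guarantees a fully
linked region of known extent around the causal variant. Chromosomes assort
independently (Mendel's second law), so with zero recombination only the
causal *chromosome* cosegregates perfectly, not the whole genome.

Offspring are drawn by rejection until both pools are full; conditioning on
the maternal phase at the causal locus is exactly the phenotype-sorting of
the real cross.

## Sequencing model

Per library and site, total depth is Poisson(coverage) (default 25×,
matching the study's 23.9–25.2× per library) and each read is alternate with
probability `f(1−e) + (1−f)e`, where `f` is the true pool allele fraction
and `e` the per-read error rate (default 0.002). Genotype calls are
maximum-likelihood diploid calls from the depths — the same simplification a
small-cohort caller applies to a pool BAM — and a missingness rate (default
1%) blanks genotype and depths together. Site densities default to 2,000
informative variants/Mb (the density observed near the locus in the mapped
interval) plus 500 non-informative background variants/Mb; background sites
use per-site independent transmission (a linkage-equilibrium approximation —
they are removed by the informative filter and never reach the scan, so
their linkage structure is irrelevant downstream). QUAL values are drawn
with a small (~3%) low-quality tail so the quality filter is exercised.

What the generator does **not** model: read-level artifacts (mapping error,
strand bias, indel realism), repeat-driven mismapping (repeats are random
intervals, and variants are masked out rather than miscalled), linked-read
structure, segregation distortion, and pool construction noise beyond
binomial sampling. Passing tests therefore demonstrate the statistical
machinery, not robustness to alignment pathology.

## Filtering and the cosegregation call

`quality_filter` keeps biallelic SNP/MNPs with QUAL ≥ 20 and depth ≥ 10 in
every library, and drops any site with a missing genotype in any library
(cosegregation needs all four observations); indels are excluded from the
scan but forwarded to consequence annotation. `is_informative` requires the
father's alternate fraction ≥ 0.95 and the mothers pool inside [0.25, 0.75]
(a call-based mode trusts the VCF genotypes instead). All thresholds are
config knobs; the defaults are conventional, so the pipeline is a superset
of any particular threshold choice.

The per-variant cosegregation rule (`CosegThresholds`) is fraction-based by
default: **homozygous pool alternate fraction ≥ 0.90**, with pools under 10
reads yielding UNEVALUABLE rather than a negative call. Whether the
heterozygous pool must additionally sit inside [0.35, 0.65] is an open
design choice; the package implements both and defaults to the
**homozygous-pool-only** rule (`require="hom"`). The reason is arithmetic:
at 25× pool coverage the heterozygous pool's observed fraction has standard
deviation ≈ 0.10 around 0.5, so a truly linked site lands outside
[0.35, 0.65] with probability ≈ 0.11, and a run of 100 consecutive
cosegregating variants would survive with probability ≈ 0.89¹⁰⁰ ≈ 10⁻⁵ —
the run criterion would be unusable at exactly the coverage of the study.
The homozygous-pool rule fails on a linked site only through ≥ 3 sequencing
errors among its reads (≈ 2 × 10⁻⁵ per site) while still limiting unlinked
chance cosegregation to the percent level; the stricter two-pool rule
remains available (`require="both"`) and is what the exact-enumeration
chance-cosegregation analysis quantifies.

## Scan, runs and intervals

Windows are anchored at coordinate 0 per chromosome, half-open, 1 Mb wide
with a 100 kb step; terminal truncated windows are kept and flagged, and a
window with fewer than 10 informative variants has an undefined proportion.
Run detection collects maximal stretches of consecutive cosegregating
informative variants. UNEVALUABLE sites are skipped entirely so the run
criterion does not become depth-dependent. The library default tolerates no
interruptions; the pipeline default allows up to 2 isolated
non-cosegregating sites inside a run, because a fully linked region
thousands of variants long is expected to accrue a fraction of a single-site
break from sequencing error alone (≈ 2 × 10⁻⁵ per site), while an unlinked
region would need ~18 failures per 100 sites and can never bridge them.
Runs of ≥ 100 cosegregating variants become candidate intervals delimited by
their outermost variants (variant-delimited, not window-delimited), ranked
by run length, then density, then chromosome and coordinate for determinism.
Interval lengths are displayed in Mb rounded half-up to 2 decimals
(1,670,000–2,960,000 prints as 1.29 Mb); densities are always computed from
unrounded endpoints and rounded only for display.

On the default toy genome (five 10-Mb chromosomes) the called interval
extends well beyond the configured 1.3 Mb core: with only 12 homozygous-pool
meioses at 1 cM/Mb the expected distance from the core edge to the nearest
run-breaking crossover is ~8 Mb, so intervals typically reach the nearest
flanking breakpoints or the chromosome ends. The meaningful recovery
properties — the top interval contains the hidden locus, ≥ 100-variant runs
occur only on the causal chromosome, and the interval tracks the *realized*
breakpoint-bounded fully linked segment — are what the acceptance tests
check, at 100 seeded replicates in a few minutes of CPU.

## Consequence prediction

Gene models are 0-based half-open with genomic-order exons; reverse-strand
genes are transformed to transcript orientation before any exon arithmetic.
Splice windows default to the canonical 2 nt (GT donor / AG acceptor), so
the 13-nt deletion removing the last 6 exonic and first 7 intronic
nucleotides of an exon always classifies as a donor disruption with the
exonic/intronic bookkeeping summing to the deletion length. `skip_exon`
rebuilds the transcript without one exon and translates from the original
start codon, reading through into the 3′ UTR after a frameshift;
`retain_intron_prefix` splices the 5′ prefix of an intron (in transcript
orientation) into the mature transcript — the cryptic donor position is an
input, not a prediction. Frame preservation is purely the mod-3 criterion;
premature stops are detected against the frame-preserving length
expectation; the functional verdict (possibly functional iff frame preserved
and no premature stop) is an explicit heuristic, not a pathogenicity score.
UTR-exonic variants are reported INTRONIC (within-gene, no coding change);
in-frame coding insertions are reported NONSYNONYMOUS. Splice-strength
scoring, domain prediction and NMD are out of scope.

The synthetic gene builder reverse-translates a specified or generated
protein codon-by-codon with canonical GT..AG introns, so every expected
protein is known by construction; `make_pax7_like_gene` fixes the
architecture relevant to the worked example (five exons, 503-aa CDS, exon 4
= codons 151–195 exactly).

## Pedigree statistics

Genotype classes are allele pairs canonicalised with the wild-type allele
last. The segregation test is chi-square without continuity correction
(small-n default; an exact binomial option exists for two-class crosses);
classes with zero expectation and zero observation are dropped, and a
nonzero count in an impossible class is reported as a Mendelian violation
with no p-value. Amplicon genotyping maps PCR product lengths across a
known deletion to genotype classes and rejects unexpected lengths.

## Determinism and problem sizes

One pipeline seed drives named, independent RNG substreams (sites, meiosis,
depths, missingness, repeats) via hashed `SeedSequence` keys; identical
seeds give byte-identical VCF output and reports. The test suite runs the
recovery property at 100 replicates of the 50 Mb / ~125,000-variant default
configuration and the chance-cosegregation comparison at 10⁵ simulated
unlinked sites; both are vectorised and complete in a few minutes on one
CPU. These sizes are the package's desk-scale stand-in for the study's
2.2 Gb genome — chosen so the binomial structure of the problem (pool sizes
12 and 14, 25× coverage, 2,000 informative variants/Mb) is preserved
exactly while chromosome lengths are not.
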