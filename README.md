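# geckomap

Mapping-by-sequencing (bulked-segregant analysis) of a recessive color-morph
locus from a single pooled-offspring cross, with splice-consequence
annotation of candidate variants and a fully specified cross simulator.

## The problem

A recessive mutation (here, the *mss* allele behind a melanistic leopard-gecko
morph) can be localised without a genetic map by sequencing four genomic DNA
libraries from one cross of an affected male (*mss/mss*) with carrier females
(*mss/+*): the father, the pooled mothers, a pool of 12 homozygous offspring
and a pool of 14 heterozygous offspring (incomplete dominance makes
heterozygotes phenotypically sortable). The pipeline consumes the
variant-called VCF of those four libraries and

1. keeps **informative variants** — homozygous-alternate in the father,
   heterozygous in the mothers pool — outside repetitive elements,
2. calls per-variant **cosegregation**: near the causal locus the
   homozygous-offspring pool must look homozygous-alternate (alternate allele
   fraction `f_hom ≥ 0.90` of the pool reads; optionally the heterozygous
   pool must stay inside `0.35 ≤ f_het ≤ 0.65`),
3. scans each chromosome with a **1 Mb sliding window, 100 kb step**,
   reporting the proportion of informative variants that cosegregate,
4. detects **runs of ≥ 100 consecutive cosegregating variants** and reports
   each run as a candidate interval with its length and variant density.

Because the father always transmits the causal-line haplotype and the mothers
transmit it to homozygous offspring only when no crossover intervenes, the
cosegregation proportion decays with genetic distance from the locus
(Haldane: `r = (1 − e^(−2d))/2` for distance `d` in Morgans); for an unlinked
informative variant the chance that all 12 + 14 maternal transmissions line
up is only `P(K₁₂ ≥ 10)·P(K₁₄ ≤ 4) ≈ 1.7 × 10⁻³` (exact binomial
enumeration), so long runs pinpoint the locus.

A `consequence` module then annotates candidate variants against gene models
(splice-donor/acceptor disruption, in-frame deletion, frameshift,
synonymous/non-synonymous) and predicts isoform-level outcomes — single-exon
skipping and intron-prefix retention — with an explicit functional heuristic
(frame preserved and no premature stop). A `pedigree` module provides
genotype tallies, Mendelian expectations and chi-square/exact segregation
tests, plus genotyping from deletion-spanning PCR product lengths.

Everything downstream of read alignment and variant calling is in scope; BAM
and FASTQ handling are not.

## Worked example

Simulate a cross on a five-chromosome 50 Mb toy genome (hidden causal locus
at chr3:5,000,001; pools of 12 + 14; ~25× coverage; ~2,000 informative
variants/Mb) and scan it:

```bash
geckomap simulate --out-dir sim --seed 7
geckomap scan --vcf sim/sim.vcf --roles roles.yaml \
    --repeats sim/repeats.bed --layout sim/layout.tsv --out-prefix out/run
```

where `roles.yaml` maps the four VCF sample names to their roles
(`FATHER_HOM`, `MOTHERS_HET`, `POOL_HOM`, `POOL_HET`). The scan prints

```
top interval chr3:2242-8284346 (8.28 Mb, run of 14485)
```

i.e. the top candidate interval sits on the causal chromosome and contains
the hidden locus; `out/run.windows.tsv` holds the per-window cosegregation
proportions, `out/run.intervals.bed` the ranked candidate intervals and
`out/run.report.json` the per-stage variant counts. (On the toy genome the
interval is several Mb wide because it extends to the nearest maternal
crossovers flanking the locus; with more offspring or a longer chromosome it
tightens accordingly.)

The same machinery is available as a library:

```python
>>> from geckomap import mean_coverage, make_pax7_like_gene, skip_exon
>>> mean_coverage(174_000_000, 151, 2_200_000_000)   # read pairs, bp, genome
23.9
>>> iso = skip_exon(make_pax7_like_gene(), 3)        # skip exon 4
>>> iso.protein_length, iso.missing_residues, iso.frame_preserved
(458, (151, 195), True)
```

The second call reproduces the key splice analysis: skipping the exon whose
13-nt boundary deletion disrupts the canonical donor site shortens the
503-aa reference protein to 458 aa, cleanly deleting residues 151–195.

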