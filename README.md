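# triodnm

Trio-based detection of germline de novo single-nucleotide mutations
(DNMs), with callable-fraction-corrected mutation-rate estimation,
mutational-spectrum characterisation, panel-based validation and
multi-generation transmission tracing. The package targets researchers in
livestock and population genomics who have joint-called, genotype-refined
whole-genome sequence data for parent–offspring trios (e.g. commercial pig
breeding populations) and want direct estimates of the per-site per-gamete
mutation rate plus a characterisation of the new variants.

## The method

A candidate DNM is a biallelic SNV called heterozygous in a trio offspring
(the *proband*) while both parents are homozygous reference — a Mendelian
violation. Candidates must survive a three-stage filter cascade:

1. **Site quality** over the trio: min GQ ≥ 20, DP ∈ [10, 100],
   QD > 4.0, FS < 60.0, MQ > 40, MQRankSum > −2, ReadPosRankSum > −8.0
   (absent annotations never fail a site).
2. **Trio genotype test**: proband het with alt-read fraction > 20% and
   both parents hom-ref with zero alt-supporting reads, all within the
   same GQ/DP bounds.
3. **Population screen**: the alt allele is not detected in any other
   cohort member — except sibs sharing a parent with the proband and
   offspring of the proband, who may legitimately share a parental-mosaic
   mutation — and the cohort allele count stays below
   max(4, ⌈0.1% · n_samples⌉).

The mutation rate per trio is

```
μ̂ = n_DNM / (2 · L · p)
```

where `L` is the autosome length, `p` the callable proportion (the
fraction of cohort SNVs surviving the site-quality filters, a proxy for
the fraction of the genome actually interrogated) and the factor 2 makes
the rate per gamete. The cohort estimate pools numerators and denominators
over trios. Spectra are reported in the pyrimidine-centred six-class
(SBS96) convention, with the Ti/Tv ratio, the C>T/T>C ratio, and the CpG
fraction of C>T changes (spontaneous deamination of methylated CpG
cytosines elevates C>T).

Because real trio cohorts of this kind are proprietary, the package ships
a first-class synthetic cohort generator (`triodnm.synthetic_data`) that
plants germline DNMs at a configurable per-site per-gamete rate (count per
offspring ~ Poisson(2·L·μ)), renders binomial read counts with reference
bias and sequencing error, re-derives GT/GQ from the simulated reads, and
records every planted event in a truth table — so calling sensitivity,
rate recovery and spectrum round-trips are all testable.

## Worked example

Simulate a 38-trio cohort on a 2 Mb contig with DNMs planted at
μ = 10⁻⁷ (inflated so a small demo contig yields a handful of events),
then call, estimate and summarise:

```bash
triodnm simulate --out demo/sim --n-trios 38 --genome-length 2000000 \
    --mu 1e-7 --background-snp-density 1e-4 --seed 1
triodnm call     --vcf demo/sim/cohort.vcf --ped demo/sim/cohort.ped --out demo/call
triodnm rate     --candidates demo/call/candidates.tsv --ped demo/sim/cohort.ped \
    --fasta demo/sim/reference.fa --out demo/rate
triodnm spectrum --candidates demo/call/candidates.tsv \
    --fasta demo/sim/reference.fa --out demo/spec
triodnm report   --rates demo/rate/rates.tsv --spectrum demo/spec/spectrum.tsv \
    --out demo/summary.tsv
```

which prints

```
Number of DNM	17
Number of trios	38
Average number of DNM per proband	0.4
Mutation rate	1.1e-07
Minimum mutation rate	0.0e+00
Maximum mutation rate	7.5e-07
Ti/Tv	3.2
```

Seventeen planted mutations were recovered as candidates (the `call` stage
logged `230 sites read, 0 skipped, 17 candidate DNMs`; the remaining 213
sites are segregating background SNPs rejected as Mendelian-consistent).
The pooled rate 1.1×10⁻⁷ recovers the simulated μ = 10⁻⁷ within the
Poisson noise of 17 events; per-trio rates range from 0 (trios that drew
no mutation) to 7.5×10⁻⁷ (a trio with 3). The Ti/Tv of 3.2 reflects the
generator's default C>T-enriched spectrum. Every stage also writes a JSON
run manifest with input checksums and stage counts, and
`demo/call/ledger.tsv` records each evaluated site/proband pair with its
rejection reasons.

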