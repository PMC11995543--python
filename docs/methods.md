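# Methods

## Candidate DNM model

A de novo single-nucleotide mutation is modelled as a Mendelian violation:
the proband carries a heterozygous genotype at a biallelic SNV where both
parents are homozygous for the reference allele. Detection quality rests
on three independent screens, applied in order.

**Site quality.** The exclusion expression mirrors a GATK-style hard
filter: a site fails when min GQ < 20 or DP outside [10, 100] over the
trio members, or when QD ≤ 4.0, FS ≥ 60.0, MQ ≤ 40, MQRankSum ≤ −2 or
ReadPosRankSum ≤ −8.0. Two deliberate semantic choices:

- *Inequality directions are taken from the executable exclusion
  expression*, which is unambiguous, so boundary values (QD exactly 4.0,
  MQ exactly 40) fail.
- *Absent annotations never fail a site.* MQRankSum and ReadPosRankSum
  only exist where reads support both alleles in some sample; treating
  absence as 0 (or as failure) would silently bias the callable set.
  `SiteRecord` therefore stores them as `None`, not 0.
- *MIN/MAX semantics over GQ/DP apply to the three trio members only.*
  Candidate validity is a trio property; a cohort-wide minimum depth
  across ~100+ samples would discard essentially every site.

**Trio genotype test.** Proband het with alt-read fraction strictly above
0.20 (alt_reads / DP, clipped reads permitted so AD may sum below DP),
GQ ≥ 20 and DP ∈ [10, 100]; each parent hom-ref within the same bounds
and with zero alt-supporting reads in the AD field. A missing genotype in
any member is a recorded rejection reason, not an exception.

**Population screen.** The candidate allele must not be detected (het or
hom-alt call) in any cohort member other than the proband, sibs sharing
at least one parent with the proband, and offspring of the proband. The
exemption exists because a mosaic mutation in a parental germline can be
transmitted to more than one offspring of that parent; we extend it to
full sibs for the same biological reason, since a full sib is as able to
inherit a parental-mosaic variant as a half sib. An allele count at or
above max(4, ⌈0.001·n⌉) also fails (with the study-scale 135 samples the
cap is 4 either way; the ceiling makes the fractional term conservative
for larger cohorts). A stricter read-level screen — any unrelated sample
with more than `max_population_alt_reads` alt reads fails the site — is
available but off by default: at realistic per-read error rates the
probability that *some* unrelated sample among ~111 shows one spurious
alt-supporting read approaches 1, which would destroy sensitivity while
the genotype-level screen already rejects genuinely shared variants.

All thresholds live in `FilterThresholds`; tightening any single one can
only shrink the candidate set (a property the test suite checks), because
each rule is an independent conjunct.

## Rate estimation

The per-trio rate is `n_DNM / (2·L·p)` with `L` the autosome length read
from the FASTA index over a configurable contig list, and `p` the
callable proportion. The factor 2 converts the diploid genome to
per-gamete units: each offspring receives two gametes, each an
opportunity for mutation over `L·p` callable sites. `p` is a SNP-based
proxy — the fraction of cohort SNVs at which the trio's calls satisfy the
site-quality screen — standing in for the unobservable fraction of the
genome interrogated; it is computed per trio when per-trio pass counts
are available, else taken from the cohort. The cohort estimate pools
counts and denominators (`Σn / Σ2·L·p_i`) rather than averaging per-trio
ratios, so low-callability trios do not get inflated weight.

## Spectrum

Base changes collapse to the pyrimidine-centred six-class convention: a
purine reference is reverse-complemented together with its ±1 flanks, so
`G>A` in context `AGT` reads `A[C>T]T`. Collapsing is an involution under
complementation (checked exhaustively over the 12 ordered base pairs).
Ti/Tv is the count ratio (C>T + T>C) / (four transversion classes); a CpG
site is a collapsed C>* change whose downstream base is G. Ratios with a
zero denominator are reported as an explicit undefined sentinel (`None`),
never as infinity. Context classification uses ±1 bp from the reference
FASTA; sites at a contig edge carry an unavailable context and still
contribute to class counts.

## Statistical tests

The three comparison procedures used in the analysis are implemented from
their formulas: a pooled two-proportion z test (no continuity
correction), Welch's unequal-variance t test with Welch–Satterthwaite
degrees of freedom, and a one-sample t test. All are two-sided and report
raw p-values. Degenerate inputs (pooled proportion 0 or 1, zero
variance) yield an undefined result or a validation error rather than a
division failure. scipy's `ttest_ind`/`ttest_1samp` serve as independent
oracles in the tests, never as the implementation. Under the null each
test's rejection rate at α = 0.05 is calibrated to within Monte-Carlo
error over 2000 simulations.

## Validation and transmission

Panel genotyping of the trio plus up to nine offspring of the proband
maps each candidate to exactly one class: **germline** (proband carrier,
parents clean, ≥ 1 offspring carrier), **possible somatic** (proband
carrier, parents clean, ≥ 2 informative offspring all non-carrier — a het
germline variant escapes transmission to k offspring with probability
0.5^k, so repeated non-transmission is evidence the variant is absent
from the germline), **not validated** (non-carrier proband, or a carrier
parent, which means inherited rather than de novo, regardless of
offspring), **assay failed** (proband assay failure), else
**inconclusive**. Failed offspring assays are excluded from the
informative count.

Transmission tracing assigns generation 1 to the proband and generation
g+1 to offspring of generation-g individuals (minimum depth over paths).
A DNM is *lost* at the first generation whose genotyped members include
no carrier; generations with no genotyped members end the trace without
declaring loss, and a carrier observed outside the proband's descendant
set raises a lineage-inconsistency error.

QC helpers compute chip-vs-WGS heterozygote concordance (missing WGS
calls excluded from the denominator and counted) and per-genotype-class
removal fractions of the filter cascade.

## Synthetic cohort generator

The generator is the package's study stand-in, with defaults fixed at the
study conditions: 38 trios (the analysed cohort), mean depth 32.4,
reference bias 0.025 so the expected het alt-read fraction is 0.475,
background SNP density 0.0114 per base (the cohort SNP count over a
2.26 Gb autosome), sequencing error 10⁻³ per read, and a spectrum solved
from Ti/Tv = 3.2 with C>T/T>C = 4.4 and the four transversion classes
split evenly (per-class transversion proportions are not printed
anywhere, and the even split is the least-informative choice consistent
with the two published ratios); 35% of C>T events are placed at CpG
sites. The default contig is a single 1 Mb linear chromosome `chrS1` —
a scaled-down genome that keeps a default run interactive while leaving
per-site behaviour identical; the acceptance script uses 50 Mb.

Truth generation: per offspring, a Poisson(2·L·μ) number of germline
DNMs at globally unique positions with class, strand, flanks and parental
origin drawn per event; optional mosaic events with a configurable
expected alt fraction; background variants with founder genotypes in
Hardy–Weinberg proportions at Uniform(0.05, 0.95) allele frequency,
transmitted Mendelianly to probands.

Rendering: per sample per site, depth ~ Poisson(depth_mean) with a floor
of 1; alt reads ~ Binomial(depth, f) with f = 0.5 − bias at het sites,
the error rate at hom-ref, its complement at hom-alt and the mosaic
fraction at mosaic sites. GT and GQ are then *re-derived* from the
simulated reads by maximum likelihood under a binomial read model with a
1e-4 error floor and flat priors, GQ capped at 99 — enough to exercise
the GQ thresholds without reimplementing a full genotype-refinement
workflow, and the route by which genotyping errors arise naturally at
low depth. Site INFO fields are drawn from pass-region distributions
(clipped at the filter boundaries) with an optional per-site probability
of drawing one field from the fail region; all values are rounded to 4
decimals so a VCF write/read round trip is exact despite htslib's float32
INFO storage.

What the generator does **not** emulate: alignment and mapping artefacts
(the dominant real-world source of false candidates), indels and
multi-nucleotide variants, linkage between background SNPs, shared
parents across trios, recombination, and chip genotyping. Passing tests
therefore demonstrate the correctness of the filter logic, estimators and
classifications under the stated generative model — not the end-to-end
error profile of a real resequencing study.

## Problem sizes and numerical choices

The test suite runs cohorts of 3–10 trios on 50 kb–2 Mb contigs and
completes in well under a minute; the acceptance script uses 200
replicates of 38 trios on 50 Mb, a scale at which the Monte-Carlo SE of
the mean rate estimate is ~1.5% of the target and the whole computation
takes seconds, because only variant sites are materialised. Rate
recovery is asserted within 3 Monte-Carlo SE; spectrum round-trips
within 3–4 multinomial SE at the generated sample size. Reported ratios
use an undefined sentinel at zero denominators; per-proband means are
reported to one decimal; rates print in scientific notation with two
significant digits. Ledger output is deterministically ordered by
(chrom, pos, proband), and identical configuration plus seed reproduces
byte-identical TSVs.

## Known limitations

- The callable-proportion proxy inherits the ascertainment of the cohort
  SNP set; regions with no segregating SNPs contribute no information.
- The alt-fraction filter at 20% removes ~0.3% of true het calls at
  depth 30 (binomial tail), a small but real downward bias the estimator
  does not correct.
- The population screen cannot distinguish a recurrent true mutation in
  two unrelated probands from shared artefact; both are rejected.
- The strict read-level population screen is provided for completeness
  but is unusable at realistic error rates (see above).
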