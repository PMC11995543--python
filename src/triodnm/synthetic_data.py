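"""Synthetic trio-cohort generator with a known truth ledger.

Emulates the study design: a cohort of sequenced trios at ~30X short-read
depth, germline DNMs planted at a per-site per-gamete rate ``mu`` (count
per offspring ~ Poisson(2 * L * mu)), a C>T-enriched mutational spectrum
with CpG enrichment, heterozygous alt-read fractions centred slightly
below 0.5 (reference mapping bias), segregating background SNPs in
Hardy-Weinberg proportions among founders, and optional low-fraction
mosaic variants. Every planted event is recorded in a :class:`TruthTable`
so the caller, rate estimator and spectrum summariser can be scored
against ground truth.

Default parameter values are the study conditions: 38 analysed trios,
mean depth 32.4, reference bias 0.025 (mean het alt fraction 0.475), a
spectrum solved from Ti/Tv = 3.2 with 4.4x more C>T than T>C and
transversions split evenly, 35% of C>T at CpG sites, and a background SNP
density of 0.0114 per base (the cohort SNP count over the autosome size).

All randomness flows from one ``numpy`` generator seeded by
``config.seed``; the stream order is: pedigree-independent truth first
(per-proband DNM counts, positions, classes, strands, flanks, parental
origin, then mosaic events, then background variants), then rendering
(per site: depth, alt reads, INFO fields, in sample order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Individual,
    Pedigree,
    SampleCall,
    SiteRecord,
    write_fasta,
    write_ped,
    write_vcf,
)
from .spectrum import BASES, CLASSES, complement

GERMLINE_DNM = "germline_dnm"
MOSAIC = "mosaic"
BACKGROUND = "background"

_PYR = ("C", "T")

# six-class spectrum consistent with Ti/Tv = 3.2 and C>T/T>C = 4.4,
# transversions split evenly
_TI_FRAC = 3.2 / 4.2
DEFAULT_SPECTRUM = {
    "C>T": 4.4 * _TI_FRAC / 5.4,
    "T>C": _TI_FRAC / 5.4,
    "C>A": (1 - _TI_FRAC) / 4,
    "C>G": (1 - _TI_FRAC) / 4,
    "T>A": (1 - _TI_FRAC) / 4,
    "T>G": (1 - _TI_FRAC) / 4,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_trios: int = 38
    genome_length: int = 1_000_000
    chrom: str = "chrS1"
    mu: float = 6.3e-9
    background_snp_density: float = 0.0114
    depth_mean: float = 32.4
    depth_floor: int = 1
    seq_error_rate: float = 1e-3
    reference_bias: float = 0.025
    spectrum_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    cpg_fraction_of_ct: float = 0.35
    mosaic_rate: float = 0.0
    mosaic_fraction: float = 0.1
    info_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.n_trios < 1:
            raise ValueError("need at least one trio")
        for name in ("mu", "background_snp_density", "seq_error_rate",
                     "mosaic_rate", "info_fail_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.reference_bias < 0.5:
            raise ValueError("reference_bias must be in [0, 0.5)")
        if not 0 <= self.cpg_fraction_of_ct <= 1:
            raise ValueError("cpg_fraction_of_ct must be in [0, 1]")
        w = sum(self.spectrum_weights.get(c, 0.0) for c in CLASSES)
        if not math.isclose(w, 1.0, abs_tol=1e-6):
            raise ValueError("spectrum_weights must sum to 1 over the six classes")


@dataclass(frozen=True)
class TruthEvent:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # germline_dnm | mosaic
    trio_id: str
    proband_id: str
    parent_of_origin: str  # "sire" | "dam" | "" for mosaic
    true_alt_fraction: float
    upstream: str
    downstream: str


@dataclass(frozen=True)
class BackgroundVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_freq: float
    genotypes: Mapping[str, str]  # sample id -> genotype label


@dataclass
class TruthTable:
    events: list[TruthEvent]
    background: list[BackgroundVariant]
    pedigree: Pedigree
    config: SimulationConfig

    def germline_positions(self) -> set[tuple[str, int, str]]:
        """(chrom, pos, proband) keys of planted germline DNMs."""
        return {
            (e.chrom, e.pos, e.proband_id)
            for e in self.events
            if e.kind == GERMLINE_DNM
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": e.chrom,
                "pos": e.pos,
                "ref": e.ref,
                "alt": e.alt,
                "kind": e.kind,
                "trio_id": e.trio_id,
                "proband_id": e.proband_id,
                "parent_of_origin": e.parent_of_origin,
                "true_alt_fraction": e.true_alt_fraction,
            }
            for e in self.events
        ]
        rows += [
            {
                "chrom": b.chrom,
                "pos": b.pos,
                "ref": b.ref,
                "alt": b.alt,
                "kind": BACKGROUND,
                "trio_id": "",
                "proband_id": "",
                "parent_of_origin": "",
                "true_alt_fraction": float("nan"),
            }
            for b in self.background
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "ref", "alt", "kind", "trio_id",
                "proband_id", "parent_of_origin", "true_alt_fraction",
            ],
        )


def make_pedigree(n_trios: int) -> Pedigree:
    inds = []
    for i in range(1, n_trios + 1):
        s, d, p = f"S{i:03d}", f"D{i:03d}", f"P{i:03d}"
        inds.append(Individual(id=s, sire=None, dam=None, sex="1"))
        inds.append(Individual(id=d, sire=None, dam=None, sex="2"))
        inds.append(Individual(id=p, sire=s, dam=d, sex="1"))
    return Pedigree(inds)


def sample_order(ped: Pedigree) -> list[str]:
    return sorted(ped.individuals)


def _draw_class(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    classes = list(CLASSES)
    p = np.array([weights.get(c, 0.0) for c in classes])
    return classes[rng.choice(len(classes), p=p / p.sum())]


def _draw_event_site(
    rng: np.random.Generator, cfg: SimulationConfig, used: set[int]
) -> tuple[int, str, str, str, str]:
    """Sample position, strand-resolved ref/alt and flanks for one planted
    event according to the spectrum weights."""
    cls = _draw_class(rng, cfg.spectrum_weights)
    ref_pyr, alt_pyr = cls.split(">")
    up = BASES[rng.integers(4)]
    if ref_pyr == "C" and rng.random() < (
        cfg.cpg_fraction_of_ct if cls == "C>T" else 0.25
    ):
        down = "G"
    else:
        # downstream conditional on not-G for C>* classes with prob 3/4 each
        choices = [b for b in BASES if not (ref_pyr == "C" and b == "G")]
        down = choices[rng.integers(len(choices))] if ref_pyr == "C" else BASES[rng.integers(4)]
    ref, alt = ref_pyr, alt_pyr
    if rng.random() < 0.5:  # place the pyrimidine on the minus strand
        ref, alt = complement(ref), complement(alt)
        up, down = complement(down), complement(up)
    while True:
        pos = int(rng.integers(2, cfg.genome_length))  # 1-based, away from edges
        if pos not in used:
            used.add(pos)
            return pos, ref, alt, up, down


def simulate_truth(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthTable:
    """Plant germline DNMs, mosaic variants and background SNPs.

    Germline counts per offspring are Poisson(2 * L * mu); planted
    positions are unique genome-wide so every variant site is biallelic.
    Background founder genotypes are Hardy-Weinberg draws at a uniform
    allele frequency, transmitted Mendelianly to probands.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ped = make_pedigree(config.n_trios)
    used: set[int] = set()
    events: list[TruthEvent] = []
    lam = 2.0 * config.genome_length * config.mu
    for trio in ped.trios():
        n_dnm = rng.poisson(lam)
        for _ in range(n_dnm):
            pos, ref, alt, up, down = _draw_event_site(rng, config, used)
            origin = "sire" if rng.random() < 0.5 else "dam"
            events.append(
                TruthEvent(
                    chrom=config.chrom, pos=pos, ref=ref, alt=alt,
                    kind=GERMLINE_DNM, trio_id=trio.id,
                    proband_id=trio.proband, parent_of_origin=origin,
                    true_alt_fraction=0.5, upstream=up, downstream=down,
                )
            )
        n_mosaic = rng.poisson(config.mosaic_rate)
        for _ in range(n_mosaic):
            pos, ref, alt, up, down = _draw_event_site(rng, config, used)
            events.append(
                TruthEvent(
                    chrom=config.chrom, pos=pos, ref=ref, alt=alt,
                    kind=MOSAIC, trio_id=trio.id, proband_id=trio.proband,
                    parent_of_origin="",
                    true_alt_fraction=config.mosaic_fraction,
                    upstream=up, downstream=down,
                )
            )
    background: list[BackgroundVariant] = []
    n_bg = rng.poisson(config.genome_length * config.background_snp_density)
    order = sample_order(ped)
    for _ in range(n_bg):
        while True:
            pos = int(rng.integers(2, config.genome_length))
            if pos not in used:
                used.add(pos)
                break
        ref = BASES[rng.integers(4)]
        alt = rng.choice([b for b in BASES if b != ref])
        q = rng.uniform(0.05, 0.95)
        genotypes: dict[str, str] = {}
        for trio in ped.trios():
            for founder in (trio.sire, trio.dam):
                n_alt = rng.binomial(2, q)
                genotypes[founder] = (HOM_REF, HET, HOM_ALT)[n_alt]
            transmitted = 0
            for parent in (trio.sire, trio.dam):
                g = genotypes[parent]
                if g == HOM_ALT:
                    transmitted += 1
                elif g == HET and rng.random() < 0.5:
                    transmitted += 1
            genotypes[trio.proband] = (HOM_REF, HET, HOM_ALT)[transmitted]
        background.append(
            BackgroundVariant(
                chrom=config.chrom, pos=pos, ref=ref, alt=str(alt),
                allele_freq=q, genotypes=genotypes,
            )
        )
    return TruthTable(
        events=events, background=background, pedigree=ped, config=config
    )


# ---------------------------------------------------------------------------
# Rendering truth into observed calls

def _genotype_and_gq(
    alt: np.ndarray, dp: np.ndarray, error: float
) -> tuple[list[str], np.ndarray]:
    """GATK-style genotype assignment from read counts: maximum-likelihood
    genotype under a binomial read model with flat priors, GQ as the Phred
    probability the call is wrong, capped at 99."""
    e = max(error, 1e-4)
    probs = np.array([e, 0.5, 1.0 - e])
    with np.errstate(divide="ignore"):
        ll = np.stack(
            [sps.binom.logpmf(alt, dp, p) for p in probs]
        )  # 3 x n
    ll = np.where(np.isfinite(ll), ll, -1e30)
    best = ll.argmax(axis=0)
    lmax = ll.max(axis=0)
    post = np.exp(ll - lmax)
    post /= post.sum(axis=0)
    perr = np.clip(1.0 - post[best, np.arange(len(best))], 1e-10, 1.0)
    gq = np.minimum(99.0, np.floor(-10.0 * np.log10(perr)))
    labels = [(HOM_REF, HET, HOM_ALT)[b] for b in best]
    return labels, gq


def _info_fields(
    rng: np.random.Generator, cfg: SimulationConfig
) -> dict[str, float]:
    """Site INFO annotations drawn from pass-region distributions, with an
    optional per-site chance of one field drawn from the fail region."""
    info = {
        "qd": round(max(4.5, rng.normal(25.0, 5.0)), 4),
        "fs": round(min(59.0, rng.exponential(5.0)), 4),
        "mq": round(max(40.1, rng.normal(60.0, 3.0)), 4),
        "mq_rank_sum": round(max(-1.9, rng.normal(0.0, 0.8)), 4),
        "read_pos_rank_sum": round(max(-7.9, rng.normal(0.0, 2.0)), 4),
    }
    if cfg.info_fail_rate > 0 and rng.random() < cfg.info_fail_rate:
        which = rng.integers(5)
        fail = {
            0: ("qd", round(rng.uniform(0.0, 4.0), 4)),
            1: ("fs", round(rng.uniform(60.0, 200.0), 4)),
            2: ("mq", round(rng.uniform(10.0, 40.0), 4)),
            3: ("mq_rank_sum", round(rng.uniform(-6.0, -2.0), 4)),
            4: ("read_pos_rank_sum", round(rng.uniform(-20.0, -8.0), 4)),
        }[int(which)]
        info[fail[0]] = fail[1]
    return info


def render_observations(
    truth: TruthTable, rng: np.random.Generator | None = None
) -> tuple[list[SiteRecord], list[str]]:
    """Render the truth into observed per-sample calls at every variant site.

    Per sample per site: depth ~ Poisson(depth_mean) floored; alt reads ~
    Binomial(depth, f) with f = 0.5 - reference_bias at het sites,
    seq_error_rate at hom-ref, 1 - seq_error_rate at hom-alt, and
    mosaic_fraction at mosaic sites. GT/GQ are re-derived from the
    simulated reads, so genotyping errors arise naturally at low depth or
    skewed draws.
    """
    cfg = truth.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ped = truth.pedigree
    samples = sample_order(ped)
    n = len(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    het_f = 0.5 - cfg.reference_bias

    # (pos, ref, alt, {sample: (true genotype, alt fraction)})
    sites: list[tuple[int, str, str, dict[str, tuple[str, float]]]] = []
    for ev in truth.events:
        carriers = {
            ev.proband_id: (
                (HET, het_f) if ev.kind == GERMLINE_DNM
                else (HET, ev.true_alt_fraction)
            )
        }
        sites.append((ev.pos, ev.ref, ev.alt, carriers))
    for bv in truth.background:
        carriers = {
            s: (g, het_f if g == HET else (1.0 - cfg.seq_error_rate))
            for s, g in bv.genotypes.items()
            if g != HOM_REF
        }
        sites.append((bv.pos, bv.ref, bv.alt, carriers))
    sites.sort(key=lambda s: s[0])

    records: list[SiteRecord] = []
    for pos, ref, alt, carriers in sites:
        dp = np.maximum(
            rng.poisson(cfg.depth_mean, size=n), cfg.depth_floor
        )
        f = np.full(n, cfg.seq_error_rate)
        for sid, (_g, frac) in carriers.items():
            f[sample_idx[sid]] = frac
        alt_reads = rng.binomial(dp, f)
        ref_reads = dp - alt_reads
        labels, gq = _genotype_and_gq(alt_reads, dp, cfg.seq_error_rate)
        calls = {}
        ac = 0
        for i, sid in enumerate(samples):
            geno = labels[i] if dp[i] > 0 else MISSING
            ac += {HET: 1, HOM_ALT: 2}.get(geno, 0)
            calls[sid] = SampleCall(
                sample_id=sid,
                genotype=geno,
                ref_reads=int(ref_reads[i]),
                alt_reads=int(alt_reads[i]),
                depth=int(dp[i]),
                genotype_quality=float(gq[i]),
            )
        info = _info_fields(rng, cfg)
        records.append(
            SiteRecord(
                chrom=cfg.chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                allele_count=ac, calls=calls, **info,
            )
        )
    return records, samples


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SiteRecord], list[str], TruthTable]:
    """Truth generation plus rendering with a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    records, samples = render_observations(truth, rng)
    return records, samples, truth


def build_reference(
    truth: TruthTable, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Materialise a reference sequence consistent with the planted events
    (random bases elsewhere). Intended for small genomes; memory is O(L)."""
    cfg = truth.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    seq = rng.integers(0, 4, size=cfg.genome_length)
    arr = np.array(list("ACGT"))[seq]
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for ev in truth.events:
        arr[ev.pos - 1] = ev.ref
        if ev.pos - 2 >= 0:
            arr[ev.pos - 2] = ev.upstream
        if ev.pos < cfg.genome_length:
            arr[ev.pos] = ev.downstream
    for bv in truth.background:
        arr[bv.pos - 1] = bv.ref
    return {cfg.chrom: "".join(arr)}


#: genomic distribution of DNM consequences emulated by the fabricated
#: annotation table: predominantly intronic/intergenic with a small coding
#: tail
DEFAULT_CONSEQUENCES = {
    "intron_variant": 0.47,
    "intergenic_variant": 0.49,
    "missense_variant": 0.015,
    "synonymous_variant": 0.01,
    "splice_donor_variant": 0.005,
    "stop_gained": 0.005,
    "upstream_gene_variant": 0.005,
}


def fabricate_annotations(
    truth: TruthTable,
    rng: np.random.Generator | None = None,
    consequence_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fabricate a pCADD/VEP/SIFT annotation table for the planted events.

    Coding consequences receive higher pCADD scores (missense centred near
    20, i.e. the ~1% most deleterious tier) and a chance of a SIFT
    'deleterious' label; non-coding events draw from a low-score
    exponential. This emulates the joined annotation input, not any real
    predictor.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.config.seed + 3)
    weights = dict(consequence_weights or DEFAULT_CONSEQUENCES)
    terms = list(weights)
    p = np.array([weights[t] for t in terms])
    p = p / p.sum()
    rows = []
    for i, ev in enumerate(truth.events):
        term = terms[rng.choice(len(terms), p=p)]
        if term in ("missense_variant", "stop_gained", "splice_donor_variant"):
            score = round(max(0.0, rng.normal(20.0, 5.0)), 2)
            sift = "deleterious" if rng.random() < 0.5 else "tolerated"
            gene = f"GENE{i:04d}"
        elif term == "synonymous_variant":
            score = round(rng.exponential(5.0), 2)
            sift = "tolerated"
            gene = f"GENE{i:04d}"
        else:
            score = round(rng.exponential(3.0), 2)
            sift = "absent"
            gene = ""
        rows.append(
            {
                "chrom": ev.chrom, "pos": ev.pos, "ref": ev.ref,
                "alt": ev.alt, "pcadd": score, "consequence": term,
                "sift": sift, "gene": gene,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "pcadd", "consequence",
                 "sift", "gene"],
    )


def emit_cohort(
    records: Sequence[SiteRecord],
    samples: Sequence[str],
    truth: TruthTable,
    outdir: str | Path,
    with_fasta: bool = True,
) -> dict[str, Path]:
    """Write VCF + PED + truth TSV (+ FASTA) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "truth": outdir / "truth.tsv",
        "annotations": outdir / "annotations.tsv",
    }
    fabricate_annotations(truth).to_csv(
        paths["annotations"], sep="\t", index=False
    )
    write_vcf(
        records, samples, paths["vcf"],
        contig_lengths={cfg.chrom: cfg.genome_length},
    )
    write_ped(truth.pedigree, paths["ped"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    if with_fasta:
        paths["fasta"] = outdir / "reference.fa"
        write_fasta(build_reference(truth), paths["fasta"])
    return paths
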