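"""Callable-fraction correction and germline mutation-rate estimation.

The per-trio rate is

    mu_hat = n_DNM / (2 * L * p)

where ``L`` is the autosome length, ``p`` the callable proportion (the
fraction of cohort SNPs surviving the site-quality filters — a proxy for
the fraction of the genome actually interrogated), and the factor 2
converts the diploid count to a per-gamete rate. The cohort rate pools
numerators and denominators across trios rather than averaging per-trio
rates, so trios with poorer callability carry proportionally less weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from pyfaidx import Fasta

from .dnm_calling import FilterThresholds, site_quality_pass
from .io_model import SiteRecord, Trio


@dataclass(frozen=True)
class CallableStats:
    n_total_snps: int
    n_pass_snps: int

    def __post_init__(self) -> None:
        if self.n_total_snps <= 0:
            raise ValueError("n_total_snps must be positive")
        if not 0 <= self.n_pass_snps <= self.n_total_snps:
            raise ValueError("n_pass_snps must be in [0, n_total_snps]")

    @property
    def proportion(self) -> float:
        return self.n_pass_snps / self.n_total_snps


@dataclass(frozen=True)
class RateEstimate:
    trio_id: str  # "cohort" for the pooled estimate
    n_dnm: float
    autosome_length: float
    callable_proportion: float
    rate: float


def callable_proportion(n_total: int, n_pass: int) -> CallableStats:
    """Pass fraction of assessed SNPs (the genome-investigated proxy)."""
    return CallableStats(n_total_snps=n_total, n_pass_snps=n_pass)


def callable_stats_for_trio(
    records: Iterable[SiteRecord],
    trio: Trio,
    thresholds: FilterThresholds | None = None,
) -> CallableStats:
    """Per-trio callable stats: fraction of cohort SNV sites at which this
    trio's calls satisfy the site-quality expression."""
    t = thresholds or FilterThresholds()
    n_total = n_pass = 0
    for rec in records:
        n_total += 1
        calls = tuple(rec.calls[m] for m in trio.members)
        ok, _ = site_quality_pass(rec, calls, t)
        if ok:
            n_pass += 1
    if n_total == 0:
        raise ValueError("no SNV sites to assess callability from")
    return CallableStats(n_total_snps=n_total, n_pass_snps=n_pass)


def per_trio_rate(
    n_dnm: float,
    autosome_length: float,
    proportion: float,
    trio_id: str = "trio",
) -> RateEstimate:
    """Per-site per-gamete rate for one trio."""
    if autosome_length <= 0:
        raise ValueError("autosome_length must be positive")
    if not 0 < proportion <= 1:
        raise ValueError("callable proportion must be in (0, 1]")
    if n_dnm < 0:
        raise ValueError("n_dnm must be non-negative")
    rate = n_dnm / (2.0 * autosome_length * proportion)
    return RateEstimate(
        trio_id=trio_id,
        n_dnm=n_dnm,
        autosome_length=autosome_length,
        callable_proportion=proportion,
        rate=rate,
    )


def cohort_rate(
    estimates: Sequence[RateEstimate],
) -> tuple[RateEstimate, float, float]:
    """Pooled cohort rate plus the min and max per-trio rates."""
    if not estimates:
        raise ValueError("need at least one per-trio estimate")
    num = sum(e.n_dnm for e in estimates)
    denom = sum(
        2.0 * e.autosome_length * e.callable_proportion for e in estimates
    )
    rates = [e.rate for e in estimates]
    pooled = RateEstimate(
        trio_id="cohort",
        n_dnm=num,
        autosome_length=sum(e.autosome_length for e in estimates) / len(estimates),
        callable_proportion=denom / (2.0 * sum(e.autosome_length for e in estimates)),
        rate=num / denom,
    )
    return pooled, min(rates), max(rates)


def mean_dnm_per_proband(n_dnm_total: float, n_trios: int) -> float:
    """Average DNM count per proband, reported to one decimal."""
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    return round(n_dnm_total / n_trios, 1)


def cohort_summary(
    estimates: Sequence[RateEstimate], titv_ratio: float | None = None
) -> dict:
    """Headline cohort block: DNM and trio counts, mean per proband,
    pooled rate and its per-trio range, optional Ti/Tv."""
    pooled, lo, hi = cohort_rate(estimates)
    return {
        "n_dnm": pooled.n_dnm,
        "n_trios": len(estimates),
        "mean_dnm_per_proband": mean_dnm_per_proband(
            pooled.n_dnm, len(estimates)
        ),
        "mutation_rate": pooled.rate,
        "min_mutation_rate": lo,
        "max_mutation_rate": hi,
        "titv_ratio": titv_ratio,
    }


def autosome_length_from_fasta(
    fasta_path: str, autosomes: Sequence[str] | None = None
) -> int:
    """Total length of the configured autosomes, read from the FASTA index
    (never hardcoded)."""
    fa = Fasta(str(fasta_path))
    names = list(autosomes) if autosomes is not None else list(fa.keys())
    missing = [n for n in names if n not in fa]
    if missing:
        raise ValueError(f"contigs absent from FASTA: {missing}")
    return sum(len(fa[n]) for n in names)
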