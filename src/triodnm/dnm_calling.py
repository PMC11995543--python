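"""Candidate de novo mutation calling: the trio filter cascade.

A candidate DNM is a biallelic SNV called heterozygous in a trio offspring
(the proband) with both parents homozygous reference, that survives three
screens applied in order:

1. **Site quality** — the GATK-style exclusion expression evaluated over
   the trio: fail if min GQ < 20, min DP < 10, max DP > 100, QD <= 4.0,
   FS >= 60.0, MQ <= 40, MQRankSum <= -2 or ReadPosRankSum <= -8.0.
   Absent annotations never trigger a failure (rank sums are legitimately
   missing at sites without het reference-supporting reads).
2. **Trio genotype test** — proband het with alt-read fraction strictly
   above 20%, GQ >= 20 and DP in [10, 100]; both parents hom-ref with the
   same GQ/DP bounds and zero alt reads.
3. **Population screen** — the alt allele is absent from every other cohort
   sample except sibs sharing a parent with the proband and offspring of
   the proband, and the cohort allele count stays below
   ``max(4, ceil(0.001 * n_samples))``.

Per-sample MIN/MAX semantics apply over the three trio members only: a
candidate's validity is a trio property, and a cohort-wide minimum would
discard nearly every site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Pedigree,
    SampleCall,
    SiteRecord,
    Trio,
    derive_relatives,
)

# reason codes
R_GQ = "gq"
R_DP = "dp"
R_QD = "qd"
R_FS = "fs"
R_MQ = "mq"
R_MQRS = "mq_rank_sum"
R_RPRS = "read_pos_rank_sum"
R_GENOTYPE = "genotype_config"
R_MISSING = "missing_genotype"
R_ALT_FRACTION = "alt_fraction"
R_PARENT_ALT = "parent_alt_reads"
R_AC = "allele_count_cap"
R_POPULATION = "population_sharing"


@dataclass(frozen=True)
class FilterThresholds:
    """All tunable cut-offs of the cascade, defaulting to the study values."""

    min_gq: float = 20.0
    min_dp: int = 10
    max_dp: int = 100
    min_qd: float = 4.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_mq_rank_sum: float = -2.0
    min_read_pos_rank_sum: float = -8.0
    min_proband_alt_fraction: float = 0.20
    max_parent_alt_reads: int = 0
    ac_cap_floor: int = 4
    ac_cap_sample_frac: float = 0.001
    #: when set, an unrelated sample with more than this many alt reads
    #: fails the population screen even without a variant call; None keeps
    #: the screen at the genotype-call level ("detected in" the population)
    max_population_alt_reads: int | None = None

    def __post_init__(self) -> None:
        if self.min_dp >= self.max_dp:
            raise ValueError("min_dp must be < max_dp")
        if not 0.0 <= self.min_proband_alt_fraction <= 1.0:
            raise ValueError("min_proband_alt_fraction must be in [0, 1]")

    def ac_cap(self, n_samples: int) -> int:
        return max(self.ac_cap_floor, math.ceil(self.ac_cap_sample_frac * n_samples))


@dataclass(frozen=True)
class CandidateDNM:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    proband_id: str
    trio_id: str
    proband_alt_fraction: float
    status: str  # "candidate" | "rejected"
    reason_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if (self.status == "candidate") != (not self.reason_codes):
            raise ValueError("status 'candidate' iff reason_codes empty")


def site_quality_pass(
    record: SiteRecord,
    trio_calls: Sequence[SampleCall],
    thresholds: FilterThresholds,
) -> tuple[bool, set[str]]:
    """Evaluate the site-level exclusion expression over the trio members."""
    t = thresholds
    reasons: set[str] = set()
    gqs = [c.genotype_quality for c in trio_calls]
    dps = [c.depth for c in trio_calls]
    if gqs and min(gqs) < t.min_gq:
        reasons.add(R_GQ)
    if dps and (min(dps) < t.min_dp or max(dps) > t.max_dp):
        reasons.add(R_DP)
    if record.qd is not None and record.qd <= t.min_qd:
        reasons.add(R_QD)
    if record.fs is not None and record.fs >= t.max_fs:
        reasons.add(R_FS)
    if record.mq is not None and record.mq <= t.min_mq:
        reasons.add(R_MQ)
    if record.mq_rank_sum is not None and record.mq_rank_sum <= t.min_mq_rank_sum:
        reasons.add(R_MQRS)
    if (
        record.read_pos_rank_sum is not None
        and record.read_pos_rank_sum <= t.min_read_pos_rank_sum
    ):
        reasons.add(R_RPRS)
    return not reasons, reasons


def _member_qc(call: SampleCall, t: FilterThresholds) -> set[str]:
    reasons: set[str] = set()
    if call.genotype_quality < t.min_gq:
        reasons.add(R_GQ)
    if not t.min_dp <= call.depth <= t.max_dp:
        reasons.add(R_DP)
    return reasons


def trio_genotype_test(
    proband: SampleCall,
    sire: SampleCall,
    dam: SampleCall,
    thresholds: FilterThresholds,
) -> tuple[bool, set[str]]:
    """The Mendelian-violation configuration plus per-member QC.

    Passes iff the proband is het with sufficient alt support and both
    parents are hom-ref with no alt reads, all three within GQ/DP bounds.
    A missing genotype in any member is a failure reason, not an exception.
    """
    t = thresholds
    reasons: set[str] = set()
    if MISSING in (proband.genotype, sire.genotype, dam.genotype):
        reasons.add(R_MISSING)
        return False, reasons
    if proband.genotype != HET or sire.genotype != HOM_REF or dam.genotype != HOM_REF:
        reasons.add(R_GENOTYPE)
    reasons |= _member_qc(proband, t)
    if proband.alt_fraction <= t.min_proband_alt_fraction:
        reasons.add(R_ALT_FRACTION)
    for parent in (sire, dam):
        reasons |= _member_qc(parent, t)
        if parent.alt_reads > t.max_parent_alt_reads:
            reasons.add(R_PARENT_ALT)
    return not reasons, reasons


def population_screen(
    record: SiteRecord,
    proband_id: str,
    ped: Pedigree,
    n_samples: int,
    thresholds: FilterThresholds,
) -> tuple[bool, set[str]]:
    """Uniqueness of the alt allele in the cohort.

    Sibs sharing a parent with the proband and offspring of the proband are
    exempt: they can legitimately share a parental-mosaic DNM. Any other
    sample in which the alt allele is detected (het or hom-alt call, or —
    when ``max_population_alt_reads`` is set — more alt reads than that
    bound) fails the screen, as does a cohort allele count at or above the
    cap.
    """
    sibs, offspring = derive_relatives(ped, proband_id)
    exempt = {proband_id} | sibs | offspring
    reasons = _population_reasons(record, exempt, n_samples, thresholds)
    return not reasons, reasons


def _population_reasons(
    record: SiteRecord,
    exempt: set[str],
    n_samples: int,
    thresholds: FilterThresholds,
) -> set[str]:
    reasons: set[str] = set()
    if record.allele_count >= thresholds.ac_cap(n_samples):
        reasons.add(R_AC)
    read_cap = thresholds.max_population_alt_reads
    for sid, call in record.calls.items():
        if sid in exempt:
            continue
        if call.genotype in (HET, HOM_ALT) or (
            read_cap is not None and call.alt_reads > read_cap
        ):
            reasons.add(R_POPULATION)
            break
    return reasons


def call_candidates(
    records: Iterable[SiteRecord],
    ped: Pedigree,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[CandidateDNM], list[CandidateDNM]]:
    """Run the full cascade for every (site, trio) pair.

    Returns ``(candidates, ledger)``: the ledger holds one entry per
    evaluated pair with its reason codes (empty for accepted candidates),
    deterministically ordered by (chrom, pos, proband).
    """
    t = thresholds or FilterThresholds()
    trios = ped.trios()
    # exemption sets are a pedigree property; compute once per trio
    exempt = {
        trio.proband: {trio.proband}
        | ped.sibs_of(trio.proband)
        | ped.offspring_of(trio.proband)
        for trio in trios
    }
    ledger: list[CandidateDNM] = []
    for rec in records:
        n_samples = len(rec.calls)
        for trio in trios:
            proband = rec.calls[trio.proband]
            sire = rec.calls[trio.sire]
            dam = rec.calls[trio.dam]
            reasons: set[str] = set()
            _, r = site_quality_pass(rec, (proband, sire, dam), t)
            reasons |= r
            trio_ok, r = trio_genotype_test(proband, sire, dam, t)
            reasons |= r
            if trio_ok:
                # population screen applies to trio-consistent pairs only
                reasons |= _population_reasons(
                    rec, exempt[trio.proband], n_samples, t
                )
            ledger.append(
                CandidateDNM(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref_allele,
                    alt_allele=rec.alt_allele,
                    proband_id=trio.proband,
                    trio_id=trio.id,
                    proband_alt_fraction=proband.alt_fraction,
                    status="candidate" if not reasons else "rejected",
                    reason_codes=frozenset(reasons),
                )
            )
    ledger.sort(key=lambda c: (c.chrom, c.pos, c.proband_id))
    candidates = [c for c in ledger if c.status == "candidate"]
    return candidates, ledger


def candidates_to_rows(ledger: Sequence[CandidateDNM]) -> list[dict]:
    """Flatten candidates/ledger entries for TSV output."""
    return [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "proband": c.proband_id,
            "status": c.status,
            "reasons": ",".join(sorted(c.reason_codes)) or ".",
            "alt_fraction": round(c.proband_alt_fraction, 4),
        }
        for c in ledger
    ]
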