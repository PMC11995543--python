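from __future__ import annotations

import pytest

from triodnm.io_model import (
    HET,
    HOM_ALT,
    HOM_REF,
    Individual,
    Pedigree,
    SampleCall,
    SiteRecord,
)
from triodnm.synthetic_data import SimulationConfig, simulate_cohort


def mk_call(
    sample_id: str,
    genotype: str = HOM_REF,
    ref_reads: int = 30,
    alt_reads: int = 0,
    depth: int | None = None,
    gq: float = 50.0,
) -> SampleCall:
    return SampleCall(
        sample_id=sample_id,
        genotype=genotype,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
        depth=depth if depth is not None else ref_reads + alt_reads,
        genotype_quality=gq,
    )


def mk_record(
    calls: dict[str, SampleCall],
    pos: int = 100,
    ref: str = "C",
    alt: str = "T",
    qd: float | None = 20.0,
    fs: float | None = 5.0,
    mq: float | None = 60.0,
    mq_rank_sum: float | None = 0.0,
    read_pos_rank_sum: float | None = 0.0,
    allele_count: int | None = None,
) -> SiteRecord:
    if allele_count is None:
        allele_count = sum(
            {HET: 1, HOM_ALT: 2}.get(c.genotype, 0) for c in calls.values()
        )
    return SiteRecord(
        chrom="chrS1",
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        qd=qd,
        fs=fs,
        mq=mq,
        mq_rank_sum=mq_rank_sum,
        read_pos_rank_sum=read_pos_rank_sum,
        allele_count=allele_count,
        calls=calls,
    )


@pytest.fixture(scope="session")
def toy_pedigree() -> Pedigree:
    """Two trios sharing a sire (P1 and Q1 are paternal half sibs) plus an
    offspring of P1 and an unrelated trio."""
    return Pedigree(
        [
            Individual("S1", None, None, "1"),
            Individual("D1", None, None, "2"),
            Individual("D2", None, None, "2"),
            Individual("P1", "S1", "D1", "1"),
            Individual("Q1", "S1", "D2", "2"),
            Individual("C1", "P1", "D2", "1"),
            Individual("S2", None, None, "1"),
            Individual("D3", None, None, "2"),
            Individual("R1", "S2", "D3", "1"),
        ]
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """A realistic small cohort: sequencing error, reference bias, a few
    background SNPs and occasional failing INFO fields."""
    cfg = SimulationConfig(
        n_trios=6,
        genome_length=150_000,
        mu=2e-6,
        background_snp_density=8e-4,
        info_fail_rate=0.1,
        seed=7,
    )
    records, samples, truth = simulate_cohort(cfg)
    return records, samples, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise cohort: no sequencing error, no reference bias, deep
    coverage — the caller must recover the truth table exactly."""
    cfg = SimulationConfig(
        n_trios=6,
        genome_length=200_000,
        mu=2e-6,
        background_snp_density=5e-4,
        seq_error_rate=0.0,
        reference_bias=0.0,
        depth_mean=30.0,
        seed=11,
    )
    records, samples, truth = simulate_cohort(cfg)
    return records, samples, truth
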