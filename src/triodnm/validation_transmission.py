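"""Panel-genotyping validation, pedigree transmission tracing, and QC.

Candidate DNMs are followed up with targeted genotyping of the trio plus up
to nine offspring of the proband. A candidate is a **germline** DNM when
the proband carries it, both parents do not, and at least one offspring
inherited it; a **possible somatic** DNM when the proband carries it, the
parents do not, at least two offspring were genotyped and none carries it
(a true heterozygous germline variant transmits to >=1 of k offspring with
probability 1 - 0.5**k, so repeated non-transmission suggests the mutation
is absent from the germline). A carrier parent or a non-carrier proband
refutes the candidate outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

CARRIER = "carrier"
NON_CARRIER = "non_carrier"
FAILED = "failed"
PANEL_CALLS = (CARRIER, NON_CARRIER, FAILED)

GERMLINE = "germline"
POSSIBLE_SOMATIC = "possible_somatic"
NOT_VALIDATED = "not_validated"
INCONCLUSIVE = "inconclusive"
ASSAY_FAILED = "assay_failed"
VALIDATION_CLASSES = (
    GERMLINE,
    POSSIBLE_SOMATIC,
    NOT_VALIDATED,
    INCONCLUSIVE,
    ASSAY_FAILED,
)


@dataclass(frozen=True)
class PanelGenotypes:
    dnm_id: str
    proband: str
    sire: str
    dam: str
    offspring: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for call in (self.proband, self.sire, self.dam, *self.offspring):
            if call not in PANEL_CALLS:
                raise ValueError(f"unknown panel call {call!r}")


@dataclass(frozen=True)
class ValidationCall:
    dnm_id: str
    klass: str

    def __post_init__(self) -> None:
        if self.klass not in VALIDATION_CLASSES:
            raise ValueError(f"unknown validation class {self.klass!r}")


def classify_validation(
    panel: PanelGenotypes, min_offspring_for_somatic: int = 2
) -> ValidationCall:
    """Map one panel result to exactly one validation class."""
    if panel.proband == FAILED:
        return ValidationCall(panel.dnm_id, ASSAY_FAILED)
    if panel.proband == NON_CARRIER or CARRIER in (panel.sire, panel.dam):
        # absent from the proband, or inherited: not de novo
        return ValidationCall(panel.dnm_id, NOT_VALIDATED)
    parents_clean = panel.sire == NON_CARRIER and panel.dam == NON_CARRIER
    informative = [c for c in panel.offspring if c != FAILED]
    carriers = sum(c == CARRIER for c in informative)
    if parents_clean and carriers >= 1:
        return ValidationCall(panel.dnm_id, GERMLINE)
    if (
        parents_clean
        and carriers == 0
        and len(informative) >= min_offspring_for_somatic
    ):
        return ValidationCall(panel.dnm_id, POSSIBLE_SOMATIC)
    return ValidationCall(panel.dnm_id, INCONCLUSIVE)


@dataclass(frozen=True)
class TransmissionTrace:
    dnm_id: str
    carriers_per_generation: tuple[int, ...]  # index 0 == generation 1 (proband)
    lost_generation: int | None  # None => still segregating

    @property
    def segregating(self) -> bool:
        return self.lost_generation is None


def trace_transmission(
    ped,
    dnm_id: str,
    proband: str,
    carrier_observations: Mapping[str, bool],
    max_generations: int = 4,
) -> TransmissionTrace:
    """Trace a DNM through genotyped descendants of the founder proband.

    Generation 1 is the proband; generation g+1 are offspring of
    generation-g individuals. The DNM is lost at the first generation
    within ``max_generations`` whose genotyped descendants include no
    carrier. Carriers observed outside the proband's descendant set
    indicate a lineage inconsistency and raise ``ValueError``.
    """
    descendants = ped.descendants_of(proband)
    lineage = descendants | {proband}
    bad = [
        iid
        for iid, is_carrier in carrier_observations.items()
        if is_carrier and iid not in lineage
    ]
    if bad:
        raise ValueError(
            f"carrier(s) outside the proband lineage for {dnm_id}: {bad}"
        )
    depths = ped.generation_depths(proband)
    counts = []
    lost_at = None
    for g in range(1, max_generations + 1):
        gen_members = [i for i, d in depths.items() if d == g]
        observed = [i for i in gen_members if i in carrier_observations]
        if g > 1 and not observed:
            # nothing genotyped this deep: trace ends, DNM not observed lost
            break
        n_carriers = sum(carrier_observations[i] for i in observed)
        counts.append(n_carriers)
        if n_carriers == 0 and g > 1:
            lost_at = g
            break
    return TransmissionTrace(
        dnm_id=dnm_id,
        carriers_per_generation=tuple(counts),
        lost_generation=lost_at,
    )


def het_concordance(
    chip_het_sites: Iterable[tuple[str, int]],
    wgs_calls: Mapping[tuple[str, int], str],
) -> tuple[float, int]:
    """Proportion of chip-heterozygous sites called het in WGS.

    Sites with a missing WGS call are excluded from the denominator; the
    excluded count is returned alongside the proportion.
    """
    n_used = n_het = n_missing = 0
    for site in chip_het_sites:
        call = wgs_calls.get(site, "missing")
        if call == "missing":
            n_missing += 1
            continue
        n_used += 1
        if call == "het":
            n_het += 1
    if n_used == 0:
        raise ValueError("no overlapping chip-het sites with a WGS call")
    return n_het / n_used, n_missing


def class_retention(
    pre_counts: Mapping[str, int], post_counts: Mapping[str, int]
) -> dict[str, float | None]:
    """Removed fraction per genotype class (Hom_RR / Het_RA / Hom_AA).

    ``None`` marks classes with a zero pre-filter count (undefined).
    """
    out: dict[str, float | None] = {}
    for klass, pre in pre_counts.items():
        post = post_counts.get(klass, 0)
        if post > pre:
            raise ValueError(
                f"{klass}: post-filter count {post} exceeds pre-filter {pre}"
            )
        out[klass] = None if pre == 0 else 1.0 - post / pre
    return out
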