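"""Filter-cascade behaviour: boundary semantics, truth recovery, and
equivalence with a plain brute-force re-implementation of every rule."""

import dataclasses
import math

import pytest

from triodnm.dnm_calling import (
    FilterThresholds,
    call_candidates,
    population_screen,
    site_quality_pass,
    trio_genotype_test,
)
from triodnm.io_model import HET, HOM_ALT, HOM_REF, MISSING, Individual, Pedigree

from conftest import mk_call, mk_record

THR = FilterThresholds()


def trio_calls(proband, sire, dam):
    return {"P1": proband, "S1": sire, "D1": dam}


@pytest.fixture(scope="module")
def trio_ped():
    return Pedigree(
        [
            Individual("S1", None, None, "1"),
            Individual("D1", None, None, "2"),
            Individual("P1", "S1", "D1", "1"),
        ]
    )


class TestSiteQuality:
    def good_calls(self):
        return [mk_call(s, HOM_REF, 30, 0) for s in ("P1", "S1", "D1")]

    def test_comfortable_site_passes(self):
        rec = mk_record({}, qd=10.0, fs=5.0, mq=60.0)
        ok, reasons = site_quality_pass(rec, self.good_calls(), THR)
        assert ok and not reasons

    @pytest.mark.parametrize(
        "info,expected",
        [
            ({"mq": 40.0}, "mq"),  # boundary is exclusive: MQ <= 40 fails
            ({"qd": 4.0}, "qd"),
            ({"fs": 60.0}, "fs"),
            ({"mq_rank_sum": -2.0}, "mq_rank_sum"),
            ({"read_pos_rank_sum": -8.0}, "read_pos_rank_sum"),
        ],
    )
    def test_boundary_values_fail(self, info, expected):
        rec = mk_record({}, **info)
        ok, reasons = site_quality_pass(rec, self.good_calls(), THR)
        assert not ok and reasons == {expected}

    def test_one_member_low_depth_fails(self):
        calls = self.good_calls()
        calls[1] = mk_call("S1", HOM_REF, 8, 0)
        ok, reasons = site_quality_pass(mk_record({}), calls, THR)
        assert not ok and reasons == {"dp"}

    def test_absent_rank_sums_do_not_fail(self):
        rec = mk_record({}, mq_rank_sum=None, read_pos_rank_sum=None)
        ok, reasons = site_quality_pass(rec, self.good_calls(), THR)
        assert ok

    def test_min_gq_over_trio(self):
        calls = self.good_calls()
        calls[2] = mk_call("D1", HOM_REF, 30, 0, gq=19.0)
        ok, reasons = site_quality_pass(mk_record({}), calls, THR)
        assert reasons == {"gq"}


class TestTrioGenotype:
    def test_clean_mendelian_violation_passes(self):
        ok, reasons = trio_genotype_test(
            mk_call("P1", HET, 15, 13, gq=50),
            mk_call("S1", HOM_REF, 30, 0, gq=40),
            mk_call("D1", HOM_REF, 30, 0, gq=40),
            THR,
        )
        assert ok and not reasons

    def test_low_alt_fraction_fails(self):
        # 5/30 = 0.167 <= 0.20
        ok, reasons = trio_genotype_test(
            mk_call("P1", HET, 25, 5),
            mk_call("S1", HOM_REF, 30, 0),
            mk_call("D1", HOM_REF, 30, 0),
            THR,
        )
        assert reasons == {"alt_fraction"}

    def test_exact_20_percent_fails(self):
        # strict inequality: exactly 20% is not enough support
        ok, reasons = trio_genotype_test(
            mk_call("P1", HET, 24, 6),
            mk_call("S1", HOM_REF, 30, 0),
            mk_call("D1", HOM_REF, 30, 0),
            THR,
        )
        assert reasons == {"alt_fraction"}

    def test_parent_alt_read_fails(self):
        ok, reasons = trio_genotype_test(
            mk_call("P1", HET, 15, 13),
            mk_call("S1", HOM_REF, 30, 0),
            mk_call("D1", HOM_REF, 29, 1),
            THR,
        )
        assert reasons == {"parent_alt_reads"}

    def test_hom_alt_proband_fails_configuration(self):
        ok, reasons = trio_genotype_test(
            mk_call("P1", HOM_ALT, 0, 28),
            mk_call("S1", HOM_REF, 30, 0),
            mk_call("D1", HOM_REF, 30, 0),
            THR,
        )
        assert "genotype_config" in reasons

    def test_missing_genotype_is_reason_not_exception(self):
        ok, reasons = trio_genotype_test(
            mk_call("P1", MISSING, 0, 0, depth=0),
            mk_call("S1", HOM_REF, 30, 0),
            mk_call("D1", HOM_REF, 30, 0),
            THR,
        )
        assert reasons == {"missing_genotype"}


class TestPopulationScreen:
    def rec_with(self, extra_calls, allele_count=1):
        calls = trio_calls(
            mk_call("P1", HET, 15, 13),
            mk_call("S1", HOM_REF, 30, 0),
            mk_call("D1", HOM_REF, 30, 0),
        )
        calls.update(extra_calls)
        return mk_record(calls, allele_count=allele_count)

    def ped_with_relatives(self):
        return Pedigree(
            [
                Individual("S1", None, None, "1"),
                Individual("D1", None, None, "2"),
                Individual("D2", None, None, "2"),
                Individual("P1", "S1", "D1", "1"),
                Individual("H1", "S1", "D2", "2"),  # paternal half sib
                Individual("U1", None, None, "1"),  # unrelated
            ]
        )

    def test_unrelated_het_carrier_fails(self):
        ped = self.ped_with_relatives()
        rec = self.rec_with({"U1": mk_call("U1", HET, 14, 14)}, allele_count=2)
        ok, reasons = population_screen(rec, "P1", ped, 135, THR)
        assert "population_sharing" in reasons

    def test_half_sib_carrier_is_exempt(self):
        ped = self.ped_with_relatives()
        rec = self.rec_with(
            {
                "H1": mk_call("H1", HET, 14, 14),
                "U1": mk_call("U1", HOM_REF, 30, 0),
            },
            allele_count=2,
        )
        ok, reasons = population_screen(rec, "P1", ped, 135, THR)
        assert ok

    def test_allele_count_cap(self):
        # cap = max(4, ceil(0.001 * 135)) = 4, so AC = 5 fails and AC = 3
        # passes
        ped = self.ped_with_relatives()
        assert THR.ac_cap(135) == 4
        rec = self.rec_with({}, allele_count=5)
        ok, reasons = population_screen(rec, "P1", ped, 135, THR)
        assert reasons == {"allele_count_cap"}
        ok, _ = population_screen(self.rec_with({}, allele_count=3), "P1", ped, 135, THR)
        assert ok

    def test_read_level_screen_is_opt_in(self):
        ped = self.ped_with_relatives()
        rec = self.rec_with({"U1": mk_call("U1", HOM_REF, 29, 1)}, allele_count=1)
        ok, _ = population_screen(rec, "P1", ped, 135, THR)
        assert ok  # a stray read without a variant call does not fail
        strict = dataclasses.replace(THR, max_population_alt_reads=0)
        ok, reasons = population_screen(rec, "P1", ped, 135, strict)
        assert reasons == {"population_sharing"}


# ---------------------------------------------------------------------------
# brute-force oracle: literal re-statement of every rule, no shared code
# with the implementation beyond the domain types

def brute_force_candidates(records, ped, thr):
    out = set()
    for rec in records:
        n = len(rec.calls)
        cap = max(thr.ac_cap_floor, math.ceil(thr.ac_cap_sample_frac * n))
        for trio in ped.trios():
            p = rec.calls[trio.proband]
            s = rec.calls[trio.sire]
            d = rec.calls[trio.dam]
            members = [p, s, d]
            if min(m.genotype_quality for m in members) < thr.min_gq:
                continue
            if min(m.depth for m in members) < thr.min_dp:
                continue
            if max(m.depth for m in members) > thr.max_dp:
                continue
            if rec.qd is not None and rec.qd <= thr.min_qd:
                continue
            if rec.fs is not None and rec.fs >= thr.max_fs:
                continue
            if rec.mq is not None and rec.mq <= thr.min_mq:
                continue
            if rec.mq_rank_sum is not None and rec.mq_rank_sum <= thr.min_mq_rank_sum:
                continue
            if (
                rec.read_pos_rank_sum is not None
                and rec.read_pos_rank_sum <= thr.min_read_pos_rank_sum
            ):
                continue
            if not (p.genotype == HET and s.genotype == HOM_REF and d.genotype == HOM_REF):
                continue
            if p.depth == 0 or p.alt_reads / p.depth <= thr.min_proband_alt_fraction:
                continue
            if s.alt_reads > thr.max_parent_alt_reads:
                continue
            if d.alt_reads > thr.max_parent_alt_reads:
                continue
            if rec.allele_count >= cap:
                continue
            exempt = (
                {trio.proband}
                | ped.sibs_of(trio.proband)
                | ped.offspring_of(trio.proband)
            )
            shared = False
            for sid, call in rec.calls.items():
                if sid in exempt:
                    continue
                if call.genotype in (HET, HOM_ALT):
                    shared = True
                elif (
                    thr.max_population_alt_reads is not None
                    and call.alt_reads > thr.max_population_alt_reads
                ):
                    shared = True
            if shared:
                continue
            out.add((rec.chrom, rec.pos, trio.proband))
    return out


class TestCallCandidates:
    def test_zero_noise_candidates_equal_truth_exactly(self, clean_cohort):
        """Perfect recovery: sensitivity 1 and FDR 0 at zero noise."""
        records, samples, truth = clean_cohort
        cands, ledger = call_candidates(records, truth.pedigree)
        found = {(c.chrom, c.pos, c.proband_id) for c in cands}
        expected = truth.germline_positions()
        assert len(expected) > 0
        assert found == expected

    def test_empty_cohort_gives_zero_candidates(self, toy_pedigree):
        cands, ledger = call_candidates([], toy_pedigree)
        assert cands == [] and ledger == []

    def test_parental_contamination_lands_in_ledger(self, trio_ped):
        rec = mk_record(
            trio_calls(
                mk_call("P1", HET, 15, 13),
                mk_call("S1", HOM_REF, 27, 3),
                mk_call("D1", HOM_REF, 30, 0),
            )
        )
        cands, ledger = call_candidates([rec], trio_ped)
        assert cands == []
        (entry,) = ledger
        assert entry.status == "rejected"
        assert entry.reason_codes == {"parent_alt_reads"}

    def test_candidate_status_iff_no_reasons(self, noisy_cohort):
        records, _, truth = noisy_cohort
        _, ledger = call_candidates(records, truth.pedigree)
        for entry in ledger:
            assert (entry.status == "candidate") == (not entry.reason_codes)

    def test_deterministic_output_order(self, noisy_cohort):
        records, _, truth = noisy_cohort
        _, ledger = call_candidates(records, truth.pedigree)
        keys = [(e.chrom, e.pos, e.proband_id) for e in ledger]
        assert keys == sorted(keys)

    def test_matches_brute_force_oracle(self, noisy_cohort):
        records, _, truth = noisy_cohort
        cands, _ = call_candidates(records, truth.pedigree)
        found = {(c.chrom, c.pos, c.proband_id) for c in cands}
        assert found == brute_force_candidates(records, truth.pedigree, THR)

    @pytest.mark.parametrize(
        "tweak",
        [
            {"min_gq": 60.0},
            {"min_dp": 25},
            {"max_dp": 35},
            {"min_qd": 20.0},
            {"max_fs": 2.0},
            {"min_mq": 59.0},
            {"min_mq_rank_sum": 0.0},
            {"min_read_pos_rank_sum": 0.0},
            {"min_proband_alt_fraction": 0.45},
            {"ac_cap_floor": 1},
            {"max_population_alt_reads": 0},
        ],
    )
    def test_tightening_any_threshold_never_adds_candidates(
        self, noisy_cohort, tweak
    ):
        records, _, truth = noisy_cohort
        base, _ = call_candidates(records, truth.pedigree, THR)
        tightened, _ = call_candidates(
            records, truth.pedigree, dataclasses.replace(THR, **tweak)
        )
        base_keys = {(c.chrom, c.pos, c.proband_id) for c in base}
        tight_keys = {(c.chrom, c.pos, c.proband_id) for c in tightened}
        assert tight_keys <= base_keys
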