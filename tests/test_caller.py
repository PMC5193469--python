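"""Per-nucleus classification, aggregation, calling and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligofish.caller import (ArmStatus, NucleusCategory, NucleusCount,
                              QCPolicy, SampleSummary, calibrate_cutoffs,
                              call_arm_status, classify_nucleus, qc_sample,
                              summarize_sample)
from oligofish.chromosomes import (CHR1, CHR9, CHR10, CHR19, CHROM_PAIRS,
                                   ChromCutoffs, CutoffSet)


def brute_force_category(monosomy_enabled: bool, r: int, g: int) -> str:
    """Independent restatement of the scoring rules by enumeration.

    Deliberately structured differently from the implementation: builds
    the full set of informative patterns first, then looks up.
    """
    if r == 2 and g == 2:
        return "NORMAL"
    if r == 1 and g == 1:
        return "MONOSOMY" if monosomy_enabled else "UNINFORMATIVE"
    # deleted: red present, at least 2 green, at most half as many red
    if g >= 2 and 1 <= r and 2 * r <= g:
        return "TARGET_DELETED"
    # imbalance: >= 3 spots in some channel and red exceeds half of green
    if g >= 1 and 2 * r > g and (r >= 3 or g >= 3):
        return "POLYSOMY_IMBALANCED"
    return "UNINFORMATIVE"


def test_classifier_matches_bruteforce_enumeration():
    """Every (r, g) in [0, 10]^2 maps to exactly the brute-force category."""
    for chrom in CHROM_PAIRS.values():
        for r in range(11):
            for g in range(11):
                got = classify_nucleus(chrom, NucleusCount("x", r, g))
                want = brute_force_category(chrom.monosomy_rule_enabled, r, g)
                assert got.value == want, (chrom.id, r, g)


@pytest.mark.parametrize("chrom, r, g, expected", [
    (CHR9, 1, 2, "TARGET_DELETED"),      # classic 1R/2G deletion pattern
    (CHR9, 1, 1, "MONOSOMY"),            # whole-chromosome-9 loss
    (CHR19, 1, 1, "UNINFORMATIVE"),      # 1R/1G rule disabled for chr19
    (CHR1, 1, 1, "UNINFORMATIVE"),
    (CHR9, 2, 4, "TARGET_DELETED"),      # ratio boundary: 0.5 counts as deleted
    (CHR9, 3, 3, "POLYSOMY_IMBALANCED"),
    (CHR9, 2, 2, "NORMAL"),
    (CHR9, 2, 1, "UNINFORMATIVE"),       # not polysomy: no channel reaches 3
    (CHR9, 1, 0, "UNINFORMATIVE"),
    (CHR9, 0, 4, "UNINFORMATIVE"),       # empty red channel: artifact
    (CHR10, 4, 2, "POLYSOMY_IMBALANCED"),
])
def test_classifier_examples(chrom, r, g, expected):
    assert classify_nucleus(chrom, NucleusCount("x", r, g)).value == expected


def test_counts_must_be_nonnegative_integers():
    with pytest.raises(ValueError):
        NucleusCount("x", -1, 2)
    with pytest.raises(TypeError):
        NucleusCount("x", 1.5, 2)


def _nuclei(pattern_counts):
    out = []
    for (r, g), k in pattern_counts.items():
        out.extend(NucleusCount(f"{r}-{g}-{i}", r, g) for i in range(k))
    return out


class TestSummarize:
    def test_percentages_over_analyzable_only(self):
        # 90 analyzable of 100, 60 of them deleted -> 66.7%
        nuclei = _nuclei({(1, 2): 60, (2, 2): 30, (1, 0): 10})
        s = summarize_sample(CHR1, nuclei)
        assert s.n_total == 100 and s.n_analyzable == 90
        assert s.pct_deleted == pytest.approx(100 * 60 / 90, abs=1e-9)

    def test_pure_diploid_sample(self):
        s = summarize_sample(CHR1, _nuclei({(2, 2): 50}))
        assert s.pct_deleted == 0 and s.pct_imbalanced == 0
        assert s.pct_normal == 100

    def test_monosomy_counts_as_deleted_when_rule_enabled(self):
        nuclei = _nuclei({(1, 1): 50, (2, 2): 50})
        s9 = summarize_sample(CHR9, nuclei)
        assert s9.pct_deleted == 50 and s9.pct_monosomy == 50
        s1 = summarize_sample(CHR1, nuclei)  # same nuclei, rule disabled
        assert s1.n_analyzable == 50 and s1.pct_deleted == 0

    def test_category_percentages_sum_to_100(self):
        nuclei = _nuclei({(1, 2): 10, (2, 2): 20, (3, 3): 5, (1, 1): 7,
                          (2, 1): 3})
        s = summarize_sample(CHR9, nuclei)
        total = s.pct_normal + s.pct_deleted + s.pct_imbalanced
        assert total == pytest.approx(100.0)  # pct_deleted includes monosomy
        assert s.pct_deleted >= s.pct_monosomy

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample(CHR1, [])

    def test_zero_analyzable_flagged_not_crashed(self):
        s = summarize_sample(CHR1, _nuclei({(1, 0): 5}))
        assert s.n_analyzable == 0
        with pytest.raises(ValueError):
            _ = s.pct_deleted


def _summary(chrom_id, n, pct_del, pct_imb, pct_mono=0.0):
    """Build a summary with the requested percentages."""
    n_mono = round(n * pct_mono / 100)
    n_del = round(n * pct_del / 100) - n_mono
    n_imb = round(n * pct_imb / 100)
    return SampleSummary(
        chrom_id=chrom_id, n_total=n, n_analyzable=n,
        n_normal=n - n_del - n_imb - n_mono, n_deleted=n_del,
        n_imbalanced=n_imb, n_monosomy=n_mono)


class TestCallArmStatus:
    CUT = CutoffSet.published_defaults()

    def call(self, chrom, **kw):
        return call_arm_status(_summary(chrom.id, 1000, **kw), self.CUT, chrom)

    def test_clear_deletion(self):
        assert self.call(CHR1, pct_del=60, pct_imb=5).target_status \
            is ArmStatus.DELETED

    def test_mixed_sum_rule(self):
        # 10 + 20 >= 25 (chr10 deletion cutoff) -> imbalanced
        assert self.call(CHR10, pct_del=10, pct_imb=20).target_status \
            is ArmStatus.IMBALANCED

    def test_monosomy_gives_target_and_control_deletion(self):
        c = self.call(CHR9, pct_del=45, pct_imb=5, pct_mono=35)
        assert c.target_status is ArmStatus.DELETED
        assert c.control_arm_deleted

    def test_imbalance_overrides_deletion(self):
        c = self.call(CHR1, pct_del=60, pct_imb=25)
        assert c.target_status is ArmStatus.IMBALANCED

    def test_control_arm_flag_needs_monosomy_rule(self):
        c = self.call(CHR1, pct_del=60, pct_imb=5, pct_mono=0)
        assert not c.control_arm_deleted

    def test_normal_below_all_cutoffs(self):
        assert self.call(CHR1, pct_del=20, pct_imb=10).target_status \
            is ArmStatus.NORMAL

    def test_no_analyzable_nuclei_is_an_error(self):
        s = SampleSummary(chrom_id="chr1", n_total=10, n_analyzable=0)
        with pytest.raises(ValueError):
            call_arm_status(s, self.CUT, CHR1)

    @given(d1=st.floats(0, 99), d2=st.floats(0, 99),
           imb=st.floats(0, 20), data=st.data())
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_deleted_fraction(self, d1, d2, imb, data):
        """With pct_imbalanced fixed below its cutoff, more deleted nuclei
        never make the call less severe (NORMAL < IMBALANCED < DELETED)."""
        lo, hi = sorted((d1, d2))
        severity = {ArmStatus.NORMAL: 0, ArmStatus.IMBALANCED: 1,
                    ArmStatus.DELETED: 2}
        c_lo = self.call(CHR1, pct_del=lo, pct_imb=imb).target_status
        c_hi = self.call(CHR1, pct_del=hi, pct_imb=imb).target_status
        assert severity[c_hi] >= severity[c_lo]


class TestCalibration:
    def test_mean_plus_three_sample_sd(self):
        summaries = [_summary("chr9", 1000, pct_del=p, pct_imb=1)
                     for p in (10, 12, 8, 11, 9)]
        cs = calibrate_cutoffs({"chr9": summaries})
        assert cs["chr9"].deletion_cutoff == pytest.approx(14.7434, abs=2e-3)
        assert cs.source == "calibrated"

    def test_floor_clamps_degenerate_controls(self):
        summaries = [_summary("chr9", 1000, pct_del=0, pct_imb=0)
                     for _ in range(5)]
        cs = calibrate_cutoffs({"chr9": summaries}, floor=5.0)
        assert cs["chr9"].deletion_cutoff == 5.0
        assert cs["chr9"].imbalance_cutoff == 5.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            calibrate_cutoffs({"chr9": [_summary("chr9", 100, 5, 1)]})

    @given(pcts=st.lists(st.floats(0, 30), min_size=3, max_size=8),
           shift=st.floats(0, 10))
    @settings(max_examples=100, derandomize=True)
    def test_nondecreasing_in_inputs(self, pcts, shift):
        base = [_summary("chr9", 10000, pct_del=p, pct_imb=1) for p in pcts]
        shifted = [_summary("chr9", 10000, pct_del=min(p + shift, 99), pct_imb=1)
                   for p in pcts]
        d0 = calibrate_cutoffs({"chr9": base})["chr9"].deletion_cutoff
        d1 = calibrate_cutoffs({"chr9": shifted})["chr9"].deletion_cutoff
        # uniform upward shift raises the mean, leaves SD alone (up to
        # rounding of counts and the clamp at 99)
        if all(p + shift <= 99 for p in pcts):
            assert d1 >= d0 - 0.2


class TestQC:
    def test_too_few_cells_fails(self):
        ok, reason = qc_sample(_summary("chr1", 45, 0, 0), QCPolicy())
        assert not ok and "45" in reason

    def test_boundary_passes(self):
        ok, _ = qc_sample(_summary("chr1", 50, 0, 0), QCPolicy())
        assert ok

    def test_zero_analyzable_fails(self):
        s = SampleSummary(chrom_id="chr1", n_total=100, n_analyzable=0)
        ok, reason = qc_sample(s, QCPolicy())
        assert not ok and "uninformative" in reason

    def test_uninformative_fraction_rule(self):
        s = SampleSummary(chrom_id="chr1", n_total=200, n_analyzable=90,
                          n_normal=90)
        ok, reason = qc_sample(s, QCPolicy())
        assert not ok and "uninformative" in reason
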