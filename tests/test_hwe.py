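import numpy as np
import pandas as pd
import pytest

import cnvrecur as cr
from cnvrecur.hwe import (DIALLELIC_GAIN, DIALLELIC_LOSS, MULTIALLELIC,
                          GenotypeCounts, RegionGenotypes,
                          assign_copy_numbers, genotype_region, hwe_test,
                          tune_thresholds, violation_rate)
from cnvrecur.io_model import SampleGroups, validate_calls
from cnvrecur.recurrence import CommonRegion

from _oracles import exact_hwe_oracle


def _calls(rows):
    return validate_calls(pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start_bp", "end_bp",
                       "copy_number", "confidence"]))


def _region(calls, start, end, state="loss", n_total=None):
    support = calls[(calls["start_bp"] <= end) & (calls["end_bp"] >= start)]
    samples = tuple(sorted(set(support["sample_id"])))
    n_total = n_total or len(set(calls["sample_id"]))
    return CommonRegion(
        region_id=f"1:{start}-{end}:{state}", chromosome="1",
        state_class=state, first_probe=0, last_probe=1,
        start_bp=start, end_bp=end,
        supporting_calls=tuple(support.index), supporting_samples=samples,
        n_total_samples=n_total, frequency=len(samples) / n_total,
        median_confidence=10.0, size_kb=(end - start) / 1000)


class TestCopyNumberAssignment:
    def test_largest_overlap_wins(self):
        calls = _calls([("a", "1", 100, 180, 1, 5.0),   # 80% of region
                        ("a", "1", 170, 200, 0, 9.0)])  # 30% of region
        region = _region(calls, 101, 200)
        cn = assign_copy_numbers(region, calls, ["a", "b"])
        assert cn == {"a": 1, "b": 2}

    def test_overlap_tie_broken_by_confidence_then_lower_cn(self):
        calls = _calls([("a", "1", 101, 150, 1, 5.0),
                        ("a", "1", 151, 200, 0, 9.0)])
        region = _region(calls, 101, 200)
        assert assign_copy_numbers(region, calls, ["a"])["a"] == 0
        calls2 = _calls([("a", "1", 101, 150, 1, 7.0),
                         ("a", "1", 151, 200, 0, 7.0)])
        region2 = _region(calls2, 101, 200)
        assert assign_copy_numbers(region2, calls2, ["a"])["a"] == 0


class TestGenotypeRegion:
    def test_loss_mapping(self):
        calls = _calls([("a", "1", 100, 200, 1, 5.0),
                        ("b", "1", 100, 200, 0, 5.0)])
        region = _region(calls, 100, 200)
        rg = genotype_region(region, calls, ["a", "b", "c", "d"])
        assert rg.allelicity == DIALLELIC_LOSS
        counts = rg.counts_by_group["all"]
        assert (counts.n_ref_hom, counts.n_het, counts.n_var_hom) == (2, 1, 1)
        assert counts.maf == pytest.approx(3 / 8)

    def test_gain_mapping(self):
        calls = _calls([("a", "1", 100, 200, 3, 5.0),
                        ("b", "1", 100, 200, 4, 5.0)])
        region = _region(calls, 100, 200, state="gain")
        rg = genotype_region(region, calls, ["a", "b", "c"])
        assert rg.allelicity == DIALLELIC_GAIN
        counts = rg.counts_by_group["all"]
        assert (counts.n_ref_hom, counts.n_het, counts.n_var_hom) == (1, 1, 1)

    def test_mixed_loss_and_gain_is_multiallelic(self):
        calls = _calls([("a", "1", 100, 200, 1, 5.0),
                        ("b", "1", 100, 200, 3, 5.0)])
        region = _region(calls, 100, 200)
        rg = genotype_region(region, calls, ["a", "b"])
        assert rg.allelicity == MULTIALLELIC
        assert rg.counts_by_group == {}

    def test_extreme_copy_number_is_multiallelic(self):
        calls = _calls([("a", "1", 100, 200, 6, 5.0)])
        region = _region(calls, 100, 200, state="gain")
        rg = genotype_region(region, calls, ["a"])
        assert rg.allelicity == MULTIALLELIC

    def test_no_carriers_all_reference_homozygous(self):
        calls = _calls([("z", "2", 900, 950, 1, 5.0)])  # elsewhere
        region = CommonRegion("1:100-200:loss", "1", "loss", 0, 1, 100, 200,
                              (), (), 4, 0.0, float("nan"), 0.1)
        rg = genotype_region(region, calls, ["a", "b", "c", "d"])
        counts = rg.counts_by_group["all"]
        assert (counts.n_ref_hom, counts.n_het, counts.n_var_hom) == (4, 0, 0)
        assert counts.maf == 0.0

    def test_counts_restricted_to_unrelated_group_members(self):
        calls = _calls([("a", "1", 100, 200, 1, 5.0),
                        ("b", "1", 100, 200, 1, 5.0)])
        region = _region(calls, 100, 200)
        groups = SampleGroups({"a": "g1", "b": "g1", "c": "g2"},
                              unrelated=frozenset({"a", "c"}))
        rg = genotype_region(region, calls, ["a", "b", "c"], groups)
        assert rg.counts_by_group["g1"].n == 1   # b related, excluded
        assert rg.counts_by_group["g1"].n_het == 1
        assert rg.counts_by_group["g2"].n == 1


class TestHweTest:
    def test_perfect_proportions_not_significant(self):
        assert hwe_test(GenotypeCounts(25, 50, 25)) > 0.9

    def test_all_heterozygotes_extreme(self):
        assert hwe_test(GenotypeCounts(0, 100, 0)) < 1e-15

    def test_matches_exact_enumeration(self):
        for triple in [(89, 10, 1), (40, 8, 2), (10, 10, 10), (5, 0, 5)]:
            got = hwe_test(GenotypeCounts(*triple))
            assert got == pytest.approx(float(exact_hwe_oracle(*triple)),
                                        rel=1e-9)

    def test_invariant_to_homozygote_label_swap(self):
        for triple in [(30, 12, 3), (1, 5, 20), (0, 3, 7)]:
            a = hwe_test(GenotypeCounts(*triple))
            b = hwe_test(GenotypeCounts(*triple[::-1]))
            assert a == pytest.approx(b, rel=1e-12)

    def test_monomorphic_convention(self):
        assert hwe_test(GenotypeCounts(42, 0, 0)) == 1.0

    def test_chisq_agrees_asymptotically(self):
        # large balanced sample: both tests far from significance
        assert hwe_test(GenotypeCounts(400, 470, 130), "chisq") > 0.05
        assert hwe_test(GenotypeCounts(400, 470, 130), "exact") > 0.05

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(GenotypeCounts(0, 0, 0))


def _rg(region_id, counts_by_group, allelicity=DIALLELIC_LOSS):
    return RegionGenotypes(region_id=region_id, copy_numbers={},
                           allelicity=allelicity,
                           counts_by_group=counts_by_group)


class TestViolationRate:
    def test_monomorphic_regions_never_violate(self):
        rgs = [_rg(str(i), {"g": GenotypeCounts(10, 0, 0)}) for i in range(4)]
        assert violation_rate(rgs) == 0.0

    def test_any_group_rule(self):
        ok = GenotypeCounts(25, 50, 25)
        bad = GenotypeCounts(0, 50, 0)
        rgs = [_rg("r1", {"g1": ok, "g2": bad, "g3": ok}),
               _rg("r2", {"g1": ok, "g2": ok, "g3": ok})]
        assert violation_rate(rgs) == 0.5

    def test_rate_arithmetic(self):
        bad = GenotypeCounts(0, 60, 0)
        ok = GenotypeCounts(25, 50, 25)
        rgs = ([_rg(f"v{i}", {"g": bad}) for i in range(2)]
               + [_rg(f"o{i}", {"g": ok}) for i in range(23)])
        assert violation_rate(rgs) == pytest.approx(0.08)

    def test_multiallelic_regions_excluded(self):
        rgs = [_rg("m", {}, allelicity=MULTIALLELIC),
               _rg("d", {"g": GenotypeCounts(25, 50, 25)})]
        assert violation_rate(rgs) == 0.0
        with pytest.raises(ValueError):
            violation_rate([_rg("m", {}, allelicity=MULTIALLELIC)])


@pytest.fixture(scope="module")
def study():
    loci = cr.default_locus_specs(6)
    calls, groups, _ = cr.simulate_population(
        loci, {"g1": 30, "g2": 30}, noise_rate=0.3, seed=11)
    return calls, groups


class TestTuneThresholds:
    def test_single_point_grid_gives_one_row(self, study):
        calls, groups = study
        table = tune_thresholds(calls, None, groups, [(0.0, 2)])
        assert len(table) == 1
        assert table.iloc[0]["n_regions"] > 0

    def test_filtering_everything_reports_zero_regions(self, study):
        calls, groups = study
        table = tune_thresholds(calls, None, groups, [(0.0, 2), (100.0, 99)])
        assert table.iloc[1]["n_regions"] == 0
        assert np.isnan(table.iloc[1]["violation_rate"])

    def test_steepest_drop_flagged_after_largest_decline(self, study):
        calls, groups = study
        table = tune_thresholds(calls, None, groups,
                                [(0.0, 2), (40.0, 2), (80.0, 2)])
        vr = table["violation_rate"].to_numpy(dtype=float)
        flags = table["steepest_drop"].to_numpy()
        if np.isfinite(vr).all() and (np.diff(vr) < 0).any():
            assert flags.sum() == 1
            assert flags[np.nanargmin(np.diff(vr))]
        else:
            assert flags.sum() == 0

    def test_composite_grid(self, study):
        calls, groups = study
        table = tune_thresholds(calls, None, groups, [90.0, 99.0],
                                method="composite")
        assert list(table["score_percentile"]) == [90.0, 99.0]
        assert (table["n_regions"] >= 0).all()
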