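import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cnvrecur as cr
from cnvrecur.io_model import ProbeMap, validate_calls
from cnvrecur.recurrence import (ProbeTrack, extract_regions,
                                 resolve_composite_threshold,
                                 resolve_confidence_cutoff)

from _oracles import brute_force_track, random_call_instance, runs_oracle


class TestConfidenceCutoff:
    def test_percentile_zero_is_minimum(self, cover_toy):
        calls, _ = cover_toy
        assert resolve_confidence_cutoff(calls, 0) == 1.0

    def test_linear_interpolation_between_order_statistics(self):
        calls = pd.DataFrame({"confidence": np.arange(1.0, 11.0)})
        assert resolve_confidence_cutoff(calls, 60) == pytest.approx(6.4)

    def test_constant_scores_give_that_constant(self):
        calls = pd.DataFrame({"confidence": [3.0] * 7})
        for pct in (0, 37, 100):
            assert resolve_confidence_cutoff(calls, pct) == 3.0

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            resolve_confidence_cutoff(pd.DataFrame({"confidence": []}), 50)


class TestTracks:
    def test_cover_counts_reliable_calls_per_probe(self, cover_toy):
        calls, probes = cover_toy
        track = cr.cover_track(calls, probes, c=4.0, state_class="loss")["1"]
        assert list(track.values) == [1, 2, 2, 2, 1]

    def test_cutoff_above_all_scores_zeroes_track(self, cover_toy):
        calls, probes = cover_toy
        track = cr.cover_track(calls, probes, c=100.0)["1"]
        assert not track.values.any()

    def test_no_calls_gives_zero_track(self, cover_toy):
        calls, probes = cover_toy
        track = cr.cover_track(calls.iloc[:0], probes)["1"]
        assert not track.values.any()

    def test_composite_sums_confidences_per_probe(self, cover_toy):
        calls, probes = cover_toy
        track = cr.composite_track(calls, probes, state_class="loss")["1"]
        assert list(track.values) == [10, 15, 16, 15, 5]

    def test_unit_confidences_reduce_composite_to_cover(self, cover_toy):
        calls, probes = cover_toy
        unit = calls.assign(confidence=1.0)
        comp = cr.composite_track(unit, probes)["1"]
        cov = cr.cover_track(unit, probes, c=0.0)["1"]
        assert np.array_equal(comp.values, cov.values)

    def test_call_on_unmapped_chromosome_rejected(self, cover_toy):
        calls, _ = cover_toy
        probes = ProbeMap({"2": [100]})
        with pytest.raises(ValueError, match="absent"):
            cr.cover_track(calls, probes)

    def test_same_sample_overlapping_calls_count_twice(self, caplog):
        calls = validate_calls(pd.DataFrame({
            "sample_id": ["a", "a"], "chromosome": ["1", "1"],
            "start_bp": [100, 150], "end_bp": [200, 250],
            "copy_number": [1, 1], "confidence": [5.0, 5.0]}))
        probes = ProbeMap({"1": [175]})
        with caplog.at_level("WARNING", logger="cnvrecur"):
            track = cr.cover_track(calls, probes)["1"]
        assert track.values[0] == 2
        assert "overlapping calls" in caplog.text

    def test_tracks_match_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            calls, positions = random_call_instance(rng)
            probes = ProbeMap({"1": positions})
            c = float(rng.uniform(0, 20))
            for sc in ("loss", "gain", "combined"):
                cov = cr.cover_track(calls, probes, c=c, state_class=sc)["1"]
                exp = brute_force_track(calls, positions, kind="cover",
                                        c=c, state_class=sc)
                assert np.array_equal(cov.values, exp)
            comp = cr.composite_track(calls, probes)["1"]
            exp = brute_force_track(calls, positions, kind="composite")
            np.testing.assert_allclose(comp.values, exp, atol=1e-9)

    def test_conservation_of_total_overlap(self, rng):
        # sum_k y_k equals the total number of (call, probe) incidences
        for _ in range(10):
            calls, positions = random_call_instance(rng)
            probes = ProbeMap({"1": positions})
            track = cr.cover_track(calls, probes)["1"]
            incidences = sum(
                int(np.sum((positions >= row.start_bp)
                           & (positions <= row.end_bp)))
                for row in calls.itertuples())
            assert int(track.values.sum()) == incidences


class TestCompositeThreshold:
    def test_zero_heavy_pool_gives_zero_below_zero_fraction(self):
        track = ProbeTrack("1", "combined", "composite",
                           np.array([0.0] * 9 + [5.0]))
        for pct in (0, 50, 89, 90):
            assert resolve_composite_threshold([track], pct) == 0.0

    def test_percentile_100_is_maximum(self):
        track = ProbeTrack("1", "combined", "composite",
                           np.array([0.0, 2.0, 7.0]))
        assert resolve_composite_threshold([track], 100) == 7.0

    def test_all_zero_tracks_resolve_to_zero(self):
        track = ProbeTrack("1", "combined", "composite", np.zeros(5))
        assert resolve_composite_threshold([track], 99) == 0.0

    def test_zero_threshold_keeps_only_covered_probes(self):
        # the "no filtering" regime: every probe touched by a call passes
        track = ProbeTrack("1", "combined", "composite",
                           np.array([0.0, 3.0, 0.0, 5.0]))
        probes = ProbeMap({"1": [10, 20, 30, 40]})
        regions = extract_regions(track, 0.0, probes,
                                  pd.DataFrame(columns=["sample_id",
                                                        "chromosome",
                                                        "start_bp", "end_bp",
                                                        "confidence"]),
                                  n_samples=1)
        assert [(r.first_probe, r.last_probe) for r in regions] == [(1, 1),
                                                                    (3, 3)]


class TestExtractRegions:
    @pytest.mark.parametrize("u,expected", [
        (3, [(2, 3), (5, 5)]),
        (1, [(1, 5)]),
        (4, []),
    ])
    def test_maximal_runs(self, u, expected):
        values = np.array([0, 1, 3, 3, 2, 3, 0], dtype=float)
        probes = ProbeMap({"1": (np.arange(7) + 1) * 100})
        track = ProbeTrack("1", "combined", "cover", values)
        calls = pd.DataFrame(columns=["sample_id", "chromosome", "start_bp",
                                      "end_bp", "confidence"])
        regions = extract_regions(track, u, probes, calls, n_samples=1)
        assert [(r.first_probe, r.last_probe) for r in regions] == expected

    def test_region_boundaries_are_probe_positions(self, cover_toy):
        calls, probes = cover_toy
        regions = cr.find_cover_regions(calls, probes, min_individuals=2)
        (region,) = regions
        assert (region.start_bp, region.end_bp) == (200, 400)
        assert region.supporting_samples == ("s1", "s2", "s3")
        assert region.frequency == 1.0
        assert region.median_confidence == 5.0

    def test_supporting_calls_respect_confidence_filter(self, cover_toy):
        calls, probes = cover_toy
        regions = cr.find_cover_regions(calls, probes, conf_cutoff=4.0,
                                        min_individuals=2)
        (region,) = regions
        # the confidence-1 call no longer qualifies
        assert region.supporting_samples == ("s1", "s2")

    def test_extraction_matches_run_length_oracle(self, rng):
        for _ in range(30):
            calls, positions = random_call_instance(rng)
            probes = ProbeMap({"1": positions})
            track = cr.cover_track(calls, probes)["1"]
            u = int(rng.integers(1, 5))
            got = [(r.first_probe, r.last_probe)
                   for r in extract_regions(track, u, probes, calls)]
            assert got == runs_oracle(track.values, u)


class TestMonotonicity:
    def test_raising_confidence_cutoff_never_raises_track(self, rng):
        for _ in range(10):
            calls, positions = random_call_instance(rng)
            probes = ProbeMap({"1": positions})
            c1, c2 = sorted(rng.uniform(0, 25, 2))
            low = cr.cover_track(calls, probes, c=c1)["1"].values
            high = cr.cover_track(calls, probes, c=c2)["1"].values
            assert (high <= low).all()

    def test_regions_at_higher_u_nest_in_lower_u(self, rng):
        for _ in range(10):
            calls, positions = random_call_instance(rng)
            probes = ProbeMap({"1": positions})
            at_u = cr.find_cover_regions(calls, probes, min_individuals=2,
                                         state_handling="combined")
            at_u1 = cr.find_cover_regions(calls, probes, min_individuals=3,
                                          state_handling="combined")
            for small in at_u1:
                parents = [big for big in at_u
                           if big.first_probe <= small.first_probe
                           and small.last_probe <= big.last_probe]
                assert len(parents) == 1

    def test_identical_inputs_identical_outputs(self, small_population):
        _, calls, _, _ = small_population
        a = cr.find_cover_regions(calls, min_individuals=3, conf_percentile=60)
        b = cr.find_cover_regions(calls.copy(), min_individuals=3,
                                  conf_percentile=60)
        assert a == b
        chroms = [int(r.chromosome) for r in a]
        assert chroms == sorted(chroms)


@given(st.lists(st.integers(min_value=0, max_value=5), min_size=1,
                max_size=40),
       st.integers(min_value=1, max_value=5))
def test_run_extraction_property(values, u):
    """Extracted runs exactly tile the above-threshold probe set."""
    arr = np.array(values, dtype=float)
    probes = ProbeMap({"1": (np.arange(len(arr)) + 1) * 10})
    track = ProbeTrack("1", "combined", "cover", arr)
    calls = pd.DataFrame(columns=["sample_id", "chromosome", "start_bp",
                                  "end_bp", "confidence"])
    regions = extract_regions(track, u, probes, calls, n_samples=1)
    covered = sorted(i for r in regions
                     for i in range(r.first_probe, r.last_probe + 1))
    assert covered == [i for i, v in enumerate(arr) if v >= u]
    for r in regions:  # maximality
        assert r.first_probe == 0 or arr[r.first_probe - 1] < u
        assert r.last_probe == len(arr) - 1 or arr[r.last_probe + 1] < u
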