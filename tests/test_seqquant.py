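"""Quantification stages: subsampling, coverage, ratio tracks, binning,
reference-peak selection, RPA normalization, and front estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resectquant.core import Genome, Peak, PeakSet, RatioTrack, ReadSet, StrandCoverage
from resectquant.seqquant import (
    QuantConfig,
    bin_dsb_window,
    coverage_from_reads,
    estimate_resection_front,
    intersect_across_samples,
    rpa_normalize,
    rpa_window_profile,
    select_reference_peaks,
    slice_reference_peaks,
    subsample_to_common_depth,
    t0_ratio,
)
from resectquant.sim import (
    LibraryParams,
    ResectionModel,
    render_rpa_chip,
    render_total_dna,
    simulate_population,
)

X0 = 100_000


def make_reads(n, name="s", seed=0, chrom_len=1000):
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, chrom_len - 50, size=n)
    return ReadSet(
        reads=pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 50,
                "strand": rng.choice(["+", "-"], size=n),
            }
        ),
        name=name,
    )


def coverage_from_arrays(fwd, rev):
    fwd = np.asarray(fwd, dtype=float)
    genome = Genome({"chr1": len(fwd)})
    return StrandCoverage(
        genome=genome, fwd={"chr1": fwd}, rev={"chr1": np.asarray(rev, dtype=float)}
    )


class TestSubsample:
    def test_all_outputs_at_minimum_depth(self):
        samples = [make_reads(n, seed=i) for i, n in enumerate([100, 60, 80])]
        out = subsample_to_common_depth(samples, seed=0)
        assert [len(s) for s in out] == [60, 60, 60]

    def test_outputs_are_subsets_of_inputs(self):
        samples = [make_reads(n, seed=i) for i, n in enumerate([100, 60])]
        out = subsample_to_common_depth(samples, seed=1)
        orig = set(map(tuple, samples[0].reads.itertuples(index=False)))
        sub = set(map(tuple, out[0].reads.itertuples(index=False)))
        assert sub <= orig

    def test_single_sample_unchanged(self):
        s = make_reads(40)
        (out,) = subsample_to_common_depth([s], seed=0)
        pd.testing.assert_frame_equal(out.reads, s.reads)

    def test_seed_determinism_and_variation(self):
        samples = [make_reads(200, seed=0), make_reads(50, seed=1)]
        a = subsample_to_common_depth(samples, seed=5)
        b = subsample_to_common_depth(samples, seed=5)
        c = subsample_to_common_depth(samples, seed=6)
        pd.testing.assert_frame_equal(a[0].reads, b[0].reads)
        assert len(c[0]) == 50
        assert not a[0].reads.equals(c[0].reads)

    def test_empty_sample_named_in_error(self):
        empty = ReadSet(
            reads=pd.DataFrame(columns=["chrom", "start", "end", "strand"]),
            name="empty-one",
        )
        with pytest.raises(ValueError, match="empty-one"):
            subsample_to_common_depth([make_reads(10), empty], seed=0)


class TestCoverageFromReads:
    def test_single_read_pileup(self):
        genome = Genome({"chr1": 100})
        rs = ReadSet(
            reads=pd.DataFrame(
                {"chrom": ["chr1"], "start": [10], "end": [15], "strand": ["+"]}
            )
        )
        cov = coverage_from_reads(rs, genome)
        expected = np.zeros(100)
        expected[10:15] = 1
        assert np.array_equal(cov.fwd["chr1"], expected)
        assert np.all(cov.rev["chr1"] == 0)

    def test_overlapping_reads_sum(self):
        genome = Genome({"chr1": 20})
        rs = ReadSet(
            reads=pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 5],
                    "end": [10, 15],
                    "strand": ["+", "+"],
                }
            )
        )
        cov = coverage_from_reads(rs, genome)
        expected = np.array([1] * 5 + [2] * 5 + [1] * 5 + [0] * 5, dtype=float)
        assert np.array_equal(cov.fwd["chr1"], expected)

    def test_empty_readset_gives_zero_coverage(self):
        genome = Genome({"chr1": 50})
        rs = ReadSet(reads=pd.DataFrame(columns=["chrom", "start", "end", "strand"]))
        cov = coverage_from_reads(rs, genome)
        assert np.all(cov.fwd["chr1"] == 0) and np.all(cov.rev["chr1"] == 0)

    def test_score_filter_drops_low_quality(self):
        genome = Genome({"chr1": 50})
        rs = ReadSet(
            reads=pd.DataFrame(
                {
                    "chrom": ["chr1"] * 3,
                    "start": [0, 10, 20],
                    "end": [5, 15, 25],
                    "strand": ["+"] * 3,
                    "score": [10, 30, 50],
                }
            )
        )
        cov = coverage_from_reads(rs, genome, min_score=30)
        assert cov.fwd["chr1"].sum() == 10  # two 5-bp reads retained

    def test_out_of_bounds_read_rejected(self):
        genome = Genome({"chr1": 10})
        rs = ReadSet(
            reads=pd.DataFrame(
                {"chrom": ["chr1"], "start": [5], "end": [15], "strand": ["+"]}
            )
        )
        with pytest.raises(ValueError, match="outside"):
            coverage_from_reads(rs, genome)


class TestT0Ratio:
    def test_identical_tracks_give_unity(self):
        cov = coverage_from_arrays([2, 4, 8], [1, 1, 1])
        ratio = t0_ratio(cov, cov)
        assert np.allclose(ratio.fwd["chr1"], 1.0)

    def test_halved_coverage_gives_half(self):
        a = coverage_from_arrays([1, 2, 3], [2, 2, 2])
        b = coverage_from_arrays([2, 4, 6], [4, 4, 4])
        ratio = t0_ratio(a, b)
        assert np.allclose(ratio.fwd["chr1"], 0.5)
        assert np.allclose(ratio.rev["chr1"], 0.5)

    def test_zero_denominator_masks_position(self):
        a = coverage_from_arrays([5, 5], [0, 0])
        b = coverage_from_arrays([1, 0], [1, 1])
        ratio = t0_ratio(a, b)
        assert ratio.fwd["chr1"][0] == 5.0
        assert np.isnan(ratio.fwd["chr1"][1])

    def test_genome_mismatch_rejected(self):
        a = coverage_from_arrays([1, 1], [1, 1])
        g2 = Genome({"chr1": 3})
        b = StrandCoverage.zeros(g2)
        with pytest.raises(ValueError, match="different genomes"):
            t0_ratio(a, b)


def ratio_track_on_dsb_chrom(values_fwd, values_rev, length=200_000):
    genome = Genome({"chrSim": length})
    return RatioTrack(
        genome=genome,
        fwd={"chrSim": np.asarray(values_fwd, dtype=float)},
        rev={"chrSim": np.asarray(values_rev, dtype=float)},
    )


class TestBinDsbWindow:
    cfg = QuantConfig(dsb_chrom="chrSim", dsb_pos=X0)

    def test_constant_ratio_gives_constant_bins(self):
        track = ratio_track_on_dsb_chrom(np.ones(200_000), np.ones(200_000))
        profile = bin_dsb_window(track, self.cfg)
        assert len(profile.fwd) == 10
        assert np.allclose(profile.fwd, 1.0)
        assert np.allclose(profile.rev, 1.0)

    def test_step_ratio_bins_resolve_the_step(self):
        fwd = np.ones(200_000)
        fwd[X0 : X0 + 4000] = 0.0
        track = ratio_track_on_dsb_chrom(fwd, np.ones(200_000))
        profile = bin_dsb_window(track, self.cfg)
        right = profile.fwd[profile.centers > 0]
        assert np.allclose(right, [0, 0, 1, 1, 1])

    def test_fully_masked_bin_is_nan_others_unaffected(self):
        fwd = np.ones(200_000)
        fwd[X0 : X0 + 2000] = np.nan
        track = ratio_track_on_dsb_chrom(fwd, np.ones(200_000))
        profile = bin_dsb_window(track, self.cfg)
        right = profile.fwd[profile.centers > 0]
        assert np.isnan(right[0])
        assert np.allclose(right[1:], 1.0)

    def test_window_beyond_chromosome_rejected(self):
        track = ratio_track_on_dsb_chrom(np.ones(15_000), np.ones(15_000), length=15_000)
        cfg = QuantConfig(dsb_chrom="chrSim", dsb_pos=5_000)
        with pytest.raises(ValueError, match="exceeds chromosome"):
            bin_dsb_window(track, cfg)


def brute_force_peaks(summed, multiplier, width_bounds, exclude=None):
    """Position-by-position threshold scan (independent oracle)."""
    threshold = multiplier * np.median(summed)
    peaks = []
    start = None
    for i, v in enumerate(list(summed) + [-np.inf]):
        if v >= threshold and start is None:
            start = i
        elif v < threshold and start is not None:
            peaks.append((start, i))
            start = None
    out = []
    for s, e in peaks:
        if not width_bounds[0] <= e - s <= width_bounds[1]:
            continue
        if exclude is not None and s < exclude[1] and exclude[0] < e:
            continue
        out.append((s, e))
    return out


class TestSliceReferencePeaks:
    def test_narrow_run_kept_or_discarded_by_width_bounds(self):
        summed = np.array([1, 1, 1, 10, 10, 10, 1, 1, 1, 1], dtype=float)
        cov = coverage_from_arrays(summed, np.zeros(10))
        loose = QuantConfig(dsb_chrom="chr1", dsb_pos=5, peak_width_bounds=(1, 500))
        found = slice_reference_peaks(cov, loose)
        assert [(p.start, p.end) for p in found] == [(3, 6)]
        strict = QuantConfig(dsb_chrom="chr1", dsb_pos=5)
        assert len(slice_reference_peaks(cov, strict)) == 0

    def test_subthreshold_coverage_gives_no_peaks(self):
        cov = coverage_from_arrays(np.full(1000, 2.0), np.zeros(1000))
        cfg = QuantConfig(dsb_chrom="chr1", dsb_pos=500)
        assert len(slice_reference_peaks(cov, cfg)) == 0

    def test_zero_median_is_degenerate(self):
        cov = coverage_from_arrays(np.zeros(100), np.zeros(100))
        cfg = QuantConfig(dsb_chrom="chr1", dsb_pos=50)
        with pytest.raises(ValueError, match="median"):
            slice_reference_peaks(cov, cfg)

    def test_exclusion_window_removes_dsb_proximal_runs(self):
        summed = np.full(2000, 1.0)
        summed[100:300] = 50.0
        summed[1000:1200] = 50.0
        cov = coverage_from_arrays(summed, np.zeros(2000))
        cfg = QuantConfig(dsb_chrom="chr1", dsb_pos=1100)
        found = slice_reference_peaks(cov, cfg, exclude=("chr1", 900, 1300))
        assert [(p.start, p.end) for p in found] == [(100, 300)]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(200, 10_000))
        summed = rng.poisson(3.0, size=length).astype(float)
        n_spikes = int(rng.integers(0, 5))
        for _ in range(n_spikes):
            s = int(rng.integers(0, length))
            w = int(rng.integers(1, 800))
            summed[s : s + w] += rng.integers(10, 60)
        if np.median(summed) == 0:
            summed += 1
        cov = coverage_from_arrays(summed, np.zeros(length))
        cfg = QuantConfig(dsb_chrom="chr1", dsb_pos=1, peak_width_bounds=(100, 500))
        found = [(p.start, p.end) for p in slice_reference_peaks(cov, cfg)]
        assert found == brute_force_peaks(summed, 6.0, (100, 500))


class TestIntersectAcrossSamples:
    def test_identical_sets_return_anchor(self):
        ps = PeakSet([Peak("chr1", 0, 200), Peak("chr1", 1000, 1300)])
        out = intersect_across_samples([ps, ps, ps])
        assert [(p.start, p.end) for p in out] == [(0, 200), (1000, 1300)]

    def test_disjoint_sets_give_empty_result(self):
        a = PeakSet([Peak("chr1", 0, 100)])
        b = PeakSet([Peak("chr1", 500, 600)])
        assert len(intersect_across_samples([a, b])) == 0

    def test_single_bp_overlap_retains_anchor_peak(self):
        anchor = PeakSet([Peak("chr1", 0, 200), Peak("chr1", 1000, 1300)])
        other = PeakSet([Peak("chr1", 150, 250)])
        out = intersect_across_samples([anchor, other])
        assert [(p.start, p.end) for p in out] == [(0, 200)]

    def test_different_chromosomes_never_overlap(self):
        a = PeakSet([Peak("chr1", 0, 100)])
        b = PeakSet([Peak("chr2", 0, 100)])
        assert len(intersect_across_samples([a, b])) == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            intersect_across_samples([])


class TestRpaNormalize:
    def test_constant_coverage_in_peaks_sets_scale(self):
        cov = coverage_from_arrays(np.full(1000, 3.0), np.full(1000, 4.0))
        refs = PeakSet([Peak("chr1", 100, 300)])
        _, scale = rpa_normalize(cov, refs)
        assert scale == pytest.approx(7.0)

    def test_scale_invariance_to_global_multiplication(self):
        rng = np.random.default_rng(0)
        fwd = rng.poisson(5, 2000).astype(float)
        rev = rng.poisson(5, 2000).astype(float)
        cov = coverage_from_arrays(fwd, rev)
        refs = PeakSet([Peak("chr1", 100, 400), Peak("chr1", 1500, 1700)])
        base, _ = rpa_normalize(cov, refs)
        for c in (0.1, 3.0, 1000.0):
            scaled, _ = rpa_normalize(cov.scaled(c), refs)
            np.testing.assert_allclose(
                scaled.fwd["chr1"], base.fwd["chr1"], rtol=1e-12
            )

    def test_two_peak_arithmetic(self):
        cov = coverage_from_arrays([10, 10, 0, 0, 30, 30], [0, 0, 0, 0, 0, 0])
        refs = PeakSet([Peak("chr1", 0, 2), Peak("chr1", 4, 6)])
        normalized, scale = rpa_normalize(cov, refs)
        assert scale == pytest.approx(20.0)
        summed = normalized.fwd["chr1"] + normalized.rev["chr1"]
        np.testing.assert_allclose(summed, [0.5, 0.5, 0, 0, 1.5, 1.5])

    def test_empty_refpeaks_rejected(self):
        cov = coverage_from_arrays([1, 1], [1, 1])
        with pytest.raises(ValueError, match="empty"):
            rpa_normalize(cov, PeakSet([]))


class TestRpaWindowProfile:
    cfg = QuantConfig(dsb_chrom="chrSim", dsb_pos=X0)

    def test_flat_track_gives_unit_bins(self):
        track = ratio_track_on_dsb_chrom(np.ones(200_000), np.ones(200_000))
        profile = rpa_window_profile(track, self.cfg)
        assert len(profile.fwd) == 100
        assert np.allclose(profile.fwd, 1.0)

    def test_reverse_strand_enrichment_localizes_right_of_break(self, spec):
        lib = LibraryParams(
            mean_depth=50, chip_enrichment=40, uniform_background=2, noise="none"
        )
        model = ResectionModel(cut_efficiency=1.0, speed_mean=4000, speed_cv=0.0)
        truth = simulate_population(spec, model, t=2.0, n_cells=10, seed=0)
        cov = render_rpa_chip(truth, spec, lib)
        refs = PeakSet([Peak("chrSim", 10_000, 10_300)])
        normalized, _ = rpa_normalize(cov, refs)
        profile = rpa_window_profile(normalized, self.cfg)
        right = profile.centers > 0
        baseline = profile.fwd[right].mean()
        assert profile.rev[right][:10].mean() > 3 * baseline

    def test_profile_area_grows_with_time(self, spec):
        lib = LibraryParams(
            mean_depth=50, chip_enrichment=40, uniform_background=2, noise="none"
        )
        model = ResectionModel(cut_efficiency=0.9, speed_mean=4000, speed_cv=0.3)
        areas = []
        for t in (2.0, 4.0):
            truth = simulate_population(spec, model, t, n_cells=2000, seed=1)
            cov = render_rpa_chip(truth, spec, lib)
            refs = PeakSet([Peak("chrSim", 10_000, 10_300)])
            normalized, _ = rpa_normalize(cov, refs)
            profile = rpa_window_profile(normalized, self.cfg)
            right = profile.centers > 0
            areas.append(np.nansum(profile.rev[right]))
        assert areas[1] > areas[0]


class TestEstimateResectionFront:
    cfg = QuantConfig(
        dsb_chrom="chrSim", dsb_pos=X0, total_half_width=24_000, total_bin_width=2_000
    )

    def test_no_loss_means_no_front(self):
        track = ratio_track_on_dsb_chrom(np.ones(200_000), np.ones(200_000))
        profile = bin_dsb_window(track, self.cfg)
        assert estimate_resection_front(profile, "right") is None

    def test_step_at_eight_kb_recovered_within_half_bin(self):
        fwd = np.ones(200_000)
        fwd[X0 : X0 + 8000] = 0.0
        track = ratio_track_on_dsb_chrom(fwd, np.ones(200_000))
        profile = bin_dsb_window(track, self.cfg)
        front = estimate_resection_front(profile, "right")
        assert front == pytest.approx(8000, abs=1000)

    def test_left_side_uses_reverse_strand(self):
        rev = np.ones(200_000)
        rev[X0 - 6000 : X0] = 0.0
        track = ratio_track_on_dsb_chrom(np.ones(200_000), rev)
        profile = bin_dsb_window(track, self.cfg)
        front = estimate_resection_front(profile, "left")
        assert front == pytest.approx(6000, abs=1000)

    def test_recovers_simulated_median_extent(self, spec):
        model = ResectionModel(cut_efficiency=0.9, speed_mean=4000, speed_cv=0.3)
        lib = LibraryParams(mean_depth=50, noise="poisson", seed=2)
        truth = simulate_population(spec, model, t=2.0, n_cells=2000, seed=2)
        t0_truth = simulate_population(spec, model, t=0.0, n_cells=2000, seed=3)
        ratio = t0_ratio(
            render_total_dna(truth, spec, lib), render_total_dna(t0_truth, spec, lib)
        )
        front = estimate_resection_front(bin_dsb_window(ratio, self.cfg), "right")
        assert front == pytest.approx(truth.median_extent("right"), rel=0.10)

    def test_fully_masked_profile_rejected(self):
        track = ratio_track_on_dsb_chrom(
            np.full(200_000, np.nan), np.full(200_000, np.nan)
        )
        profile = bin_dsb_window(track, self.cfg)
        with pytest.raises(ValueError, match="masked"):
            estimate_resection_front(profile, "right")


class TestSelectReferencePeaks:
    def test_pooled_anchor_requires_support_in_every_sample(self, spec_with_peaks):
        lib_a = LibraryParams(
            mean_depth=50, chip_enrichment=40, uniform_background=2, noise="none"
        )
        from resectquant.sim import ResectionTruth

        truth = ResectionTruth(
            spec=spec_with_peaks,
            cut=np.zeros(2, dtype=bool),
            left_extent=np.zeros(2),
            right_extent=np.zeros(2),
            time=0.0,
        )
        cov_a = render_rpa_chip(truth, spec_with_peaks, lib_a)
        cov_b = render_rpa_chip(truth, spec_with_peaks, lib_a).scaled(2.0)
        cfg = QuantConfig(dsb_chrom="chrSim", dsb_pos=X0)
        refs = select_reference_peaks(
            [cov_a, cov_b], cfg, exclude=("chrSim", 50_000, 150_000)
        )
        assert len(refs) == 3
        for peak, center in zip(refs, (20_000, 40_000, 170_000)):
            assert peak.start <= center < peak.end
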