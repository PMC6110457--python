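"""Sawtooth detector: pre-processing, regression, MCMC, peaks, FDR."""

import collections
import math

import numpy as np
import pytest

from ratchetsplice.model import Intron
from ratchetsplice.ratchet_scan import (
    DEFAULT_TEMPERATURE,
    ProfileError,
    SiteProbabilityTrack,
    _FitCache,
    _score_region,
    acceptance_probability,
    call_peaks,
    estimate_sawtooth_fdr,
    flank_potential,
    heteroscedastic_regression,
    jump_fold,
    mask_repeats,
    mcmc_sawtooth,
    preprocess_coverage,
    shuffle_regions,
    state_bic,
    threshold_regions,
)
from ratchetsplice.synthetic_data import (
    SimulatedIntronSpec,
    simulate_sawtooth_coverage,
)


def _intron(length, chrom="chr", start=0):
    return Intron(chrom, start, start + length, "+", "g")


class TestPreprocess:
    def test_constant_coverage_bins(self):
        prof = preprocess_coverage(np.full(10_000, 10.0), _intron(10_000))
        assert prof.n_bins == 100
        assert np.allclose(prof.bins, 10.0)

    def test_short_intron_rejected(self):
        with pytest.raises(ProfileError, match="8000"):
            preprocess_coverage(np.full(5000, 10.0), _intron(5000))

    def test_no_spanning_read_rejected(self):
        with pytest.raises(ProfileError, match="spanning"):
            preprocess_coverage(
                np.full(10_000, 10.0), _intron(10_000), spanning_reads=0
            )

    def test_repeat_masking_replaces_spike_with_flanking_median(self):
        counts = np.full(10_000, 10.0)
        counts[5100] = 1000.0  # spike inside the repeat
        masked = mask_repeats(counts, [(5000, 5300)])
        assert np.allclose(masked[4900:5400], 10.0)  # repeat + 100-nt flanks
        assert masked[4899] == 10.0

    def test_bins_match_brute_force(self):
        # oracle: direct mean/median recomputation
        rng = np.random.default_rng(4)
        counts = rng.poisson(20, 9050).astype(float)
        repeats = [(3000, 3250)]
        exons = [(6000, 6100)]
        prof = preprocess_coverage(
            counts, _intron(9050), repeats=repeats, exons=exons
        )
        expected = counts.copy()
        ctx = np.concatenate(
            [counts[2900 - 900 : 2900], counts[3350 : 3350 + 900]]
        )
        expected[2900:3350] = np.median(ctx)
        kept = np.r_[expected[:6000], expected[6100:]]
        n_bins = math.ceil(len(kept) / 100)
        brute = [kept[b * 100 : (b + 1) * 100].mean() for b in range(n_bins)]
        assert prof.n_bins == n_bins
        assert np.allclose(prof.bins, brute)

    def test_binned_length_is_ceiling(self):
        prof = preprocess_coverage(np.full(10_050, 5.0), _intron(10_050))
        assert prof.n_bins == math.ceil(10_050 / 100)


class TestHeteroscedasticRegression:
    def test_noiseless_line_is_fixed_point(self):
        y = 100.0 - 0.01 * np.arange(200)
        fit = heteroscedastic_regression(y)
        assert fit.slope == pytest.approx(-0.01, abs=1e-12)
        assert fit.intercept == pytest.approx(100.0, abs=1e-9)
        assert fit.iterations <= 2
        assert fit.rss == pytest.approx(0.0, abs=1e-15)

    def test_constant_array(self):
        fit = heteroscedastic_regression(np.full(50, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(7.0)

    def test_poisson_noise_estimates_near_true_weight_wls(self):
        # oracle: closed-form WLS using the true-mean weights
        rng = np.random.default_rng(8)
        x = np.arange(150, dtype=float)
        mean = 200.0 - 1.0 * x
        y = rng.poisson(mean).astype(float)
        fit = heteroscedastic_regression(y)
        w = 1.0 / mean
        sw, sx, sy = w.sum(), (w * x).sum(), (w * y).sum()
        sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
        denom = sw * sxx - sx**2
        slope_o = (sw * sxy - sx * sy) / denom
        intercept_o = (sy * sxx - sx * sxy) / denom
        se_slope = math.sqrt(sw / denom)
        se_int = math.sqrt(sxx / denom)
        assert abs(fit.slope - slope_o) < 3 * se_slope
        assert abs(fit.intercept - intercept_o) < 3 * se_int

    def test_single_bin_segment_rejected(self):
        with pytest.raises(ValueError):
            heteroscedastic_regression(np.array([5.0]))


class TestAcceptanceRule:
    def test_ratio_matches_hand_computed_boltzmann(self):
        # oracle: direct arithmetic on two fixed states of a small array
        rng = np.random.default_rng(1)
        spec = SimulatedIntronSpec(10_000, (5000,), (40.0, 40.0))
        counts, _ = simulate_sawtooth_coverage(spec, seed=1)
        cache = _FitCache(
            np.array([counts[b : b + 100].mean() for b in range(0, 10_000, 100)])
        )
        bic_good = state_bic(cache, (50,), 10_000)
        bic_bad = state_bic(cache, (), 10_000)
        assert bic_good < bic_bad  # the planted split fits better
        p = acceptance_probability(bic_good, bic_bad)
        assert p == math.exp(-(bic_bad - bic_good) / DEFAULT_TEMPERATURE)
        assert acceptance_probability(bic_bad, bic_good) == 1.0

    def test_leaving_zero_state_halves_probability(self):
        p = acceptance_probability(100.0, 101.0)
        p_half = acceptance_probability(100.0, 101.0, leaving_zero_state=True)
        assert p_half == pytest.approx(p / 2)


class TestMcmc:
    def test_null_profile_stays_near_zero_sites(self):
        spec = SimulatedIntronSpec(12_000, (), (30.0,))
        counts, _ = simulate_sawtooth_coverage(spec, seed=21)
        prof = preprocess_coverage(counts, _intron(12_000))
        track = mcmc_sawtooth(prof, 50_000, 5_000, 50, seed=22)
        assert track.probs.max() < 0.08

    def test_planted_site_recovered_and_matches_bic_oracle(self):
        spec = SimulatedIntronSpec(14_000, (7000,), (30.0, 30.0))
        counts, _ = simulate_sawtooth_coverage(spec, seed=23)
        prof = preprocess_coverage(counts, _intron(14_000))
        track = mcmc_sawtooth(prof, 100_000, 10_000, 50, seed=24)
        best_bin = int(track.probs.argmax())
        assert abs(best_bin - 70) <= 5
        assert track.probs[best_bin] > 0.08
        # oracle: exhaustive BIC over all 0- and 1-site models
        cache = _FitCache(prof.bins)
        candidates = {(): state_bic(cache, (), prof.length_nt)}
        for s in range(2, prof.n_bins - 1):
            bic = state_bic(cache, (s,), prof.length_nt)
            if bic is not None:
                candidates[(s,)] = bic
        oracle_state = min(candidates, key=candidates.get)
        assert oracle_state != ()
        assert abs(oracle_state[0] - best_bin) <= 5

    def test_track_sums_to_mean_sites_per_sample(self):
        spec = SimulatedIntronSpec(10_000, (5000,), (30.0, 30.0))
        counts, _ = simulate_sawtooth_coverage(spec, seed=25)
        prof = preprocess_coverage(counts, _intron(10_000))
        track = mcmc_sawtooth(prof, 60_000, 6_000, 50, seed=26)
        assert track.mean_sites_per_sample() == pytest.approx(
            np.mean(track.size_trace)
        )

    def test_state_size_distribution_stable_between_thirds(self):
        # detailed-balance sanity on a null profile
        spec = SimulatedIntronSpec(10_000, (), (30.0,))
        counts, _ = simulate_sawtooth_coverage(spec, seed=27)
        prof = preprocess_coverage(counts, _intron(10_000))
        track = mcmc_sawtooth(prof, 120_000, 20_000, 50, seed=28)
        trace = track.size_trace
        third = len(trace) // 3
        second, last = trace[third : 2 * third], trace[2 * third : 3 * third]
        sizes = set(second) | set(last)
        tv = 0.5 * sum(
            abs(
                second.count(s) / len(second) - last.count(s) / len(last)
            )
            for s in sizes
        )
        assert tv < 0.05


class TestPeakCalling:
    def test_flank_potential_reference_values(self):
        assert flank_potential(-500, 0, 1000) == pytest.approx(0.5)
        assert flank_potential(1500, 0, 1000) == pytest.approx(0.5)
        assert flank_potential(500, 0, 1000) == 1.0
        assert flank_potential(-1000, 0, 1000) < 0.01
        assert flank_potential(2000, 0, 1000) < 0.01

    def test_all_zero_track_gives_no_peaks(self, study_env):
        annotation, genome, _, pwm = study_env
        intron = annotation.introns[0]
        counts = np.full(intron.length, 10.0)
        prof = preprocess_coverage(counts, intron)
        track = SiteProbabilityTrack(np.zeros(prof.n_bins), 100, 100)
        assert call_peaks(track, prof, genome, pwm) == []

    def test_region_merging_within_500(self):
        probs = np.zeros(100)
        probs[10:12] = 0.5
        probs[15:16] = 0.5  # 300 nt gap -> merged
        probs[40:41] = 0.5  # far -> separate
        track = SiteProbabilityTrack(probs, 100, 100)
        assert threshold_regions(track) == [(1000, 1600), (4000, 4100)]

    def test_winner_matches_brute_force_site_score(self):
        # region [2000, 2600); in-region AGGT M=0.95 vs one 800 nt away M=0.99
        track = SiteProbabilityTrack(np.zeros(100), 100, 100)
        region = (2000, 2600)
        candidates = [
            (2300, 2300, 0.95, "w1"),
            (3400, 3400, 0.99, "w2"),
        ]
        peak = _score_region(region, candidates, track)
        s_inside = 1.0 * (0.95 - 0.8)
        s_outside = flank_potential(3400, *region) * (0.99 - 0.8)
        assert peak.site == (2300 if s_inside > s_outside else 3400)
        assert peak.score == pytest.approx(max(s_inside, s_outside))

    def test_region_without_scoring_aggt_dropped(self):
        track = SiteProbabilityTrack(np.zeros(100), 100, 100)
        assert _score_region((2000, 2600), [(2300, 2300, 0.5, "w")], track) is None


class TestFdr:
    def test_shuffles_preserve_count_and_lengths(self):
        rng = np.random.default_rng(31)
        regions = [(100, 600), (4000, 4200), (7000, 7100)]
        for _ in range(1000):
            shuffled = shuffle_regions(regions, 10_000, rng)
            assert len(shuffled) == len(regions)
            assert sorted(hi - lo for lo, hi in shuffled) == sorted(
                hi - lo for lo, hi in regions
            )
            assert all(0 <= lo and hi <= 10_000 for lo, hi in shuffled)

    def test_zero_observed_regions_gives_empty(self, study_env):
        annotation, genome, _, pwm = study_env
        intron = annotation.introns[0]
        prof = preprocess_coverage(np.full(intron.length, 10.0), intron)
        track = SiteProbabilityTrack(np.zeros(prof.n_bins), 100, 100)
        assert estimate_sawtooth_fdr(track, prof, genome, pwm) == []

    def test_planted_site_attains_low_fdr(self, study, study_env):
        annotation, genome, _, pwm = study_env
        gene = next(g for g in study.genes if g.site is not None)
        intron = next(i for i in annotation.introns if i.gene_id == gene.id)
        prof = preprocess_coverage(study.coverage[gene.id], intron)
        track = mcmc_sawtooth(prof, 100_000, 10_000, 50, seed=33)
        peaks = estimate_sawtooth_fdr(
            track, prof, genome, pwm, n_shuffles=50, seed=34
        )
        (peak,) = peaks
        assert peak.site == gene.site
        assert peak.fdr <= 0.05


def test_jump_fold_detects_planted_jump():
    spec = SimulatedIntronSpec(12_000, (6000,), (30.0, 30.0))
    counts, _ = simulate_sawtooth_coverage(spec, seed=35)
    prof = preprocess_coverage(counts, _intron(12_000))
    assert jump_fold(prof, 60) >= 1.5
    spec0 = SimulatedIntronSpec(12_000, (), (30.0,))
    counts0, _ = simulate_sawtooth_coverage(spec0, seed=36)
    prof0 = preprocess_coverage(counts0, _intron(12_000))
    assert jump_fold(prof0, 60) < 1.5
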