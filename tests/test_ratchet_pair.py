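"""Spanning-pair selection, fragment-length distribution, EM inference."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from ratchetsplice.genome_io import load_annotation
from ratchetsplice.model import AlignedRead, AlignedReadPair, ReadSegment
from ratchetsplice.ratchet_pair import (
    estimate_fragment_distribution,
    gem_infer_sites,
    pair_implied_insert,
    pooled_inserts,
    select_spanning_pairs,
)
from ratchetsplice.synthetic_data import simulate_read_pairs


def _pair(chrom, s1, e1, s2, e2):
    r1 = AlignedRead(chrom, s1, e1, (ReadSegment(chrom, s1, e1),))
    r2 = AlignedRead(chrom, s2, e2, (ReadSegment(chrom, s2, e2),))
    return AlignedReadPair(r1, r2)


LONG_INTRON_GFF = """\
##gff-version 3
chrL\t.\tgene\t1\t22000\t.\t+\t.\tID=gL
chrL\t.\tmRNA\t1\t22000\t.\t+\t.\tID=gL.t1;Parent=gL
chrL\t.\texon\t1\t1000\t.\t+\t.\tParent=gL.t1
chrL\t.\texon\t21001\t22000\t.\t+\t.\tParent=gL.t1
"""

SKIPPING_TRANSCRIPT = """\
chrL\t.\tmRNA\t1\t22000\t.\t+\t.\tID=gL.t2;Parent=gL
chrL\t.\texon\t1\t1000\t.\t+\t.\tParent=gL.t2
chrL\t.\texon\t20501\t22000\t.\t+\t.\tParent=gL.t2
"""


class TestSelectSpanningPairs:
    def test_pair_near_donor_and_deep_in_intron_kept(self):
        ann = load_annotation(LONG_INTRON_GFF)
        pair = _pair("chrL", 909, 960, 6000, 6051)  # ends 40 nt before the donor
        selected = select_spanning_pairs([pair], ann)
        (intron,) = selected
        assert selected[intron] == [pair]

    def test_read2_only_600_downstream_dropped(self):
        ann = load_annotation(LONG_INTRON_GFF)
        pair = _pair("chrL", 909, 960, 1509, 1560)
        assert select_spanning_pairs([pair], ann) == {}

    def test_pair_explained_by_annotated_event_dropped(self):
        ann = load_annotation(LONG_INTRON_GFF + SKIPPING_TRANSCRIPT)
        # completion of the gL.t2 intron [1000, 20500) implies insert
        # (20651 - 909) - 19500 = 242 < 1000
        pair = _pair("chrL", 909, 960, 20600, 20651)
        assert select_spanning_pairs([pair], ann) == {}

    def test_exempted_cassette_event_does_not_drop(self):
        ann = load_annotation(LONG_INTRON_GFF + SKIPPING_TRANSCRIPT)
        pair = _pair("chrL", 909, 960, 20600, 20651)
        selected = select_spanning_pairs(
            [pair], ann, aggt_cassette_introns={("chrL", 1000, 20500)}
        )
        assert sum(len(v) for v in selected.values()) == 1


class TestFragmentDistribution:
    def test_point_mass(self):
        dist = estimate_fragment_distribution([300] * 50, bandwidth=0)
        assert dist.pmf(np.array(300)) == pytest.approx(1.0)
        assert dist.pmf(np.array(299)) == 0.0

    def test_two_bin_symmetric_histogram(self):
        dist = estimate_fragment_distribution([290] * 50 + [310] * 50, bandwidth=0)
        assert dist.pmf(np.array(290)) == pytest.approx(0.5)
        assert dist.pmf(np.array(310)) == pytest.approx(0.5)

    def test_sampled_mean_within_3_se(self):
        rng = np.random.default_rng(3)
        n = 10_000
        draws = rng.normal(300, 50, n).astype(int)
        dist = estimate_fragment_distribution(draws)
        assert abs(dist.mean() - 300) < 3 * 50 / math.sqrt(n)

    def test_pooled_inserts_subtract_annotated_gaps(self):
        ann = load_annotation(LONG_INTRON_GFF)
        pair = _pair("chrL", 900, 951, 21100, 21151)  # straddles the intron
        (insert,) = pooled_inserts([pair], ann)
        assert insert == (21151 - 900) - 20_000


class TestGemInference:
    def test_single_candidate_takes_all_mass(self):
        pairs = simulate_read_pairs(10, 1000, 5000, frag_sd=0, seed=0)
        dist = estimate_fragment_distribution([300] * 100, bandwidth=0)
        result = gem_infer_sites(pairs, {}, dist, [(5000, 0.95)], donor=1000)
        assert result.priors == pytest.approx([1.0])
        assert (result.map_assignments == 0).all()

    def test_low_motif_candidates_never_gain_prior(self):
        pairs = simulate_read_pairs(10, 1000, 5000, seed=0)
        dist = estimate_fragment_distribution(
            np.random.default_rng(0).normal(300, 50, 2000).astype(int)
        )
        result = gem_infer_sites(
            pairs, {}, dist, [(5000, 0.95), (6000, 0.5)], donor=1000
        )
        assert len(result.positions) == 1  # the M <= 0.8 candidate was dropped

    def test_two_candidates_map_matches_exact_bayes(self):
        # 200 pairs from site A; candidate B is 2 kb downstream
        A, B, donor = 20_000, 22_000, 1000
        pairs = simulate_read_pairs(200, donor, A, seed=5)
        rng = np.random.default_rng(6)
        dist = estimate_fragment_distribution(rng.normal(300, 50, 10_000).astype(int))
        result = gem_infer_sites(
            pairs, {}, dist, [(A, 0.95), (B, 0.95)], donor=donor
        )
        frac_to_A = (result.map_assignments == 0).mean()
        assert frac_to_A >= 0.95
        assert result.priors[0] > result.priors[1]
        # oracle: exact Bayes posterior under the true generating distribution
        agree = 0
        for n, pair in enumerate(pairs):
            like = [
                norm.pdf(pair_implied_insert(pair, donor, m, "+"), 300, 50)
                for m in (A, B)
            ]
            oracle = int(np.argmax(like))
            agree += oracle == result.map_assignments[n]
        assert agree / len(pairs) >= 0.95

    def test_impossible_inserts_collapse_to_empty(self):
        pairs = simulate_read_pairs(5, 1000, 5000, seed=1)
        dist = estimate_fragment_distribution([40] * 100, bandwidth=0)
        with pytest.warns(UserWarning, match="sparsified"):
            result = gem_infer_sites(
                pairs, {}, dist, [(5000, 0.9), (7000, 0.9)], donor=1000
            )
        assert result is None

    def test_no_candidate_warns(self):
        with pytest.warns(UserWarning, match="no candidate"):
            result = gem_infer_sites(
                [], {}, estimate_fragment_distribution([300]), [(5000, 0.5)], 1000
            )
        assert result is None

    def test_junction_reads_anchor_site(self):
        # junction evidence at A outweighs ambiguous pair evidence
        A, B = 20_000, 20_060
        pairs = simulate_read_pairs(4, 1000, A, seed=2)
        rng = np.random.default_rng(7)
        dist = estimate_fragment_distribution(rng.normal(300, 50, 10_000).astype(int))
        result = gem_infer_sites(
            pairs, {A: 30}, dist, [(A, 0.9), (B, 0.9)], donor=1000
        )
        assert result.priors[0] > result.priors[1]

    def test_likelihood_monotone_without_sparsity(self):
        A, B = 20_000, 21_500
        pairs = simulate_read_pairs(60, 1000, A, seed=9)
        rng = np.random.default_rng(10)
        dist = estimate_fragment_distribution(rng.normal(300, 50, 5_000).astype(int))
        result = gem_infer_sites(
            pairs, {}, dist, [(A, 0.95), (B, 0.9)], donor=1000,
            alpha_divisor=math.inf,
        )
        trace = result.log_likelihood_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_priors_sum_to_one(self):
        pairs = simulate_read_pairs(30, 1000, 20_000, seed=11)
        rng = np.random.default_rng(12)
        dist = estimate_fragment_distribution(rng.normal(300, 50, 5_000).astype(int))
        result = gem_infer_sites(
            pairs, {}, dist, [(20_000, 0.95), (22_000, 0.85)], donor=1000
        )
        assert result.priors.sum() == pytest.approx(1.0)

    def test_planted_site_recovery_over_seeds(self):
        # MAP site within +/-10 nt of the planted site in >=19 of 20 fixtures
        hits = 0
        base_rng = np.random.default_rng(99)
        dist = estimate_fragment_distribution(
            base_rng.normal(300, 50, 10_000).astype(int)
        )
        for seed in range(20):
            A = 20_000
            candidates = [(A - 1500, 0.9), (A, 0.9), (A + 1500, 0.9)]
            pairs = simulate_read_pairs(50, 1000, A, seed=1000 + seed)
            result = gem_infer_sites(pairs, {}, dist, candidates, donor=1000)
            if result is not None:
                best = result.positions[np.argmax(result.priors)]
                hits += abs(best - A) <= 10
        assert hits >= 19
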