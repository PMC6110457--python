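"""Sawtooth-pattern detection in intronic read density by MCMC.

Co-transcriptional excision of recursive segments leaves a characteristic
"sawtooth" in nascent-RNA coverage: linear decay across each segment with an
upward jump at each recursive site. This module bins repeat-masked intronic
coverage, explores recursive-site configurations with a round-based MCMC whose
states are scored by a BIC over segment-wise heteroscedastic linear fits,

    BIC(M) = L * RSS(M) + 2 * (2N) * log(L)

(L = intron length in nt, N = number of proposed sites, RSS = weighted sum of
squared deviations over all segments), converts sample frequencies into a
per-bin site-probability track, calls peaks with a logistic position
potential, scores candidate AG|GT boundaries by

    S(i) = P(i) * max(M(i) - 0.8, 0)

and quantifies an FDR from uniformly repositioned null regions.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .motif_scoring import SpliceSitePWM, score_site

DEFAULT_TEMPERATURE = 5.0
PROBABILITY_THRESHOLD = 0.08
MERGE_DISTANCE = 500
FLANK_X0 = 500
FLANK_K = 6 / 500


class ProfileError(ValueError):
    """Intron not eligible for sawtooth scanning (with the reason)."""


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Binned, repeat-masked intronic read density.

    `positions` maps each retained per-base index back to its offset within
    the intron (exon-overlapping sub-regions are excised, so the mapping can
    be non-contiguous); `bins` holds 100-nt bin means over the retained
    positions."""

    chrom: str
    start: int  # intron genomic start
    end: int
    strand: str
    bins: np.ndarray
    positions: np.ndarray  # retained per-base offsets within the intron
    bin_size: int = 100

    @property
    def length_nt(self) -> int:
        return len(self.positions)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_to_offset(self, b: float) -> int:
        """Intron-relative offset of (fractional) bin coordinate b."""
        idx = min(int(b * self.bin_size), self.length_nt - 1)
        return int(self.positions[idx])

    def offset_to_retained(self, offset: int) -> int:
        """Retained-coordinate position of an intron-relative offset."""
        return int(np.searchsorted(self.positions, offset))


def mask_repeats(
    counts: np.ndarray,
    repeats: list[tuple[int, int]],
    flank: int = 100,
    median_window: int = 900,
) -> np.ndarray:
    """Replace counts in repeat regions plus `flank` nt on each side with the
    median of the `median_window` nt flanking either side of the masked span."""
    out = counts.astype(float).copy()
    n = len(out)
    for start, end in repeats:
        lo, hi = max(start - flank, 0), min(end + flank, n)
        ctx = np.concatenate(
            [counts[max(lo - median_window, 0) : lo], counts[hi : hi + median_window]]
        )
        if len(ctx):
            out[lo:hi] = np.median(ctx)
    return out


def preprocess_coverage(
    counts: np.ndarray,
    intron,
    repeats: list[tuple[int, int]] = (),
    exons: list[tuple[int, int]] = (),
    spanning_reads: int = 1,
    min_length: int = 8000,
    min_spanning: int = 1,
    bin_size: int = 100,
) -> CoverageProfile:
    """Per-base intron counts -> masked, exon-excised, 100-nt-binned profile.

    Repeats/exons are intron-relative half-open intervals. Introns of at most
    `min_length` nt, or without a spanning splice-junction read, are rejected
    (short introns give a high sawtooth false-positive rate)."""
    if intron.length <= min_length:
        raise ProfileError(
            f"intron {intron.length} nt <= {min_length} nt: skipped "
            "(high false-positive rate in short introns)"
        )
    if spanning_reads < min_spanning:
        raise ProfileError("no spanning splice junction read: skipped")
    masked = mask_repeats(np.asarray(counts, dtype=float), list(repeats))
    keep = np.ones(len(masked), dtype=bool)
    for start, end in exons:
        keep[max(start, 0) : end] = False
    positions = np.nonzero(keep)[0]
    retained = masked[keep]
    n_bins = math.ceil(len(retained) / bin_size)
    bins = np.array(
        [retained[b * bin_size : (b + 1) * bin_size].mean() for b in range(n_bins)]
    )
    return CoverageProfile(
        intron.chrom, intron.start, intron.end, intron.strand, bins, positions, bin_size
    )


# ---------------------------------------------------------------------------
# heteroscedastic regression
# ---------------------------------------------------------------------------


@dataclass
class SegmentFit:
    slope: float
    intercept: float
    weights: np.ndarray
    rss: float
    iterations: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    if denom == 0:
        return 0.0, sy / sw if sw else 0.0
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy * sxx - sx * sxy) / denom
    return slope, intercept


def heteroscedastic_regression(
    y: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 200,
    weight_floor: float = 1e-6,
) -> SegmentFit:
    """Iteratively reweighted linear fit with Var(y) proportional to the mean.

    Weights are updated to 1 / predicted value each round (floored at
    `weight_floor` where the prediction is non-positive) and iteration stops
    once no weight changes by more than `tol`. The returned RSS is the
    weighted sum of squared deviations under the converged weights."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("segment must have at least 2 bins")
    x = np.arange(len(y), dtype=float)
    w = np.ones(len(y))
    slope = intercept = 0.0
    for it in range(1, max_iter + 1):
        slope, intercept = _wls(x, y, w)
        pred = intercept + slope * x
        w_next = np.where(pred > 0, 1.0 / np.maximum(pred, weight_floor), weight_floor)
        if np.abs(w_next - w).max() <= tol:
            w = w_next
            break
        w = w_next
    pred = intercept + slope * x
    rss = float((w * (y - pred) ** 2).sum())
    return SegmentFit(slope, intercept, w, rss, it)


# ---------------------------------------------------------------------------
# MCMC over site configurations
# ---------------------------------------------------------------------------


@dataclass
class SawtoothState:
    """A proposed configuration of recursive-site bin indices with its score."""

    sites: tuple[int, ...]
    rss: float
    bic: float

    def score(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        return math.exp(self.bic / temperature)


@dataclass
class SiteProbabilityTrack:
    """Per-bin probability of being a recursive site (sample frequencies)."""

    probs: np.ndarray
    n_samples: int
    bin_size: int
    size_trace: list[int] = field(default_factory=list)

    def mean_sites_per_sample(self) -> float:
        return float(self.probs.sum())


class _FitCache:
    """Memoized heteroscedastic fits per bin segment [a, b)."""

    def __init__(self, bins: np.ndarray):
        self.bins = bins
        self._cache: dict[tuple[int, int], tuple[float, float, float]] = {}

    def get(self, a: int, b: int) -> tuple[float, float, float]:
        """(rss, predicted value at segment start, predicted value at b)."""
        key = (a, b)
        hit = self._cache.get(key)
        if hit is None:
            fit = heteroscedastic_regression(self.bins[a:b])
            hit = (fit.rss, fit.intercept, fit.predict(b - a))
            self._cache[key] = hit
        return hit


def state_bic(
    cache: _FitCache,
    sites: tuple[int, ...],
    length_nt: int,
    min_fold: float = 1.5,
    min_seg_bins: int = 2,
) -> float | None:
    """BIC of a site configuration, or None when the configuration is invalid
    (a segment shorter than `min_seg_bins` bins, or a site whose downstream
    fitted density does not exceed the upstream boundary prediction by at
    least `min_fold`)."""
    n_bins = len(cache.bins)
    bounds = (0, *sites, n_bins)
    for a, b in zip(bounds, bounds[1:]):
        if b - a < min_seg_bins:
            return None
    total_rss = 0.0
    seg_fits = [cache.get(a, b) for a, b in zip(bounds, bounds[1:])]
    for k, s in enumerate(sites):
        up_pred = seg_fits[k][2]  # upstream fit extrapolated to the boundary
        down_pred = seg_fits[k + 1][1]  # downstream fit at its start
        if down_pred <= 0:
            return None
        if up_pred > 0 and down_pred < min_fold * up_pred:
            return None
    for rss, _, _ in seg_fits:
        total_rss += rss
    return length_nt * total_rss + 2 * (2 * len(sites)) * math.log(length_nt)


def acceptance_probability(
    bic_old: float,
    bic_new: float,
    leaving_zero_state: bool = False,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Metropolis acceptance for a proposed state.

    A lower-BIC proposal is adopted deterministically; otherwise adoption
    probability is exp(-(BIC_new - BIC_old)/T), halved when the current state
    has zero sites (transition-probability imbalance correction)."""
    if bic_new < bic_old:
        return 1.0
    p = math.exp(-(bic_new - bic_old) / temperature)
    if leaving_zero_state:
        p /= 2.0
    return p


def mcmc_sawtooth(
    profile: CoverageProfile,
    iterations: int = 10_000_000,
    burn_in: int = 100_000,
    sample_every: int = 50,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    min_fold: float = 1.5,
    min_seg_bins: int = 2,
    shift_max: int = 5,
    exclusion_bins: int = 10,
    p_add: float = 0.4,
    p_remove: float = 0.4,
) -> SiteProbabilityTrack:
    """Round-based MCMC over recursive-site configurations.

    Each round perturbs the current state (add a site with probability 0.4,
    remove with 0.4, shift one by 1-5 bins with 0.2), rejects proposals
    violating the 1.5-fold jump constraint outright, and otherwise applies the
    Metropolis rule on the BIC. States are sampled every `sample_every`
    rounds after `burn_in`; the returned track holds per-bin site sample
    frequencies. The chain starts from the empty (zero-site) state."""
    n_bins = profile.n_bins
    if n_bins < 2 * min_seg_bins:
        raise ProfileError(f"profile of {n_bins} bins is too short to segment")
    rng = random.Random(seed)
    cache = _FitCache(profile.bins)
    length_nt = profile.length_nt

    sites: tuple[int, ...] = ()
    cur_bic = state_bic(cache, sites, length_nt, min_fold, min_seg_bins)
    assert cur_bic is not None  # zero-site state is always valid

    site_counts = np.zeros(n_bins)
    n_samples = 0
    size_trace: list[int] = []

    for it in range(1, iterations + 1):
        u = rng.random()
        proposal: tuple[int, ...] | None = None
        if u < p_add:
            b = rng.randrange(n_bins)
            if all(abs(b - s) > exclusion_bins for s in sites):
                proposal = tuple(sorted((*sites, b)))
        elif u < p_add + p_remove:
            if sites:
                k = rng.randrange(len(sites))
                proposal = sites[:k] + sites[k + 1 :]
        else:
            if sites:
                k = rng.randrange(len(sites))
                delta = rng.choice((-1, 1)) * rng.randint(1, shift_max)
                moved = sites[k] + delta
                if 0 <= moved < n_bins and all(
                    abs(moved - s) > exclusion_bins
                    for i, s in enumerate(sites)
                    if i != k
                ):
                    proposal = tuple(sorted(sites[:k] + (moved,) + sites[k + 1 :]))

        if proposal is not None:
            new_bic = state_bic(cache, proposal, length_nt, min_fold, min_seg_bins)
            if new_bic is not None:
                p = acceptance_probability(
                    cur_bic, new_bic, leaving_zero_state=not sites,
                    temperature=temperature,
                )
                if p >= 1.0 or rng.random() < p:
                    sites, cur_bic = proposal, new_bic

        if it > burn_in and it % sample_every == 0:
            for s in sites:
                site_counts[s] += 1
            n_samples += 1
            size_trace.append(len(sites))

    probs = site_counts / n_samples if n_samples else site_counts
    return SiteProbabilityTrack(probs, n_samples, profile.bin_size, size_trace)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------


def flank_potential(x: float, lo: float, hi: float, x0: float = FLANK_X0,
                    k: float = FLANK_K) -> float:
    """Position potential of a called region [lo, hi) at position x (nt).

    1 inside the region; logistic decay outside with midpoints `x0` nt from
    each edge (value 0.5 exactly `x0` nt outside, near 0 at 2*x0)."""
    if lo <= x < hi:
        return 1.0
    if x < lo:
        return 1.0 / (1.0 + math.exp(-k * (x - (lo - x0))))
    return 1.0 / (1.0 + math.exp(k * (x - (hi + x0))))


def threshold_regions(
    track: SiteProbabilityTrack,
    threshold: float = PROBABILITY_THRESHOLD,
    merge_nt: int = MERGE_DISTANCE,
) -> list[tuple[int, int]]:
    """Contiguous above-threshold bin runs as retained-nt intervals, merged
    when closer than `merge_nt`."""
    above = track.probs > threshold
    regions: list[list[int]] = []
    b = 0
    while b < len(above):
        if above[b]:
            start = b
            while b < len(above) and above[b]:
                b += 1
            regions.append([start * track.bin_size, b * track.bin_size])
        else:
            b += 1
    merged: list[list[int]] = []
    for lo, hi in regions:
        if merged and lo - merged[-1][1] < merge_nt:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


@dataclass
class ScanPeak:
    site: int  # genomic coordinate of the winning AG|GT boundary
    region: tuple[int, int]  # retained-nt interval
    score: float  # S(i)
    probability: float  # track probability at the site's bin
    motif_score: float
    window: str
    fdr: float | None = None


def _score_region(
    region: tuple[int, int],
    candidates: list[tuple[int, int, float, str]],
    track: SiteProbabilityTrack,
) -> ScanPeak | None:
    """Best-S(i) AG|GT for one region; None when no candidate scores > 0.

    candidates: (genomic site, retained-nt position, motif score M, window)."""
    best = None
    for site, pos, m, window in candidates:
        s = flank_potential(pos, *region) * max(m - 0.8, 0.0)
        if s > 0 and (best is None or s > best[0]):
            best = (s, site, pos, m, window)
    if best is None:
        return None
    s, site, pos, m, window = best
    b = min(pos // track.bin_size, len(track.probs) - 1)
    return ScanPeak(site, region, s, float(track.probs[b]), m, window)


def intron_aggt_candidates(
    profile: CoverageProfile, genome, pwm: SpliceSitePWM
) -> list[tuple[int, int, float, str]]:
    """All AG|GT boundaries in the intron (transcript orientation) with their
    retained-nt position and motif score."""
    from .motif_scoring import find_aggt_sites
    from .genome_io import revcomp

    seq = genome.fetch(profile.chrom, profile.start, profile.end)
    if profile.strand == "+":
        boundaries = find_aggt_sites(seq, offset=profile.start)
    else:
        boundaries = [
            profile.end - q for q in find_aggt_sites(revcomp(seq))
        ]
    out = []
    margin = max(pwm.acceptor_len, pwm.donor_len)
    for site in boundaries:
        offset = site - profile.start
        if offset < margin or offset > profile.end - profile.start - margin:
            continue
        if len(profile.positions) and not (
            profile.positions[0] <= offset <= profile.positions[-1]
        ):
            continue
        m, window, _ = score_site(genome, profile.chrom, site, profile.strand, pwm)
        out.append((site, profile.offset_to_retained(offset), m, window))
    return out


def call_peaks(
    track: SiteProbabilityTrack,
    profile: CoverageProfile,
    genome,
    pwm: SpliceSitePWM,
    threshold: float = PROBABILITY_THRESHOLD,
    merge_nt: int = MERGE_DISTANCE,
) -> list[ScanPeak]:
    """Threshold + merge probability regions, then report the maximum-S(i)
    AG|GT per region (regions whose candidates all score 0 are dropped)."""
    regions = threshold_regions(track, threshold, merge_nt)
    if not regions:
        return []
    candidates = intron_aggt_candidates(profile, genome, pwm)
    peaks = []
    for region in regions:
        peak = _score_region(region, candidates, track)
        if peak is not None:
            peaks.append(peak)
    return peaks


def shuffle_regions(
    regions: list[tuple[int, int]], length_nt: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Reposition each region uniformly across the intron, preserving the
    number of regions and each region's length exactly."""
    out = []
    for lo, hi in regions:
        size = hi - lo
        start = int(rng.integers(0, max(length_nt - size, 0) + 1))
        out.append((start, start + size))
    return out


def estimate_sawtooth_fdr(
    track: SiteProbabilityTrack,
    profile: CoverageProfile,
    genome,
    pwm: SpliceSitePWM,
    n_shuffles: int = 100,
    seed: int = 0,
    threshold: float = PROBABILITY_THRESHOLD,
    merge_nt: int = MERGE_DISTANCE,
) -> list[ScanPeak]:
    """Attach an FDR to each called peak from uniformly repositioned nulls.

    For each shuffle the above-threshold regions are redistributed uniformly
    across the intron (count and lengths maintained) and peak calling is
    re-applied; FDR at score s = (mean null peaks with S >= s) /
    (observed peaks with S >= s), clipped to [0, 1]."""
    peaks = call_peaks(track, profile, genome, pwm, threshold, merge_nt)
    if not peaks:
        return []
    regions = threshold_regions(track, threshold, merge_nt)
    candidates = intron_aggt_candidates(profile, genome, pwm)
    rng = np.random.default_rng(seed)
    null_scores: list[float] = []
    for _ in range(n_shuffles):
        for region in shuffle_regions(regions, profile.length_nt, rng):
            null = _score_region(region, candidates, track)
            if null is not None:
                null_scores.append(null.score)
    null_arr = np.array(null_scores)
    for peak in peaks:
        mean_null = (null_arr >= peak.score).sum() / n_shuffles if len(null_arr) else 0.0
        observed = sum(1 for p in peaks if p.score >= peak.score)
        peak.fdr = float(min(max(mean_null / observed, 0.0), 1.0))
    return peaks


def jump_fold(profile: CoverageProfile, site_bin: int,
              other_sites: tuple[int, ...] = ()) -> float:
    """Fitted downstream/upstream density ratio at a site bin (the automated
    sawtooth-presence check replacing manual inspection of read densities)."""
    sites = tuple(sorted({site_bin, *other_sites}))
    bounds = (0, *sites, profile.n_bins)
    k = sites.index(site_bin)
    a, s, b = bounds[k], site_bin, bounds[k + 2]
    up = heteroscedastic_regression(profile.bins[a:s])
    down = heteroscedastic_regression(profile.bins[s:b])
    up_pred = up.predict(s - a)
    down_pred = down.intercept
    if up_pred <= 0:
        return math.inf if down_pred > 0 else 0.0
    return down_pred / up_pred
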