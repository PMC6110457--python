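"""Recursive-site inference from junction-spanning read pairs (modified GEM).

Read pairs with one mate just upstream of an annotated 5' splice site and the
other deep inside the intron only make sense, given the sequenced fragment
length, if the recursive segment between them was excised. Each candidate
intronic AG|GT position m is scored by how well the implied insert length of
each pair fits the empirical fragment-length distribution, via an EM mixture
with a motif-informed prior:

    P(r_n | m)  = empirical probability of the implied insert length
    Pi_m        ∝ max(0, M(m) - 0.8)                    (initial prior)
    E-step      resp(n, m) ∝ Pi_m * P(r_n | m)
    M-step      N_m = sum_n resp(n, m) + junction reads at m
                Pi_m <- max(0, N_m - alpha_s), renormalized
    alpha_s     = (number of assigned reads) / 40       (sparsity)

iterated until no prior changes by more than 1e-5, after which pairs are
MAP-assigned to candidate sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .genome_io import GenomeAnnotation
from .model import AlignedReadPair, Intron


@dataclass
class FragmentLengthDistribution:
    """Empirical insert-length histogram (1-nt bins), optionally smoothed."""

    probs: np.ndarray  # probs[l] = P(insert length == l)
    n_obs: int

    def __post_init__(self):
        total = self.probs.sum()
        if not np.isclose(total, 1.0):
            raise ValueError("fragment-length probabilities must sum to 1")

    def pmf(self, length: int | np.ndarray) -> np.ndarray:
        length = np.asarray(length)
        out = np.zeros(length.shape, dtype=float)
        ok = (length >= 0) & (length < len(self.probs))
        out[ok] = self.probs[length[ok].astype(int)]
        return out

    def mean(self) -> float:
        return float((np.arange(len(self.probs)) * self.probs).sum())


def estimate_fragment_distribution(
    inserts, max_length: int = 2000, bandwidth: float = 10.0
) -> FragmentLengthDistribution:
    """Histogram of implied insert lengths, Gaussian-smoothed (`bandwidth` nt;
    0 disables smoothing). Inserts outside [0, max_length) are clipped out."""
    inserts = np.asarray(list(inserts), dtype=int)
    inserts = inserts[(inserts >= 0) & (inserts < max_length)]
    if len(inserts) == 0:
        raise ValueError("no fragment-length observations")
    hist = np.bincount(inserts, minlength=max_length).astype(float)
    if bandwidth > 0:
        hist = gaussian_filter1d(hist, bandwidth)
    return FragmentLengthDistribution(hist / hist.sum(), len(inserts))


def pair_implied_insert(
    pair: AlignedReadPair, donor: int, site: int, strand: str
) -> int:
    """Insert length implied by excision of the segment between `donor` and
    `site`: the portion of the fragment before the 5'SS plus the portion
    after the candidate site (transcript orientation)."""
    if strand == "+":
        return (donor - pair.read1.start) + (pair.read2.end - site)
    return (pair.read2.end - donor) + (site - pair.read1.start)


def pooled_inserts(
    pairs: list[AlignedReadPair], annotation: GenomeAnnotation | None = None
) -> list[int]:
    """Observed insert lengths with annotated-intron gaps subtracted.

    Any annotated intron falling entirely between the two mates is assumed
    spliced out of the fragment."""
    junction_gaps = (
        sorted(annotation.junction_set()) if annotation is not None else []
    )
    out = []
    for pair in pairs:
        gross = pair.read2.end - pair.read1.start
        for chrom, start, end in junction_gaps:
            if (
                chrom == pair.read1.chrom
                and pair.read1.end <= start
                and end <= pair.read2.start
            ):
                gross -= end - start
        out.append(gross)
    return out


def select_spanning_pairs(
    pairs: list[AlignedReadPair],
    annotation: GenomeAnnotation,
    max_upstream: int = 300,
    min_downstream: int = 1000,
    aggt_cassette_introns: set[tuple[str, int, int]] = frozenset(),
) -> dict[Intron, list[AlignedReadPair]]:
    """Candidate recursive-junction-spanning pairs, grouped by intron.

    Keeps pairs whose transcript-first mate ends within `max_upstream` nt
    upstream of an annotated 5' splice site and whose second mate lies inside
    the corresponding intron more than `min_downstream` nt downstream of the
    first. Pairs whose implied insert drops below `min_downstream` under
    completion of some annotated splicing event are discarded (events in
    `aggt_cassette_introns` — cassette exons with an AG|GT at their 5' end —
    are exempt from that test)."""
    out: dict[Intron, list[AlignedReadPair]] = {}
    junction_gaps = sorted(annotation.junction_set())
    for intron in annotation.introns:
        donor, strand = intron.donor, intron.strand
        for pair in pairs:
            if pair.read1.chrom != intron.chrom or not pair.unique:
                continue
            if strand == "+":
                first, second = pair.read1, pair.read2
                gap_to_donor = donor - first.end
                downstream_dist = second.start - first.start
                inside = intron.start <= second.start and second.end <= intron.end
            else:
                first, second = pair.read2, pair.read1
                gap_to_donor = first.start - donor
                downstream_dist = first.end - second.end
                inside = intron.start <= second.start and second.end <= intron.end
            if not (0 <= gap_to_donor <= max_upstream):
                continue
            if not inside or downstream_dist <= min_downstream:
                continue
            gross = pair.read2.end - pair.read1.start
            explained = False
            for chrom, start, end in junction_gaps:
                if (chrom, start, end) in aggt_cassette_introns:
                    continue
                if (
                    chrom == pair.read1.chrom
                    and pair.read1.end <= start
                    and end <= pair.read2.start
                    and gross - (end - start) < min_downstream
                ):
                    explained = True
                    break
            if explained:
                continue
            out.setdefault(intron, []).append(pair)
    return out


@dataclass
class GemResult:
    """Converged mixture state over candidate recursive-site positions."""

    positions: np.ndarray  # candidate AG|GT coordinates (transcript order)
    motif_scores: np.ndarray
    priors: np.ndarray  # Pi after convergence (sums to 1 over candidates)
    responsibilities: np.ndarray  # (n_pairs, n_candidates)
    map_assignments: np.ndarray  # candidate index per pair
    effective_counts: np.ndarray  # N_m at convergence
    iterations: int
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def supported_sites(self) -> list[int]:
        """Candidate positions retaining positive prior after sparsification."""
        return [int(p) for p, pi in zip(self.positions, self.priors) if pi > 0]

    def pair_support(self, periods: list[int | None]) -> dict[int, dict[int, int]]:
        """site -> {labeling period -> MAP-assigned pair count}."""
        out: dict[int, dict[int, int]] = {}
        for k, period in zip(self.map_assignments, periods):
            site = int(self.positions[k])
            if self.priors[k] > 0:
                per = out.setdefault(site, {})
                per[period or 0] = per.get(period or 0, 0) + 1
        return out


def gem_infer_sites(
    pairs: list[AlignedReadPair],
    junction_read_counts: dict[int, int],
    fragment_dist: FragmentLengthDistribution,
    candidates: list[tuple[int, float]],
    donor: int,
    strand: str = "+",
    prior_floor: float = 0.8,
    alpha_divisor: float = 40.0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> GemResult | None:
    """EM inference of recursive sites from spanning pairs + junction reads.

    `candidates` are (position, motif score M) for intronic AG|GT boundaries;
    only candidates with M > `prior_floor` can carry prior mass. Junction
    reads at a candidate add to its effective count in every M-step (before
    sparsification). Returns None when no candidate has positive prior or
    all priors are sparsified to zero."""
    cand = [(pos, m) for pos, m in candidates if m > prior_floor]
    if not cand:
        warnings.warn("no candidate position with positive motif prior")
        return None
    positions = np.array([pos for pos, _ in cand])
    scores = np.array([m for _, m in cand])
    pi = np.maximum(0.0, scores - prior_floor)
    pi = pi / pi.sum()

    n_pairs = len(pairs)
    lik = np.zeros((n_pairs, len(cand)))
    for n, pair in enumerate(pairs):
        inserts = np.array(
            [pair_implied_insert(pair, donor, int(m), strand) for m in positions]
        )
        lik[n] = fragment_dist.pmf(inserts)

    junction = np.array(
        [float(junction_read_counts.get(int(p), 0)) for p in positions]
    )
    # pairs whose implied insert is impossible under every candidate get
    # uniform responsibilities but are never effectively assigned
    alive = lik.sum(axis=1) > 0
    total_assigned = alive.sum() + junction.sum()
    alpha = total_assigned / alpha_divisor if np.isfinite(alpha_divisor) else 0.0

    trace: list[float] = []
    resp = np.full((n_pairs, len(cand)), 1.0 / len(cand))
    for it in range(1, max_iter + 1):
        weighted = lik * pi  # E-step
        row_sums = weighted.sum(axis=1)
        with np.errstate(divide="ignore"):
            trace.append(float(np.log(row_sums[row_sums > 0]).sum()))
        dead = row_sums == 0
        if n_pairs:
            resp = np.where(
                dead[:, None], 1.0 / len(cand), weighted / np.where(dead, 1, row_sums)[:, None]
            )
        counts = resp[alive].sum(axis=0) + junction  # M-step
        pi_new = np.maximum(0.0, counts - alpha)
        if pi_new.sum() == 0:
            warnings.warn("all priors sparsified to zero: no supported site")
            return None
        pi_new = pi_new / pi_new.sum()
        delta = np.abs(pi_new - pi).max()
        pi = pi_new
        if delta <= tol:
            break
    map_assignments = resp.argmax(axis=1) if n_pairs else np.zeros(0, dtype=int)
    return GemResult(
        positions, scores, pi, resp, map_assignments,
        resp[alive].sum(axis=0) + junction, it, trace,
    )
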