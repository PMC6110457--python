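"""Splicing kinetics from progressive 4sU labeling, and splicing accuracy.

Under progressive metabolic labeling, transcripts isolated after a labeling
period of t minutes have ages uniform on [0, t]. For first-order splicing at
rate lambda (min^-1), the fraction of junction-read evidence showing
completed splicing at labeling time t is

    theta(t) = 1 - (1 - exp(-lambda t)) / (lambda t)

The per-segment rate is fit by least squares on the observed completed
fractions at t in {5, 10, 20} min, giving a half-life t1/2 = ln 2 / lambda.
Whole-intron lifetime for a two-segment recursive intron is the expected
maximum of the two segment exponentials plus the time to transcribe the
first segment at 1500 nt/min:

    tau = 1/lambda1 + 1/lambda2 - 1/(lambda1 + lambda2) + l1/1500
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import minimize_scalar

from .genome_io import GenomeAnnotation, SequenceStore, revcomp
from .model import Intron, JunctionEvidence

ELONGATION_RATE = 1500.0  # nt per minute
HALF_LIFE_FLOOR = 0.1  # minutes; resolution floor when splicing looks complete
DEFAULT_PERIODS = (5, 10, 20)


def completed_fraction(lam: float, t: float) -> float:
    """theta(t): completed fraction under uniform transcript ages in [0, t]."""
    x = lam * t
    if x < 1e-8:
        return x / 2.0
    return 1.0 - (1.0 - math.exp(-x)) / x


@dataclass
class HalfLifeFit:
    half_life: float  # minutes (inf when no completion observed)
    rate: float  # lambda, min^-1
    flag: str  # ok / floor / infinite / undefined
    sse: float = 0.0


def estimate_half_life(
    counts: dict[int, tuple[int, int]],
    bounds: tuple[float, float] = (1e-4, 1e3),
    floor: float = HALF_LIFE_FLOOR,
) -> HalfLifeFit:
    """Fit lambda to observed completed fractions ee/(ee+ie) per period.

    `counts` maps labeling period (min) to (incomplete, complete) reads.
    All-complete data hits the resolution floor; all-incomplete data is
    flagged infinite; periods without reads are ignored."""
    observed = {
        t: (ie, ee) for t, (ie, ee) in counts.items() if ie + ee > 0
    }
    if not observed:
        return HalfLifeFit(math.nan, math.nan, "undefined")
    total_ie = sum(ie for ie, _ in observed.values())
    total_ee = sum(ee for _, ee in observed.values())
    if total_ee == 0:
        return HalfLifeFit(math.inf, 0.0, "infinite")
    if total_ie == 0:
        return HalfLifeFit(floor, math.log(2) / floor, "floor")

    fractions = {t: ee / (ie + ee) for t, (ie, ee) in observed.items()}

    def sse(lam: float) -> float:
        return sum(
            (frac - completed_fraction(lam, t)) ** 2
            for t, frac in fractions.items()
        )

    res = minimize_scalar(
        sse, bounds=bounds, method="bounded", options={"xatol": 1e-8}
    )
    lam = float(res.x)
    return HalfLifeFit(math.log(2) / lam, lam, "ok", float(res.fun))


@dataclass
class SegmentKinetics:
    """Per-segment incomplete/complete junction counts and fitted half-life."""

    intron: Intron
    index: int  # 1-based segment position in transcript order
    seg_type: str  # 'segment' (ends at a recursive site) or 'threess'
    boundary: int  # genomic coordinate of the segment's 3'-bounding site
    length: int  # nt
    three_length: int  # nt from the boundary to the intron's 3' splice site
    ie_counts: dict[int, int] = field(default_factory=dict)
    ee_counts: dict[int, int] = field(default_factory=dict)
    fit: HalfLifeFit | None = None

    @property
    def txn_to_three(self) -> float:
        """Minutes to transcribe from the boundary to the 3' splice site."""
        return self.three_length / ELONGATION_RATE


def assign_segment_junction_reads(
    junctions: list[JunctionEvidence],
    rs_sites: list[int],
    intron: Intron,
    overlap_reads: list[tuple[int, int, int]] = (),
    periods: tuple[int, ...] = DEFAULT_PERIODS,
) -> list[SegmentKinetics]:
    """Split an intron at its recursive sites and count, per segment and
    labeling period, incomplete evidence (reads overlapping the segment's
    3'-bounding site contiguously) and complete evidence (junction reads
    whose acceptor side is that site, from any donor).

    `overlap_reads` are (start, end, period) spans of non-split reads."""
    sites = sorted(set(rs_sites), reverse=intron.strand == "-")
    boundaries = sites + [intron.acceptor]
    prev = intron.donor
    out = []
    for k, boundary in enumerate(boundaries, start=1):
        seg_type = "threess" if boundary == intron.acceptor else "segment"
        length = abs(boundary - prev)
        three_length = abs(intron.acceptor - boundary)
        seg = SegmentKinetics(
            intron, k, seg_type, boundary, length, three_length,
            {t: 0 for t in periods}, {t: 0 for t in periods},
        )
        for start, end, period in overlap_reads:
            if start < boundary < end and period in seg.ie_counts:
                seg.ie_counts[period] += 1
        for j in junctions:
            acceptor_side = j.acceptor if intron.strand == "+" else j.donor
            if j.chrom == intron.chrom and acceptor_side == boundary:
                for period, count in j.counts:
                    if period in seg.ee_counts:
                        seg.ee_counts[period] += count
        seg.fit = estimate_half_life(
            {t: (seg.ie_counts[t], seg.ee_counts[t]) for t in periods}
        )
        out.append(seg)
        prev = boundary
    return out


def transcription_time(length_nt: float, rate: float = ELONGATION_RATE) -> float:
    """Minutes for RNA polymerase II to transcribe `length_nt` nucleotides."""
    return length_nt / rate


def splicing_delay(
    first_segment_half_life: float,
    intron_length: int,
    first_segment_length: int,
    rate: float = ELONGATION_RATE,
) -> float:
    """Ratio of the first segment's splicing half-life to the time needed to
    transcribe the remainder of the intron; < 1 implies co-transcriptional
    splicing of the first segment."""
    return first_segment_half_life / transcription_time(
        intron_length - first_segment_length, rate
    )


@dataclass
class IntronLifetime:
    tau_recursive: float  # minutes, includes first-segment transcription
    txn_seg1: float  # minutes to transcribe the first segment
    expected_max: float  # E[max(Exp(lambda1), Exp(lambda2))]

    def __post_init__(self):
        if not self.tau_recursive >= self.expected_max - 1e-12:
            raise ValueError("lifetime below the expected maximum")


def recursive_intron_lifetime(
    lam1: float, lam2: float, l1: float, rate: float = ELONGATION_RATE
) -> IntronLifetime:
    """Mean lifetime of a one-recursive-site (two-segment) intron.

    The waiting time to splice both segments is the maximum of two
    independent exponentials, with expectation
    1/lambda1 + 1/lambda2 - 1/(lambda1 + lambda2); the time to transcribe
    the first segment is added since that segment must exist before the
    second can be spliced."""
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("rates must be positive")
    expected_max = 1.0 / lam1 + 1.0 / lam2 - 1.0 / (lam1 + lam2)
    txn = l1 / rate
    return IntronLifetime(expected_max + txn, txn, expected_max)


# ---------------------------------------------------------------------------
# splicing accuracy
# ---------------------------------------------------------------------------

_CANONICAL = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_CANONICAL_RC = {("CT", "AC"), ("CT", "GC"), ("GT", "AT")}


def classify_junction(
    j: JunctionEvidence, annotation: GenomeAnnotation, genome: SequenceStore
) -> str:
    """'annotated', 'canonical' (GT-AG / GC-AG / AT-AC on either strand), or
    'noncanonical' for a splice junction's terminal dinucleotides."""
    if (j.chrom, j.donor, j.acceptor) in annotation.junction_set():
        return "annotated"
    left = genome.fetch(j.chrom, j.donor, j.donor + 2)
    right = genome.fetch(j.chrom, j.acceptor - 2, j.acceptor)
    if (left, right) in _CANONICAL or (left, right) in _CANONICAL_RC:
        return "canonical"
    return "noncanonical"


def splicing_accuracy(
    junctions: list[JunctionEvidence],
    annotation: GenomeAnnotation,
    genome: SequenceStore,
) -> dict[Intron, float]:
    """Per-intron fraction of junction-read density arising from non-canonical
    non-annotated splice sites (junctions assigned to the intron containing
    them); 0 when an intron has no junction reads."""
    out: dict[Intron, float] = {}
    for intron in annotation.introns:
        total = bad = 0
        for j in junctions:
            if j.chrom != intron.chrom:
                continue
            if not (intron.start <= j.donor and j.acceptor <= intron.end):
                continue
            total += j.total
            if classify_junction(j, annotation, genome) == "noncanonical":
                bad += j.total
        if total:
            out[intron] = bad / total
    return out
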