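"""Recursive-site detection from split junction reads.

A ratchet junction read joins an annotated 5' splice site to an intronic
AG|GT boundary (the recursive site acting as an acceptor), providing direct
evidence of a recursive intermediate. This module also searches for
alternative-order junctions (RS->RS and RS->3'SS) that would indicate
recursive segments spliced out of 5'-to-3' order, and categorizes all
junction reads of an intron for order-of-splicing summaries.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

from .genome_io import GenomeAnnotation, SequenceStore
from .model import Intron, JunctionEvidence, RecursiveSiteCall
from .motif_scoring import SpliceSitePWM, score_site


def _transcript_endpoints(j: JunctionEvidence, strand: str) -> tuple[int, int]:
    """(donor-side, acceptor-side) genomic coordinates in transcript
    orientation for a forward-coordinate junction."""
    return (j.donor, j.acceptor) if strand == "+" else (j.acceptor, j.donor)


def find_ratchet_junctions(
    junctions: list[JunctionEvidence],
    annotation: GenomeAnnotation,
    genome: SequenceStore,
    pwm: SpliceSitePWM | None = None,
) -> list[RecursiveSiteCall]:
    """Candidate recursive sites with 5'SS->RS junction support.

    A junction is evidence iff its donor side matches an annotated 5' splice
    site exactly, its acceptor side falls strictly inside the intron (before
    the downstream-most annotated 3' splice site sharing that donor), and the
    genomic context at the acceptor is AG immediately upstream with GT
    starting at the site (strand-corrected). Non-matching junctions are
    silently skipped."""
    donor_map: dict[tuple[str, int, str], list[Intron]] = collections.defaultdict(list)
    for intron in annotation.introns:
        donor_map[(intron.chrom, intron.donor, intron.strand)].append(intron)

    calls: dict[tuple[str, int], RecursiveSiteCall] = {}
    for j in junctions:
        for strand in ("+", "-"):
            donor, site = _transcript_endpoints(j, strand)
            introns = donor_map.get((j.chrom, donor, strand))
            if not introns:
                continue
            # downstream-most 3'SS among introns sharing this donor
            if strand == "+":
                far_3ss = max(i.end for i in introns)
                inside = donor < site < far_3ss
            else:
                far_3ss = min(i.start for i in introns)
                inside = far_3ss < site < donor
            if not inside:
                continue
            if not _is_aggt(genome, j.chrom, site, strand):
                continue
            host = max(
                (i for i in introns if i.start < site < i.end),
                key=lambda i: i.length,
                default=None,
            )
            if host is None:
                continue
            key = (j.chrom, site)
            call = calls.get(key)
            if call is None:
                call = RecursiveSiteCall(host, site, {"junction"})
                if pwm is not None:
                    m, window, _ = score_site(genome, j.chrom, site, strand, pwm)
                    call.motif_score, call.motif = m, window
                calls[key] = call
            for period, count in j.counts:
                call.junction_support[period] = (
                    call.junction_support.get(period, 0) + count
                )
    return sorted(calls.values(), key=lambda c: (c.intron.chrom, c.site))


def _is_aggt(genome: SequenceStore, chrom: str, site: int, strand: str) -> bool:
    ctx = genome.fetch(chrom, site - 2, site + 2)
    if strand == "+":
        return ctx == "AGGT"
    return ctx == "ACCT"  # revcomp(AGGT)


def categorize_junctions(
    junctions: list[JunctionEvidence],
    intron: Intron,
    rs_sites: set[int],
) -> dict[str, int]:
    """Partition an intron's junction reads over the four categories
    (5SS-3SS, 5SS-RS, RS-RS, RS-3SS); junctions with an endpoint matching
    none of the annotated boundaries or recursive sites land in 'other'.
    Counts over all keys sum to the intron's total junction reads."""
    counts = dict.fromkeys(("5SS-3SS", "5SS-RS", "RS-RS", "RS-3SS", "other"), 0)
    for j in junctions:
        if j.chrom != intron.chrom:
            continue
        lo, hi = sorted(_transcript_endpoints(j, intron.strand))
        if not (intron.start <= lo and hi <= intron.end):
            continue
        donor_side, acceptor_side = _transcript_endpoints(j, intron.strand)

        def kind(pos: int, end: str) -> str:
            if end == "donor" and pos == intron.donor:
                return "5SS"
            if end == "acceptor" and pos == intron.acceptor:
                return "3SS"
            if pos in rs_sites:
                return "RS"
            return "?"

        pair = (kind(donor_side, "donor"), kind(acceptor_side, "acceptor"))
        label = {
            ("5SS", "3SS"): "5SS-3SS",
            ("5SS", "RS"): "5SS-RS",
            ("RS", "RS"): "RS-RS",
            ("RS", "3SS"): "RS-3SS",
        }.get(pair, "other")
        counts[label] += j.total
    return counts


@dataclass
class AlternativeOrderEvent:
    """An RS->RS or RS->3'SS junction implying non-5'-to-3' splicing order."""

    intron: Intron
    category: str  # 'RS-RS' or 'RS-3SS'
    donor_site: int
    acceptor_site: int
    reads: int
    motif_scores: tuple[float, ...]


def find_alternative_order_junctions(
    junctions: list[JunctionEvidence],
    annotation: GenomeAnnotation,
    genome: SequenceStore,
    pwm: SpliceSitePWM,
    min_segment: int = 1000,
    min_reads: int = 3,
    min_score: float = 0.85,
) -> list[AlternativeOrderEvent]:
    """Junctions whose endpoints are two intronic AG|GT boundaries (RS-RS) or
    an intronic AG|GT and an annotated 3' splice site (RS-3SS), with an
    implied segment of at least `min_segment` nt, at least `min_reads`
    uniquely aligned reads, and every involved recursive site scoring above
    `min_score`."""
    acceptors = annotation.acceptors()
    donors = annotation.donors()
    events = []
    for j in junctions:
        for intron in annotation.introns:
            if j.chrom != intron.chrom:
                continue
            donor_side, acceptor_side = _transcript_endpoints(j, intron.strand)
            if not intron.start < donor_side < intron.end:
                continue
            if acceptor_side != intron.acceptor and not (
                intron.start < acceptor_side < intron.end
            ):
                continue
            if abs(acceptor_side - donor_side) < min_segment:
                continue
            if j.total < min_reads:
                continue
            donor_is_rs = (
                intron.start < donor_side < intron.end
                and (j.chrom, donor_side, intron.strand) not in donors
                and _is_aggt(genome, j.chrom, donor_side, intron.strand)
            )
            if not donor_is_rs:
                continue
            rs_sites = [donor_side]
            if acceptor_side == intron.acceptor:
                category = "RS-3SS"
            elif intron.start < acceptor_side < intron.end and _is_aggt(
                genome, j.chrom, acceptor_side, intron.strand
            ) and (j.chrom, acceptor_side, intron.strand) not in acceptors:
                category = "RS-RS"
                rs_sites.append(acceptor_side)
            else:
                continue
            scores = tuple(
                score_site(genome, j.chrom, s, intron.strand, pwm)[0]
                for s in rs_sites
            )
            if any(m <= min_score for m in scores):
                continue
            events.append(
                AlternativeOrderEvent(
                    intron, category, donor_side, acceptor_side, j.total, scores
                )
            )
            break  # one host intron per junction
    return events


def spanning_read_count(
    junctions: list[JunctionEvidence],
    annotation: GenomeAnnotation,
    intron: Intron,
) -> int:
    """5'SS->3'SS junction reads over the largest annotated intron sharing
    this intron's donor (the quantity used by the candidate filter)."""
    largest = annotation.largest_intron_sharing_donor(intron)
    return sum(
        j.total
        for j in junctions
        if j.chrom == largest.chrom
        and j.donor == largest.start
        and j.acceptor == largest.end
    )
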