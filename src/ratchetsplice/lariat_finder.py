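"""Branchpoint-spanning (lariat) read detection.

A read sequenced across the 5'SS-branchpoint junction of an excised lariat
cannot align contiguously: its first part is genomic sequence ending at the
branchpoint and its second part is sequence starting at the intron (or
recursive-segment) donor. Such reads are recovered by splitting each
unalignable read just before the 7-mer best matching the 5' splice-site
consensus and aligning the two halves as an inverted pair, requiring that

    (1) each segment is at least 15 nt long,
    (2) at most 1 mismatch per segment,
    (3) the segments are separated by less than 1 Mbp, and
    (4) the pair has a unique alignment,

with the second (donor) segment landing genomically upstream of the first.
Survivors are kept when the second segment starts exactly at a 5'SS or
recursive site and the first segment ends within 100 nt upstream of a 3'SS
or recursive site; the branchpoint is the last genomic base of the first
segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeAnnotation, SequenceStore
from .motif_scoring import SpliceSitePWM, build_pwms


@dataclass
class LariatRead:
    read_id: str
    split_pos: int  # read position where the second (donor) segment begins
    first_segment: tuple[str, int, int]  # ends at the branchpoint
    second_segment: tuple[str, int, int]  # starts at the donor / recursive site
    branchpoint: int
    junction_type: str  # 5SS-RS / RS-RS / 5SS-3SS / 5SS-BP
    period: int | None = None
    mismatches: tuple[int, int] = (0, 0)


def build_donor_7mer_pwm(
    annotation: GenomeAnnotation, genome: SequenceStore
) -> np.ndarray:
    """7-column log2-probability matrix of the intronic 5'SS consensus."""
    pwm = build_pwms(annotation, genome, acceptor_len=20, donor_len=7)
    return np.log2(pwm.donor)


_IDX = {b: i for i, b in enumerate("ACGT")}


def best_split_position(read: str, donor_logp: np.ndarray) -> int:
    """Read offset of the best-scoring 7-mer (ties broken leftmost)."""
    width = donor_logp.shape[0]
    best_pos, best_score = 0, -np.inf
    col_min = donor_logp.min(axis=1)
    for p in range(len(read) - width + 1):
        score = 0.0
        for c, base in enumerate(read[p : p + width].upper()):
            i = _IDX.get(base)
            score += donor_logp[c, i] if i is not None else col_min[c]
        if score > best_score:
            best_pos, best_score = p, score
    return best_pos


def _hamming_placements(
    genome_arr: np.ndarray, pattern: str, max_mismatch: int
) -> list[tuple[int, int]]:
    """(start, mismatches) for every ungapped placement within the tolerance."""
    pat = np.frombuffer(pattern.upper().encode(), dtype="S1")
    n = len(genome_arr) - len(pat) + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int32)
    for j, ch in enumerate(pat):
        mism += genome_arr[j : j + n] != ch
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(h), int(mism[h])) for h in hits]


def find_lariat_reads(
    reads: list[tuple[str, str, int | None]],
    genome: SequenceStore,
    donor_logp: np.ndarray,
    annotation: GenomeAnnotation,
    rs_sites: dict[str, set[int]] | None = None,
    min_half: int = 15,
    max_mismatch: int = 1,
    max_separation: int = 1_000_000,
    upstream_window: int = 100,
    donor_offset: int = 0,
) -> list[LariatRead]:
    """Scan unalignable reads (id, sequence, labeling period) for lariats.

    Alignment is an exhaustive ungapped (Hamming) scan of the forward strand
    of every chromosome. `donor_offset` relaxes "immediately downstream" of a
    donor to an allowed gap (0 by default)."""
    rs_sites = rs_sites or {}
    donors: dict[str, set[int]] = {}
    acceptors: dict[str, set[int]] = {}
    for intron in annotation.introns:
        donors.setdefault(intron.chrom, set()).add(intron.donor)
        acceptors.setdefault(intron.chrom, set()).add(intron.acceptor)

    arrays = {
        chrom: np.frombuffer(
            genome.fetch(chrom, 0, genome.length(chrom)).encode(), dtype="S1"
        )
        for chrom in genome.chroms()
    }

    out = []
    for read_id, seq, period in reads:
        split = best_split_position(seq, donor_logp)
        first, second = seq[:split], seq[split:]
        if len(first) < min_half or len(second) < min_half:
            continue
        pairings = []
        for chrom, arr in arrays.items():
            first_hits = _hamming_placements(arr, first, max_mismatch)
            second_hits = _hamming_placements(arr, second, max_mismatch)
            for s2, mm2 in second_hits:
                for s1, mm1 in first_hits:
                    sep = s1 - s2
                    if 0 < sep < max_separation:  # second strictly upstream
                        pairings.append((chrom, s1, mm1, s2, mm2))
        if len(pairings) != 1:  # constraint (4): unique pair alignment
            continue
        chrom, s1, mm1, s2, mm2 = pairings[0]
        first_end = s1 + len(first)
        branchpoint = first_end - 1
        donor_hit = None
        for d in donors.get(chrom, set()) | rs_sites.get(chrom, set()):
            if 0 <= s2 - d <= donor_offset:
                donor_hit = d
                break
        if donor_hit is None:
            continue
        acceptor_hit = None
        for a in acceptors.get(chrom, set()) | rs_sites.get(chrom, set()):
            if 0 < a - branchpoint <= upstream_window:
                acceptor_hit = a
                break
        if acceptor_hit is None:
            continue
        donor_kind = "5SS" if donor_hit in donors.get(chrom, set()) else "RS"
        acceptor_kind = (
            "3SS" if acceptor_hit in acceptors.get(chrom, set()) else "RS"
        )
        junction_type = {
            ("5SS", "RS"): "5SS-RS",
            ("RS", "RS"): "RS-RS",
            ("5SS", "3SS"): "5SS-3SS",
        }.get((donor_kind, acceptor_kind), "5SS-BP")
        lariat = LariatRead(
            read_id, split, (chrom, s1, first_end), (chrom, s2, s2 + len(second)),
            branchpoint, junction_type, period, (mm1, mm2),
        )
        _assert_constraints(lariat, min_half, max_mismatch, max_separation)
        out.append(lariat)
    return out


def _assert_constraints(lariat: LariatRead, min_half, max_mismatch, max_separation):
    c1, s1, e1 = lariat.first_segment
    c2, s2, e2 = lariat.second_segment
    assert e1 - s1 >= min_half and e2 - s2 >= min_half
    assert max(lariat.mismatches) <= max_mismatch
    assert c1 == c2 and 0 < s1 - s2 < max_separation
    assert lariat.branchpoint == e1 - 1


def lariat_table(lariats: list[LariatRead], genome: SequenceStore):
    """Rows mirroring the lariat summary table (branchpoint context +/-10 nt)."""
    import pandas as pd

    rows = []
    for lr in lariats:
        chrom = lr.first_segment[0]
        rows.append(
            {
                "read_id": lr.read_id,
                "chrom": chrom,
                "junction_type": lr.junction_type,
                "donor": lr.second_segment[1],
                "branchpoint": lr.branchpoint,
                "branchpoint_context": genome.fetch(
                    chrom, lr.branchpoint - 10, lr.branchpoint + 11
                ),
                "timepoint": lr.period,
            }
        )
    return pd.DataFrame(rows)
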