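"""Shared domain types for the recursive-splicing detection suite.

All genomic intervals are 0-based half-open on the forward strand; strand-aware
logic (which end is the 5' splice site, what "upstream" means) is resolved at
use sites, never in storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Transcript:
    id: str
    exons: tuple[tuple[int, int], ...]  # ordered, non-overlapping, half-open

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (_, left_end), (right_start, _) in zip(self.exons, self.exons[1:]):
            out.append((left_end, right_start))
        return out


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: tuple[Transcript, ...]


@dataclass(frozen=True)
class Intron:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty intron {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor(self) -> int:
        """Genomic coordinate of the 5' splice site (exon|intron boundary)."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        """Genomic coordinate of the 3' splice site (intron|exon boundary)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class IntronRecord:
    """An intron with the per-intron evidence used by the candidate filters."""

    intron: Intron
    tpm: float = 0.0
    spanning_reads: int = 0  # 5'SS -> 3'SS junction reads

    def __post_init__(self):
        if self.tpm < 0:
            raise ValueError("TPM must be non-negative")


@dataclass(frozen=True)
class ReadSegment:
    chrom: str
    start: int
    end: int


@dataclass
class AlignedRead:
    chrom: str
    start: int
    end: int
    segments: tuple[ReadSegment, ...] = ()

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) pairs implied by gaps between split segments."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            out.append((a.end, b.start))
        return out


@dataclass
class AlignedReadPair:
    read1: AlignedRead
    read2: AlignedRead
    unique: bool = True
    period: int | None = None  # labeling period in minutes, if known


@dataclass(frozen=True)
class JunctionEvidence:
    """A splice junction (donor < acceptor, forward strand) with read counts
    per metabolic-labeling period."""

    chrom: str
    donor: int
    acceptor: int
    counts: tuple[tuple[int, int], ...]  # ((period_min, reads), ...)

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)

    def count_at(self, period: int) -> int:
        return dict(self.counts).get(period, 0)


JUNCTION_CATEGORIES = ("5SS-3SS", "5SS-RS", "RS-RS", "RS-3SS")


@dataclass
class RecursiveSiteCall:
    """A candidate recursive site with per-method support and tiering."""

    intron: Intron
    site: int  # genomic coordinate of the AG|GT boundary
    methods: set[str] = field(default_factory=set)  # ⊆ {junction, pair, sawtooth}
    junction_support: dict[int, int] = field(default_factory=dict)  # period -> reads
    pair_support: dict[int, int] = field(default_factory=dict)
    sawtooth_score: float | None = None
    mcmc_probability: float | None = None
    fdr: float | None = None
    motif: str = ""
    motif_score: float | None = None
    sawtooth_jump: bool | None = None  # automated >=1.5-fold jump flag
    confidence: str | None = None  # high / medium / rejected

    @property
    def junction_total(self) -> int:
        return sum(self.junction_support.values())

    @property
    def pair_total(self) -> int:
        return sum(self.pair_support.values())
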