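"""Seed-deterministic generators for every input the detectors consume.

The generators emulate the statistical structure of nascent RNA-seq over
recursively spliced introns: per-base coverage with linear decay across each
recursive segment and an upward jump at each recursive site (the sawtooth),
split junction reads joining the 5' splice site to intronic AG|GT boundaries,
read pairs whose implied insert length is only consistent with excision of the
recursive segment, branchpoint-crossing (lariat) reads, and
incomplete/complete junction counts across 4sU labeling periods.

Coverage noise is Poisson (variance equal to the mean), matching the
heteroscedasticity assumption of the sawtooth regression. Background sequence
is uniform over ACGT with AG|GT occurrences scrubbed near planted sites so the
decoy motif density around true sites is controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import AlignedRead, AlignedReadPair, ReadSegment

# Consensus training windows used for all synthetic annotated splice sites:
# a fly-like 5'SS intronic hexamer and a 20-nt polypyrimidine 3'SS ending AG.
DONOR_CONSENSUS = "GTAAGT"
ACCEPTOR_CONSENSUS = "T" * 16 + "TCAG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(n: int, rng: np.random.Generator) -> list[str]:
    return [b.decode() for b in _BASES[rng.integers(0, 4, n)]]


@dataclass(frozen=True)
class SimulatedIntronSpec:
    """Blueprint for one simulated intron.

    site_offsets are intron-relative recursive-site positions (the AG|GT
    boundary); segment_densities give the expected per-base read count at the
    start of each recursive segment (len(site_offsets) + 1 values). Expected
    coverage at position x within segment [a, b) is density * (b - x)/(b - a).
    """

    length: int
    site_offsets: tuple[int, ...] = ()
    segment_densities: tuple[float, ...] = (30.0,)
    frag_mean: float = 300.0
    frag_sd: float = 50.0
    noise: str = "poisson"  # 'poisson' or 'none'
    min_spacing: int = 1000

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("intron length must be positive")
        if len(self.segment_densities) != len(self.site_offsets) + 1:
            raise ValueError("need one density per segment")
        if any(d <= 0 for d in self.segment_densities):
            raise ValueError("segment densities must be positive")
        bounds = (0, *self.site_offsets, self.length)
        for a, b in zip(bounds, bounds[1:]):
            if b - a < self.min_spacing:
                raise ValueError(
                    f"sites closer than {self.min_spacing} nt to a neighbor or "
                    f"intron end: segment [{a},{b})"
                )
        # fold-jump feasibility: predicted density just downstream of each
        # site must exceed the upstream prediction at the boundary >=1.5-fold
        for k, s in enumerate(self.site_offsets):
            a = bounds[k]
            upstream_at_boundary = self.segment_densities[k] / (s - a)
            if self.segment_densities[k + 1] < 1.5 * upstream_at_boundary:
                raise ValueError(
                    f"segment [{a},{s}) too short for a >=1.5-fold jump at {s}"
                )

    @property
    def segments(self) -> list[tuple[int, int]]:
        bounds = (0, *self.site_offsets, self.length)
        return list(zip(bounds, bounds[1:]))


def expected_coverage(spec: SimulatedIntronSpec) -> np.ndarray:
    """Closed-form expected per-base coverage (linear decay per segment)."""
    out = np.empty(spec.length)
    for (a, b), dens in zip(spec.segments, spec.segment_densities):
        x = np.arange(a, b)
        out[a:b] = dens * (b - x) / (b - a)
    return out


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def scrub_aggt(
    seq: list[str],
    start: int,
    end: int,
    protect: set[int] = frozenset(),
    sub: str = "C",
) -> None:
    """Destroy AGGT occurrences overlapping [start, end) by mutating the first
    G, except occurrences whose center boundary is protected."""
    text = "".join(seq)
    i = max(start - 3, 0)
    while True:
        hit = text.find("AGGT", i, end + 3)
        if hit < 0:
            break
        if hit + 2 not in protect:
            seq[hit + 1] = sub
            text = "".join(seq)  # re-scan; substitution may create no new AGGT
        i = hit + 1


def simulate_intron_sequence(
    spec: SimulatedIntronSpec, rng: np.random.Generator, exclusion: int = 50
) -> str:
    """Uniform-background intron sequence with the juxtaposed consensus
    (3'SS + 5'SS) planted at each recursive site and all other AG|GT
    occurrences scrubbed within +/- `exclusion` nt of planted sites."""
    seq = _random_seq(spec.length, rng)
    window = ACCEPTOR_CONSENSUS + DONOR_CONSENSUS
    for s in spec.site_offsets:
        _plant(seq, s - len(ACCEPTOR_CONSENSUS), window)
    protect = set(spec.site_offsets)
    for s in spec.site_offsets:
        scrub_aggt(seq, s - exclusion, s + exclusion, protect)
    return "".join(seq)


def simulate_sawtooth_coverage(
    spec: SimulatedIntronSpec, seed: int = 0
) -> tuple[np.ndarray, str]:
    """Per-base coverage counts plus a matching intron sequence.

    Counts are Poisson around the segment-wise linear expectation (exactly the
    expectation when spec.noise == 'none')."""
    rng = np.random.default_rng(seed)
    mean = expected_coverage(spec)
    counts = rng.poisson(mean).astype(float) if spec.noise == "poisson" else mean
    seq = simulate_intron_sequence(spec, rng)
    return counts, seq


def simulate_read_pairs(
    n_pairs: int,
    donor: int,
    site: int,
    chrom: str = "chr",
    frag_mean: float = 300.0,
    frag_sd: float = 50.0,
    read_len: int = 51,
    seed: int = 0,
    period: int | None = None,
) -> list[AlignedReadPair]:
    """Read pairs straddling the recursive junction donor -> site.

    The implied insert (donor - read1.start) + (read2.end - site) is drawn
    from Normal(frag_mean, frag_sd); frag_sd = 0 gives the degenerate
    distribution."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        f = frag_mean if frag_sd == 0 else rng.normal(frag_mean, frag_sd)
        f = max(int(round(f)), 2 * read_len)
        x = int(rng.integers(read_len, f - read_len + 1))
        r1 = AlignedRead(
            chrom, donor - x, donor - x + read_len,
            (ReadSegment(chrom, donor - x, donor - x + read_len),),
        )
        r2 = AlignedRead(
            chrom, site + f - x - read_len, site + f - x,
            (ReadSegment(chrom, site + f - x - read_len, site + f - x),),
        )
        pairs.append(AlignedReadPair(r1, r2, True, period))
    return pairs


def simulate_labeling_counts(
    half_life_min: float,
    labeling_periods: tuple[int, ...] = (5, 10, 20),
    depth: int = 10_000,
    seed: int = 0,
) -> dict[int, tuple[int, int]]:
    """Binomial (incomplete, complete) junction counts per labeling period
    under the progressive-labeling completed fraction
    theta(t) = 1 - (1 - exp(-lambda t)) / (lambda t)."""
    from .kinetics import completed_fraction

    rng = np.random.default_rng(seed)
    out = {}
    for t in labeling_periods:
        if half_life_min == 0:
            theta = 1.0
        elif math.isinf(half_life_min):
            theta = 0.0
        else:
            theta = completed_fraction(math.log(2) / half_life_min, t)
        complete = int(rng.binomial(depth, theta))
        out[t] = (depth - complete, complete)
    return out


def simulate_lariat_read(
    fetch,
    chrom: str,
    donor: int,
    branchpoint: int,
    left_len: int = 25,
    right_len: int = 26,
    n_mismatches: int = 0,
    seed: int = 0,
) -> str:
    """A branchpoint-crossing read: genomic sequence ending at the branchpoint
    followed by sequence starting at the donor (or recursive site).

    `fetch` is a SequenceStore.fetch-like callable. Optional mismatches are
    planted per half (transversions, avoiding split-position ambiguity)."""
    rng = np.random.default_rng(seed)
    left = fetch(chrom, branchpoint - left_len + 1, branchpoint + 1)
    right = fetch(chrom, donor, donor + right_len)

    def mutate(half: str, k: int) -> str:
        chars = list(half)
        for pos in rng.choice(len(chars), size=k, replace=False):
            chars[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[pos]]
        return "".join(chars)

    if n_mismatches:
        left = mutate(left, n_mismatches)
        right = mutate(right, n_mismatches)
    return left + right


# ---------------------------------------------------------------------------
# whole-study fixture
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGene:
    id: str
    chrom: str
    exon1: tuple[int, int]
    intron: tuple[int, int]
    exon2: tuple[int, int]
    site: int | None  # genomic recursive-site coordinate, None for decoys
    spec: SimulatedIntronSpec


@dataclass
class StudyFixture:
    """A complete synthetic study: genome, annotation, reads, coverage, TPM."""

    genome: dict[str, str]
    genes: list[SimulatedGene]
    sam_text: str
    tpm: dict[str, float] = field(default_factory=dict)
    coverage: dict[str, np.ndarray] = field(default_factory=dict)  # gene -> per-base

    @property
    def truth(self) -> dict[str, int | None]:
        return {g.id: g.site for g in self.genes}

    def gff3(self) -> str:
        lines = ["##gff-version 3"]
        for g in self.genes:
            a, b = g.exon1[0], g.exon2[1]
            lines.append(f"{g.chrom}\t.\tgene\t{a + 1}\t{b}\t.\t+\t.\tID={g.id}")
            lines.append(
                f"{g.chrom}\t.\tmRNA\t{a + 1}\t{b}\t.\t+\t.\tID={g.id}.t1;Parent={g.id}"
            )
            for s, e in (g.exon1, g.exon2):
                lines.append(
                    f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t+\t.\tParent={g.id}.t1"
                )
        return "\n".join(lines) + "\n"


def _sam_header(genome: dict[str, str], periods=(5, 10, 20)) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, seq in genome.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    for p in periods:
        lines.append(f"@RG\tID:{p}\tSM:nascent")
    return lines


def _junction_read(qname, chrom, donor, acceptor, period, left=25, right=26):
    pos = donor - left
    cigar = f"{left}M{acceptor - donor}N{right}M"
    return (
        f"{qname}\t0\t{chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t*\t*\t"
        f"NH:i:1\tRG:Z:{period}"
    )


def _pair_records(qname, pair: AlignedReadPair, period):
    r1, r2 = pair.read1, pair.read2
    tlen = r2.end - r1.start
    n1 = r1.end - r1.start
    n2 = r2.end - r2.start
    return [
        f"{qname}\t99\t{r1.chrom}\t{r1.start + 1}\t60\t{n1}M\t=\t{r2.start + 1}\t"
        f"{tlen}\t*\t*\tNH:i:1\tRG:Z:{period}",
        f"{qname}\t147\t{r2.chrom}\t{r2.start + 1}\t60\t{n2}M\t=\t{r1.start + 1}\t"
        f"{-tlen}\t*\t*\tNH:i:1\tRG:Z:{period}",
    ]


def simulate_study(
    n_recursive: int = 5,
    n_decoy: int = 5,
    intron_length_range: tuple[int, int] = (12_000, 20_000),
    start_density: float = 30.0,
    rs_junction_reads: dict[int, int] = None,
    spanning_reads: int = 6,
    n_spanning_pairs: int = 12,
    n_background_pairs: int = 60,
    tpm: float = 50.0,
    seed: int = 0,
) -> StudyFixture:
    """Build a full synthetic study: `n_recursive` genes whose single long
    intron carries one mid-intron recursive site (sawtooth coverage, 5'SS->RS
    junction reads, spanning read pairs) and `n_decoy` genes with a plain
    single-decay intron and no recursive evidence."""
    if rs_junction_reads is None:
        rs_junction_reads = {5: 4, 10: 3, 20: 2}
    rng = np.random.default_rng(seed)
    exon_len, flank = 600, 1000
    genome: dict[str, str] = {}
    genes: list[SimulatedGene] = []
    sam_body: list[str] = []
    coverage: dict[str, np.ndarray] = {}
    tpms: dict[str, float] = {}
    periods = (5, 10, 20)

    names = [f"rec{i + 1}" for i in range(n_recursive)] + [
        f"dec{i + 1}" for i in range(n_decoy)
    ]
    for gi, gene_id in enumerate(names):
        recursive = gene_id.startswith("rec")
        chrom = f"chr_{gene_id}"
        length = int(rng.integers(*intron_length_range))
        if recursive:
            offset = int(length * rng.uniform(0.4, 0.6))
            spec = SimulatedIntronSpec(
                length, (offset,), (start_density, start_density)
            )
        else:
            offset = None
            spec = SimulatedIntronSpec(length, (), (start_density,))
        counts, intron_seq = simulate_sawtooth_coverage(
            spec, seed=int(rng.integers(2**31))
        )

        exon1 = (flank, flank + exon_len)
        intron = (exon1[1], exon1[1] + length)
        exon2 = (intron[1], intron[1] + exon_len)
        total = exon2[1] + flank
        seq = _random_seq(total, rng)
        seq[intron[0] : intron[1]] = list(intron_seq)
        _plant(seq, intron[0], DONOR_CONSENSUS)
        _plant(seq, intron[1] - len(ACCEPTOR_CONSENSUS), ACCEPTOR_CONSENSUS)
        # keep the donor/acceptor boundaries unambiguous: no AG right before
        # the intron and no stray AG|GT inside the splice-site windows
        seq[intron[0] - 2 : intron[0]] = ["C", "C"]
        site = intron[0] + offset if recursive else None
        genome[chrom] = "".join(seq)
        genes.append(SimulatedGene(gene_id, chrom, exon1, intron, exon2, site, spec))
        coverage[gene_id] = counts
        tpms[gene_id] = tpm

        donor, acceptor = intron
        for k in range(spanning_reads):
            sam_body.append(
                _junction_read(
                    f"{gene_id}_span{k}", chrom, donor, acceptor, periods[k % 3]
                )
            )
        if recursive:
            n = 0
            for period, count in rs_junction_reads.items():
                for _ in range(count):
                    sam_body.append(
                        _junction_read(f"{gene_id}_rs{n}", chrom, donor, site, period)
                    )
                    n += 1
            pair_seed = int(rng.integers(2**31))
            pairs = simulate_read_pairs(
                n_spanning_pairs, donor, site, chrom, seed=pair_seed
            )
            for k, pair in enumerate(pairs):
                sam_body.extend(
                    _pair_records(f"{gene_id}_pair{k}", pair, periods[k % 3])
                )
        # exonic background pairs (fragment-length distribution evidence)
        for k in range(n_background_pairs):
            f = max(int(rng.normal(300, 50)), 110)
            start = int(rng.integers(exon2[0], exon2[1] - f))
            r1 = AlignedRead(chrom, start, start + 51,
                             (ReadSegment(chrom, start, start + 51),))
            r2 = AlignedRead(chrom, start + f - 51, start + f,
                             (ReadSegment(chrom, start + f - 51, start + f),))
            sam_body.extend(
                _pair_records(
                    f"{gene_id}_bg{k}", AlignedReadPair(r1, r2), periods[k % 3]
                )
            )

    sam_text = "\n".join(_sam_header(genome) + sam_body) + "\n"
    return StudyFixture(genome, genes, sam_text, tpms, coverage)


def write_study(study: StudyFixture, outdir) -> dict[str, str]:
    """Write genome.fa / annotation.gff3 / reads.sam / tpm.tsv /
    coverage.bedgraph / truth.tsv under `outdir`; returns the path map."""
    import os

    from .genome_io import write_bedgraph

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fn) for name, fn in [
        ("genome", "genome.fa"), ("annotation", "annotation.gff3"),
        ("reads", "reads.sam"), ("tpm", "tpm.tsv"),
        ("coverage", "coverage.bedgraph"), ("truth", "truth.tsv"),
    ]}
    with open(paths["genome"], "w") as fh:
        for chrom, seq in study.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["annotation"], "w") as fh:
        fh.write(study.gff3())
    with open(paths["reads"], "w") as fh:
        fh.write(study.sam_text)
    with open(paths["tpm"], "w") as fh:
        for gene, val in study.tpm.items():
            fh.write(f"{gene}\t{val}\n")
    with open(paths["coverage"], "w") as fh:
        pass
    for gene in study.genes:
        tmp = os.path.join(outdir, f".cov_{gene.id}")
        write_bedgraph(gene.chrom, gene.intron[0], study.coverage[gene.id], tmp)
        with open(tmp) as src, open(paths["coverage"], "a") as dst:
            dst.write(src.read())
        os.remove(tmp)
    with open(paths["truth"], "w") as fh:
        for gene in study.genes:
            fh.write(f"{gene.id}\t{'' if gene.site is None else gene.site}\n")
    return paths
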