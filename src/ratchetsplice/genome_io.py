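"""Annotation, genome, alignment and table I/O.

Parses GFF3/GTF into the internal annotation model (introns derived as gaps
between consecutive exons), extracts split-read splice junctions from SAM/BAM
via pysam, and writes BED/bedGraph/TSV outputs. Internal coordinates are
0-based half-open on the forward strand; GFF/GTF input (1-based closed) is
converted on load and restored on write.
"""

from __future__ import annotations

import collections
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .model import (
    AlignedRead,
    AlignedReadPair,
    Gene,
    Intron,
    IntronRecord,
    JunctionEvidence,
    ReadSegment,
    Transcript,
)


class AnnotationError(ValueError):
    """Malformed annotation input; carries the offending line."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class GenomeAnnotation:
    """Genes, transcripts and derived introns from a GFF3/GTF annotation."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self):
        self._introns: list[Intron] | None = None

    @property
    def introns(self) -> list[Intron]:
        """All distinct introns (per gene), derived from transcript exon gaps."""
        if self._introns is None:
            out: list[Intron] = []
            for gene in self.genes.values():
                seen = set()
                for tx in gene.transcripts:
                    for start, end in tx.introns():
                        if (start, end) not in seen:
                            seen.add((start, end))
                            out.append(
                                Intron(gene.chrom, start, end, gene.strand, gene.id)
                            )
            self._introns = out
        return self._introns

    def donors(self) -> set[tuple[str, int, str]]:
        """Annotated 5' splice sites as (chrom, coordinate, strand)."""
        return {(i.chrom, i.donor, i.strand) for i in self.introns}

    def acceptors(self) -> set[tuple[str, int, str]]:
        """Annotated 3' splice sites as (chrom, coordinate, strand)."""
        return {(i.chrom, i.acceptor, i.strand) for i in self.introns}

    def junction_set(self) -> set[tuple[str, int, int]]:
        """Annotated exon-exon junctions as forward-strand (chrom, start, end)."""
        return {(i.chrom, i.start, i.end) for i in self.introns}

    def introns_sharing_donor(self, intron: Intron) -> list[Intron]:
        return [
            i
            for i in self.introns
            if i.gene_id == intron.gene_id and i.donor == intron.donor
        ]

    def largest_intron_sharing_donor(self, intron: Intron) -> Intron:
        """The longest annotated intron using the same 5' splice site.

        Used by the candidate filter that counts 5'->3' spanning reads over
        "the largest annotated intron"."""
        return max(self.introns_sharing_donor(intron), key=lambda i: i.length)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse GFF3 (`k=v;`) or GTF (`k "v";`) attribute strings."""
    attrs: dict[str, str] = {}
    if "=" in attr_field and '"' not in attr_field:
        for part in attr_field.rstrip(";").split(";"):
            if not part.strip():
                continue
            key, _, value = part.strip().partition("=")
            attrs[key] = value.split(",")[0]
    else:
        for part in attr_field.rstrip(";").split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(source: str | io.TextIOBase) -> GenomeAnnotation:
    """Parse GFF3 or GTF text (path, text, or stream) into a GenomeAnnotation.

    1-based closed GFF coordinates become 0-based half-open. Introns are the
    gaps between consecutive exons of each transcript. Exon features that are
    out of order within a transcript, or whose parent transcript cannot be
    resolved, are rejected with the offending line reported.
    """
    if isinstance(source, str):
        if "\t" in source or "\n" in source:
            text = source
        else:
            with open(source) as fh:
                text = fh.read()
    else:
        text = source.read()

    tx_exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tx -> (chrom, strand)
    gene_meta: dict[str, tuple[str, str]] = {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise AnnotationError(f"malformed feature line: {raw!r}")
        chrom, _, ftype, start1, end1, _, strand, _, attr_field = fields[:9]
        start, end = int(start1) - 1, int(end1)
        attrs = _parse_attributes(attr_field)
        ftype = ftype.lower()
        if ftype == "gene":
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid:
                gene_meta[gid] = (chrom, strand)
        elif ftype in ("transcript", "mrna"):
            tid = attrs.get("ID") or attrs.get("transcript_id")
            gid = attrs.get("Parent") or attrs.get("gene_id")
            if tid is None:
                raise AnnotationError(f"transcript without ID: {raw!r}")
            tx_gene[tid] = gid or tid
            tx_meta[tid] = (chrom, strand)
        elif ftype == "exon":
            tid = attrs.get("Parent") or attrs.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"orphan exon (no parent transcript): {raw!r}")
            exons = tx_exons[tid]
            if exons and start < exons[-1][1]:
                raise AnnotationError(
                    f"unsorted or overlapping exon within transcript {tid}: {raw!r}"
                )
            exons.append((start, end))
            if tid not in tx_meta:
                tx_meta[tid] = (chrom, strand)
            if tid not in tx_gene and "gene_id" in attrs:
                tx_gene[tid] = attrs["gene_id"]

    for tid in tx_exons:
        if tid not in tx_gene:
            # GTF without explicit transcript rows and no gene_id on exons
            raise AnnotationError(f"orphan exons: transcript {tid} has no gene")

    genes: dict[str, Gene] = {}
    by_gene: dict[str, list[Transcript]] = collections.defaultdict(list)
    for tid, exons in tx_exons.items():
        by_gene[tx_gene[tid]].append(Transcript(tid, tuple(exons)))
    for gid, txs in by_gene.items():
        chrom, strand = gene_meta.get(gid) or tx_meta[txs[0].id]
        genes[gid] = Gene(gid, chrom, strand, tuple(sorted(txs, key=lambda t: t.id)))
    return GenomeAnnotation(genes)


def annotation_to_gff3(ann: GenomeAnnotation) -> str:
    """Serialize back to GFF3 (restores 1-based closed coordinates)."""
    lines = ["##gff-version 3"]
    for gene in ann.genes.values():
        gstart = min(tx.exons[0][0] for tx in gene.transcripts)
        gend = max(tx.exons[-1][1] for tx in gene.transcripts)
        lines.append(
            f"{gene.chrom}\t.\tgene\t{gstart + 1}\t{gend}\t.\t{gene.strand}\t.\t"
            f"ID={gene.id}"
        )
        for tx in gene.transcripts:
            lines.append(
                f"{gene.chrom}\t.\tmRNA\t{tx.exons[0][0] + 1}\t{tx.exons[-1][1]}\t.\t"
                f"{gene.strand}\t.\tID={tx.id};Parent={gene.id}"
            )
            for start, end in tx.exons:
                lines.append(
                    f"{gene.chrom}\t.\texon\t{start + 1}\t{end}\t.\t{gene.strand}\t.\t"
                    f"Parent={tx.id}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------


class SequenceStore:
    """Uniform fetch() over a pyfaidx.Fasta or an in-memory {chrom: seq} dict."""

    def __init__(self, source):
        if isinstance(source, str):
            import pyfaidx

            source = pyfaidx.Fasta(source, as_raw=True, sequence_always_upper=True)
        self._src = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(start, 0)
        if isinstance(self._src, dict):
            return self._src[chrom][start:end].upper()
        return str(self._src[chrom][start:end]).upper()

    def length(self, chrom: str) -> int:
        return len(self._src[chrom])

    def chroms(self) -> list[str]:
        return list(self._src.keys())


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _is_unique(read: pysam.AlignedSegment) -> bool:
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality > 3


def _cigar_segments(read: pysam.AlignedSegment) -> list[ReadSegment]:
    """Split an alignment at N-gaps into reference segments."""
    segs = []
    pos = read.reference_start
    seg_start = pos
    for op, length in read.cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length
        elif op == 3:  # N gap: close segment
            segs.append(ReadSegment(read.reference_name, seg_start, pos))
            pos += length
            seg_start = pos
    segs.append(ReadSegment(read.reference_name, seg_start, pos))
    return segs


def iter_aligned_reads(
    path: str, region: tuple[str, int, int] | None = None, unique_only: bool = True
):
    """Yield (AlignedRead, period, read_name, is_read1) over a SAM/BAM file.

    The labeling period (minutes) is taken from the read group ID when it is
    an integer, else None. Multi-mapped reads are excluded by default.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        it = fh.fetch(*region) if region else fh
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if unique_only and not _is_unique(read):
                continue
            period = None
            if read.has_tag("RG"):
                rg = str(read.get_tag("RG"))
                if rg.isdigit():
                    period = int(rg)
            segs = tuple(_cigar_segments(read))
            aligned = AlignedRead(
                read.reference_name, read.reference_start, read.reference_end, segs
            )
            yield aligned, period, read.query_name, not read.is_read2


def extract_junction_reads(
    path: str,
    region: tuple[str, int, int] | None = None,
    unique_only: bool = True,
) -> list[JunctionEvidence]:
    """Aggregate split-read junctions from CIGAR N-gaps.

    Donor = reference position where the gap starts (exclusive end of the last
    aligned base before the gap); acceptor = first aligned base after the gap.
    Reads without gaps are ignored. Counts are aggregated per (junction,
    labeling period).
    """
    counts: dict[tuple[str, int, int], collections.Counter] = collections.defaultdict(
        collections.Counter
    )
    for read, period, _, _ in iter_aligned_reads(path, region, unique_only):
        for donor, acceptor in read.junctions():
            counts[(read.chrom, donor, acceptor)][period] += 1
    out = []
    for (chrom, donor, acceptor), per_period in sorted(counts.items()):
        out.append(
            JunctionEvidence(
                chrom, donor, acceptor, tuple(sorted(per_period.items(), key=str))
            )
        )
    return out


def read_pairs_from_sam(
    path: str, unique_only: bool = True
) -> list[AlignedReadPair]:
    """Pair mates by query name into AlignedReadPair (read1 = leftmost mate)."""
    first: dict[str, tuple[AlignedRead, int | None, bool]] = {}
    pairs = []
    for read, period, name, is_read1 in iter_aligned_reads(path, None, unique_only):
        if name not in first:
            first[name] = (read, period, is_read1)
            continue
        mate, mperiod, _ = first.pop(name)
        r1, r2 = (mate, read) if mate.start <= read.start else (read, mate)
        pairs.append(AlignedReadPair(r1, r2, True, period or mperiod))
    return pairs


def coverage_from_sam(
    path: str, chrom: str, start: int, end: int, unique_only: bool = True
) -> np.ndarray:
    """Per-base read-pair coverage over [start, end).

    Positions straddled by a read pair (between the mates) count as covered,
    matching the pre-processing used for sawtooth detection; split-read gaps
    within a mate do not."""
    cov = np.zeros(end - start, dtype=float)
    spans: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    for read, _, name, _ in iter_aligned_reads(path, None, unique_only):
        if read.chrom != chrom:
            continue
        spans[name].append((read.start, read.end))
    for intervals in spans.values():
        lo = min(s for s, _ in intervals)
        hi = max(e for _, e in intervals)
        a, b = max(lo, start), min(hi, end)
        if a < b:
            cov[a - start : b - start] += 1
    return cov


# ---------------------------------------------------------------------------
# tables and tracks
# ---------------------------------------------------------------------------


def read_tpm_table(path: str) -> dict[str, float]:
    """Two-column TSV (gene id, TPM) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "tpm"], comment="#")
    return dict(zip(df["gene"].astype(str), df["tpm"].astype(float)))


def write_introns_bed(introns: list[Intron], path: str) -> None:
    with open(path, "w") as fh:
        for i in introns:
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{i.gene_id}\t0\t{i.strand}\n"
            )


def read_introns_bed(path: str) -> list[Intron]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, name, _, strand = line.rstrip("\n").split("\t")[:6]
            out.append(Intron(chrom, int(start), int(end), strand, name))
    return out


def write_bedgraph(chrom: str, start: int, values: np.ndarray, path: str) -> None:
    """Run-length-encoded bedGraph of a per-base value array."""
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                fh.write(
                    f"{chrom}\t{start + run_start}\t{start + i}\t"
                    f"{values[run_start]:g}\n"
                )
                run_start = i


def read_bedgraph(path: str, chrom: str, start: int, end: int) -> np.ndarray:
    values = np.zeros(end - start, dtype=float)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            c, s, e, v = line.split("\t")[:4]
            if c != chrom:
                continue
            a, b = max(int(s), start), min(int(e), end)
            if a < b:
                values[a - start : b - start] = float(v)
    return values


S1_COLUMNS = [
    "intron",
    "gene",
    "TPM",
    "completed_splicing_junction_reads",
    "recursive_site",
    "method",
    "high_confidence",
    "junction_reads",
    "spanning_read_pairs",
    "sawtooth_score",
    "mcmc_probability",
    "recursive_index",
    "motif",
    "motif_score",
]


def _period_list(support: dict[int, int], periods=(5, 10, 20)) -> str:
    vals = [support.get(p, 0) for p in periods]
    return ",".join(str(v) for v in vals + [sum(vals)])


def calls_to_table(calls, records: dict[str, IntronRecord] | None = None) -> pd.DataFrame:
    """Render RecursiveSiteCalls as the summary table (one row per site)."""
    rows = []
    for call in calls:
        i = call.intron
        rec = (records or {}).get(f"{i.chrom}:{i.start}-{i.end}")
        rows.append(
            {
                "intron": f"{i.chrom}:{i.start}-{i.end}:{i.strand}",
                "gene": i.gene_id,
                "TPM": rec.tpm if rec else "",
                "completed_splicing_junction_reads": rec.spanning_reads if rec else "",
                "recursive_site": call.site,
                "method": "+".join(sorted(call.methods)),
                "high_confidence": int(call.confidence == "high"),
                "junction_reads": _period_list(call.junction_support),
                "spanning_read_pairs": _period_list(call.pair_support),
                "sawtooth_score": ""
                if call.sawtooth_score is None
                else round(call.sawtooth_score, 6),
                "mcmc_probability": ""
                if call.mcmc_probability is None
                else round(call.mcmc_probability, 6),
                "recursive_index": "",  # named in the table spec but undefined
                "motif": call.motif,
                "motif_score": ""
                if call.motif_score is None
                else round(float(call.motif_score), 6),
            }
        )
    return pd.DataFrame(rows, columns=S1_COLUMNS)
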