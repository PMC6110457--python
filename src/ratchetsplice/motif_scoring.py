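"""Splice-site position weight matrices and normalized bit scoring.

A recursive site juxtaposes a 3' splice-site motif (intronic window ending in
AG) with a 5' splice-site motif (intronic window starting with GT). PWMs are
trained on all annotated splice sites; a candidate window is scored by the sum
of per-column log probabilities, normalized to [0, 1] by subtracting the
minimum attainable bit score and dividing by the attainable range:

    M(i) = (sum_c log2 p_c(base_c) - min) / (max - min)

so the per-column-consensus window scores exactly 1 and the anti-consensus
window exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeAnnotation, SequenceStore, revcomp

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SpliceSitePWM:
    """Juxtaposed 3'SS + 5'SS position weight matrix.

    acceptor: (acceptor_len, 4) probabilities for the intronic 3'SS window
        (last `acceptor_len` intronic nt, ending in AG).
    donor: (donor_len, 4) probabilities for the intronic 5'SS window
        (first `donor_len` intronic nt, starting with GT).
    The juxtaposed matrix is acceptor columns followed by donor columns; the
    scored genomic window runs [site - acceptor_len, site + donor_len) with
    the AG|GT boundary at `site`.
    """

    acceptor: np.ndarray
    donor: np.ndarray

    def __post_init__(self):
        for mat in (self.acceptor, self.donor):
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("PWM columns must sum to 1")
        self._logp = np.log2(self.juxtaposed)
        self._col_min = self._logp.min(axis=1)
        self._col_max = self._logp.max(axis=1)
        self.min_score = float(self._col_min.sum())
        self.max_score = float(self._col_max.sum())
        if not self.max_score > self.min_score:
            raise ValueError("degenerate PWM: max score equals min score")

    @property
    def juxtaposed(self) -> np.ndarray:
        return np.vstack([self.acceptor, self.donor])

    @property
    def acceptor_len(self) -> int:
        return self.acceptor.shape[0]

    @property
    def donor_len(self) -> int:
        return self.donor.shape[0]

    @property
    def width(self) -> int:
        return self.acceptor_len + self.donor_len

    def bit_score(self, window: str) -> float:
        """Sum of per-column log2 probabilities; N contributes the column
        minimum (conservative)."""
        if len(window) != self.width:
            raise ValueError(
                f"window length {len(window)} != juxtaposed width {self.width}"
            )
        total = 0.0
        for c, base in enumerate(window.upper()):
            i = _IDX.get(base)
            total += self._logp[c, i] if i is not None else self._col_min[c]
        return total

    def score(self, window: str) -> float:
        """Normalized bit score M(i) in [0, 1]."""
        return (self.bit_score(window) - self.min_score) / (
            self.max_score - self.min_score
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.juxtaposed.argmax(axis=1))

    def to_text(self) -> str:
        lines = [f"# acceptor_len={self.acceptor_len} donor_len={self.donor_len}"]
        lines.append("pos\t" + "\t".join(BASES))
        for c, row in enumerate(self.juxtaposed):
            lines.append(f"{c}\t" + "\t".join(f"{p:.6g}" for p in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SpliceSitePWM":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0]
        kv = dict(part.split("=") for part in header.lstrip("# ").split())
        a_len = int(kv["acceptor_len"])
        rows = [
            [float(x) for x in ln.split("\t")[1:5]]
            for ln in lines[2:]
        ]
        mat = np.array(rows)
        return cls(mat[:a_len], mat[a_len:])


def _counts_to_probs(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = counts + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def intron_boundary_windows(
    intron, genome: SequenceStore, acceptor_len: int, donor_len: int
) -> tuple[str, str]:
    """Strand-corrected (acceptor_window, donor_window) for one intron.

    The donor window is the first `donor_len` intronic nt in transcript
    orientation (starts with GT for canonical introns); the acceptor window is
    the last `acceptor_len` intronic nt (ends with AG)."""
    if intron.strand == "+":
        donor_w = genome.fetch(intron.chrom, intron.start, intron.start + donor_len)
        accept_w = genome.fetch(intron.chrom, intron.end - acceptor_len, intron.end)
    else:
        donor_w = revcomp(genome.fetch(intron.chrom, intron.end - donor_len, intron.end))
        accept_w = revcomp(
            genome.fetch(intron.chrom, intron.start, intron.start + acceptor_len)
        )
    return accept_w, donor_w


def build_pwms(
    annotation: GenomeAnnotation,
    genome: SequenceStore,
    acceptor_len: int = 20,
    donor_len: int = 6,
    pseudocount: float = 1.0,
) -> SpliceSitePWM:
    """Tally strand-corrected intronic splice-site windows over all annotated
    introns into a juxtaposed PWM (pseudocount per base per column)."""
    if not annotation.introns:
        raise ValueError("empty annotation: no introns to train on")
    acc_counts = np.zeros((acceptor_len, 4))
    don_counts = np.zeros((donor_len, 4))
    for intron in annotation.introns:
        if intron.length < max(acceptor_len, donor_len):
            continue
        accept_w, donor_w = intron_boundary_windows(
            intron, genome, acceptor_len, donor_len
        )
        for c, base in enumerate(accept_w.upper()):
            if base in _IDX:
                acc_counts[c, _IDX[base]] += 1
        for c, base in enumerate(donor_w.upper()):
            if base in _IDX:
                don_counts[c, _IDX[base]] += 1
    return SpliceSitePWM(
        _counts_to_probs(acc_counts, pseudocount),
        _counts_to_probs(don_counts, pseudocount),
    )


def site_window(
    genome: SequenceStore, chrom: str, site: int, strand: str, pwm: SpliceSitePWM
) -> str:
    """Strand-corrected juxtaposed window around an AG|GT boundary at `site`."""
    if strand == "+":
        return genome.fetch(chrom, site - pwm.acceptor_len, site + pwm.donor_len)
    return revcomp(genome.fetch(chrom, site - pwm.donor_len, site + pwm.acceptor_len))


def score_site(
    genome: SequenceStore, chrom: str, site: int, strand: str, pwm: SpliceSitePWM
) -> tuple[float, str, bool]:
    """Score the juxtaposed window centered at the AG|GT boundary `site`.

    Returns (M, window, canonical_center); the score is reported even when the
    center is not AG|GT, with the flag set False."""
    window = site_window(genome, chrom, site, strand, pwm)
    center = window[pwm.acceptor_len - 2 : pwm.acceptor_len + 2]
    return pwm.score(window), window, center == "AGGT"


def find_aggt_sites(seq: str, offset: int = 0) -> list[int]:
    """All AG|GT boundary coordinates in `seq` (positions such that
    seq[p-2:p+2] == 'AGGT'), shifted by `offset` into genomic coordinates."""
    out = []
    start = 0
    seq = seq.upper()
    while True:
        hit = seq.find("AGGT", start)
        if hit < 0:
            return out
        out.append(offset + hit + 2)
        start = hit + 1
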