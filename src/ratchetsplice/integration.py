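"""Evidence integration: merge the three detectors, filter candidates, assign
confidence tiers, and run subsampling-sensitivity and iterative GO analyses.

Candidate filters (any failure removes the call, with the reason recorded):
(1) parent gene TPM >= 1; (2) at least 3 reads spanning the 5' to 3' splice
sites of the largest annotated intron sharing the donor; (3) the site does
not coincide with an annotated 5' splice site.

Confidence tiers: high = detected by >= 2 methods AND (junction + pair
support > 5 OR sawtooth FDR <= 5%); medium = detected by >= 1 method AND
(support > 5 OR FDR <= 20%); everything else is rejected. The tiers form a
partition (a high call is never also medium).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, fisher_exact

from . import genome_io, kinetics, motif_scoring, ratchet_junction, ratchet_pair
from . import ratchet_scan as scan
from .genome_io import GenomeAnnotation, SequenceStore
from .model import Intron, IntronRecord, RecursiveSiteCall


def filter_candidates(
    calls: list[RecursiveSiteCall],
    records: dict[str, IntronRecord],
    annotation: GenomeAnnotation,
    min_tpm: float = 1.0,
    min_spanning: int = 3,
) -> tuple[list[RecursiveSiteCall], list[tuple[RecursiveSiteCall, str]]]:
    """Apply the three candidate filters; returns (kept, removed+reason)."""
    donors = annotation.donors()
    kept, removed = [], []
    for call in calls:
        i = call.intron
        rec = records.get(f"{i.chrom}:{i.start}-{i.end}")
        if rec is None or rec.tpm < min_tpm:
            removed.append((call, "TPM"))
        elif rec.spanning_reads < min_spanning:
            removed.append((call, "spanning"))
        elif (i.chrom, call.site, i.strand) in donors:
            removed.append((call, "5SS-overlap"))
        else:
            kept.append(call)
    return kept, removed


def assign_confidence(
    call: RecursiveSiteCall,
    min_support: int = 5,
    high_methods: int = 2,
    high_fdr: float = 0.05,
    medium_methods: int = 1,
    medium_fdr: float = 0.20,
) -> str:
    """Tier = (method count >= k) AND (support > 5 OR FDR <= threshold),
    with k = 2 / 5% for high and k = 1 / 20% for medium. Support sums
    junction reads and spanning pairs. Sets and returns call.confidence."""
    support = call.junction_total + call.pair_total
    fdr = call.fdr if call.fdr is not None else 1.0
    n = len(call.methods)
    if n >= high_methods and (support > min_support or fdr <= high_fdr):
        tier = "high"
    elif n >= medium_methods and (support > min_support or fdr <= medium_fdr):
        tier = "medium"
    else:
        tier = "rejected"
    call.confidence = tier
    return tier


# ---------------------------------------------------------------------------
# subsampling sensitivity
# ---------------------------------------------------------------------------


def subsample_sam(sam_text: str, fraction: float, seed: int = 0) -> str:
    """Bernoulli-subsample a SAM's reads (mates kept or dropped together)."""
    rng = random.Random(seed)
    decisions: dict[str, bool] = {}
    out = []
    for line in sam_text.splitlines():
        if line.startswith("@"):
            out.append(line)
            continue
        qname = line.split("\t", 1)[0]
        if qname not in decisions:
            decisions[qname] = rng.random() < fraction
        if decisions[qname]:
            out.append(line)
    return "\n".join(out) + "\n"


def subsample_sensitivity(
    sam_text: str,
    fractions: list[float],
    pipeline,
    seed: int = 0,
) -> dict[float, int]:
    """Detections per subsampling fraction. `pipeline` maps SAM text to a
    detection count; fraction 1.0 bypasses subsampling entirely."""
    out = {}
    for k, fraction in enumerate(fractions):
        text = (
            sam_text
            if fraction >= 1.0
            else subsample_sam(sam_text, fraction, seed + k)
        )
        out[fraction] = pipeline(text)
    return out


# ---------------------------------------------------------------------------
# iterative GO enrichment
# ---------------------------------------------------------------------------


def iterative_go_enrichment(
    foreground: set[str],
    background: set[str],
    ontology: dict[str, set[str]],
) -> pd.DataFrame:
    """Iterative Fisher-exact GO enrichment with term-set elimination.

    Each round tests every term on the current foreground/background (2x2
    Fisher exact, enrichment alternative), takes the most significant term,
    then removes its genes from both sets; repeats until the foreground is
    exhausted. Benjamini-Hochberg correction is applied across the reported
    terms. Background genes also in the foreground are excluded from the
    background margin."""
    fg = set(foreground)
    bg = set(background) - fg
    rows = []
    while fg:
        best = None
        for term, genes in ontology.items():
            fg_in = len(fg & genes)
            if fg_in == 0:
                continue
            table = [
                [fg_in, len(fg) - fg_in],
                [len(bg & genes), len(bg) - len(bg & genes)],
            ]
            p = fisher_exact(table, alternative="greater")[1]
            if best is None or (p, term) < (best[1], best[0]):
                best = (term, p, fg_in)
        if best is None:
            break
        term, p, fg_in = best
        rows.append({"term": term, "p": p, "foreground_genes": fg_in})
        fg -= ontology[term]
        bg -= ontology[term]
    df = pd.DataFrame(rows, columns=["term", "p", "foreground_genes"])
    if len(df):
        df["p_adjusted"] = false_discovery_control(df["p"], method="bh")
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    iterations: int = 10_000_000
    burn_in: int = 100_000
    sample_every: int = 50
    n_shuffles: int = 100
    seed: int = 0
    min_tpm: float = 1.0
    min_spanning: int = 3
    fdr_keep: float = 0.05  # final report keeps scan-only calls at this FDR
    acceptor_len: int = 20
    donor_len: int = 6


@dataclass
class PipelineResult:
    calls: list[RecursiveSiteCall]
    removed: list[tuple[RecursiveSiteCall, str]]
    records: dict[str, IntronRecord]
    table: pd.DataFrame = field(default=None)

    def accepted(self) -> list[RecursiveSiteCall]:
        return [c for c in self.calls if c.confidence in ("high", "medium")]


def _intron_candidates(genome, intron, pwm):
    """(site, M) for every AG|GT boundary inside an intron, transcript
    orientation, away from the splice-site windows themselves."""
    from .motif_scoring import find_aggt_sites

    seq = genome.fetch(intron.chrom, intron.start, intron.end)
    if intron.strand == "+":
        sites = find_aggt_sites(seq, offset=intron.start)
    else:
        sites = [intron.end - q for q in find_aggt_sites(genome_io.revcomp(seq))]
    margin = max(pwm.acceptor_len, pwm.donor_len)
    out = []
    for site in sites:
        if min(site - intron.start, intron.end - site) < margin:
            continue
        m = motif_scoring.score_site(genome, intron.chrom, site, intron.strand, pwm)[0]
        out.append((site, m))
    return out


def run_pipeline(
    annotation: GenomeAnnotation,
    genome: SequenceStore,
    sam_path: str,
    tpm: dict[str, float],
    coverage: dict[str, np.ndarray] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full detection pipeline over one study.

    Extracts junctions and read pairs from `sam_path`, trains the splice-site
    PWM from the annotation, runs all three detectors per intron, merges
    per-site evidence, applies the candidate filters and assigns tiers.
    `coverage` maps gene id -> per-base intron counts; when absent, coverage
    is computed from the alignments."""
    cfg = config or PipelineConfig()
    pwm = motif_scoring.build_pwms(
        annotation, genome, cfg.acceptor_len, cfg.donor_len
    )
    junctions = genome_io.extract_junction_reads(sam_path)
    pairs = genome_io.read_pairs_from_sam(sam_path)

    records: dict[str, IntronRecord] = {}
    for intron in annotation.introns:
        records[f"{intron.chrom}:{intron.start}-{intron.end}"] = IntronRecord(
            intron,
            tpm.get(intron.gene_id, 0.0),
            ratchet_junction.spanning_read_count(junctions, annotation, intron),
        )

    merged: dict[tuple[str, int], RecursiveSiteCall] = {}

    def get_call(intron: Intron, site: int) -> RecursiveSiteCall:
        key = (intron.chrom, site)
        if key not in merged:
            m, window, _ = motif_scoring.score_site(
                genome, intron.chrom, site, intron.strand, pwm
            )
            merged[key] = RecursiveSiteCall(
                intron, site, set(), motif=window, motif_score=m
            )
        return merged[key]

    # --- junction detector
    for jcall in ratchet_junction.find_ratchet_junctions(
        junctions, annotation, genome, pwm
    ):
        call = get_call(jcall.intron, jcall.site)
        call.methods.add("junction")
        call.junction_support = jcall.junction_support

    # --- read-pair detector (EM over candidate AG|GT positions)
    spanning = ratchet_pair.select_spanning_pairs(pairs, annotation)
    if spanning:
        frag = ratchet_pair.estimate_fragment_distribution(
            ratchet_pair.pooled_inserts(pairs, annotation)
        )
        for intron, intron_pairs in spanning.items():
            candidates = _intron_candidates(genome, intron, pwm)
            junction_counts = {
                site: sum(
                    j.total
                    for j in junctions
                    if j.chrom == intron.chrom
                    and (j.acceptor if intron.strand == "+" else j.donor) == site
                )
                for site, _ in candidates
            }
            result = ratchet_pair.gem_infer_sites(
                intron_pairs, junction_counts, frag, candidates,
                intron.donor, intron.strand,
            )
            if result is None:
                continue
            support = result.pair_support([p.period for p in intron_pairs])
            for site, per_period in support.items():
                call = get_call(intron, site)
                call.methods.add("pair")
                call.pair_support = per_period

    # --- sawtooth detector
    seed_rng = np.random.default_rng(cfg.seed)
    for intron in annotation.introns:
        key = f"{intron.chrom}:{intron.start}-{intron.end}"
        rec = records[key]
        counts = None
        if coverage is not None and intron.gene_id in coverage:
            counts = coverage[intron.gene_id]
        elif coverage is None:
            counts = genome_io.coverage_from_sam(
                sam_path, intron.chrom, intron.start, intron.end
            )
        if counts is None or len(counts) != intron.length:
            continue
        try:
            profile = scan.preprocess_coverage(
                counts, intron, spanning_reads=rec.spanning_reads
            )
        except scan.ProfileError:
            continue
        track = scan.mcmc_sawtooth(
            profile, cfg.iterations, cfg.burn_in, cfg.sample_every,
            seed=int(seed_rng.integers(2**31)),
        )
        peaks = scan.estimate_sawtooth_fdr(
            track, profile, genome, pwm,
            n_shuffles=cfg.n_shuffles, seed=int(seed_rng.integers(2**31)),
        )
        for peak in peaks:
            call = get_call(intron, peak.site)
            call.methods.add("sawtooth")
            call.sawtooth_score = peak.score
            call.mcmc_probability = peak.probability
            call.fdr = peak.fdr
        # automated sawtooth-presence flag for every call in this intron
        for call in merged.values():
            if call.intron == intron:
                offset = abs(call.site - intron.start)
                b = min(
                    profile.offset_to_retained(offset) // profile.bin_size,
                    profile.n_bins - 1,
                )
                try:
                    call.sawtooth_jump = bool(scan.jump_fold(profile, b) >= 1.5)
                except ValueError:
                    call.sawtooth_jump = None

    calls = sorted(merged.values(), key=lambda c: (c.intron.chrom, c.site))
    kept, removed = filter_candidates(
        calls, records, annotation, cfg.min_tpm, cfg.min_spanning
    )
    for call in kept:
        assign_confidence(call)
    # scan-only calls additionally gated by the reporting FDR
    final = []
    for call in kept:
        if call.methods == {"sawtooth"} and (
            call.fdr is None or call.fdr > cfg.fdr_keep
        ) and call.confidence != "medium":
            call.confidence = "rejected"
        final.append(call)
    result = PipelineResult(final, removed, records)
    result.table = genome_io.calls_to_table(
        [c for c in final if c.confidence in ("high", "medium")], records
    )
    return result
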