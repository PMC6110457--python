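# Methods

This note documents the models implemented in `ratchetsplice`, the parameter
choices that matter, the design decisions taken where the design was open,
and the limits of what the synthetic fixtures demonstrate.

## Data model and coordinates

All intervals are 0-based half-open on the forward genomic strand; GFF3/GTF
input (1-based closed) is converted on load and restored on write. Strand
logic (which end of an intron is the 5' splice site, what "upstream" means)
is resolved at use sites. An intron is the gap between consecutive exons of a
transcript; a gene's introns are deduplicated across transcripts but introns
sharing a donor with different acceptors are all retained, and the filter
that counts 5'→3' spanning reads uses the *largest* intron sharing the
donor under test. Multi-mapped reads (NH > 1, or MAPQ ≤ 3 when NH is absent)
are excluded everywhere.

## Motif scoring

Position weight matrices for the intronic portions of the 5' and 3' splice
sites are tallied over all annotated introns, strand-corrected, with a
pseudocount of 1 per base per column. Window geometry — 20 nt ending in AG
for the acceptor portion, 6 nt starting with GT for the donor portion,
juxtaposed to a 26-nt recursive-site window centered on `AG|GT` — is a
configurable choice of typical fly intronic extents; the original extents are
not fixed by any published description. A window's normalized bit score is

    M(i) = (Σ_c log2 p_c(base_c) − min) / (max − min)

where min/max are the attainable column-sum extremes, so M ∈ [0, 1] with the
per-column consensus at exactly 1. Ambiguous bases contribute the column
minimum (conservative). Downstream thresholds (M > 0.8 for priors and peak
scoring, M > 0.85 for alternative-order junctions) are plain comparisons on
this value.

## Ratchet junctions

A split read is recursive-site evidence iff its donor edge matches an
annotated 5' splice site exactly (split aligners report exact gap edges, so
no wobble is allowed), its acceptor edge falls strictly inside the intron
before the downstream-most 3' splice site sharing that donor, and the
genomic context at the acceptor is AG|GT after strand correction.
Alternative-order events (RS→RS, RS→3'SS) require implied segments ≥ 1 kb,
≥ 3 uniquely aligned reads, and M > 0.85 at every involved recursive site.

## Read-pair inference (EM)

Candidate spanning pairs have their transcript-first mate ending within
300 nt upstream of an annotated donor (a bounded-fragment-length choice,
configurable) and their second mate inside the intron more than 1000 nt
downstream; pairs whose implied insert under completion of any annotated
splicing event drops below 1000 nt are discarded (cassette exons starting
with AG|GT can be exempted, since a recursive intermediate would mimic their
completion). The implied insert for a pair under candidate site m is
(donor − read1 start) + (read2 end − m), the only length consistent with
excision between donor and m.

The fragment-length distribution is the empirical histogram of inserts (all
pairs pooled, annotated-intron gaps subtracted), smoothed with a Gaussian
kernel of bandwidth 10 nt — the raw unit-width histogram is too sparse at
small scale, and smoothing choice is otherwise free. EM then iterates:
responsibilities ∝ Π_m·P(rₙ|m); effective counts N_m add junction reads at m
*before* sparsification (the alternative order is not determined by any
stated constraint; adding before keeps junction evidence from being eroded by
the sparsity subtraction); priors update as max(0, N_m − α) renormalized with
α = (assigned reads)/40; convergence at max |ΔΠ| ≤ 1e-5; pairs are then
MAP-assigned. Pairs whose insert is impossible under every candidate carry
uniform responsibilities but are never effectively assigned, so an
all-impossible intron collapses to an empty result. Initialization is
Π ∝ max(0, M(i) − 0.8), ties broken by position order; candidates with
M ≤ 0.8 can never acquire prior mass.

## Sawtooth MCMC

Pre-processing: introns over 8 kb with at least one spanning junction read
(shorter introns give a high false-positive rate because short-segment
regressions are noise-sensitive); exon-overlapping sub-regions excised;
RepeatMasker-style repeat intervals plus 100 nt flanks replaced by the median
of the 900 nt on each side; 100-nt bin means.

Each segment is fit by iteratively reweighted linear regression under the
assumption Var ∝ mean (read coverage is a sum of Bernoullis): weights update
to 1/prediction, floored at 1e-6 where a prediction is non-positive, until no
weight changes by more than 1e-3. As literally printed elsewhere the loop
condition would terminate immediately; the tolerance is implemented as the
stopping criterion, which is the only reading that iterates. RSS(M) is the
weighted sum of squared deviations over all segments, and

    BIC(M) = L·RSS(M) + 2·(2N)·log L,    Score(M) = exp(BIC/T),  T = 5

with L the intron length in retained nt and 2N the free parameters (slope
and intercept per segment).

The chain starts from the empty configuration (a draw from the proposal
prior concentrated at N = 0) and perturbs it each round: add a site with
probability 0.4 (uniform over bins not within 10 bins of an existing site,
preventing degenerate adjacent segments), remove one with 0.4, or shift one
by 1–5 bins with 0.2. Proposals violating the sawtooth constraint — the
downstream fit's value at each site must exceed the upstream fit's boundary
value ≥ 1.5-fold — are rejected outright, as are segments under 2 bins.
Acceptance is Metropolis: a lower-BIC state is adopted deterministically,
otherwise with probability exp(−ΔBIC/T), halved when leaving the zero-site
state (transition-imbalance correction). A verbatim ratio of Scores would
exceed 1 for worse states under Score = exp(BIC/T); the Metropolis form is
the only self-consistent reading that matches the deterministic-acceptance
direction. The default schedule is 10⁷ iterations, 10⁵ burn-in, sampling
every 50; tests and the acceptance fixtures use 10⁵ iterations with 10⁴
burn-in, which recovers strong single sites reliably because ΔBIC at a true
site is large enough that the chain behaves nearly greedily.

Per-bin sample frequencies form the probability track. Peak calling records
regions above 0.08, merges regions within 500 nt (flanks attach to the
merged region's outer edges), builds a position potential P that is 1 inside
a region with logistic flanks f(x) = 1/(1 + e^(−k(x−x₀))), x₀ = 500 nt from
each edge and |k| = 6/500 (value 0.5 exactly 500 nt outside, near 0 at
1000 nt), scores every intronic AG|GT by S(i) = P(i)·max(M(i) − 0.8, 0), and
reports the maximum-S site per region; regions whose candidates all score 0
are dropped. The FDR repositions the recorded regions uniformly across the
intron (count and lengths preserved exactly), re-applies peak calling, and
sets FDR(s) = (mean null peaks with S ≥ s)/(observed peaks with S ≥ s),
clipped to [0, 1].

## Lariat reads

Unalignable reads are split just before the 7-mer best matching the 5'SS
consensus (scored by a 7-column donor PWM; ties leftmost) and the halves
aligned as an inverted ungapped pair: each half ≥ 15 nt, ≤ 1 Hamming
mismatch, separation < 1 Mbp, unique pairing, donor half genomically
upstream. Survivors must start exactly at a 5'SS or recursive site (the
"immediately downstream" offset is 0, configurable) and end within 100 nt
upstream of a 3'SS or recursive site; the branchpoint is the last base of
the first half. Alignment is an exhaustive forward-strand scan, appropriate
for the fixture-scale genomes this package targets.

## Kinetics and accuracy

Progressive labeling for t minutes yields transcript ages uniform on [0, t];
with first-order splicing at rate λ the completed fraction of junction
evidence is θ(t) = 1 − (1 − e^(−λt))/(λt). The upstream junction-dynamics
model is not restated in any published description we implement from; this
θ(t) is this package's own documented model, and parameter recovery on the
generator is the test surface. λ is fit by bounded 1-D least squares on the
observed fractions ee/(ee+ie) at t ∈ {5, 10, 20} min, λ ∈ [1e-4, 1e3] min⁻¹;
all-complete data reports the 0.1-min resolution floor and all-incomplete
data is flagged infinite. Per segment, incomplete evidence is reads
contiguously overlapping the segment's 3'-bounding site (boundary overlap
only; body reads are not used) and complete evidence is junction reads whose
acceptor is that site.

Elongation is fixed at 1500 nt/min (configurable). The splicing delay is
t½(segment 1)/((L − l₁)/1500); a 30 kb remainder transcribes in 20 min. For
one-site introns the lifetime is the expected maximum of the two segment
exponentials plus first-segment transcription,
τ = 1/λ₁ + 1/λ₂ − 1/(λ₁+λ₂) + l₁/1500; a printed version of this formula
with +1/(λ₁+λ₂) contradicts its own max-of-exponentials derivation, and the
minus sign is validated here against Monte Carlo to < 1%.

Splicing accuracy classifies each junction by annotation membership, then by
terminal dinucleotides (GT-AG, GC-AG, AT-AC, or their reverse complements);
the per-intron error proxy is the read-density fraction from non-canonical
non-annotated junctions.

## Integration

Filters: gene TPM ≥ 1; ≥ 3 spanning reads over the largest same-donor
intron; no overlap with an annotated 5'SS. Tiers parse the confidence clause
as (methods ≥ k) AND (junction+pair support > 5 OR FDR ≤ threshold), k = 2
and 5% for high, k = 1 and 20% for medium — the only reading in which each
tier is strictly stronger than the next; support sums both evidence types.
The manual inspection of read densities is replaced by an automated flag
(fitted downstream jump ≥ 1.5-fold at the call), recorded on each call;
scan-only calls are additionally gated by a 5% reporting FDR. The summary
table mirrors the standard per-site column set; the `recursive_index` column
is emitted empty as it has no published definition. GO enrichment iterates
Fisher exact tests, removing each most-significant term's genes from
foreground and background until the foreground is exhausted, with BH
correction across reported terms; the background length cutoff is 10 kb
(a printed "10,000 kb" exceeds chromosome scale and is read as nt).

## Synthetic data: what it does and does not show

Coverage is Poisson around a segment-wise linear expectation
density·(b − x)/(b − a) — exactly the heteroscedasticity the regression
assumes. Sequences are uniform ACGT with the juxtaposed splice-site
consensus planted at each recursive site and competing AG|GT occurrences
scrubbed within ±50 nt; study fixtures use one long intron per gene,
consensus splice sites for PWM training, 5'SS→RS junction reads split
{5 m: 4, 10 m: 3, 20 m: 2}, 12 spanning pairs per recursive intron,
Normal(300, 50) fragment lengths, TPM 50, and ~30× segment-start coverage.
All generators are seed-deterministic.

Passing tests therefore demonstrate correctness of the algorithms under
their own statistical assumptions — planted-site recovery, oracle-exact
numerics, calibrated nulls — not performance on real nascent RNA-seq, which
adds repeat families, GC and 5'→3' coverage bias, motif decoys near true
sites, overdispersed counts, and alignment artifacts none of which are
emulated. Genome-scale results (hundreds of sites, catalog overlap rates)
require the original sequencing depth and are out of scope by design.

## Numerical choices

Weight floor 1e-6 for non-positive predictions; EM tolerance 1e-5 on priors;
regression tolerance 1e-3 on weights; MCMC temperature 5; bin size 100 nt;
probability threshold 0.08; merge distance 500 nt; flank x₀ = 500 nt,
|k| = 6/500; half-life search bounds [1e-4, 1e3] min⁻¹ with xatol 1e-8.
Ties: leftmost split position for lariats, position order for EM priors,
first-listed site for equal peak scores. Degenerate inputs: empty
annotations, all-zero tracks, all-impossible inserts, and read-free segments
all return empty results or explicit flags rather than raising mid-pipeline.
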