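# ratchetsplice

Detection of **recursive splicing** in long introns from nascent RNA-seq.

Very long introns (tens of kilobases, common in *Drosophila* developmental
genes) are often removed not in one piece but in sequential segments, each
ending at an intronic **recursive site (RS)** — a position that juxtaposes a
3' splice-site motif with a 5' splice-site motif around a central `AG|GT`.
The splicing intermediates are unstable, so detection must work from indirect
signatures in short-labeling (4sU) nascent RNA sequencing. This package
implements three complementary detectors over aligned reads, plus the
statistics needed to interpret the calls:

- **Ratchet junctions** — split reads joining an annotated 5' splice site to
  an intronic `AG|GT`, the direct evidence of a recursive intermediate.
- **Spanning read pairs (EM)** — pairs straddling a recursive junction whose
  implied insert length only makes sense if the intervening segment was
  excised; candidate positions *m* are inferred with an EM mixture using the
  empirical fragment-length distribution P(rₙ|m), a motif prior
  Πᵢ ∝ max(0, M(i) − 0.8), junction reads folded into the effective counts,
  and a sparsity parameter α = (assigned reads)/40.
- **Sawtooth MCMC** — co-transcriptional excision leaves a sawtooth in
  intronic coverage (linear decay per segment, upward jump ≥ 1.5-fold at each
  site). Repeat-masked, 100-nt-binned coverage is explored by a round-based
  MCMC over site configurations scored by
  `BIC(M) = L·RSS(M) + 2·(2N)·log L` (heteroscedastic segment fits,
  weights 1/prediction), with Metropolis acceptance exp(−ΔBIC/T), T = 5.
  Sample frequencies give a per-bin site probability; regions above 0.08 are
  merged within 500 nt and every `AG|GT` is scored by
  `S(i) = P(i)·max(M(i) − 0.8, 0)` with a logistic position potential
  (value 0.5 at 500 nt outside a region). An FDR comes from uniformly
  repositioned null regions.

Around the detectors: PWM-based motif scoring normalized to M(i) ∈ [0, 1],
lariat (branchpoint-spanning) read recovery, candidate filters (gene TPM ≥ 1,
≥ 3 intron-spanning reads, no 5'SS overlap), confidence tiers, splicing
half-lives from progressive-labeling junction dynamics
θ(t) = 1 − (1 − e^(−λt))/(λt), whole-intron lifetimes
τ = 1/λ₁ + 1/λ₂ − 1/(λ₁+λ₂) + l₁/1500, splicing-accuracy fractions from
junction terminal dinucleotides, subsampling sensitivity, and iterative
Fisher-exact GO enrichment. A synthetic-data module generates genomes,
annotations, reads, and coverage with the exact statistical structure each
detector assumes, so the whole pipeline runs and is tested offline.

## Worked example

Simulate a small study (2 recursive introns with one planted site each,
2 decoy introns) and run the full pipeline:

```bash
ratchet simulate --n-recursive 2 --n-decoy 2 --seed 11 --out demo
ratchet run --annotation demo/annotation.gff3 --genome demo/genome.fa \
    --reads demo/reads.sam --tpm demo/tpm.tsv \
    --coverage demo/coverage.bedgraph \
    --iterations 100000 --burn-in 10000 --seed 11 --out demo/results
# 2 high-confidence and 0 medium-confidence sites -> demo/results/recursive_sites.tsv
```

The site table (one row per call):

```
intron                  gene  TPM   completed_splicing_junction_reads  recursive_site  method                 high_confidence  junction_reads  spanning_read_pairs  sawtooth_score  mcmc_probability  motif                       motif_score
chr_rec1:1600-14670:+   rec1  50.0  6                                  8133            junction+pair+sawtooth 1                4,3,2,9         4,4,4,12             0.2             1.0               TTTTTTTTTTTTTTTTTCAGGTAAGT  1.0
chr_rec2:1600-15107:+   rec2  50.0  6                                  9309            junction+pair+sawtooth 1                4,3,2,9         4,4,4,12             0.2             1.0               TTTTTTTTTTTTTTTTTCAGGTAAGT  1.0
```

Both planted sites (`demo/truth.tsv`: rec1 → 8133, rec2 → 9309) are recovered
at the exact coordinate by all three methods; the comma lists are read counts
per labeling period [5 m, 10 m, 20 m, total]; `sawtooth_score` is
S(i) = P(i)·max(M(i) − 0.8, 0) — here 1 × (1.0 − 0.8) = 0.2 for a
consensus-motif site inside the probability region; neither decoy intron
produces a call.

The library surface mirrors the CLI: `load_annotation`, `build_pwms`,
`find_ratchet_junctions`, `gem_infer_sites`, `mcmc_sawtooth` / `call_peaks` /
`estimate_sawtooth_fdr`, `estimate_half_life`, `splicing_accuracy`,
`run_pipeline`, and the generators in `ratchetsplice.synthetic_data`.

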