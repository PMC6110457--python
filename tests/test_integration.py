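"""Filters, confidence tiers, subsampling, iterative GO enrichment."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from ratchetsplice.integration import (
    assign_confidence,
    filter_candidates,
    iterative_go_enrichment,
    subsample_sam,
    subsample_sensitivity,
)
from ratchetsplice.model import Intron, IntronRecord, RecursiveSiteCall


def _call(intron, site, methods=("junction",), junctions=0, pairs=0, fdr=None):
    call = RecursiveSiteCall(intron, site, set(methods))
    if junctions:
        call.junction_support = {5: junctions}
    if pairs:
        call.pair_support = {5: pairs}
    call.fdr = fdr
    return call


@pytest.fixture()
def filter_env(study_env):
    annotation = study_env[0]
    intron = annotation.introns[0]
    key = f"{intron.chrom}:{intron.start}-{intron.end}"
    return annotation, intron, key


class TestFilterCandidates:
    def test_low_tpm_removed(self, filter_env):
        annotation, intron, key = filter_env
        records = {key: IntronRecord(intron, tpm=0.5, spanning_reads=10)}
        kept, removed = filter_candidates(
            [_call(intron, intron.start + 5000)], records, annotation
        )
        assert kept == [] and removed[0][1] == "TPM"

    def test_too_few_spanning_reads_removed(self, filter_env):
        annotation, intron, key = filter_env
        records = {key: IntronRecord(intron, tpm=10.0, spanning_reads=2)}
        kept, removed = filter_candidates(
            [_call(intron, intron.start + 5000)], records, annotation
        )
        assert kept == [] and removed[0][1] == "spanning"

    def test_site_on_annotated_donor_removed(self, filter_env):
        annotation, intron, key = filter_env
        records = {key: IntronRecord(intron, tpm=10.0, spanning_reads=10)}
        kept, removed = filter_candidates(
            [_call(intron, intron.donor)], records, annotation
        )
        assert kept == [] and removed[0][1] == "5SS-overlap"

    def test_passing_call_kept(self, filter_env):
        annotation, intron, key = filter_env
        records = {key: IntronRecord(intron, tpm=10.0, spanning_reads=10)}
        kept, removed = filter_candidates(
            [_call(intron, intron.start + 5000)], records, annotation
        )
        assert len(kept) == 1 and removed == []


class TestAssignConfidence:
    INTRON = Intron("c", 0, 20_000, "+", "g")

    def test_two_methods_six_junctions_high(self):
        call = _call(self.INTRON, 5000, ("junction", "pair"), junctions=6)
        assert assign_confidence(call) == "high"

    def test_one_method_six_junctions_high_fdr_medium(self):
        call = _call(self.INTRON, 5000, ("junction",), junctions=6, fdr=0.25)
        assert assign_confidence(call) == "medium"

    def test_weak_everything_rejected(self):
        call = _call(self.INTRON, 5000, ("junction",), junctions=2, fdr=0.5)
        assert assign_confidence(call) == "rejected"

    def test_two_methods_low_support_good_fdr_high(self):
        call = _call(self.INTRON, 5000, ("sawtooth", "pair"), pairs=2, fdr=0.03)
        assert assign_confidence(call) == "high"

    def test_support_sums_junctions_and_pairs(self):
        call = _call(
            self.INTRON, 5000, ("junction", "pair"), junctions=3, pairs=3
        )
        assert assign_confidence(call) == "high"

    def test_tiers_are_a_partition(self):
        # every combination lands in exactly one tier
        for methods in [("junction",), ("junction", "pair")]:
            for junctions in (0, 6):
                for fdr in (None, 0.03, 0.25):
                    call = _call(self.INTRON, 5000, methods, junctions, 0, fdr)
                    tier = assign_confidence(call)
                    assert tier in ("high", "medium", "rejected")


class TestSubsampling:
    def test_fraction_one_is_identity(self, study):
        assert subsample_sam(study.sam_text, 1.01, seed=1) == study.sam_text

    def test_fraction_zero_keeps_header_only(self, study):
        text = subsample_sam(study.sam_text, 0.0, seed=1)
        assert all(line.startswith("@") for line in text.splitlines() if line)

    def test_mates_kept_together(self, study):
        text = subsample_sam(study.sam_text, 0.5, seed=2)
        names = [
            line.split("\t")[0]
            for line in text.splitlines()
            if line and not line.startswith("@")
        ]
        from collections import Counter

        full_counts = Counter(
            line.split("\t")[0]
            for line in study.sam_text.splitlines()
            if line and not line.startswith("@")
        )
        for name, count in Counter(names).items():
            assert count == full_counts[name]

    def test_detections_nondecreasing_in_fraction(self, study):
        # pipeline proxy: distinct 5'SS-RS junction read names present
        truth = {g.id: g.site for g in study.genes if g.site is not None}

        def pipeline(text):
            found = set()
            for line in text.splitlines():
                if line.startswith("@") or "N" not in line.split("\t")[5]:
                    continue
                name = line.split("\t")[0]
                gene = name.split("_")[0]
                if "_rs" in name and gene in truth:
                    found.add(gene)
            return len(found)

        means = []
        for fraction in (0.05, 0.3, 1.0):
            vals = [
                subsample_sensitivity(
                    study.sam_text, [fraction], pipeline, seed=s
                )[fraction]
                for s in range(5)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[2] == len(truth)


class TestIterativeGo:
    def test_empty_foreground_empty_result(self):
        df = iterative_go_enrichment(set(), {"g1", "g2"}, {"T": {"g1"}})
        assert len(df) == 0

    def test_single_term_p_matches_hypergeometric_tail(self):
        # 10 fg-in, 5 fg-out, 20 bg-in, 100 bg-out
        fg = {f"f{i}" for i in range(15)}
        bg = {f"b{i}" for i in range(120)}
        term_genes = {f"f{i}" for i in range(10)} | {f"b{i}" for i in range(20)}
        df = iterative_go_enrichment(fg, bg, {"T": term_genes})
        # oracle: exact hypergeometric tail by direct summation
        M, n, N, k = 135, 30, 15, 10
        tail = sum(hypergeom.pmf(x, M, n, N) for x in range(k, min(n, N) + 1))
        assert abs(df.iloc[0]["p"] - tail) <= 1e-12

    def test_nested_terms_lose_significance_after_removal(self):
        core = {f"c{i}" for i in range(10)}
        fg = core | {"x1"}
        bg = {f"b{i}" for i in range(200)}
        ontology = {"small": core, "large": core | {f"b{i}" for i in range(5)}}
        df = iterative_go_enrichment(fg, bg, ontology)
        assert df.iloc[0]["term"] == "small"
        if len(df) > 1:
            # oracle: Fisher on the reduced sets is no longer significant
            from scipy.stats import fisher_exact

            fg2 = fg - core
            bg2 = bg - core
            table = [
                [len(fg2 & ontology["large"]), len(fg2 - ontology["large"])],
                [len(bg2 & ontology["large"]), len(bg2 - ontology["large"])],
            ]
            p = fisher_exact(table, alternative="greater")[1]
            assert df.set_index("term").loc["large", "p"] == pytest.approx(p)
            assert p > 0.05

    def test_bh_correction_is_monotone(self):
        fg = {f"f{i}" for i in range(12)}
        bg = {f"b{i}" for i in range(100)}
        ontology = {
            "A": {f"f{i}" for i in range(6)},
            "B": {f"f{i}" for i in range(6, 10)} | {"b1", "b2"},
            "C": {"f10", "f11", "b3"},
        }
        df = iterative_go_enrichment(fg, bg, ontology)
        assert (df["p_adjusted"] >= df["p"] - 1e-15).all()
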