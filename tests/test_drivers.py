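"""Candidate calling, CIS recurrence, and oncogene/TSG classification."""

import numpy as np
import pytest

from sbcis import (HotspotParams, call_candidates, call_cis,
                   cis_tumor_threshold, classify, hotspot_regions)
from sbcis.drivers import ONCOGENE, TUMOR_SUPPRESSOR, CandidateCall
from sbcis.saturation import DepthCutoff
from sbcis.significance import LibraryEntry, SampleLibrary

from conftest import make_gene


def _library(entries: dict[str, int], sample_id="s1", n=10_000) -> SampleLibrary:
    lib = SampleLibrary(sample_id=sample_id, total_reads=n)
    for gid, k in entries.items():
        lib.entries[gid] = LibraryEntry(read_count=k, p_value=1e-6)
    return lib


def _cutoff(depth, sample_id="s1") -> DepthCutoff:
    return DepthCutoff(sample_id=sample_id, depth=depth, x_total=10_000,
                       y_at_total=10_000 / depth)


class TestCandidates:
    def test_boundary_at_depth(self):
        lib = _library({"hit": 169, "nearmiss": 168, "big": 513})
        calls = call_candidates(lib, _cutoff(169))
        assert [c.gene_id for c in calls] == ["big", "hit"]

    def test_depth_one_returns_full_library(self):
        lib = _library({"a": 1, "b": 7, "c": 3})
        assert {c.gene_id for c in call_candidates(lib, _cutoff(1))} == {"a", "b", "c"}

    def test_empty_library(self):
        assert call_candidates(_library({}), _cutoff(10)) == []


class TestCIS:
    def test_threshold_examples(self):
        assert cis_tumor_threshold(306) == 16   # ceil(0.05 * 306)
        assert cis_tumor_threshold(20) == 3     # floor of 3 dominates
        assert cis_tumor_threshold(1) == 3

    def _calls(self, gene_samples: dict[str, list[str]]):
        return [
            CandidateCall(sample_id=s, gene_id=g, read_count=100,
                          depth_cutoff=10, p_value=1e-9)
            for g, samples in gene_samples.items()
            for s in samples
        ]

    def test_recurrence_cut(self):
        calls = self._calls({"gA": ["s1", "s2", "s3"], "gB": ["s1", "s2"]})
        cis = call_cis(calls, cohort_size=20)
        assert [c.gene_id for c in cis] == ["gA"]
        assert cis[0].tumor_count == 3
        assert cis[0].frequency == pytest.approx(0.15)

    def test_raising_min_frac_never_adds_genes(self):
        calls = self._calls({
            "gA": [f"s{i}" for i in range(8)],
            "gB": [f"s{i}" for i in range(4)],
            "gC": [f"s{i}" for i in range(3)],
        })
        previous = None
        for frac in (0.05, 0.15, 0.3, 0.5):
            got = {c.gene_id for c in call_cis(calls, cohort_size=20, min_frac=frac)}
            if previous is not None:
                assert got <= previous
            previous = got

    def test_deterministic_ordering(self):
        calls = self._calls({"gB": ["s1", "s2", "s3"], "gA": ["s1", "s2", "s3"]})
        cis = call_cis(calls, cohort_size=10)
        assert [c.gene_id for c in cis] == ["gA", "gB"]  # tie broken by id

    def test_cohort_size_validation(self):
        with pytest.raises(ValueError):
            call_cis([], cohort_size=0)


class TestClassification:
    def test_reported_forward_fraction_arithmetic(self):
        # 551166 forward reads of 628330 pooled: 87.7% engage the promoter
        gene = make_gene("fgfr2_like", strand="+")
        label, ff, _ = classify(
            [(150, "+", 551_166), (150, "-", 628_330 - 551_166)], gene
        )
        assert round(100 * ff, 1) == 87.7
        assert label == ONCOGENE

    def test_exactly_half_forward_is_suppressor(self):
        gene = make_gene("g", strand="+")
        label, ff, _ = classify([(150, "+", 50), (150, "-", 50)], gene)
        assert ff == 0.5 and label == TUMOR_SUPPRESSOR

    def test_scattered_balanced_pattern_is_suppressor(self):
        # reads spread uniformly over 40 well-separated sites, 50/50
        gene = make_gene("g", start=0, end=40_000, strand="+")
        ins = []
        for i in range(40):
            ins.append((i * 1000, "+" if i % 2 else "-", 10))
        label, ff, regions = classify(ins, gene)
        assert label == TUMOR_SUPPRESSOR

    def test_zero_reads_is_error(self):
        with pytest.raises(ValueError):
            classify([], make_gene("g"))

    def test_split_across_samples_invariant(self):
        gene = make_gene("g", strand="-")
        pooled = [(10, "-", 30), (5000, "+", 10)]
        halves = [(10, "-", 15), (10, "-", 15), (5000, "+", 4), (5000, "+", 6)]
        assert classify(pooled, gene) == classify(halves, gene)


class TestHotspots:
    def test_gap_merging(self):
        params = HotspotParams(min_site_read_frac=0.0)
        sites = {0: 50, 400: 50, 2000: 100}   # first two merge (gap 400 <= 500)
        assert hotspot_regions(sites, params) == 2

    def test_small_regions_filtered(self):
        params = HotspotParams(min_site_read_frac=0.0)
        sites = {0: 97, 2000: 2, 5000: 1}     # minor sites hold < 5% each
        assert hotspot_regions(sites, params) == 1

    def test_background_bridge_sites_filtered(self):
        # two real clusters joined by sporadic single-read positions: the
        # per-site filter removes the bridge so two regions remain
        params = HotspotParams()
        sites = {0: 5000, 5000: 5000}
        sites.update({p: 1 for p in range(400, 5000, 400)})
        assert hotspot_regions(sites, params) == 2

    def test_param_validation(self):
        with pytest.raises(ValueError):
            HotspotParams(forward_threshold=1.5)
        with pytest.raises(ValueError):
            HotspotParams(merge_gap_bp=0)


def test_classification_accuracy_on_planted_patterns():
    """>=95% accuracy on synthetic oncogene/suppressor insertion patterns.

    Oncogenes: one or two fixed TA hotspots, ~95% promoter-aligned reads.
    Suppressors: reads spread over 8-14 well-separated sites, balanced
    orientation.  Both get a sprinkling of background reads inside the gene.
    """
    rng = np.random.default_rng(2024)
    correct = 0
    n_genes = 200
    for i in range(n_genes):
        gene = make_gene(f"g{i}", start=0, end=12_000,
                         strand="+" if rng.random() < 0.5 else "-")
        truth = ONCOGENE if i % 2 == 0 else TUMOR_SUPPRESSOR
        total = int(rng.integers(2_000, 30_000))
        ins = []
        if truth == ONCOGENE:
            sites = rng.choice(12_000, size=int(rng.integers(1, 3)), replace=False)
            split = rng.multinomial(total, np.full(len(sites), 1 / len(sites)))
            for pos, cnt in zip(sites, split):
                fwd = rng.binomial(cnt, 0.95)
                ins += [(int(pos), gene.strand, int(fwd)),
                        (int(pos), "-" if gene.strand == "+" else "+", int(cnt - fwd))]
        else:
            m = int(rng.integers(8, 15))
            sites = np.sort(rng.choice(np.arange(0, 12_000, 1200), size=min(m, 10),
                                       replace=False))
            split = rng.multinomial(total, np.full(len(sites), 1 / len(sites)))
            for pos, cnt in zip(sites, split):
                fwd = rng.binomial(cnt, 0.5)
                ins += [(int(pos), gene.strand, int(fwd)),
                        (int(pos), "-" if gene.strand == "+" else "+", int(cnt - fwd))]
        # background: ~0.5% of reads at random positions
        for _ in range(max(1, total // 200)):
            ins.append((int(rng.integers(0, 12_000)),
                        "+" if rng.random() < 0.5 else "-", 1))
        label, _, _ = classify([t for t in ins if t[2] > 0], gene)
        correct += label == truth
    assert correct / n_genes >= 0.95
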