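"""Gradient construction, nested subsampling, curve fitting, depth cutoff."""

import numpy as np
import pytest

from sbcis import (InsertionRecord, count_per_gene, build_library,
                   depth_cutoff, fit_curve, make_gradients, subsample_curve,
                   tailored_depth)
from sbcis.saturation import MODELS, SaturationFit

from conftest import make_gene, make_index


class TestGradients:
    def test_even_fifty_gradients(self):
        g = make_gradients(10_000)
        assert g[:6] == [200, 400, 600, 800, 1000, 1200]
        assert len(g) == 50 and g[-1] == 10_000

    def test_remainder_folded_into_last(self):
        g = make_gradients(10_007)
        assert g[-1] == 10_007 and g[-2] == 9_800

    def test_total_equals_gradient_count(self):
        assert make_gradients(50) == list(range(1, 51))

    def test_fewer_reads_than_gradients(self):
        assert make_gradients(7) == [1, 2, 3, 4, 5, 6, 7]

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            make_gradients(0)


def _toy_sample():
    """Three library genes with very different read mass plus off-gene reads."""
    genes = [make_gene(f"g{i}", start=i * 10_000, end=i * 10_000 + 1000,
                       insert_prob=1e-4) for i in range(1, 4)]
    idx = make_index(genes)
    recs = []
    for gid, k in (("g1", 400), ("g2", 60), ("g3", 8)):
        g = idx.genes[gid]
        recs.append(InsertionRecord("s", g.chrom, g.start + 5, "+", weight=k))
    recs.append(InsertionRecord("s", "chr9", 42, "+", weight=532))
    counts, n = count_per_gene(recs, idx)
    lib = build_library(counts, n, idx)
    assert len(lib) == 3
    return recs, lib, idx, n


class TestSubsampling:
    def test_deterministic_under_fixed_seed(self):
        recs, lib, idx, n = _toy_sample()
        grads = make_gradients(n, 20)
        p1 = subsample_curve(recs, lib, idx, grads, seed=9)
        p2 = subsample_curve(recs, lib, idx, grads, seed=9)
        assert p1 == p2
        assert p1 != subsample_curve(recs, lib, idx, grads, seed=10)

    def test_nested_draws_give_monotone_y(self):
        recs, lib, idx, n = _toy_sample()
        points = subsample_curve(recs, lib, idx, make_gradients(n, 25), seed=3)
        ys = [y for _, y in points]
        assert ys == sorted(ys)

    def test_full_subsample_detects_whole_library(self):
        recs, lib, idx, n = _toy_sample()
        points = subsample_curve(recs, lib, idx, [n], seed=1)
        assert points == [(n, len(lib))]

    def test_no_library_read_drawn_gives_zero(self):
        idx = make_index([make_gene("g1", insert_prob=0.1)])
        recs = [InsertionRecord("s", "chr1", 150, "+"),
                InsertionRecord("s", "chr9", 0, "+", weight=9)]
        counts, n = count_per_gene(recs, idx)
        lib = build_library(counts, n, idx)  # empty: 1 read of 10 not significant
        assert len(lib) == 0
        points = subsample_curve(recs, lib, idx, [5, 10], seed=0)
        assert points == [(5, 0), (10, 0)]

    def test_oversized_gradient_rejected(self):
        recs, lib, idx, n = _toy_sample()
        with pytest.raises(ValueError):
            subsample_curve(recs, lib, idx, [n + 1], seed=0)


def _model_points(a, b, model="hyperbolic", n=50, x_max=None, noise_sd=0.0, rng=None):
    x = np.linspace(1, x_max or 5 * b, n)
    y = MODELS[model](x, a, b)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, size=n)
    return list(zip(x, y))


class TestFit:
    def test_noiseless_self_consistency(self):
        fit = fit_curve(_model_points(1000.0, 50_000.0))
        assert fit.a == pytest.approx(1000.0, rel=1e-6)
        assert fit.b == pytest.approx(50_000.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(7)
        fit = fit_curve(_model_points(800.0, 40_000.0, noise_sd=5.0, rng=rng))
        assert fit.a == pytest.approx(800.0, rel=0.05)
        assert fit.b == pytest.approx(40_000.0, rel=0.05)
        assert fit.r_squared > 0.99

    def test_exponential_model_recovery(self):
        fit = fit_curve(_model_points(300.0, 20_000.0, model="exponential"),
                        model="exponential")
        assert fit.a == pytest.approx(300.0, rel=1e-5)
        assert fit.b == pytest.approx(20_000.0, rel=1e-5)

    def test_degenerate_constant_y_flagged(self):
        fit = fit_curve([(100, 5), (200, 5), (300, 5)])
        assert fit.degenerate and fit.a == 5.0 and np.isnan(fit.b)
        assert fit.predict(10_000) == 5.0

    def test_parameter_recovery_ensemble(self):
        """Median relative error <= 5% at 1% noise across many regimes."""
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(25):
            a = rng.uniform(50, 2000)
            b = 10 ** rng.uniform(3, 6)
            fit = fit_curve(_model_points(a, b, noise_sd=0.01 * a, rng=rng))
            errs.append(max(abs(fit.a - a) / a, abs(fit.b - b) / b))
        assert float(np.median(errs)) <= 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_curve([(1, 1), (2, 2)])
        with pytest.raises(ValueError):
            fit_curve([(1, 1), (2, 2), (3, 3)], model="cubic")


class TestDepth:
    @pytest.mark.parametrize("genes, expected", [(10, 1000), (100, 100), (1000, 10)])
    def test_worked_heterogeneity_example(self, genes, expected):
        # 3 hypothetical tumors, 10000 reads each, very different driver
        # counts: the average depth differs by two orders of magnitude.
        assert tailored_depth(10_000, genes) == expected

    def test_depth_floor_and_rounding(self):
        assert tailored_depth(10, 10) == 1
        assert tailored_depth(5, 10) == 1          # floored at 1
        assert tailored_depth(25, 10) == 3         # round half up: 2.5 -> 3

    def test_invalid_gene_number(self):
        with pytest.raises(ValueError):
            tailored_depth(100, 0)

    def test_depth_increases_with_reads_at_fixed_richness(self):
        # hyperbolic model: depth(x) = (b + x)/a is strictly increasing
        fit = SaturationFit(sample_id="s", points=[], a=200.0, b=30_000.0, r_squared=1.0)
        depths = [depth_cutoff(fit, x).depth for x in (10_000, 50_000, 200_000)]
        assert depths == sorted(depths) and len(set(depths)) == 3
        for x, d in zip((10_000, 50_000, 200_000), depths):
            assert d == round((30_000 + x) / 200.0)

    def test_observed_gene_mode(self):
        fit = SaturationFit(sample_id="s", points=[], a=50.0, b=1e9, r_squared=1.0)
        cut = depth_cutoff(fit, 10_000, use_observed_genes=True, observed_genes=100)
        assert cut.depth == 100 and cut.y_at_total == 100
        with pytest.raises(ValueError):
            depth_cutoff(fit, 10_000, use_observed_genes=True)
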