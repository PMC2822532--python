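"""Relation histograms, the GDP law, and mixture/exponential fitting."""

import math

import numpy as np
import pytest

from splicefn.distfit import (
    FitError,
    FrequencyDistribution,
    describe,
    fit_exponential,
    fit_gdp,
    fit_mixture,
    fls_per_tu,
    gdp_norm,
    gdp_pmf,
    histogram,
    svs_per_tu,
    tus_per_fl,
)
from splicefn.simulate import _sample_disc_exp, sample_gdp, sample_sv_counts, SVModel

from conftest import make_dataset


class TestHistogram:
    def test_counts_multiplicity(self):
        freq = histogram([1, 1, 2, 9])
        assert freq.counts == {1: 2, 2: 1, 9: 1}
        assert (freq.M, freq.J, freq.total_events) == (4, 9, 13)

    def test_singleton_sample(self):
        assert histogram([5]).counts == {5: 1}

    @pytest.mark.parametrize("bad", [[], [0, 1], [-2]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            histogram(bad)

    def test_values_roundtrip(self):
        vals = [3, 1, 1, 7, 3, 3]
        assert list(histogram(vals).values()) == sorted(vals)


class TestRelations:
    def test_hand_enumerated_relations(self):
        ds = make_dataset({"tu1": [{"F1kw"}], "tu2": [{"F1kw"}, {"F2kw"}]})
        assert fls_per_tu(ds).counts == {1: 1, 2: 1}
        assert tus_per_fl(ds).counts == {1: 1, 2: 1}

    def test_duality_of_total_events(self, small_dataset):
        assert (
            fls_per_tu(small_dataset).total_events
            == tus_per_fl(small_dataset).total_events
        )

    def test_svs_per_tu_counts_proteins(self):
        ds = make_dataset({"tu1": [{"A"}, {"A"}, {"A"}]})
        assert svs_per_tu(ds).counts == {3: 1}

    def test_unannotated_tus_excluded(self, small_dataset):
        assert svs_per_tu(small_dataset).M == 3

    def test_all_unannotated_rejected(self):
        ds = make_dataset({"tu1": [set()]})
        with pytest.raises(ValueError):
            fls_per_tu(ds)


class TestGDPPmf:
    def test_small_support(self):
        assert gdp_pmf(1, 1, 0, 2) == pytest.approx(0.8)
        assert gdp_pmf(2, 1, 0, 2) == pytest.approx(0.2)

    def test_infinite_support_matches_zeta(self):
        assert gdp_pmf(1, 1, 0, None) == pytest.approx(6 / math.pi**2, abs=1e-12)
        # closed forms: zeta(2) = pi^2/6, zeta(3) (Apery), zeta(4) = pi^4/90
        closed = {1: math.pi**2 / 6, 2: 1.2020569031595943, 3: math.pi**4 / 90}
        for k, zeta in closed.items():
            c_inv = 1.0 / gdp_norm(k, 0.0, None)
            assert c_inv == pytest.approx(zeta, abs=1e-8)

    def test_normalization_over_random_params(self):
        rng = np.random.default_rng(2010)
        for _ in range(1000):
            k = rng.uniform(0.05, 6.0)
            b = rng.uniform(-0.95, 12.0)
            J = int(rng.integers(1, 1000))
            total = gdp_pmf(np.arange(1, J + 1), k, b, J).sum()
            assert abs(total - 1.0) < 1e-12

    def test_strictly_decreasing_in_m(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.uniform(0.05, 6.0)
            b = rng.uniform(-0.95, 12.0)
            f = gdp_pmf(np.arange(1, 51), k, b, 50)
            assert np.all(np.diff(f) < 0)

    @pytest.mark.parametrize("k, b", [(0.0, 0.0), (-1.0, 0.0), (1.0, -1.0)])
    def test_invalid_params_rejected(self, k, b):
        with pytest.raises(ValueError):
            gdp_pmf(1, k, b, 10)

    def test_m_outside_support_rejected(self):
        with pytest.raises(ValueError):
            gdp_pmf(11, 1.0, 0.0, 10)


class TestFitExponential:
    def test_noiseless_recovery(self):
        # amplitude large enough that integer rounding is below 1e-6 relative
        counts = {m: int(round(1e9 * math.exp(-0.5 * m))) for m in range(1, 10)}
        p = fit_exponential(FrequencyDistribution(counts))
        assert p.a == pytest.approx(1e9, rel=1e-6)
        assert p.b == pytest.approx(0.5, rel=1e-6)

    def test_flat_frequencies_hit_boundary(self):
        with pytest.raises(FitError):
            fit_exponential(FrequencyDistribution({m: 100 for m in range(1, 6)}))

    def test_monte_carlo_recovery_within_3se(self):
        rng = np.random.default_rng(2010)
        vals = _sample_disc_exp(rng, 20000, 0.5, 1, 9)
        p = fit_exponential(histogram(vals))
        assert abs(p.b - 0.5) < 3 * p.se_b
        assert p.p_b < 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_exponential(FrequencyDistribution({1: 5, 2: 3}))


class TestFitGDP:
    def test_noiseless_standard_pareto(self):
        f = gdp_pmf(np.arange(1, 51), 1, 0, 50)
        counts = {m: int(round(1e7 * f[m - 1])) for m in range(1, 51)}
        g = fit_gdp(FrequencyDistribution(counts))
        assert g.k == pytest.approx(1.0, rel=1e-6)  # slope k+1 = 2
        assert abs(g.b) < 1e-4

    def test_noiseless_heavy_tail_params(self):
        f = gdp_pmf(np.arange(10, 74), 4.16, 8.75, 73, m_min=10)
        counts = {m: int(round(1e9 * f[m - 10])) for m in range(10, 74)}
        counts = {m: c for m, c in counts.items() if c > 0}
        g = fit_gdp(FrequencyDistribution(counts), m_range=(10, 73))
        assert g.k == pytest.approx(4.16, rel=1e-4)
        assert g.b == pytest.approx(8.75, rel=1e-4)

    @pytest.mark.parametrize("method", ["ls", "mle"])
    def test_monte_carlo_pareto_recovery(self, method):
        vals = sample_gdp(50000, 1, 0, 1000, seed=2010)
        g = fit_gdp(histogram(vals), m_range=(1, 1000), fix_b_zero=True,
                    method=method)
        assert abs(g.k - 1.0) / 1.0 < 0.10
        assert g.b == 0.0


MIX = SVModel(s=0.9, exp_b=0.5, gdp_k=4.16, gdp_b=8.75, breakpoint=10, J=73)


class TestFitMixture:
    def test_pure_exponential_has_nan_tail(self):
        counts = {m: int(round(1e6 * math.exp(-0.5 * m))) for m in range(1, 10)}
        freq = FrequencyDistribution(counts)
        fit = fit_mixture(freq, breakpoint=freq.J)
        assert fit.s == 1.0
        assert fit.comp2 is None
        m = np.arange(1, freq.J + 1)
        assert fit.pmf(m).sum() == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_recovery(self):
        vals = sample_sv_counts(20000, MIX, seed=2010)
        fit = fit_mixture(histogram(vals), breakpoint=10, method="mle")
        assert abs(fit.s - 0.9) < 0.05
        assert abs(fit.comp2.k - 4.16) / 4.16 < 0.15
        assert abs(fit.comp1.b - 0.5) < 3 * fit.comp1.se_b

    def test_mixture_pmf_sums_to_one(self):
        vals = sample_sv_counts(5000, MIX, seed=3)
        freq = histogram(vals)
        fit = fit_mixture(freq, breakpoint=10)
        assert fit.pmf(np.arange(1, freq.J + 1)).sum() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_breakpoint_bounds_enforced(self):
        freq = histogram([1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            fit_mixture(freq, breakpoint=1)
        with pytest.raises(ValueError):
            fit_mixture(freq, breakpoint=6)


class TestDescribe:
    def test_printed_marginals(self):
        from splicefn.simulate import fixture_histogram

        freq = fixture_histogram(23640, 20928, 18575, 9)
        row = describe(freq)
        assert round(row.ratio, 2) == 1.13
        assert round(row.p1, 1) == 88.8
        assert (row.n1, row.max_m) == (18575, 9)

    def test_all_singletons(self):
        row = describe(histogram([1, 1, 1]))
        assert row.p1 == 100.0
        assert row.skewness == 0.0

    def test_hand_arithmetic(self):
        row = describe(FrequencyDistribution({1: 2, 4: 1}))
        assert row.ratio == pytest.approx(2.0)
        assert row.n1 == 2
        assert row.p1 == pytest.approx(200 / 3)

    def test_n1_matches_count_of_ones(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(1, 6, size=200).tolist()
        assert describe(histogram(vals)).n1 == vals.count(1)
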