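"""Episodic birth-death likelihood: closed-form oracles, refinement
invariance, quadrature identities and degenerate-input behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import epochdiv as ed
from epochdiv.phylo_io import CladeRow

from conftest import nee_p1, nee_survival, nee_tree_loglik, yule_tree_loglik


def const_grid(span, lam, mu, rho=1.0, k=1):
    return ed.EpochGrid.regular(span, [lam] * k, [mu] * k, rho)


class TestNetRateExponent:
    def test_zero_when_rates_equal(self):
        g = const_grid(10, 0.3, 0.3, k=4)
        assert ed.net_rate_exponent(g, 1.0, 9.0) == pytest.approx(0.0)

    def test_constant_rate_value(self):
        g = const_grid(10, 0.2, 0.1)
        assert ed.net_rate_exponent(g, 0.0, 10.0) == pytest.approx(-1.0)

    def test_additive_across_epochs(self):
        g = ed.EpochGrid.regular(10, [0.3, 0.1], [0.05, 0.2])
        whole = ed.net_rate_exponent(g, 1.0, 9.0)
        parts = ed.net_rate_exponent(g, 1.0, 5.0) + ed.net_rate_exponent(g, 5.0, 9.0)
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_out_of_span_error(self):
        g = const_grid(10, 0.2, 0.1)
        with pytest.raises(ValueError):
            ed.net_rate_exponent(g, -1.0, 5.0)
        with pytest.raises(ValueError):
            ed.net_rate_exponent(g, 5.0, 2.0)


class TestEpochGridCoordinates:
    def test_forward_time_construction_round_trips(self):
        g = ed.EpochGrid.regular(12.0, [0.3, 0.2, 0.1], [0.05, 0.1, 0.02], 0.7)
        g2 = ed.EpochGrid.from_forward_times(
            g.forward_boundaries, g.lam[::-1], g.mu[::-1], g.rho
        )
        np.testing.assert_allclose(g2.breaks, g.breaks)
        np.testing.assert_allclose(g2.lam, g.lam)
        np.testing.assert_allclose(g2.mu, g.mu)
        # same likelihood quantities either way
        assert ed.survival_probability(g2, 3.0) == ed.survival_probability(g, 3.0)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ed.EpochGrid(np.array([0.0, 1.0]), np.array([-0.1]), np.array([0.0]))
        with pytest.raises(ValueError):
            ed.EpochGrid(np.array([0.0, 1.0]), np.array([0.1]), np.array([0.0]), rho=0.0)
        with pytest.raises(ValueError):
            ed.EpochGrid(np.array([1.0, 2.0]), np.array([0.1]), np.array([0.0]))


class TestSurvivalProbability:
    def test_no_extinction_full_sampling(self):
        g = const_grid(10, 0.4, 0.0, rho=1.0)
        assert ed.survival_probability(g, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [0.1, 0.5, 1.0])
    def test_equals_rho_at_present(self, rho):
        g = const_grid(10, 0.2, 0.1, rho)
        assert ed.survival_probability(g, 10.0) == rho

    def test_constant_rate_closed_form(self):
        lam, mu, rho, T = 0.2, 0.1, 0.5, 10.0
        g = const_grid(T, lam, mu, rho)
        assert ed.survival_probability(g, 0.0) == pytest.approx(
            nee_survival(lam, mu, rho, T), abs=1e-10
        )

    @pytest.mark.parametrize("k", [2, 7, 30])
    def test_refinement_invariance(self, k):
        lam, mu, rho = 0.25, 0.12, 0.8
        one = ed.survival_probability(const_grid(12, lam, mu, rho), 3.0)
        many = ed.survival_probability(const_grid(12, lam, mu, rho, k=k), 3.0)
        assert many == pytest.approx(one, abs=1e-10)

    def test_critical_rates_no_nan(self):
        g = const_grid(10, 0.3, 0.3, rho=0.7)
        v = ed.survival_probability(g, 0.0)
        assert 0 < v < 1
        # exact critical closed form: s(t) = rho / (1 + rho*lam*t)
        assert v == pytest.approx(0.7 / (1 + 0.7 * 0.3 * 10), abs=1e-10)


class TestSpeciationTimeCdf:
    def test_zero_at_origin(self):
        g = ed.EpochGrid.regular(10, [0.3, 0.2], [0.1, 0.05], 0.6)
        assert ed.speciation_time_cdf(g, 0.0) == pytest.approx(0.0)

    def test_one_at_present_complete_sampling(self):
        g = const_grid(10, 0.3, 0.1, 1.0)
        assert ed.speciation_time_cdf(g, 10.0) == pytest.approx(1.0)

    def test_monotone_non_decreasing(self):
        g = ed.EpochGrid.regular(10, [0.35, 0.1, 0.25], [0.2, 0.05, 0.1], 0.5)
        ts = np.linspace(0, 10, 101)
        vals = [ed.speciation_time_cdf(g, t) for t in ts]
        assert np.all(np.diff(vals) >= -1e-12)

    @pytest.mark.parametrize("k", [5, 40])
    def test_refinement_invariance(self, k):
        one = ed.speciation_time_cdf(const_grid(10, 0.3, 0.1, 0.7), 6.0)
        many = ed.speciation_time_cdf(const_grid(10, 0.3, 0.1, 0.7, k=k), 6.0)
        assert many == pytest.approx(one, abs=1e-10)


class TestTreeLogDensity:
    @pytest.mark.parametrize("k", [1, 10])
    def test_epoch_refinement_invariance(self, toy_tree, k):
        base = ed.tree_log_density(toy_tree, const_grid(10, 0.2, 0.1))
        refined = ed.tree_log_density(toy_tree, const_grid(10, 0.2, 0.1, k=max(k, 1)))
        assert refined == pytest.approx(base, abs=1e-10)

    def test_matches_nee_closed_form(self, toy_tree):
        ll = ed.tree_log_density(toy_tree, const_grid(10, 0.2, 0.1, 1.0))
        assert ll == pytest.approx(nee_tree_loglik(toy_tree, 0.2, 0.1, 1.0), abs=1e-8)

    def test_matches_nee_with_incomplete_sampling(self, toy_tree):
        ll = ed.tree_log_density(toy_tree, const_grid(10, 0.3, 0.15, 0.4))
        assert ll == pytest.approx(nee_tree_loglik(toy_tree, 0.3, 0.15, 0.4), abs=1e-8)

    def test_matches_yule_closed_form(self, toy_tree):
        ll = ed.tree_log_density(toy_tree, const_grid(10, 0.2, 0.0, 1.0))
        assert ll == pytest.approx(yule_tree_loglik(toy_tree, 0.2), abs=1e-8)

    def test_grid_must_cover_root(self, toy_tree):
        with pytest.raises(ValueError, match="root age"):
            ed.tree_log_density(toy_tree, const_grid(5, 0.2, 0.1))

    def test_normalisation_constant_identity(self):
        # int_0^span lambda(a) p1(a) da telescopes to (rho - P_s e^r)/rho
        g = ed.EpochGrid.regular(12, [0.3, 0.2, 0.3], [0.15, 0.05, 0.15], 0.7)

        def p1(age):
            s = ed.survival_probability(g, g.span - age)
            return s * s * math.exp(ed.net_rate_exponent(g, g.span - age, g.span)) / g.rho

        val, err = integrate.quad(
            lambda a: g.lam[g.epoch_index(a)] * p1(a),
            0,
            g.span,
            points=list(g.breaks),
            limit=200,
        )
        sT = ed.survival_probability(g, 0.0)
        rT = ed.net_rate_exponent(g, 0.0, g.span)
        assert val == pytest.approx((g.rho - sT * math.exp(rT)) / g.rho, abs=1e-8)

    def test_three_tip_density_integrates_to_clade_size_probability(self):
        # Sum over the 3 labelled histories of the density integrated over
        # the free branching time must equal P(n = 3 | two surviving root
        # lineages), which for constant rates follows from the geometric
        # offspring distribution with success probability u = p1/s.
        lam, mu, rho, t1 = 0.3, 0.1, 1.0, 8.0
        g = const_grid(t1, lam, mu, rho)

        def f(x):
            tree = ed.TimeTree.from_newick(
                f"((A:{x:.10f},B:{x:.10f}):{t1 - x:.10f},C:{t1:.10f});"
            )
            return math.exp(ed.tree_log_density(tree, g))

        total, _ = integrate.quad(f, 1e-6, t1 - 1e-6, limit=200)
        u = nee_p1(lam, mu, rho, t1) / nee_survival(lam, mu, rho, t1)
        assert 3 * total == pytest.approx(2 * u * u * (1 - u), rel=1e-3)


class TestEmpiricalSamplingDensity:
    def _resolved(self, tree, rows):
        return ed.resolve_clades(tree, ed.CladeSamplingTable(rows))

    def test_collapses_when_no_missing(self, toy_tree):
        g = const_grid(10, 0.25, 0.1, 1.0, k=2)
        tab = self._resolved(toy_tree, [CladeRow("w", "A", "D", 0)])
        assert ed.empirical_sampling_log_density(toy_tree, g, tab) == ed.tree_log_density(
            toy_tree, g
        )

    @pytest.mark.parametrize(
        "newick,rows",
        [
            ("((A:3,B:3):7,C:10);", [("c", "A", "B", 1)]),
            ("((A:3,B:3):7,(C:6,D:6):4);", [("c1", "A", "B", 2), ("c2", "C", "D", 1)]),
            (
                "(((A:2,B:2):3,C:5):5,(D:7,E:7):3);",
                [("c1", "A", "C", 3), ("c2", "D", "E", 2)],
            ),
        ],
    )
    def test_clade_mass_matches_quadrature(self, newick, rows):
        """Each missing species contributes the integral of lambda p1 over
        the clade window (computed independently by quadrature), times the
        labelled-assignment constants."""
        tree = ed.TimeTree.from_newick(newick)
        g = ed.EpochGrid.regular(tree.root_age, [0.3, 0.2], [0.1, 0.15], 1.0)
        tab = self._resolved(tree, [CladeRow(*r) for r in rows])

        def p1(age):
            s = ed.survival_probability(g, g.span - age)
            return s * s * math.exp(ed.net_rate_exponent(g, g.span - age, g.span))

        expected = ed.tree_log_density(tree, g)
        n = tree.n_tips
        m = n + tab.total_missing
        expected += math.lgamma(m) - math.lgamma(n)
        for row in tab.rows:
            mass, _ = integrate.quad(
                lambda a: g.lam[g.epoch_index(a)] * p1(a),
                0,
                row.crown_age,
                points=[b for b in g.breaks if b < row.crown_age],
                limit=200,
            )
            expected += row.missing * math.log(mass) - math.lgamma(row.missing + 1)
        got = ed.empirical_sampling_log_density(tree, g, tab)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_doubling_missing_count_decreases_density(self, toy_tree):
        g = const_grid(10, 0.25, 0.1, 1.0)
        t1 = self._resolved(toy_tree, [CladeRow("c", "A", "B", 2)])
        t2 = self._resolved(toy_tree, [CladeRow("c", "A", "B", 4)])
        assert ed.empirical_sampling_log_density(
            toy_tree, g, t2
        ) < ed.empirical_sampling_log_density(toy_tree, g, t1)

    def test_requires_complete_sampling_grid(self, toy_tree):
        g = const_grid(10, 0.25, 0.1, 0.5)
        tab = self._resolved(toy_tree, [CladeRow("c", "A", "B", 2)])
        with pytest.raises(ValueError, match="rho"):
            ed.empirical_sampling_log_density(toy_tree, g, tab)

    def test_stem_conditioning_differs_from_crown(self, toy_tree):
        g = const_grid(10, 0.25, 0.1, 1.0)
        tab = self._resolved(toy_tree, [CladeRow("c", "A", "B", 2)])
        crown = ed.empirical_sampling_log_density(toy_tree, g, tab, clade_age="crown")
        stem = ed.empirical_sampling_log_density(toy_tree, g, tab, clade_age="stem")
        # stem age (10) is older than crown age (3): a wider window has more
        # mass, so the density is higher
        assert stem > crown


class TestNumericalRobustness:
    @given(
        lam=st.floats(1e-6, 10.0),
        mu=st.floats(0.0, 10.0),
        rho=st.floats(0.01, 1.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_no_nan_anywhere(self, lam, mu, rho):
        g = ed.EpochGrid.regular(10, [lam, lam], [mu, mu], rho)
        s = ed.survival_probability(g, 2.0)
        assert np.isfinite(s) and 0 <= s <= 1
        f = ed.speciation_time_cdf(g, 6.0)
        assert np.isfinite(f) and -1e-12 <= f <= 1 + 1e-12

    @given(
        lam=st.floats(1e-4, 10.0),
        dmu=st.floats(-1e-12, 1e-12),
        rho=st.floats(0.01, 1.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_critical_regime_continuous(self, lam, dmu, rho):
        g = ed.EpochGrid.regular(10, [lam], [max(lam + dmu, 0.0)], rho)
        assert np.isfinite(ed.survival_probability(g, 0.0))

    def test_tree_density_finite_over_rate_box(self, toy_tree):
        for lam in (1e-6, 0.1, 10.0):
            for mu in (0.0, lam, 10.0):
                for rho in (0.05, 1.0):
                    g = ed.EpochGrid.regular(10, [lam] * 3, [mu] * 3, rho)
                    ll = ed.tree_log_density(toy_tree, g)
                    assert not math.isnan(ll)
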