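import math

import numpy as np
import pytest

from proptab import (
    ComCoords,
    com_coords,
    delta_s,
    effect_size_report,
    make_table,
    odds_ratio,
    perspective_measures,
    phi,
    phi_factorization,
    relative_risk,
    rxc_measures,
    simple_matching,
    simplex_pair,
    u_scale,
    yule_symmetrize,
    yules_q,
)
from proptab.effect_sizes import FORMS, cohen_label
from proptab.errors import DomainError, UndefinedStatisticError, ZeroMarginError


def brute_force_tau(m: np.ndarray, dependent: str) -> float:
    """Independent oracle: Goodman-Kruskal tau via expected misclassification
    probabilities under proportional random guessing."""
    p = m / m.sum()
    if dependent == "col":
        dep_margin = p.sum(axis=0)
        groups = p  # rows are the conditioning groups
    else:
        dep_margin = p.sum(axis=1)
        groups = p.T
    p_err_baseline = sum(pj * (1 - pj) for pj in dep_margin)
    p_err_cond = 0.0
    for gi in range(groups.shape[0]):
        gsum = groups[gi].sum()
        for pij in groups[gi]:
            p_err_cond += pij * (1 - pij / gsum)
    return (p_err_baseline - p_err_cond) / p_err_baseline


class TestSimplexPair:
    def test_csum_rows_example(self, fig_table):
        sp = simplex_pair(fig_table, "csum_rows")
        assert sp.p_alpha == pytest.approx(0.25 / 0.85, rel=1e-6)
        assert sp.p_beta == pytest.approx(0.75 / 1.15, rel=1e-6)

    def test_csum_cols_example(self, fig_table):
        sp = simplex_pair(fig_table, "csum_cols")
        assert (sp.p_alpha, sp.p_beta) == pytest.approx((0.6, 0.25))

    def test_rsum_rows_example(self, fig_table):
        sp = simplex_pair(fig_table, "rsum_rows")
        assert (sp.p_alpha, sp.p_beta) == pytest.approx((0.6, 0.25))

    def test_uniform_table_all_forms(self, uniform_table):
        for form in FORMS:
            sp = simplex_pair(uniform_table, form)
            assert sp.p_alpha == pytest.approx(0.5)
            assert sp.p_beta == pytest.approx(0.5)

    def test_zero_margin_error(self):
        with pytest.raises(ZeroMarginError):
            simplex_pair(make_table(0, 1, 0, 1), "csum_rows")

    def test_symmetric_rejects_asymmetric(self, fig_table):
        with pytest.raises(DomainError):
            simplex_pair(fig_table, "symmetric")


class TestComCoords:
    def test_fig5_anchor(self, fig_table):
        cc = com_coords(simplex_pair(fig_table, "csum_rows"))
        assert cc.delta == pytest.approx(0.179028, abs=5e-7)
        assert cc.mu == pytest.approx(0.473146, abs=5e-7)
        assert cc.displacement == pytest.approx(2 * cc.delta)

    def test_equal_points(self, uniform_table):
        cc = com_coords(simplex_pair(uniform_table, "csum_rows"))
        assert cc.delta == 0
        assert cc.mu == pytest.approx(0.5)

    def test_extreme_displacement(self):
        from proptab.effect_sizes import SimplexPair

        cc = com_coords(SimplexPair(0.0, 1.0, "csum_cols"))
        assert (cc.delta, cc.mu) == (0.5, 0.5)

    def test_range_constraint_pool(self, table_pool):
        for t in table_pool[:200]:
            for form in FORMS:
                cc = com_coords(simplex_pair(t, form))
                assert -1e-12 <= cc.mu - cc.delta <= 1 + 1e-12
                assert -1e-12 <= cc.mu + cc.delta <= 1 + 1e-12


class TestScalarMeasures:
    def test_odds_ratio(self, fig_table, uniform_table):
        assert odds_ratio(fig_table) == pytest.approx(2 / 9)
        assert odds_ratio(uniform_table) == 1
        assert odds_ratio(make_table(2, 0, 0, 3)) == math.inf
        assert odds_ratio(make_table(0, 2, 3, 0)) == 0
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(make_table(0, 0, 3, 0))

    def test_yules_q(self, fig_table, uniform_table):
        assert yules_q(fig_table) == pytest.approx(-7 / 11)
        assert yules_q(uniform_table) == 0
        assert yules_q(make_table(2, 0, 0, 3)) == 1
        with pytest.raises(UndefinedStatisticError):
            yules_q(make_table(0, 0, 1, 0))

    def test_relative_risk(self, fig_table, uniform_table):
        assert relative_risk(fig_table) == pytest.approx(0.25 / 0.6)
        assert relative_risk(uniform_table) == 1
        assert relative_risk(fig_table, "csum_rows") == pytest.approx(
            (0.25 / 0.85) / (0.75 / 1.15), rel=1e-10
        )

    def test_relative_risk_infinite(self):
        assert relative_risk(make_table(1, 1, 0, 5)) == math.inf

    def test_phi(self, fig_table, uniform_table):
        assert phi(fig_table) == pytest.approx(-0.35)
        assert phi(make_table(2, 0, 0, 3)) == pytest.approx(1)
        assert phi(uniform_table) == 0
        with pytest.raises(ZeroMarginError):
            phi(make_table(0, 1, 0, 1))


class TestPerspectiveMeasures:
    def test_reproduces_omega_q(self, fig_table):
        cc = com_coords(simplex_pair(fig_table, "csum_rows"))
        pm = perspective_measures(
            ComCoords(delta=-cc.delta, mu=cc.mu, form_id="csum_rows")
        )
        assert pm.omega == pytest.approx(odds_ratio(fig_table), rel=1e-10)
        assert pm.q == pytest.approx(yules_q(fig_table), rel=1e-10)

    def test_zero_delta(self):
        pm = perspective_measures(ComCoords(delta=0.0, mu=0.3, form_id="csum_cols"))
        assert (pm.omega, pm.q, pm.rho, pm.ratio_diff) == (1, 0, 1, 0)

    def test_ratio_diff_is_beta_minus_alpha(self, table_pool):
        for t in table_pool[:200]:
            sp = simplex_pair(t, "csum_rows")
            if sp.p_alpha == 1 or sp.p_beta == 1:
                continue
            pm = perspective_measures(com_coords(sp))
            direct = sp.p_beta / (1 - sp.p_beta) - sp.p_alpha / (1 - sp.p_alpha)
            assert pm.ratio_diff == pytest.approx(direct, rel=1e-9, abs=1e-12)

    def test_eq_residuals_pool(self, table_pool):
        # delta^2 - delta/Q + mu(1-mu) = 0 and delta(rho+1) - mu(rho-1) = 0
        for t in table_pool[:300]:
            for form in FORMS:
                cc = com_coords(simplex_pair(t, form))
                pm = perspective_measures(cc)
                if pm.q != 0:
                    res = cc.delta ** 2 - cc.delta / pm.q + cc.mu * (1 - cc.mu)
                    assert abs(res) < 1e-10
                if math.isfinite(pm.rho):
                    res = cc.delta * (pm.rho + 1) - cc.mu * (pm.rho - 1)
                    assert abs(res) < 1e-10

    def test_omega_q_roundtrip_pool(self, table_pool):
        for t in table_pool[:300]:
            cc = com_coords(simplex_pair(t, "csum_rows"))
            pm = perspective_measures(
                ComCoords(delta=-cc.delta, mu=cc.mu, form_id=cc.form_id)
            )
            w = odds_ratio(t)
            if math.isfinite(w):  # boundary tables lose inf to rounding
                assert pm.omega == pytest.approx(w, rel=1e-10)
            assert pm.q == pytest.approx(yules_q(t), rel=1e-10, abs=1e-12)


class TestPhiFactorization:
    def test_rsum_example(self, fig_table):
        m, d = phi_factorization(fig_table, "rsum")
        assert m == pytest.approx(0.9775, rel=1e-12)
        assert d == pytest.approx(-0.358056, abs=5e-7)
        assert m * d == pytest.approx(-0.35, rel=1e-10)

    def test_csum_example(self, fig_table):
        m, d = phi_factorization(fig_table, "csum")
        assert m == pytest.approx(0.9775, rel=1e-12)
        assert m * d == pytest.approx(-0.35, rel=1e-10)

    def test_diagonally_symmetric_m_is_one(self):
        t = make_table(4, 9, 9, 4)
        for form in ("rsum", "csum"):
            m, d = phi_factorization(t, form)
            assert m == pytest.approx(1.0, rel=1e-12)
            assert d == pytest.approx(phi(t), rel=1e-12)

    def test_identity_pool(self, table_pool):
        for t in table_pool:
            for form in ("rsum", "csum"):
                m, d = phi_factorization(t, form)
                assert m * d == pytest.approx(phi(t), rel=1e-10, abs=1e-10)


class TestDeltaS:
    def test_yule_symmetrized_example(self, fig_table):
        sp = simplex_pair(yule_symmetrize(fig_table), "symmetric")
        expected = (math.sqrt(200) - 30) / (math.sqrt(200) + 30)
        assert delta_s(sp) == pytest.approx(expected, rel=1e-12)
        assert delta_s(sp) == pytest.approx(-0.3592455, abs=5e-7)

    def test_equal_cells(self):
        sp = simplex_pair(make_table(3, 3, 3, 3), "symmetric")
        assert delta_s(sp) == 0

    def test_boundary(self):
        sp = simplex_pair(yule_symmetrize(make_table(2, 0, 0, 3)), "symmetric")
        assert delta_s(sp) == pytest.approx(1.0)

    def test_equals_colligation_coefficient_pool(self, table_pool):
        # delta_s(yule_symmetrize(t)) = (sqrt(w)-1)/(sqrt(w)+1)
        for t in table_pool[:300]:
            w = odds_ratio(t)
            if not math.isfinite(w):
                continue
            y = (math.sqrt(w) - 1) / (math.sqrt(w) + 1)
            ds = delta_s(simplex_pair(yule_symmetrize(t), "symmetric"))
            assert ds == pytest.approx(y, rel=1e-10, abs=1e-12)

    def test_equals_phi_of_symmetrized_table(self, table_pool):
        for t in table_pool[:100]:
            s = yule_symmetrize(t)
            ds = delta_s(simplex_pair(s, "symmetric"))
            assert ds == pytest.approx(phi(s), rel=1e-10, abs=1e-12)


class TestSimpleMatching:
    def test_example(self, fig_table):
        s_m, col, row = simple_matching(fig_table)
        assert s_m == pytest.approx(1 / 3)
        assert row.weights == pytest.approx((40 / 90, 50 / 90))
        assert row.proportions == pytest.approx((0.25, 0.4))
        assert row.value() == pytest.approx(1 / 3, rel=1e-12)
        assert col.value() == pytest.approx(1 / 3, rel=1e-12)

    def test_uniform(self, uniform_table):
        assert simple_matching(uniform_table)[0] == 0.5

    def test_non_invariance_witness(self):
        # doubling row 1 changes s_M
        s_m, _, _ = simple_matching(make_table(20, 60, 30, 20))
        assert s_m == pytest.approx(40 / 130)
        assert s_m != pytest.approx(1 / 3)

    def test_decomposition_identity_pool(self, table_pool):
        for t in table_pool[:200]:
            s_m, col, row = simple_matching(t)
            assert col.value() == pytest.approx(s_m, rel=1e-12, abs=1e-12)
            assert row.value() == pytest.approx(s_m, rel=1e-12, abs=1e-12)


class TestRxCMeasures:
    def test_2x2_equivalences(self, fig_table):
        r = rxc_measures(fig_table)
        assert r.cramers_v == pytest.approx(0.35, rel=1e-10)
        assert r.tau_col == pytest.approx(0.1225, rel=1e-10)
        assert r.tau_row == pytest.approx(0.1225, rel=1e-10)

    def test_uniform_zero(self, uniform_table):
        r = rxc_measures(uniform_table)
        assert r.chi2 == pytest.approx(0, abs=1e-12)
        assert r.cramers_v == pytest.approx(0, abs=1e-9)

    def test_2x3_against_brute_force(self):
        m = np.array([[2.0, 3.0, 5.0], [4.0, 1.0, 5.0]])
        r = rxc_measures(m)
        assert r.tau_col == pytest.approx(brute_force_tau(m, "col"), rel=1e-10)
        assert r.tau_row == pytest.approx(brute_force_tau(m, "row"), rel=1e-10)

    def test_pool_equivalences(self, table_pool):
        for t in table_pool[:200]:
            r = rxc_measures(t)
            p = phi(t)
            assert r.cramers_v == pytest.approx(abs(p), rel=1e-10, abs=1e-10)
            assert r.tau_col == pytest.approx(p * p, rel=1e-10, abs=1e-10)
            assert r.tau_row == pytest.approx(p * p, rel=1e-10, abs=1e-10)

    def test_zero_margin(self):
        with pytest.raises(ZeroMarginError):
            rxc_measures(np.array([[0.0, 1.0], [0.0, 1.0]]))


class TestInvarianceMatrix:
    """Which measures survive which rescalings."""

    def test_csum_forms_invariant_to_column_scaling(self, table_pool, rng):
        for t in table_pool[:50]:
            s = float(rng.uniform(0.2, 5))
            scaled = make_table(t.a, t.b * s, t.c, t.d * s)
            for form in ("csum_rows", "csum_cols"):
                c0 = com_coords(simplex_pair(t, form))
                c1 = com_coords(simplex_pair(scaled, form))
                assert c1.delta == pytest.approx(c0.delta, abs=1e-12)
                assert c1.mu == pytest.approx(c0.mu, abs=1e-12)

    def test_rsum_forms_invariant_to_row_scaling(self, table_pool, rng):
        for t in table_pool[:50]:
            s = float(rng.uniform(0.2, 5))
            scaled = make_table(t.a, t.b, t.c * s, t.d * s)
            for form in ("rsum_rows", "rsum_cols"):
                c0 = com_coords(simplex_pair(t, form))
                c1 = com_coords(simplex_pair(scaled, form))
                assert c1.delta == pytest.approx(c0.delta, abs=1e-12)
                assert c1.mu == pytest.approx(c0.mu, abs=1e-12)

    def test_omega_q_invariant_under_u_scale(self, table_pool, rng):
        for t in table_pool[:50]:
            j, k = rng.uniform(0.2, 5, size=2)
            s = u_scale(t, float(j), float(k))
            assert odds_ratio(s) == pytest.approx(odds_ratio(t), rel=1e-10)
            assert yules_q(s) == pytest.approx(yules_q(t), rel=1e-10, abs=1e-12)

    def test_phi_sm_rr_not_invariant_witness(self, fig_table):
        s = u_scale(fig_table, j=2, k=3)
        assert phi(s) != pytest.approx(phi(fig_table), rel=1e-3)
        assert simple_matching(s)[0] != pytest.approx(
            simple_matching(fig_table)[0], rel=1e-3
        )
        assert relative_risk(s) != pytest.approx(relative_risk(fig_table), rel=1e-3)


class TestReport:
    def test_report_consistency(self, fig_table):
        rep = effect_size_report(fig_table)
        assert rep.q == pytest.approx((rep.omega - 1) / (rep.omega + 1), rel=1e-12)
        assert rep.tau_col == pytest.approx(rep.phi ** 2, rel=1e-10)
        assert rep.cramers_v == pytest.approx(abs(rep.phi), rel=1e-10)
        assert rep.forms["csum_rows"]["delta"] == pytest.approx(0.179028, abs=5e-7)
        assert rep.m_factors["rsum"] == pytest.approx(0.9775)
        d = rep.to_dict()
        assert d["counts"] == {"a": 10, "b": 30, "c": 30, "d": 20}

    def test_cohen_labels(self):
        assert cohen_label(0.05) == "negligible"
        assert cohen_label(-0.2) == "small"
        assert cohen_label(0.31) == "medium"
        assert cohen_label(-0.9) == "large"
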