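"""Phase-plane analysis: vector fields, nullclines, equilibrium search,
stability classification, and the enrichment threshold."""

import numpy as np
import pytest

from ecodyn.core import DomainError, validate_params
from ecodyn.interactions import lv_competition_spec, predprey_spec
from ecodyn.phase import (
    classify_equilibrium,
    find_equilibria,
    nullclines,
    rm_enrichment_threshold,
    vector_field,
)
from ecodyn.single_population import make_single_pop_spec


class TestVectorField:
    def test_zero_arrow_at_equilibrium(self, lv_params):
        spec = predprey_spec("lv")
        vf = vector_field(spec, lv_params, "H", "P", [15.0], [5.0])
        np.testing.assert_allclose(vf[0, 2:], 0.0, atol=1e-12)

    def test_prey_axis_is_invariant_for_all_variants(self, rm_params):
        for variant in ("lv", "logistic_prey", "type2", "rosenzweig_macarthur"):
            spec = predprey_spec(variant)
            full = dict(rm_params, K=300.0)
            params = {k: v for k, v in full.items() if k in spec.param_schema}
            vf = vector_field(spec, params, "H", "P",
                              np.linspace(1.0, 200.0, 5), [0.0])
            np.testing.assert_array_equal(vf[:, 3], 0.0)

    def test_grid_rows_cover_the_product_grid(self, lv_params):
        spec = predprey_spec("lv")
        vf = vector_field(spec, lv_params, "H", "P", np.arange(4.0), np.arange(3.0))
        assert vf.shape == (12, 4)


class TestNullclines:
    def test_numeric_contour_matches_analytic_competition_line(self):
        """dN1/dt = 0 along N2 = (K1 - N1)/a12."""
        spec = lv_competition_spec()
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 0.5, "a21": 0.5}
        curves = nullclines(spec, p, 0, "N1", "N2",
                            np.linspace(5.0, 95.0, 10), np.linspace(0.0, 250.0, 40))
        assert curves
        pts = np.vstack(curves)
        interior = pts[pts[:, 1] > 1.0]  # skip the trivial N1-axis branch
        np.testing.assert_allclose(interior[:, 1], (100.0 - interior[:, 0]) / 0.5, atol=1e-6)

    def test_empty_window_returns_no_curves(self):
        spec = make_single_pop_spec("logistic_cont")
        # dN/dt > 0 strictly inside (0, K): no nullcline in this window
        curves = nullclines(spec, {"r": 1.0, "K": 100.0}, 0, "N", "N",
                            np.linspace(10.0, 90.0, 5), np.linspace(10.0, 90.0, 5))
        assert curves == [] or all(len(c) == 0 for c in curves)

    def test_rm_predator_nullcline_is_vertical_at_h_star(self, rm_params):
        spec = predprey_spec("rosenzweig_macarthur")
        p = dict(rm_params, K=300.0)
        curves = nullclines(spec, p, 1, "H", "P",
                            np.linspace(50.0, 150.0, 41), np.linspace(1.0, 30.0, 10))
        pts = np.vstack(curves)
        np.testing.assert_allclose(pts[:, 0], 100.0, atol=1e-6)


class TestFindEquilibria:
    def test_lv_predprey_equilibria_in_box(self, lv_params):
        spec = predprey_spec("lv")
        eqs = find_equilibria(spec, lv_params, {"H": (0.0, 50.0), "P": (0.0, 50.0)})
        pts = sorted((round(e["H"], 6), round(e["P"], 6)) for e in eqs)
        assert pts == [(0.0, 0.0), (15.0, 5.0)]

    def test_lv_competition_finds_all_four(self):
        spec = lv_competition_spec()
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 0.5, "a21": 0.5}
        eqs = find_equilibria(spec, p, {"N1": (0.0, 120.0), "N2": (0.0, 120.0)})
        assert len(eqs) == 4
        assert any(
            abs(e["N1"] - 200.0 / 3.0) < 1e-6 and abs(e["N2"] - 200.0 / 3.0) < 1e-6
            for e in eqs
        )

    def test_box_without_equilibria_is_empty(self, lv_params):
        spec = predprey_spec("lv")
        eqs = find_equilibria(spec, lv_params, {"H": (20.0, 50.0), "P": (10.0, 50.0)})
        assert eqs == []

    def test_closed_form_equilibria_refound_numerically(self, rm_params):
        """Numeric multi-start search recovers every registered closed form."""
        spec = predprey_spec("rosenzweig_macarthur")
        p = validate_params(spec, dict(rm_params, K=300.0))
        expected = spec.closed_forms["equilibria"](p)
        numeric_spec = predprey_spec("rosenzweig_macarthur")
        numeric_spec.closed_forms = {}  # force pure Newton search
        eqs = find_equilibria(numeric_spec, p, {"H": (0.0, 320.0), "P": (0.0, 50.0)})
        for target in expected:
            assert any(
                abs(e["H"] - target["H"]) < 1e-6 and abs(e["P"] - target["P"]) < 1e-6
                for e in eqs
            )


class TestClassification:
    def test_classic_lv_center(self, lv_params):
        rep = classify_equilibrium(predprey_spec("lv"), lv_params, {"H": 15.0, "P": 5.0})
        assert rep.classification == "center"
        assert rep.marginal
        # eigenvalues +- i sqrt(r d)
        np.testing.assert_allclose(
            sorted(rep.eigenvalues.imag), [-np.sqrt(0.15), np.sqrt(0.15)], atol=1e-6
        )

    def test_logistic_fixed_points(self):
        spec = make_single_pop_spec("logistic_cont")
        p = {"r": 0.7, "K": 100.0}
        assert classify_equilibrium(spec, p, {"N": 100.0}).classification == "stable_node"
        assert classify_equilibrium(spec, p, {"N": 0.0}).classification == "unstable_node"

    def test_priority_effect_interior_is_saddle(self):
        spec = lv_competition_spec()
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 2.0, "a21": 2.0}
        rep = classify_equilibrium(spec, p, {"N1": 100.0 / 3.0, "N2": 100.0 / 3.0})
        assert rep.classification == "saddle"

    def test_class_invariant_to_finite_difference_step(self, rm_params):
        from ecodyn.phase import jacobian

        spec = predprey_spec("rosenzweig_macarthur")
        p = dict(rm_params, K=330.0)
        eq = {"H": 100.0, "P": (0.5 / 0.02) * 1.6 * (1 - 100.0 / 330.0)}
        classes = set()
        for h in (1e-7, 1e-6, 1e-5):
            eigs = np.linalg.eigvals(jacobian(spec, p, eq, h_scale=h))
            classes.add("stable" if np.all(eigs.real < 0) else "unstable")
        assert classes == {"stable"}

    def test_non_equilibrium_input_rejected(self, lv_params):
        with pytest.raises(DomainError):
            classify_equilibrium(predprey_spec("lv"), lv_params, {"H": 30.0, "P": 5.0})


class TestEnrichmentThreshold:
    def test_closed_form_value(self, rm_params, rm_k_crit):
        # 2 H* + 1/(a T_h) with H* = 100
        assert rm_enrichment_threshold(rm_params) == pytest.approx(rm_k_crit, rel=1e-12)

    def test_hump_position_meets_equilibrium_at_threshold(self, rm_params, rm_k_crit):
        # prey-isocline hump at K/2 - 1/(2 a T_h) equals H* when K = K_crit
        a, T_h = rm_params["a"], rm_params["T_h"]
        hump = rm_k_crit / 2.0 - 1.0 / (2.0 * a * T_h)
        assert hump == pytest.approx(100.0, rel=1e-12)

    def test_stability_flips_across_threshold(self, rm_params, rm_k_crit):
        spec = predprey_spec("rosenzweig_macarthur")
        for K, expected in ((0.9 * rm_k_crit, "stable_spiral"), (1.1 * rm_k_crit, "unstable_spiral")):
            p = validate_params(spec, dict(rm_params, K=K))
            interior = spec.closed_forms["equilibria"](p)[-1]
            assert classify_equilibrium(spec, p, interior).classification == expected

    def test_hopf_crossing_tightly_bracketed(self, rm_params, rm_k_crit):
        """The leading eigenvalue's real part changes sign within a +-1e-3
        window around K_crit."""
        from ecodyn.phase import jacobian

        spec = predprey_spec("rosenzweig_macarthur")

        def leading_real(K):
            p = validate_params(spec, dict(rm_params, K=K))
            interior = spec.closed_forms["equilibria"](p)[-1]
            return np.max(np.linalg.eigvals(jacobian(spec, p, interior)).real)

        assert leading_real(rm_k_crit - 1e-3) < 0
        assert leading_real(rm_k_crit + 1e-3) > 0

    def test_unviable_predator_rejected(self, rm_params):
        with pytest.raises(DomainError):
            rm_enrichment_threshold(dict(rm_params, e=0.1, K=300.0))
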