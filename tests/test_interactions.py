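"""Two-species models: competition outcomes, mutualism equilibria, and the
four predator-prey variants with their isoclines and first integral."""

import math

import numpy as np
import pytest

from ecodyn.core import SchemaError
from ecodyn.interactions import (
    PREDPREY_VARIANTS,
    lv_conserved_quantity,
    lvcomp_outcome,
    predprey_isoclines,
    predprey_spec,
    run_lvcomp,
    run_mutualism,
    run_predprey,
)


class TestLVCompetition:
    def test_decoupled_species_reach_their_own_capacities(self):
        p = {"r1": 1.0, "r2": 0.8, "K1": 80.0, "K2": 120.0, "a12": 0.0, "a21": 0.0}
        traj = run_lvcomp(p, {"N1": 5.0, "N2": 5.0}, 60.0)
        assert traj["N1"][-1] == pytest.approx(80.0, rel=1e-6)
        assert traj["N2"][-1] == pytest.approx(120.0, rel=1e-6)

    def test_symmetric_weak_competition_coexists_at_closed_form(self):
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 0.5, "a21": 0.5}
        out = lvcomp_outcome(p)
        assert out["outcome"] == "coexistence"
        interior = out["equilibria"][-1]
        assert interior["N1"] == pytest.approx(200.0 / 3.0, rel=1e-12)
        traj = run_lvcomp(p, {"N1": 10.0, "N2": 20.0}, 200.0)
        assert traj["N1"][-1] == pytest.approx(200.0 / 3.0, rel=1e-5)
        assert traj["N2"][-1] == pytest.approx(200.0 / 3.0, rel=1e-5)

    def test_strong_symmetric_competition_is_priority_effect(self):
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 2.0, "a21": 2.0}
        out = lvcomp_outcome(p)
        assert out["outcome"] == "priority_effect"
        interior = out["equilibria"][-1]
        assert interior["N1"] == pytest.approx(100.0 / 3.0, rel=1e-12)

    def test_asymmetric_competition_one_species_wins(self):
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 0.5, "a21": 1.5}
        assert lvcomp_outcome(p)["outcome"] == "sp1_wins"
        p["a12"], p["a21"] = 1.5, 0.5
        assert lvcomp_outcome(p)["outcome"] == "sp2_wins"

    def test_no_competition_coexists_at_capacities(self):
        p = {"K1": 90.0, "K2": 110.0, "a12": 0.0, "a21": 0.0, "r1": 1.0, "r2": 1.0}
        out = lvcomp_outcome(p)
        assert out["outcome"] == "coexistence"
        assert out["equilibria"][-1] == {"N1": 90.0, "N2": 110.0}

    def test_resident_at_capacity_repels_noninvader(self):
        # a21*K1 > K2: species 2 cannot invade a species-1 monoculture
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 0.5, "a21": 1.5}
        traj = run_lvcomp(p, {"N1": 100.0, "N2": 0.1}, 50.0)
        assert np.all(traj["N2"] <= 0.1 + 1e-9)

    def test_degenerate_equilibrium_line_flagged(self):
        p = {"r1": 1.0, "r2": 1.0, "K1": 100.0, "K2": 100.0, "a12": 1.0, "a21": 1.0}
        assert lvcomp_outcome(p)["degenerate"]


class TestMutualism:
    def test_weak_mutualism_converges_to_closed_form(self):
        p = {"r1": 0.5, "r2": 0.5, "K1": 100.0, "K2": 100.0, "b12": 0.3, "b21": 0.3}
        traj = run_mutualism(p, {"N1": 10.0, "N2": 10.0}, 300.0)
        expected = 130.0 / 0.91  # (K1 + b12 K2)/(1 - b12 b21)
        assert traj["N1"][-1] == pytest.approx(expected, rel=1e-5)
        assert traj["N2"][-1] == pytest.approx(expected, rel=1e-5)
        assert not traj.meta["unbounded"]

    def test_no_benefit_reduces_to_independent_logistic(self):
        p = {"r1": 0.5, "r2": 0.5, "K1": 70.0, "K2": 90.0, "b12": 0.0, "b21": 0.0}
        traj = run_mutualism(p, {"N1": 5.0, "N2": 5.0}, 200.0)
        assert traj["N1"][-1] == pytest.approx(70.0, rel=1e-6)
        assert traj["N2"][-1] == pytest.approx(90.0, rel=1e-6)

    def test_runaway_mutualism_flagged_unbounded(self):
        p = {"r1": 0.5, "r2": 0.5, "K1": 100.0, "K2": 100.0, "b12": 1.1, "b21": 1.1}
        traj = run_mutualism(p, {"N1": 10.0, "N2": 10.0}, 400.0)
        assert traj.meta["unbounded"]
        assert traj.meta["diverged"]


class TestPredPrey:
    def test_lv_orbit_circles_the_coexistence_point(self, lv_params):
        """The worked example: H* = d/(ea) = 15, P* = r/a = 5; the orbit is
        closed and repeatedly crosses both sides of the equilibrium."""
        traj = run_predprey("lv", lv_params, {"H": 10.0, "P": 10.0}, 100.0, dt_out=1.0)
        assert len(traj.time) == 101
        H, P = traj["H"], traj["P"]
        assert np.min(H) < 15.0 < np.max(H)
        assert np.min(P) < 5.0 < np.max(P)
        # oscillatory: multiple sign changes of H - H*
        crossings = np.sum(np.diff(np.sign(H - 15.0)) != 0)
        assert crossings >= 4

    def test_conserved_quantity_drift_is_tiny(self, lv_params):
        traj = run_predprey("lv", lv_params, {"H": 10.0, "P": 10.0}, 100.0, rel_tol=1e-10)
        V = lv_conserved_quantity(traj, lv_params)
        assert np.max(np.abs(V - V[0])) / abs(V[0]) < 1e-5

    @staticmethod
    def _variant_params(variant, rm_params):
        spec = predprey_spec(variant)
        full = dict(rm_params, K=300.0)
        return {k: v for k, v in full.items() if k in spec.param_schema}

    @pytest.mark.parametrize("variant", PREDPREY_VARIANTS)
    def test_predator_free_axis_is_invariant(self, variant, rm_params):
        params = self._variant_params(variant, rm_params)
        traj = run_predprey(variant, params, {"H": 10.0, "P": 0.0}, 50.0)
        np.testing.assert_array_equal(traj["P"], 0.0)

    @pytest.mark.parametrize("variant", PREDPREY_VARIANTS)
    def test_interior_equilibrium_annihilates_derivatives(self, variant, rm_params):
        spec = predprey_spec(variant)
        from ecodyn.core import validate_params

        p = validate_params(spec, self._variant_params(variant, rm_params))
        interior = spec.closed_forms["equilibria"](p)[-1]
        y = np.array([interior["H"], interior["P"]])
        assert interior["P"] > 0
        assert np.max(np.abs(spec.dynamics(0.0, y, p))) < 1e-10

    def test_missing_variant_parameter_is_named(self, rm_params):
        params = {k: v for k, v in rm_params.items() if k != "T_h"}
        with pytest.raises(SchemaError) as exc:
            run_predprey("rosenzweig_macarthur", dict(params, K=300.0),
                         {"H": 10.0, "P": 10.0}, 10.0)
        assert exc.value.param == "T_h"

    def test_rm_stability_dichotomy_around_threshold(self, rm_params, rm_k_crit):
        """Below K_crit prey-peak amplitudes decay; above they grow
        (successive maxima over t in [200, 400], near-equilibrium start)."""
        from ecodyn.phase import peak_amplitudes

        H_star = 100.0
        for factor, growing in ((0.9, False), (1.1, True)):
            K = factor * rm_k_crit
            P_star = (0.5 / 0.02) * (1 + 0.02 * 0.3 * H_star) * (1 - H_star / K)
            traj = run_predprey("rosenzweig_macarthur", dict(rm_params, K=K),
                                {"H": 1.1 * H_star, "P": P_star}, 400.0)
            amps = peak_amplitudes(traj, "H", H_star, 200.0, 400.0)
            assert len(amps) >= 3
            if growing:
                assert amps[-1] > 1.5 * amps[0]
            else:
                assert amps[-1] < 0.5 * amps[0]


class TestIsoclines:
    def test_lv_isoclines_at_worked_example(self, lv_params):
        iso = predprey_isoclines("lv", lv_params)
        assert iso["predator_isocline"] == pytest.approx(15.0)
        np.testing.assert_allclose(iso["prey_isocline"](np.array([1.0, 50.0])), 5.0)

    def test_rm_predator_isocline_vertical_line(self, rm_params):
        iso = predprey_isoclines("rosenzweig_macarthur", dict(rm_params, K=300.0))
        assert iso["predator_isocline"] == pytest.approx(100.0)  # d/(a(e - d T_h))

    def test_rm_prey_isocline_endpoints(self, rm_params):
        p = dict(rm_params, K=300.0)
        iso = predprey_isoclines("rosenzweig_macarthur", p)
        assert iso["prey_isocline"](0.0) == pytest.approx(p["r"] / p["a"])
        assert iso["prey_isocline"](p["K"]) == pytest.approx(0.0, abs=1e-12)

    def test_unviable_predator_has_no_isocline(self, rm_params):
        p = dict(rm_params, K=300.0, e=0.1, d=0.5, T_h=0.3)  # e < d*T_h
        iso = predprey_isoclines("rosenzweig_macarthur", p)
        assert iso["predator_isocline"] is None
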