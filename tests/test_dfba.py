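"""Two-step FBA relaxation loop, depletion switching and the dFBA driver."""

import numpy as np
import pytest

from fluxcourse.dfba import (
    DfbaConfig,
    DfbaStepError,
    MediumComponent,
    apply_depletion_rules,
    relaxation_band,
    relaxed_two_step_fba,
    run_dfba,
)
from fluxcourse.gsm import solve_fba
from fluxcourse.timecourse import ConstraintProfile


def branch_config(**kw):
    defaults = dict(
        biomass_reaction="GROWTH",
        substrate_exchange="EX_glc",
        product_exchange="EX_prod",
        t_start=0.0,
        t_end=10.0,
        step=0.05,
    )
    defaults.update(kw)
    return DfbaConfig(**defaults)


def constant_profile(uptake: float, growth: float) -> ConstraintProfile:
    return ConstraintProfile(
        uptake_targets={"EX_glc": lambda t: uptake},
        growth_target=lambda t: growth,
    )


class TestRelaxationBand:
    def test_n1_is_zero_width(self):
        assert relaxation_band(3.0, 1, 0.01) == (3.0, 3.0)

    def test_band_widens_multiplicatively(self):
        lo, hi = relaxation_band(2.0, 6, 0.01)
        assert lo == pytest.approx(2.0 * 0.95)
        assert hi == pytest.approx(2.0 * 1.05)

    def test_lower_bound_floored_at_zero(self):
        lo, hi = relaxation_band(1.0, 102, 0.01)  # 1 - 1.01 < 0
        assert lo == 0.0
        assert hi == pytest.approx(2.01)

    def test_zero_target_stays_degenerate(self):
        """A zero target keeps the band {0} under the multiplicative formula."""
        assert relaxation_band(0.0, 50, 0.01) == (0.0, 0.0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            relaxation_band(1.0, 0, 0.01)


class TestRelaxedTwoStepFba:
    def test_interior_feasible_targets_need_no_relaxation(self, branch_model):
        """Feasible targets: n = 1 and growth equals the target exactly."""
        cfg = branch_config()
        step = relaxed_two_step_fba(branch_model, 5.0, 5.0, 0.3, cfg)
        assert step.relaxation_count == 1
        # step 2 may sit at the edge of the growth-fixing slack (1e-6)
        assert step.growth_rate == pytest.approx(0.3, abs=2e-6)
        assert step.uptake_rate == pytest.approx(5.0, rel=1e-6)

    def test_five_percent_gap_first_feasible_at_n6(self, branch_model):
        """Growth capped 5% below target with d=0.01 needs band +/-5%: n=6."""
        cfg = branch_config()
        mu_target = 0.5
        cap = {"DM_X": (0.0, 0.95 * mu_target)}  # caps growth independent of bands
        step = relaxed_two_step_fba(
            branch_model, 5.0, 5.0, mu_target, cfg, extra_overrides=cap
        )
        assert step.relaxation_count == 6
        assert step.growth_rate == pytest.approx(0.95 * mu_target, abs=2e-6)

    def test_returned_n_is_minimal(self, branch_model):
        """Re-solving step 1 with the band at n-1 must be infeasible."""
        cfg = branch_config()
        mu_target = 0.5
        cap = {"DM_X": (0.0, 0.95 * mu_target)}
        step = relaxed_two_step_fba(
            branch_model, 5.0, 5.0, mu_target, cfg, extra_overrides=cap
        )
        n = step.relaxation_count
        lo_u, hi_u = relaxation_band(5.0, n - 1, cfg.relax_increment)
        lo_m, hi_m = relaxation_band(mu_target, n - 1, cfg.relax_increment)
        res = solve_fba(
            branch_model, "GROWTH", "max",
            {**cap, "EX_glc": (-hi_u, -lo_u), "GROWTH": (lo_m, hi_m)},
        )
        assert res.status == "infeasible"

    def test_growth_and_uptake_inside_reported_band(self, branch_model):
        cfg = branch_config()
        cap = {"DM_X": (0.0, 0.4)}
        step = relaxed_two_step_fba(branch_model, 5.0, 5.0, 0.5, cfg, cap)
        lo_u, hi_u = relaxation_band(5.0, step.relaxation_count, cfg.relax_increment)
        lo_m, hi_m = relaxation_band(0.5, step.relaxation_count, cfg.relax_increment)
        tol = 1e-6
        assert lo_u - tol <= step.uptake_rate <= hi_u + tol
        assert lo_m - tol <= step.growth_rate <= hi_m + tol

    def test_exhaustion_raises_step_failure(self, branch_model):
        """A target unreachable within n_max relaxations fails loudly."""
        cfg = branch_config(n_max=50)
        with pytest.raises(DfbaStepError, match="50 relaxations"):
            relaxed_two_step_fba(branch_model, 0.0, 0.0, 1.0, cfg)

    def test_product_export_blocked_during_induction(self, branch_model):
        cfg = branch_config(induction_end=2.0)
        step = relaxed_two_step_fba(branch_model, 1.0, 5.0, 0.3, cfg)
        assert step.time < cfg.induction_end
        assert step.product_flux == pytest.approx(0.0, abs=1e-9)

    def test_bilevel_dominance(self, branch_model):
        """Step-2 product flux >= the product flux of any step-1 optimum."""
        cfg = branch_config()
        for t, u, mu in [(3.0, 5.0, 0.3), (1.0, 4.0, 0.2), (6.0, 8.0, 0.1)]:
            step = relaxed_two_step_fba(branch_model, t, u, mu, cfg)
            n = step.relaxation_count
            lo_u, hi_u = relaxation_band(u, n, cfg.relax_increment)
            lo_m, hi_m = relaxation_band(mu, n, cfg.relax_increment)
            overrides = {"EX_glc": (-hi_u, -lo_u), "GROWTH": (lo_m, hi_m)}
            if t < cfg.induction_end:
                overrides["EX_prod"] = (0.0, 0.0)
            step1 = solve_fba(branch_model, "GROWTH", "max", overrides)
            assert step.product_flux >= step1.fluxes["EX_prod"] - 1e-7
            assert step.growth_rate == pytest.approx(
                step1.objective_value, abs=2e-6
            )

    def test_negative_targets_rejected(self, branch_model):
        with pytest.raises(ValueError, match="clamped"):
            relaxed_two_step_fba(branch_model, 0.0, -1.0, 0.1, branch_config())


class TestApplyDepletionRules:
    MEDIUM = (MediumComponent("EX_trp", 1.7, max_uptake=50.0),)

    def test_component_present_allows_uptake(self):
        depleted = set()
        out = apply_depletion_rules({"EX_trp": 0.5}, depleted, self.MEDIUM)
        assert out["EX_trp"] == (-50.0, 1000.0)
        assert not depleted

    def test_depleted_component_blocks_uptake_permanently(self):
        depleted = set()
        out = apply_depletion_rules({"EX_trp": 0.0}, depleted, self.MEDIUM)
        assert out["EX_trp"][0] == 0.0
        # stays blocked even if the state were (spuriously) positive again
        out = apply_depletion_rules({"EX_trp": 5.0}, depleted, self.MEDIUM)
        assert out["EX_trp"][0] == 0.0

    def test_zero_initial_concentration_disabled_from_first_step(self):
        medium = (MediumComponent("EX_phe", 0.0),)
        out = apply_depletion_rules({}, set(), medium)
        assert out["EX_phe"][0] == 0.0


class TestRunDfba:
    def test_constant_growth_matches_exponential(self, branch_model):
        """mu = 0.1/h, product blocked: X(10) = e within 1e-4."""
        cfg = branch_config(
            step=0.05, induction_end=1e9, initial_biomass=1.0,
            initial_substrate_mM=1000.0,
        )
        traj = run_dfba(branch_model, constant_profile(1.0, 0.1), cfg)
        assert traj.biomass[-1] == pytest.approx(np.exp(1.0), abs=1e-4)
        assert np.all(np.asarray([s.product_flux for s in traj.steps]) == 0.0)

    def test_empty_horizon_returns_single_state(self, branch_model):
        cfg = branch_config(t_end=0.0, initial_biomass=1.0,
                            initial_substrate_mM=5.0)
        traj = run_dfba(branch_model, constant_profile(1.0, 0.1), cfg)
        assert len(traj.times) == 1
        assert len(traj.steps) == 1
        assert traj.biomass.tolist() == [1.0]
        assert traj.concentrations["EX_glc"].tolist() == [5.0]

    def test_product_zero_through_induction(self, shik_model, case_profile,
                                            toy_case_config):
        traj = run_dfba(shik_model, case_profile, toy_case_config)
        in_induction = traj.times < toy_case_config.induction_end
        prod_flux = np.array([s.product_flux for s in traj.steps])
        np.testing.assert_allclose(prod_flux[in_induction], 0.0, atol=1e-9)
        np.testing.assert_allclose(
            traj.concentrations["EX_prod"][in_induction], 0.0, atol=1e-9
        )

    def test_amino_acid_depletion_switches_uptake_off(
        self, shik_model, case_profile, toy_case_config
    ):
        traj = run_dfba(shik_model, case_profile, toy_case_config)
        raw_trp = traj.raw_concentrations["EX_trp"]
        assert raw_trp[-1] <= 1e-6  # tryptophan runs out in this scenario
        crossed = np.nonzero(raw_trp <= 1e-9)[0]
        assert crossed.size > 0
        k = crossed[0]
        trp_flux = np.array([s.fluxes.get("EX_trp", 0.0) for s in traj.steps])
        # the crossing step is the last one allowed to take anything up;
        # uptake is switched off from the following step onward
        assert trp_flux[k] <= 1e-9
        np.testing.assert_allclose(trp_flux[k + 1:], 0.0, atol=1e-9)
        # undershoot is bounded by the last allowed step's own consumption
        max_step_uptake = (
            np.abs(trp_flux[max(k - 1, 0): k + 1]).max()
            * traj.biomass[k]
            * toy_case_config.step
        )
        assert raw_trp.min() >= -max_step_uptake - 1e-9
        # reported (floored) concentrations never go negative
        assert traj.concentrations["EX_trp"].min() >= 0.0

    def test_conservation_audit_on_toy(self, shik_model, case_profile,
                                       toy_case_config):
        """Yields bound the trajectory: growth and product cannot outrun glucose."""
        traj = run_dfba(shik_model, case_profile, toy_case_config)
        glc_used = (
            traj.concentrations["EX_glc"][0] - traj.concentrations["EX_glc"][-1]
        )
        biomass_formed = traj.biomass[-1] - traj.biomass[0]
        product_formed = traj.concentrations["EX_prod"][-1]
        assert glc_used > 0
        # growth consumes 5 glucose per unit; product branch yields 0.5/1
        assert 5.0 * biomass_formed <= glc_used + 1e-6
        assert product_formed / 0.5 * 1.0 <= glc_used - 5.0 * biomass_formed + 1e-6

    def test_missing_uptake_target_rejected(self, branch_model):
        profile = ConstraintProfile(
            uptake_targets={"EX_other": lambda t: 1.0},
            growth_target=lambda t: 0.1,
        )
        with pytest.raises(KeyError, match="EX_glc"):
            run_dfba(branch_model, profile, branch_config())

    def test_step_failure_annotates_time(self, branch_model):
        cfg = branch_config(n_max=10)
        profile = constant_profile(0.0, 1.0)  # no carbon but must grow
        with pytest.raises(DfbaStepError) as err:
            run_dfba(branch_model, profile, cfg)
        assert err.value.time == pytest.approx(0.0)
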