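"""Unit tests for the isotope-accounting operations."""

import math
from datetime import datetime

import numpy as np
import pytest

import ptracer as pt
from ptracer.partitioning import PartitioningError


class TestDecayCorrect:
    @pytest.mark.parametrize(
        "activity, elapsed, expected",
        [
            (100.0, 0.0, 100.0),
            (100.0, 14.276, 200.0),          # one half-life back doubles
            (100.0, 2 * 14.276, 400.0),
        ],
    )
    def test_against_exponential_oracle(self, activity, elapsed, expected):
        got = pt.decay_correct(activity, elapsed, 14.276)
        assert got == pytest.approx(expected)
        # independent closed form exp(ln2 * t / T)
        assert got == pytest.approx(activity * math.exp(math.log(2) * elapsed / 14.276))

    def test_round_trip_is_identity(self):
        a = pt.decay_correct(pt.decay_correct(57.3, 9.1), -9.1)
        assert a == pytest.approx(57.3, rel=1e-12)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(PartitioningError):
            pt.decay_correct(1.0, 1.0, 0.0)


class TestRecoveryAndRatios:
    def test_fraction_recovered(self):
        assert pt.fraction_recovered(0.0, 3.7e6) == 0.0
        assert pt.fraction_recovered(3.7e6, 3.7e6) == pytest.approx(100.0)
        assert pt.fraction_recovered(4.366e5, 3.7e6) == pytest.approx(11.8, abs=0.005)
        with pytest.raises(PartitioningError):
            pt.fraction_recovered(1.0, 0.0)

    @pytest.mark.parametrize(
        "r_over_R, shoot_p, expected",
        [(11.8, 4.6, 0.026), (20.1, 19.7, 0.010), (0.0, 5.0, 0.0)],
    )
    def test_specific_activity(self, r_over_R, shoot_p, expected):
        assert pt.specific_activity(r_over_R, shoot_p) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "shoot_p, r_over_R, expected",
        [(4.6, 11.8, 39.0), (19.7, 20.1, 98.0), (7.3, 100.0, 7.3)],
    )
    def test_l_value(self, shoot_p, r_over_R, expected):
        assert pt.l_value(shoot_p, r_over_R) == pytest.approx(expected, abs=0.5)

    def test_l_is_reciprocal_of_sa(self):
        assert pt.l_value(4.6, 11.8) * pt.specific_activity(11.8, 4.6) == pytest.approx(1.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(PartitioningError):
            pt.specific_activity(10.0, 0.0)
        with pytest.raises(PartitioningError):
            pt.l_value(4.6, 0.0)


class TestSeedAllocation:
    def test_no_depletion_allocates_nothing(self):
        b = pt.SeedBudget(1.2, 1.2, 3.0, 1.2, 0.3)
        assert pt.seed_p_allocated(b) == 0.0

    def test_shoot_share_of_depleted_seed_p(self):
        b = pt.SeedBudget(1.2, 0.3, 3.0, 1.2, 0.3)
        assert pt.seed_p_allocated(b) == pytest.approx(0.9 * 3.0 / 4.5)

    def test_full_shoot_share_limiting_case(self):
        b = pt.SeedBudget(1.0, 0.0, 2.0, 0.0, 0.0)
        assert pt.seed_p_allocated(b) == pytest.approx(1.0)

    def test_residual_above_sown_rejected(self):
        with pytest.raises(PartitioningError):
            pt.SeedBudget(0.5, 0.6, 1.0, 1.0)


class TestPartitionChain:
    def test_ic0_on_control_means(self):
        assert pt.ic0(11.8, 4.6, 0.62) == pytest.approx(2.965, abs=0.001)
        assert pt.ic0(10.0, 5.0, 0.0) == pytest.approx(2.0)
        with pytest.raises(PartitioningError):
            pt.ic0(11.8, 0.5, 0.62)

    def test_psoil_from_tracer(self):
        assert pt.psoil_from_tracer(4.6, 0.62, 20.1, 11.8) == pytest.approx(6.78, abs=0.01)
        assert pt.psoil_from_tracer(4.6, 0.62, 11.8, 11.8) == pytest.approx(4.6 - 0.62)
        assert pt.psoil_from_tracer(4.6, 0.62, 0.0, 11.8) == 0.0
        with pytest.raises(PartitioningError):
            pt.psoil_from_tracer(4.6, 0.62, 10.0, 0.0)

    def test_pfert_residual_and_negative_contract(self):
        assert pt.pfert_residual(10.0, 3.0, 7.0) == pytest.approx(0.0)
        assert pt.pfert_residual(12.5, 0.67, 5.5) == pytest.approx(6.33)
        # noise can push the residual negative; it is retained, not clipped
        assert pt.pfert_residual(10.0, 1.0, 10.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "pfert, pt_val, expected", [(10.9, 19.7, 55.3), (7.0, 12.5, 56.0), (0.0, 5.0, 0.0)]
    )
    def test_pdff(self, pfert, pt_val, expected):
        assert pt.pdff(pfert, pt_val) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "pfert, dose, expected", [(10.9, 50.0, 21.8), (7.0, 50.0, 14.0), (0.0, 50.0, 0.0)]
    )
    def test_cpu(self, pfert, dose, expected):
        assert pt.cpu(pfert, dose) == pytest.approx(expected)

    def test_agronomic_effectiveness(self):
        ref = pt.PartitionResult("TSP", "cumulative", 19.7, 0.89, 8.0, 10.9, 20.1,
                                 Pdff=55.33, CPU=21.8)
        test = pt.PartitionResult("TCSS", "cumulative", 12.5, 0.67, 4.8, 7.0, 14.0,
                                  Pdff=56.0, CPU=14.0)
        eff = pt.agronomic_effectiveness(test, ref)
        assert eff.AE_CPU == pytest.approx(64.2, abs=0.05)
        assert eff.AE_Pdff == pytest.approx(101.2, abs=0.05)
        same = pt.agronomic_effectiveness(ref, ref)
        assert same.AE_CPU == pytest.approx(100.0)
        assert same.AE_Pdff == pytest.approx(100.0)


class TestCumulateCuts:
    def _res(self, trt, Pt, Pseed, Psoil, Pfert, r):
        return pt.PartitionResult(trt, "cut", Pt, Pseed, Psoil, Pfert, r)

    def test_single_cut_identity(self):
        r = self._res("TSP", 5.0, 1.0, 2.0, 2.0, 8.0)
        out = pt.cumulate_cuts([r], dose=50.0)
        assert (out.Pt, out.Pseed, out.Psoil, out.Pfert) == (5.0, 1.0, 2.0, 2.0)

    def test_additivity_and_ratio_recompute(self):
        cuts = [self._res("TSP", 2.0, 0.0, 1.0, 1.0, 4.0)] * 2
        out = pt.cumulate_cuts(cuts, dose=50.0)
        assert out.Pt == 4.0 and out.Pfert == 2.0
        assert out.Pdff == pytest.approx(50.0)
        assert out.CPU == pytest.approx(4.0)

    def test_three_cuts_against_sum_oracle(self):
        rng = np.random.default_rng(3)
        cuts = [
            self._res("TCSS", *rng.uniform(0.5, 5.0, 4), rng.uniform(1, 10))
            for _ in range(3)
        ]
        out = pt.cumulate_cuts(cuts)
        assert out.Pt == pytest.approx(sum(c.Pt for c in cuts))
        assert out.r_over_R == pytest.approx(sum(c.r_over_R for c in cuts))
        assert out.L == pytest.approx(out.Pt / (out.r_over_R / 100.0))

    def test_mixed_treatments_rejected(self):
        with pytest.raises(PartitioningError):
            pt.cumulate_cuts(
                [self._res("TSP", 1, 0, 1, 0, 1), self._res("TCSS", 1, 0, 1, 0, 1)]
            )


class TestPartitionExperiment:
    def test_noise_free_consistency(self, noise_free_experiment):
        """On noise-free data meeting the equal-SA assumption the estimator
        is exact: recovered Pdff, CPU, Psoil equal ground truth."""
        cfg, obs, budgets, truth, label, doses = noise_free_experiment
        table = pt.partition_experiment(obs, budgets, label, doses)
        for m in table.treatment_means:
            assert m.Pt == pytest.approx(truth.truth(m.treatment, "Pt"), rel=1e-9)
            assert m.Psoil == pytest.approx(truth.truth(m.treatment, "Psoil"), rel=1e-9)
            assert m.Pfert == pytest.approx(truth.truth(m.treatment, "Pfert"), abs=1e-9)
            if doses[m.treatment] > 0:
                assert m.Pdff == pytest.approx(truth.truth(m.treatment, "Pdff"), rel=1e-9)
                assert m.CPU == pytest.approx(truth.truth(m.treatment, "CPU"), rel=1e-9)

    def test_mass_balance_on_every_row(self, noisy_experiment):
        cfg, obs, budgets, truth, label, doses = noisy_experiment
        table = pt.partition_experiment(obs, budgets, label, doses)
        per_pot = table.per_pot
        residual = per_pot["Pt"] - (per_pot["Pseed"] + per_pot["Psoil"] + per_pot["Pfert"])
        assert np.allclose(residual, 0.0, atol=1e-10)

    def test_missing_control_raises(self, noisy_experiment):
        cfg, obs, budgets, truth, label, doses = noisy_experiment
        fert_only = obs[obs["treatment"] != "control"]
        with pytest.raises(PartitioningError, match="control"):
            pt.partition_experiment(fert_only, budgets, label, doses)

    def test_sa_violation_biases_psoil_in_known_direction(self):
        """If a treatment's soil pool has SA below the control's (label
        diluted, e.g. by microbial turnover), its tracer recovery drops and
        the method underestimates Psoil: bias = Psoil_true * (m - 1)."""
        for mult in (0.8, 1.2):
            cfg = pt.default_pot_config(seed=11, cv_dm=0.0, cv_p=0.0, cv_count=0.0)
            treatments = dict(cfg.treatments)
            tcss = treatments["TCSS"]
            treatments["TCSS"] = pt.TreatmentConfig(
                dose=tcss.dose, soil_uptake=tcss.soil_uptake,
                fert_fraction=tcss.fert_fraction, seed_shoot_p=tcss.seed_shoot_p,
                shoot_dm=tcss.shoot_dm, sa_multiplier=mult,
            )
            cfg2 = pt.SimulationConfig(
                treatments=treatments, seed=11, cv_dm=0.0, cv_p=0.0, cv_count=0.0
            )
            obs, budgets, truth, label = pt.simulate_pot_experiment(cfg2)
            doses = {t: c.dose for t, c in treatments.items()}
            table = pt.partition_experiment(obs, budgets, label, doses)
            est = next(m for m in table.treatment_means if m.treatment == "TCSS")
            true_psoil = truth.truth("TCSS", "Psoil")
            bias = est.Psoil - true_psoil
            assert bias == pytest.approx(true_psoil * (mult - 1.0), rel=1e-9)
            # Pfert moves the opposite way by the same amount (mass balance)
            assert est.Pfert - truth.truth("TCSS", "Pfert") == pytest.approx(-bias, rel=1e-9)

    def test_aggregate_mode_reproduces_desk_arithmetic(self, noise_free_experiment):
        cfg, obs, budgets, truth, label, doses = noise_free_experiment
        table = pt.partition_experiment(obs, budgets, label, doses, mode="aggregate")
        ctl = next(m for m in table.treatment_means if m.treatment == "control")
        tsp = next(m for m in table.treatment_means if m.treatment == "TSP")
        expected_psoil = pt.psoil_from_tracer(ctl.Pt, ctl.Pseed, tsp.r_over_R, ctl.r_over_R)
        assert tsp.Psoil == pytest.approx(expected_psoil, rel=1e-12)
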