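"""Synthetic-experiment generators: reproducibility, conservation, calibration."""

import numpy as np
import pandas as pd
import pytest

import ptracer as pt
from ptracer.simulate import SimulationError, IncubationTreatment


class TestPotGenerator:
    def test_unseeded_refused(self):
        cfg = pt.default_pot_config(seed=1)
        unseeded = pt.SimulationConfig(treatments=cfg.treatments, seed=None)
        with pytest.raises(SimulationError, match="seed"):
            pt.simulate_pot_experiment(unseeded)

    def test_reproducible_given_seed(self):
        a, *_ = pt.simulate_pot_experiment(pt.default_pot_config(seed=42))
        b, *_ = pt.simulate_pot_experiment(pt.default_pot_config(seed=42))
        pd.testing.assert_frame_equal(a, b)
        c, *_ = pt.simulate_pot_experiment(pt.default_pot_config(seed=43))
        assert not a["shoot_p"].equals(c["shoot_p"])

    def test_label_conservation(self):
        cfg = pt.default_pot_config(seed=3)
        obs, *_ = pt.simulate_pot_experiment(cfg)
        per_pot = obs.groupby("pot_id")["shoot_activity"].sum()
        assert (per_pot <= cfg.introduced_activity_R).all()

    def test_activities_require_decay_correction(self):
        """Raw activities are decayed to the count dates: analysing without
        correction would understate recovery severalfold at day 59+."""
        cfg = pt.default_pot_config(seed=5, cv_dm=0.0, cv_p=0.0, cv_count=0.0)
        obs, budgets, truth, label = pt.simulate_pot_experiment(cfg)
        last = obs[obs["cut"] == 3].iloc[0]
        elapsed = (last["count_timestamp"] - label.labeling_timestamp).total_seconds() / 86400
        assert elapsed > 55
        corrected = pt.decay_correct(last["shoot_activity"], elapsed)
        assert corrected / last["shoot_activity"] > 10  # ~2^(61/14.3)

    def test_default_config_matches_calibrated_magnitudes(self):
        """Noise-free defaults reproduce the calibrated cumulative magnitudes:
        Pt ~= 4.6/19.7/12.5 mg P per kg and fertilizer fractions ~0.55."""
        cfg = pt.default_pot_config(seed=1, cv_dm=0.0, cv_p=0.0, cv_count=0.0)
        _, _, truth, _ = pt.simulate_pot_experiment(cfg)
        cum = truth.cumulative.set_index("treatment")
        assert cum.loc["control", "Pt"] == pytest.approx(4.6, abs=0.15)
        assert cum.loc["TSP", "Pt"] == pytest.approx(19.7, abs=0.3)
        assert cum.loc["TCSS", "Pt"] == pytest.approx(12.5, abs=0.3)
        assert cum.loc["TSP", "Pdff"] == pytest.approx(55.0, abs=1.5)
        assert cum.loc["TCSS", "Pdff"] == pytest.approx(56.0, abs=1.5)

    def test_stochastic_recovery_within_monte_carlo_error(self):
        """At n=5 and 10% CV the pipeline recovers the true Pdff within
        2 standard errors over seeded replicate simulations."""
        truths, ests = [], []
        for seed in range(40):
            cfg = pt.default_pot_config(seed=seed)
            obs, budgets, truth, label = pt.simulate_pot_experiment(cfg)
            doses = {t: c.dose for t, c in cfg.treatments.items()}
            table = pt.partition_experiment(obs, budgets, label, doses)
            est = next(m for m in table.treatment_means if m.treatment == "TSP")
            truths.append(truth.truth("TSP", "Pdff"))
            ests.append(est.Pdff)
        bias = np.mean(np.array(ests) - np.array(truths))
        se = np.std(np.array(ests) - np.array(truths), ddof=1) / np.sqrt(len(ests))
        assert abs(bias) < 2 * se


class TestIncubationGenerator:
    def test_zero_model_gives_blank_volumes(self):
        cfg = pt.default_incubation_config(
            seed=1,
            treatments={"null": IncubationTreatment(basal=0.0, amplitude=0.0, k=0.5)},
        )
        records = pt.simulate_incubation(cfg)
        assert all(r.v_sample == pytest.approx(r.v_blank) for r in records)

    def test_round_trip_through_respiration_module(self):
        """The titration analysis recovers the generating interval masses."""
        cfg = pt.default_incubation_config(seed=2)
        records = pt.simulate_incubation(cfg)
        series = pt.respiration_series_from_records(records)
        model = cfg.treatments["TCSS"]
        got = series["TCSS"].interval_mass
        bounds = list(zip((0.0,) + tuple(cfg.schedule[:-1]), cfg.schedule))
        expected = [model.interval_mass(s, e) for s, e in bounds]
        assert np.allclose(got, expected, rtol=1e-10)

    def test_tcss_default_lands_in_calibration_envelope(self):
        """Default organic-amendment parameters give a day-1 flux in the
        49-61 mg C/kg/d range and a 63-day cumulative within 214-255 mg C/kg."""
        cfg = pt.default_incubation_config(seed=3)
        records = pt.simulate_incubation(cfg)
        series = pt.respiration_series_from_records(records)["TCSS"]
        assert 49.0 <= series.daily[0] <= 61.0
        assert 214.0 <= series.total <= 255.0
        # independent numeric-integration oracle for the cumulative
        model = cfg.treatments["TCSS"]
        t = np.linspace(0, 63, 200_000)
        flux = model.basal + model.amplitude * np.exp(-model.k * t)
        assert series.total == pytest.approx(np.trapezoid(flux, t), rel=1e-4)

    def test_trap_saturation_raises(self):
        cfg = pt.default_incubation_config(
            seed=1,
            treatments={"hot": IncubationTreatment(basal=500.0, amplitude=0.0, k=0.5)},
        )
        with pytest.raises(SimulationError, match="saturation"):
            pt.simulate_incubation(cfg)


class TestDegreeDays:
    def test_constant_temperature(self):
        assert pt.degree_days([25.0] * 4) == pytest.approx(100.0)

    def test_growing_season_magnitude(self):
        # a 27-day run at the season's mean temperature accumulates ~693 dd
        assert pt.degree_days([25.67] * 27) == pytest.approx(693.1, abs=0.1)

    def test_days_below_base_contribute_zero(self):
        assert pt.degree_days([4.0, -3.0, 6.0], base=5.0) == pytest.approx(1.0)
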