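from datetime import datetime

import pytest

import ptracer as pt


@pytest.fixture()
def labeling():
    return pt.LabelingEvent(3.7e6, datetime(2008, 4, 1, 12, 0))


@pytest.fixture()
def noise_free_experiment():
    """Deterministic noise-free pot experiment with known ground truth."""
    cfg = pt.default_pot_config(seed=7, cv_dm=0.0, cv_p=0.0, cv_count=0.0)
    obs, budgets, truth, label = pt.simulate_pot_experiment(cfg)
    doses = {t: c.dose for t, c in cfg.treatments.items()}
    return cfg, obs, budgets, truth, label, doses


@pytest.fixture()
def noisy_experiment():
    """Seeded stochastic pot experiment at the default CVs (10 % biological)."""
    cfg = pt.default_pot_config(seed=20)
    obs, budgets, truth, label = pt.simulate_pot_experiment(cfg)
    doses = {t: c.dose for t, c in cfg.treatments.items()}
    return cfg, obs, budgets, truth, label, doses
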