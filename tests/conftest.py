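import warnings

import pytest

import foragebudget as fb


@pytest.fixture(scope="session")
def heifer_setup():
    """Parameter set of the replacement-heifer case study."""
    params = fb.IntakeParameters(pct_bw=2.5, head_count=60, period_days=167)
    supply = fb.ForageSupply(forage_kg_per_ha=917.78, harvest_efficiency=0.25)
    period = fb.GrazingPeriod(167, label="heifer")
    return params, supply, period


@pytest.fixture(scope="session")
def synthetic_run():
    """A seeded synthetic heifer herd observed through the noisy scale."""
    cfg = fb.heifer_config(seed=42)
    true = fb.simulate_true_weights(cfg)
    records, truth = fb.observe_weights(true, cfg)
    return cfg, true, records, truth


@pytest.fixture(scope="session")
def cleaned_run(synthetic_run):
    """The synthetic herd pushed through the full cleaning pipeline."""
    cfg, true, records, truth = synthetic_run
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", fb.DataQualityWarning)
        herd, flagged = fb.clean_herd(records, fb.GrazingPeriod(cfg.period_days))
    return herd, flagged
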