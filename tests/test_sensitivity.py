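"""Monte Carlo %BW sensitivity and the exact linear envelope."""

import numpy as np
import pytest

import foragebudget as fb
from foragebudget.core import ParameterError
from foragebudget.sensitivity import DEFAULT_BAND_LEVELS, _band_percentiles


@pytest.fixture(scope="module")
def pinned_herd(heifer_setup):
    """Constant herd whose nominal (2.5 %BW) total is 338.96 ha — the
    published precision total, used to anchor the envelope checks."""
    params, supply, period = heifer_setup
    bw = 338.96 * supply.consumable_kg_per_ha / (
        params.head_count * params.pct_bw / 100 * params.period_days
    )
    return fb.HerdWeightMatrix.constant(bw, params.head_count, period)


class TestSampling:
    def test_draws_are_reproducible_and_in_range(self):
        dist = fb.PctBwDistribution(seed=11, n_draws=5000)
        a = fb.sample_pct_bw(dist)
        b = fb.sample_pct_bw(dist)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= dist.lower and a.max() <= dist.upper
        assert len(a) == 5000

    def test_sample_mean_matches_truncated_normal(self):
        dist = fb.PctBwDistribution(seed=3, n_draws=10_000)
        draws = fb.sample_pct_bw(dist)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - dist.truncated_mean()) < 3 * se

    def test_degenerate_distributions_rejected(self):
        with pytest.raises(ParameterError):
            fb.PctBwDistribution(lower=2.7, upper=1.8)
        with pytest.raises(ParameterError):
            fb.PctBwDistribution(n_draws=0)


class TestDeterministicBounds:
    def test_published_hectare_range(self):
        lo, hi = fb.deterministic_bounds(338.96, 2.5, 1.8, 2.7)
        assert (round(lo), round(hi)) == (244, 366)
        assert lo == pytest.approx(244.05, abs=0.01)
        assert hi == pytest.approx(366.08, abs=0.01)

    def test_degenerate_range_collapses(self):
        assert fb.deterministic_bounds(123.4, 2.5, 2.5, 2.5) == (123.4, 123.4)

    def test_published_steer_dmi_range(self):
        # nominal back-solved from the printed upper bound: 12795 * 2.5/2.7
        nominal = 12_795 * 2.5 / 2.7
        lo, hi = fb.deterministic_bounds(nominal, 2.5, 1.8, 2.7)
        assert lo == pytest.approx(8_530, rel=1e-3)
        assert hi == pytest.approx(12_795, rel=1e-9)

    def test_max_min_ratio_equals_pct_ratio(self):
        for nominal in (84_014, 366, 12_795, 10_774):
            lo, hi = fb.deterministic_bounds(float(nominal), 2.5, 1.8, 2.7)
            assert hi / lo == pytest.approx(2.7 / 1.8)


class TestEnvelope:
    def test_band_percentile_grid(self):
        qs = _band_percentiles(DEFAULT_BAND_LEVELS)
        assert qs == [0.0, 2.5, 12.5, 25.0, 50.0, 75.0, 87.5, 97.5, 100.0]

    def test_envelope_within_bounds_and_monotone(self, pinned_herd, heifer_setup):
        _, supply, _ = heifer_setup
        dist = fb.PctBwDistribution(seed=5, n_draws=2000)
        env = fb.run_monte_carlo(pinned_herd, supply, dist)
        pcols = [c for c in env.ha.columns if c.startswith("p")]
        band = env.ha[pcols].to_numpy()
        # percentile curves ordered at every day and inside the exact bounds
        assert (np.diff(band, axis=1) >= -1e-9).all()
        assert (band >= env.ha["det_min"].to_numpy()[:, None] - 1e-9).all()
        assert (band <= env.ha["det_max"].to_numpy()[:, None] + 1e-9).all()
        # cumulative curves non-decreasing in day
        assert (np.diff(env.ha["p50"].to_numpy()) >= 0).all()

    def test_median_curve_is_scaled_nominal(self, pinned_herd, heifer_setup):
        params, supply, _ = heifer_setup
        dist = fb.PctBwDistribution(seed=5, n_draws=2000)
        env = fb.run_monte_carlo(pinned_herd, supply, dist)
        nominal = fb.run_intake_ledger(pinned_herd, params, supply)
        factor = np.median(env.draws) / params.pct_bw
        np.testing.assert_allclose(
            env.dmi["p50"].to_numpy(), nominal.cum_dmi.to_numpy() * factor, rtol=1e-9
        )

    def test_scaled_run_equals_full_rerun(self, pinned_herd, heifer_setup):
        """Exactness of the linearity shortcut: scaling the nominal
        ledger by a drawn %BW reproduces a from-scratch rerun."""
        params, supply, _ = heifer_setup
        nominal = fb.run_intake_ledger(pinned_herd, params, supply)
        draw = 1.93
        rerun = fb.run_intake_ledger(
            pinned_herd,
            fb.IntakeParameters(pct_bw=draw, head_count=60, period_days=167),
            supply,
        )
        np.testing.assert_allclose(
            nominal.cum_dmi.to_numpy() * draw / 2.5,
            rerun.cum_dmi.to_numpy(),
            rtol=1e-12,
        )

    def test_extreme_band_approaches_deterministic_bounds(self, pinned_herd, heifer_setup):
        """At 10,000 draws the 100% band nearly fills the exact envelope."""
        _, supply, _ = heifer_setup
        dist = fb.PctBwDistribution(seed=5, n_draws=10_000)
        env = fb.run_monte_carlo(pinned_herd, supply, dist)
        final = env.ha.iloc[-1]
        assert final["p0"] >= final["det_min"]
        assert final["p100"] <= final["det_max"]
        assert final["p0"] <= final["det_min"] * 1.02
        assert final["p100"] >= final["det_max"] * 0.98

    def test_per_animal_mode_stays_within_bounds_and_is_narrower(
        self, pinned_herd, heifer_setup
    ):
        _, supply, _ = heifer_setup
        dist = fb.PctBwDistribution(seed=5, n_draws=500)
        herd_env = fb.run_monte_carlo(pinned_herd, supply, dist)
        animal_env = fb.run_monte_carlo(pinned_herd, supply, dist, per_animal=True)
        f_herd, f_animal = herd_env.ha.iloc[-1], animal_env.ha.iloc[-1]
        assert f_animal["p100"] <= f_animal["det_max"] + 1e-9
        assert f_animal["p0"] >= f_animal["det_min"] - 1e-9
        # herd-wide averaging of independent draws shrinks the spread
        assert (f_animal["p97.5"] - f_animal["p2.5"]) < (f_herd["p97.5"] - f_herd["p2.5"])

    def test_tidy_export_shape(self, pinned_herd, heifer_setup):
        _, supply, _ = heifer_setup
        dist = fb.PctBwDistribution(seed=5, n_draws=100)
        tidy = fb.run_monte_carlo(pinned_herd, supply, dist).to_frame()
        assert set(tidy.columns) == {"day", "quantity", "stat", "value"}
        assert set(tidy["quantity"]) == {"cum_dmi_kg", "cum_ha"}
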