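"""Quantification chain: counting, regressions, thresholds, folds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtnuc import (
    AssayConfig,
    CountSeries,
    KineticParams,
    build_count_series,
    critical_nucleus_range,
    detect_min_concentration,
    fit_nucleation_rate,
    fit_power_law,
    fit_speed_line,
    fold_stimulation,
    fraction_nucleated,
    simulate_events,
)


def _events(times) -> pd.DataFrame:
    times = np.asarray(times, dtype=float)
    return pd.DataFrame({"event_id": np.arange(times.size),
                         "template_id": np.arange(times.size),
                         "t_nucleation": times,
                         "x": 0.0, "y": 0.0, "origin": "surface",
                         "orientation": 0.0})


def _series(counts, dt=60.0) -> CountSeries:
    counts = np.asarray(counts, dtype=float)
    return CountSeries(timepoints=dt * np.arange(1, counts.size + 1),
                       counts=counts)


class TestCountSeries:
    def test_empty_events_all_zero(self):
        cs = build_count_series(_events([]), duration=600.0)
        assert np.all(cs.counts == 0)

    def test_early_events_constant_series(self):
        cs = build_count_series(_events(np.full(10, 5.0)), duration=600.0)
        assert np.all(cs.counts == 10)

    def test_last_count_equals_total(self):
        cs = build_count_series(_events([10, 50, 400, 590]), duration=600.0)
        assert cs.counts[-1] == 4

    def test_simulated_linear_regime_passes_linearity_check(self):
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=50_000,
                          duration=1200.0, rng_seed=6)
        ev = simulate_events(cfg, KineticParams(k_spont_ref=0.0))
        cs = build_count_series(ev, duration=1200.0)
        _, fit = fit_nucleation_rate(cs)
        assert fit.r_squared > 0.95

    def test_decreasing_counts_rejected(self):
        with pytest.raises(ValueError):
            _series([3, 2, 1])


class TestNucleationRate:
    def test_exact_line_slope(self):
        rate, fit = fit_nucleation_rate(_series(np.arange(0, 50, 5)))
        assert rate == pytest.approx(5.0 / 60.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_counts_zero_rate(self):
        rate, _ = fit_nucleation_rate(_series([7, 7, 7, 7]))
        assert rate == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_nucleation_rate(_series([0, 1]))

    def test_estimates_true_event_rate(self):
        """r_nuc ~ n_templates * k within 3 standard errors (Poisson)."""
        k, n = 5e-5, 30_000
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=n,
                          duration=1200.0, rng_seed=31)
        ev = simulate_events(cfg, KineticParams(k_ref=k, k_spont_ref=0.0))
        rate, fit = fit_nucleation_rate(build_count_series(ev, duration=1200.0))
        true_rate = n * k * np.exp(-k * 600.0)   # mild survival depletion
        se = max(fit.stderr["slope"], np.sqrt(n * k * 1200.0) / 1200.0)
        assert abs(rate - true_rate) < 3.0 * se


class TestPowerLaw:
    @pytest.mark.parametrize("n_true", [6.7, 1.0])
    def test_exact_points_recovered_to_six_digits(self, n_true):
        concs = [7.5, 10.0, 12.5, 15.0, 18.0, 20.0]
        rates = {c: 0.37 * c ** n_true for c in concs}
        _, n_fit, _ = fit_power_law(rates)
        assert n_fit == pytest.approx(n_true, rel=1e-6)

    def test_nonpositive_rates_excluded(self):
        rates = {5.0: 0.0, 10.0: 1.0, 15.0: 10.0, 20.0: 60.0}
        amp, n_fit, _ = fit_power_law(rates)
        assert np.isfinite(n_fit)

    def test_too_few_positive_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law({5.0: 0.0, 10.0: 1.0, 15.0: 2.0})


class TestCriticalNucleus:
    @pytest.mark.parametrize("exponent, expected", [
        (6.7, (7, 13)),
        (1.0, (1, 2)),
        (7.5, (8, 15)),
    ])
    def test_one_to_two_times_exponent_rounded(self, exponent, expected):
        assert critical_nucleus_range(exponent) == expected

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            critical_nucleus_range(0.0)


class TestDetection:
    def test_all_zero_counts_none(self):
        series = {c: [_series([0, 0, 0, 0], dt=300.0)] for c in (5.0, 7.5)}
        assert detect_min_concentration(series) is None

    def test_definition_applied(self):
        series = {
            5.0: [_series([0, 0, 0, 0], dt=300.0)],
            7.5: [_series([0, 1, 1, 2], dt=300.0),
                  _series([0, 0, 1, 1], dt=300.0)],
            10.0: [_series([2, 4, 6, 8], dt=300.0)],
        }
        assert detect_min_concentration(series, window=1200.0) == 7.5

    @settings(derandomize=True, max_examples=30)
    @given(extra=st.integers(0, 5), conc=st.sampled_from([5.0, 7.5, 10.0]))
    def test_monotone_under_added_events(self, extra, conc):
        """Adding events can only lower (or keep) the detected threshold."""
        base = {5.0: [[0, 0, 0, 0]], 7.5: [[0, 0, 1, 1]], 10.0: [[1, 2, 3, 4]]}
        series = {c: [_series(v, dt=300.0) for v in vals]
                  for c, vals in base.items()}
        before = detect_min_concentration(series, window=1200.0)
        bumped = {c: [_series(np.asarray(v) + (extra if c == conc else 0),
                              dt=300.0) for v in vals]
                  for c, vals in base.items()}
        after = detect_min_concentration(bumped, window=1200.0)
        assert after is not None
        assert before is None or after <= before


class TestSpeedLine:
    def test_exact_line_intercept(self):
        slope, x_int, _ = fit_speed_line({2.0: 0.0, 15.0: 26.8})
        assert x_int == pytest.approx(2.0, rel=1e-12)
        assert slope == pytest.approx(26.8 / 13.0, rel=1e-12)

    def test_flat_line_rejected(self):
        with pytest.raises(ValueError):
            fit_speed_line({5.0: 3.0, 10.0: 3.0, 15.0: 3.0})


class TestFractionAndFolds:
    def test_no_events_zero(self):
        assert fraction_nucleated(_events([]), 1000) == 0.0

    def test_all_templates_fired(self):
        assert fraction_nucleated(_events(np.linspace(0, 500, 100)), 100) == 1.0

    def test_window_respected(self):
        ev = _events([100.0, 200.0, 600.0])
        assert fraction_nucleated(ev, 10, window=540.0) == pytest.approx(0.2)

    def test_equal_rates_unit_folds(self):
        folds, mx = fold_stimulation({0.0: 2.0, 50.0: 2.0, 100.0: 2.0})
        assert all(f == 1.0 for f in folds.values())
        assert mx == 1.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_stimulation({50.0: 2.0}, reference=0.0)
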