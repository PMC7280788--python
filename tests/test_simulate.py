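"""Stochastic simulator: waiting-time law, count statistics, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtnuc import (
    AssayConfig,
    KineticParams,
    nucleation_rate_per_complex,
    simulate_dilution_series,
    simulate_events,
    simulate_trajectories,
    speeds_from_trajectories,
)
from mtnuc.simulate import derive_seed


def _rate_params(k: float, n_spont: float = 8.0) -> KineticParams:
    """Params with per-template rate exactly k at the reference conc."""
    return KineticParams(k_ref=k, n_coop=1.0, k_spont_ref=0.0)


class TestSimulateEvents:
    def test_zero_concentration_gives_empty_table(self):
        cfg = AssayConfig(assay="gturc", tubulin_conc=0.0, n_templates=100,
                          rng_seed=1)
        ev = simulate_events(cfg, KineticParams(k_spont_ref=0.0))
        assert len(ev) == 0

    def test_same_seed_identical_tables(self):
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=5000,
                          rng_seed=42)
        a = simulate_events(cfg)
        b = simulate_events(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_count_matches_binomial_oracle(self):
        """n(1-e^{-k t}) templates fire on average; k=1e-4, t=600, n=1000."""
        k, n, t = 1e-4, 1000, 600.0
        p = 1.0 - np.exp(-k * t)
        expected, sd = n * p, np.sqrt(n * p * (1.0 - p))
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=n,
                          duration=t)
        counts = []
        for s in range(30):
            ev = simulate_events(cfg.model_copy(update={"rng_seed": s}),
                                 _rate_params(k))
            counts.append(len(ev))
        assert abs(np.mean(counts) - expected) < 3.0 * sd / np.sqrt(30)

    def test_waiting_times_are_exponential(self):
        """KS agreement of first-firing times with Exponential(k), n=10^4."""
        k = 1e-3
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=10_000,
                          duration=5e4, rng_seed=7)
        ev = simulate_events(cfg, _rate_params(k))
        assert len(ev) == 10_000          # duration >> 1/k: all fire
        res = stats.kstest(ev["t_nucleation"], "expon", args=(0.0, 1.0 / k))
        assert res.pvalue > 0.01

    def test_cumulative_count_linear_in_early_regime(self):
        """For kt <= 0.05 the count curve is linear (R^2 > 0.99)."""
        k = 0.05 / 1200.0
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=50_000,
                          duration=1200.0, rng_seed=3)
        ev = simulate_events(cfg, _rate_params(k))
        t = np.sort(ev["t_nucleation"])
        counts = np.arange(1, t.size + 1)
        res = stats.linregress(t, counts)
        assert res.rvalue ** 2 > 0.99

    def test_events_confined_to_duration_and_field(self):
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=20_000,
                          duration=800.0, rng_seed=5)
        ev = simulate_events(cfg)
        assert ev["t_nucleation"].between(0, cfg.duration).all()
        assert ev["x"].between(0, cfg.field_size[0]).all()
        assert ev["y"].between(0, cfg.field_size[1]).all()
        surface = ev[ev["template_id"] >= 0]
        assert surface["template_id"].value_counts().max() == 1  # fire once

    def test_template_free_assay_only_landed_events(self):
        cfg = AssayConfig(assay="none", tubulin_conc=18.0, n_templates=0,
                          duration=1200.0, rng_seed=9)
        ev = simulate_events(cfg)
        assert (ev["origin"] == "landed").all()
        assert (ev["template_id"] == -1).all()


class TestSimulateTrajectories:
    def test_zero_variance_kinematics(self):
        """No speed dispersion: plus-end displacement is exactly v*t."""
        p = KineticParams(speed_sd_plus=0.0, speed_sd_minus=0.0,
                          k_spont_ref=0.0)
        cfg = AssayConfig(assay="seed", tubulin_conc=15.0, n_templates=1,
                          duration=100.0, frame_interval=5.0, rng_seed=0)
        traj = simulate_trajectories(simulate_events(cfg, p), cfg, p)
        end = traj[traj["t"] == 100.0].iloc[0]
        assert end["plus_end_pos"] == pytest.approx(26.8e-3 * 100.0)
        assert end["minus_end_pos"] == pytest.approx(-7.0e-3 * 100.0)

    def test_turc_minus_end_static(self):
        cfg = AssayConfig(assay="gturc", tubulin_conc=20.0, n_templates=50_000,
                          duration=600.0, rng_seed=2)
        ev = simulate_events(cfg, KineticParams(k_spont_ref=0.0))
        traj = simulate_trajectories(ev, cfg, KineticParams(k_spont_ref=0.0))
        assert (traj.groupby("event_id")["minus_end_pos"].nunique() == 1).all()

    def test_length_nonnegative_and_nondecreasing(self, seed_config):
        traj = simulate_trajectories(simulate_events(seed_config), seed_config)
        length = traj["plus_end_pos"] - traj["minus_end_pos"]
        assert (length >= 0).all()
        assert (traj.groupby("event_id")
                .apply(lambda g: np.all(np.diff(g["plus_end_pos"]
                                                - g["minus_end_pos"]) >= 0),
                       include_groups=False).all())

    def test_drawn_speeds_match_calibration(self):
        """Seed-assay sample means sit within 3 SEM of 26.8 / 7.0 nm/s."""
        cfg = AssayConfig(assay="seed", tubulin_conc=15.0, n_templates=200,
                          duration=600.0, rng_seed=21)
        p = KineticParams()
        speeds = speeds_from_trajectories(
            simulate_trajectories(simulate_events(cfg, p), cfg, p))
        for col, mean, sd in [("plus_speed", 26.8, p.speed_sd_plus),
                              ("minus_speed", 7.0, p.speed_sd_minus)]:
            sem = sd / np.sqrt(len(speeds))
            assert abs(speeds[col].mean() - mean) < 3.0 * sem

    def test_mismatched_config_rejected(self, seed_config):
        ev = simulate_events(seed_config)
        other = seed_config.model_copy(update={"tubulin_conc": 10.0})
        with pytest.raises(ValueError):
            simulate_trajectories(ev, other)


class TestDilutionSeries:
    def test_single_conc_single_replicate_matches_direct_run(self):
        base = AssayConfig(assay="gturc", tubulin_conc=15.0, n_templates=2000,
                           rng_seed=5)
        series = simulate_dilution_series([15.0], 1, base)
        direct_cfg = base.model_copy(update={
            "rng_seed": derive_seed(base.rng_seed, 0, 0)})
        pd.testing.assert_frame_equal(series[15.0][0],
                                      simulate_events(direct_cfg))

    def test_full_series_shape_and_reproducibility(self):
        base = AssayConfig(assay="gturc", n_templates=1000, rng_seed=8)
        concs = [7.5, 10.0, 12.5, 15.0, 18.0, 20.0]
        s1 = simulate_dilution_series(concs, 3, base)
        s2 = simulate_dilution_series(concs, 3, base)
        assert sum(len(v) for v in s1.values()) == 18
        for c in concs:
            for a, b in zip(s1[c], s2[c]):
                pd.testing.assert_frame_equal(a, b)

    def test_counts_follow_power_law_scaling(self):
        """Expected counts scale as (c/c_ref)^6.7 across the series."""
        base = AssayConfig(assay="gturc", n_templates=200_000, rng_seed=13)
        p = KineticParams(k_spont_ref=0.0)
        series = simulate_dilution_series([10.0, 20.0], 3, base, p)
        mean = {c: np.mean([len(t) for t in tabs])
                for c, tabs in series.items()}
        expected_ratio = (
            (1 - np.exp(-nucleation_rate_per_complex(20.0, p) * 1200))
            / (1 - np.exp(-nucleation_rate_per_complex(10.0, p) * 1200)))
        assert mean[20.0] / mean[10.0] == pytest.approx(expected_ratio, rel=0.2)

    def test_empty_conc_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_series([], 3, AssayConfig())
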