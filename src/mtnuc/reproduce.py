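"""End-to-end recovery of the assay's headline numbers from synthetic data.

Each function here runs the full pipeline — simulate, (where relevant)
render and measure, then quantify — at a desk-scale problem size and
returns the recovered quantity.  These are the quantities a complete
analysis of the real assay would print: the cooperativity exponent and the
critical-nucleus bound, assay-resolved end speeds through the kymograph
path, the elongation and detection thresholds, the per-template efficiency
and the chTOG/EB3 fold-stimulation.

All randomness is derived from one base seed, so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fits import (
    CountSeries,
    build_count_series,
    critical_nucleus_range,
    detect_min_concentration,
    fit_nucleation_rate,
    fit_power_law,
    fit_speed_line,
    fold_stimulation,
    fraction_nucleated,
)
from .kinetics import KineticParams, MapDose
from .measure import MIN_LIFETIME_S, classify_ends, extract_end_traces
from .render import render_kymograph
from .simulate import (
    AssayConfig,
    derive_seed,
    simulate_dilution_series,
    simulate_events,
    simulate_trajectories,
)

__all__ = [
    "DILUTION_CONCS_UM",
    "DETECTION_GRID_UM",
    "CHTOG_DOSES_NM",
    "dilution_series_rates",
    "cooperativity_exponent",
    "speed_pipeline",
    "speed_line_intercept",
    "efficiency_percent",
    "map_fold_series",
    "detection_threshold",
    "reproduce_all",
]

#: Tubulin concentrations of the dilution series (uM).
DILUTION_CONCS_UM = (7.5, 10.0, 12.5, 15.0, 18.0, 20.0)
#: Concentration grid for the empirical detection thresholds (uM).
DETECTION_GRID_UM = (5.0, 6.0, 7.5, 10.0, 12.5, 15.0, 18.0, 20.0)
#: chTOG dose series (nM), 0 to saturating.
CHTOG_DOSES_NM = (0.0, 6.0, 13.0, 25.0, 50.0, 100.0, 1000.0)
#: Replicate fields per concentration for the detection-threshold estimate
#: (more than the 3 fields used for rate fits: the replicate-mean >= 1
#: criterion sits on a grid, so its Monte-Carlo error is reduced by
#: averaging more fields).
DETECTION_REPLICATES = 12


def dilution_series_rates(seed: int, replicates: int = 12,
                          concs: Sequence[float] = DILUTION_CONCS_UM,
                          params: Optional[KineticParams] = None,
                          ) -> Dict[float, float]:
    """Per-concentration nucleation rates from simulated count series.

    Simulates the tubulin dilution series, counts surface-nucleated
    filaments at 10 time points per field and averages the OLS rate over
    replicate fields (the assay pools at least three independent
    experiments per condition; twelve fields keep the Monte-Carlo error of
    the downstream exponent small).  Returns conc (uM) ->
    r_nuc (filaments/field/s).
    """
    params = params or KineticParams()
    base = AssayConfig(assay="gturc", rng_seed=derive_seed(seed, 10))
    series = simulate_dilution_series(concs, replicates, base, params)
    rates: Dict[float, float] = {}
    for conc, tables in series.items():
        per_rep = []
        for ev in tables:
            surface = ev[ev["origin"] == "surface"]
            cs = build_count_series(surface, duration=base.duration)
            rate, _ = fit_nucleation_rate(cs)
            per_rep.append(rate)
        rates[conc] = float(np.mean(per_rep))
    return rates


def cooperativity_exponent(seed: int, replicates: int = 12,
                           params: Optional[KineticParams] = None,
                           ) -> Tuple[float, Dict[float, float]]:
    """Recovered power-law exponent of r_nuc vs tubulin concentration."""
    rates = dilution_series_rates(seed, replicates, params=params)
    _, exponent, _ = fit_power_law(rates)
    return exponent, rates


def _speed_batch_events(n: int) -> pd.DataFrame:
    """n filaments starting at t=0, for speed measurement batches."""
    return pd.DataFrame({
        "event_id": np.arange(n, dtype=int),
        "template_id": np.arange(n, dtype=int),
        "t_nucleation": np.zeros(n),
        "x": np.zeros(n),
        "y": np.zeros(n),
        "origin": "surface",
        "orientation": np.zeros(n),
    })


def _measure_filaments(traj: pd.DataFrame, frame_interval: float,
                       seed: int, max_filaments: Optional[int] = None,
                       ) -> pd.DataFrame:
    """Render each filament to a kymograph and measure both end speeds."""
    rows: List[dict] = []
    for event_id, g in traj.groupby("event_id", sort=True):
        if len(g) * frame_interval < MIN_LIFETIME_S:
            continue
        k = render_kymograph(g, seed=derive_seed(seed, 3, int(event_id)),
                             frame_interval=frame_interval)
        traces = extract_end_traces(k)
        cls = classify_ends(traces)
        if cls["ambiguous"]:
            continue
        rows.append({"event_id": int(event_id),
                     "plus_speed": cls["plus"].speed,
                     "minus_speed": cls["minus"].speed,
                     "capped": cls["capped"]})
        if max_filaments is not None and len(rows) >= max_filaments:
            break
    return pd.DataFrame(rows)


def speed_pipeline(seed: int, assay: str = "seed", conc: float = 15.0,
                   n_filaments: int = 100,
                   params: Optional[KineticParams] = None) -> pd.DataFrame:
    """Simulate, render and measure >= n filaments through the kymograph path.

    Seed assays start all filaments at t=0 (stabilised seeds elongate on
    warming); gammaTuRC assays use natural stochastic firing and keep
    filaments observed for at least 2 min.  Returns the per-filament speed
    table (plus/minus nm/s and the capped flag).
    """
    params = params or KineticParams()
    if assay == "seed":
        cfg = AssayConfig(assay="seed", tubulin_conc=conc,
                          n_templates=n_filaments, duration=600.0,
                          rng_seed=derive_seed(seed, 20))
        events = simulate_events(cfg, params)
    else:
        cfg = AssayConfig(assay="gturc", tubulin_conc=conc,
                          duration=1200.0, rng_seed=derive_seed(seed, 21))
        events = simulate_events(cfg, params)
        events = events[events["origin"] == "surface"].reset_index(drop=True)
        events.attrs["config_key"] = cfg.config_key()
    traj = simulate_trajectories(events, cfg, params)
    return _measure_filaments(traj, cfg.frame_interval, seed,
                              max_filaments=n_filaments)


def speed_line_intercept(seed: int,
                         concs: Sequence[float] = DILUTION_CONCS_UM,
                         n_per_conc: int = 100,
                         params: Optional[KineticParams] = None,
                         ) -> Tuple[float, Dict[float, float]]:
    """x-intercept (uM) of mean extracted plus-end speed vs concentration.

    A batch of gammaTuRC filaments is rendered and measured at each
    concentration of the dilution series; the intercept estimates the
    critical tubulin concentration for plus-end elongation.
    """
    params = params or KineticParams()
    mean_speeds: Dict[float, float] = {}
    for ci, conc in enumerate(concs):
        cfg = AssayConfig(assay="gturc", tubulin_conc=float(conc),
                          n_templates=n_per_conc, duration=600.0,
                          rng_seed=derive_seed(seed, 30, ci))
        events = _speed_batch_events(n_per_conc)
        traj = simulate_trajectories(events, cfg, params)
        measured = _measure_filaments(traj, cfg.frame_interval,
                                      derive_seed(seed, 31, ci))
        mean_speeds[float(conc)] = float(measured["plus_speed"].mean())
    _, x_intercept, _ = fit_speed_line(mean_speeds)
    return x_intercept, mean_speeds


def efficiency_percent(seed: int, conc: float = 20.0,
                       n_templates: int = 100_000, window: float = 540.0,
                       params: Optional[KineticParams] = None) -> float:
    """Percentage of templates that nucleate within the window at conc."""
    cfg = AssayConfig(assay="gturc", tubulin_conc=conc,
                      n_templates=n_templates, duration=window,
                      rng_seed=derive_seed(seed, 40))
    events = simulate_events(cfg, params or KineticParams())
    return 100.0 * fraction_nucleated(events, n_templates, window=window)


def map_fold_series(seed: int, map_kind: str = "chTOG",
                    doses: Sequence[float] = CHTOG_DOSES_NM,
                    conc: float = 10.0, n_templates: int = 2_000_000,
                    replicates: int = 3,
                    params: Optional[KineticParams] = None,
                    ) -> Tuple[Dict[float, float], float]:
    """Fold-stimulation of the nucleation rate across a MAP dose series.

    Rates are recovered through the count-series regression at each dose
    and averaged over replicate fields (the assay pools at least three
    independent experiments per condition); folds are relative to the
    zero-dose condition.
    """
    params = params or KineticParams()
    rates: Dict[float, float] = {}
    for di, dose_nm in enumerate(doses):
        per_rep = []
        for ri in range(replicates):
            cfg = AssayConfig(
                assay="gturc", tubulin_conc=conc, n_templates=n_templates,
                dose=MapDose.for_kind(map_kind, float(dose_nm)),
                rng_seed=derive_seed(seed, 50, di, ri))
            events = simulate_events(cfg, params)
            surface = events[events["origin"] == "surface"]
            cs = build_count_series(surface, duration=cfg.duration)
            rate, _ = fit_nucleation_rate(cs)
            per_rep.append(rate)
        rates[float(dose_nm)] = float(np.mean(per_rep))
    return fold_stimulation(rates, reference=0.0)


def detection_threshold(seed: int, template_free: bool = False,
                        concs: Sequence[float] = DETECTION_GRID_UM,
                        replicates: int = DETECTION_REPLICATES,
                        params: Optional[KineticParams] = None,
                        ) -> Optional[float]:
    """Lowest concentration (uM) passing the >=1 filament/field/20 min rule.

    With ``template_free`` only the spontaneous solution stream fires; all
    visible filaments (surface and landed) count toward detection.
    """
    params = params or KineticParams()
    base = AssayConfig(assay="none" if template_free else "gturc",
                       n_templates=0 if template_free else
                       AssayConfig().n_templates,
                       duration=1200.0,
                       rng_seed=derive_seed(seed, 60 + int(template_free)))
    series = simulate_dilution_series(concs, replicates, base, params)
    by_conc: Dict[float, List[CountSeries]] = {}
    for conc, tables in series.items():
        by_conc[conc] = [build_count_series(ev, duration=base.duration,
                                            replicate=ri)
                         for ri, ev in enumerate(tables)]
    return detect_min_concentration(by_conc, window=1200.0)


def reproduce_all(seed: int, fast: bool = False) -> Dict[str, Dict[str, float]]:
    """Run every headline quantity's pipeline; returns name -> {value, n}.

    With ``fast`` the problem sizes are reduced (fewer filaments and
    replicates) for a quick smoke run.
    """
    n_fil = 30 if fast else 100
    n_eff = 20_000 if fast else 100_000
    n_map = 300_000 if fast else 2_000_000
    det_reps = 4 if fast else DETECTION_REPLICATES

    exponent, rates = cooperativity_exponent(seed)
    n_lower, n_upper = critical_nucleus_range(exponent)
    seed_speeds = speed_pipeline(seed, "seed", n_filaments=n_fil)
    turc_speeds = speed_pipeline(seed, "gturc", n_filaments=n_fil)
    x_int, _ = speed_line_intercept(seed, n_per_conc=25 if fast else 100)
    eff = efficiency_percent(seed, n_templates=n_eff)
    _, max_fold = map_fold_series(seed, "chTOG", n_templates=n_map)
    c_det = detection_threshold(seed, template_free=False, replicates=det_reps)
    c_spont = detection_threshold(seed, template_free=True, replicates=det_reps)

    return {
        "cooperativity_exponent": {
            "value": exponent, "n": len(rates) * 12},
        "critical_nucleus_lower": {"value": float(n_lower), "n": 1},
        "seed_plus_speed_nm_s": {
            "value": float(seed_speeds["plus_speed"].mean()),
            "n": len(seed_speeds)},
        "turc_plus_speed_nm_s": {
            "value": float(turc_speeds["plus_speed"].mean()),
            "n": len(turc_speeds)},
        "seed_minus_speed_nm_s": {
            "value": float(seed_speeds["minus_speed"].mean()),
            "n": len(seed_speeds)},
        "elongation_threshold_um": {"value": x_int, "n": len(DILUTION_CONCS_UM)},
        "efficiency_9min_pct": {"value": eff, "n": n_eff},
        "chtog_max_fold": {"value": max_fold, "n": len(CHTOG_DOSES_NM)},
        "turc_detection_threshold_um": {
            "value": float(c_det) if c_det is not None else float("nan"),
            "n": det_reps * len(DETECTION_GRID_UM)},
        "spont_detection_threshold_um": {
            "value": float(c_spont) if c_spont is not None else float("nan"),
            "n": det_reps * len(DETECTION_GRID_UM)},
    }
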