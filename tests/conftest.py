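import numpy as np
import pandas as pd
import pytest

from mtnuc import AssayConfig, KineticParams


@pytest.fixture
def params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def seed_config() -> AssayConfig:
    """A small seed assay: all filaments elongate from t=0."""
    return AssayConfig(assay="seed", tubulin_conc=15.0, n_templates=20,
                       duration=600.0, rng_seed=11)


def straight_trajectory(v_plus_um_s: float, v_minus_um_s: float = 0.0,
                        duration: float = 600.0, dt: float = 5.0,
                        event_id: int = 0) -> pd.DataFrame:
    """Deterministic single-filament trajectory for geometry oracles."""
    t = np.arange(0.0, duration, dt)
    return pd.DataFrame({
        "event_id": event_id,
        "t": t,
        "plus_end_pos": v_plus_um_s * t,
        "minus_end_pos": -v_minus_um_s * t,
    })
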