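import numpy as np
import pandas as pd
import pytest

from corticomap.synth import SimulationConfig, TrackingParams


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A fast cohort: 4/group, 30 stimulations, 10 s tracking trials."""
    return SimulationConfig(
        n_per_group=4,
        n_stims=30,
        seed=11,
        tracking=TrackingParams(duration_s=10.0, sampling_rate=50.0),
    )


@pytest.fixture
def study_cfg() -> SimulationConfig:
    """The default study-scale configuration (25 + 25, 100 stimulations)."""
    return SimulationConfig(seed=3)


def simulate_long_cohort(
    n_per_group: int,
    effects: dict[str, float],
    rng: np.random.Generator,
    subject_sd: float = 1.0,
    residual_sd: float = 1.0,
) -> pd.DataFrame:
    """Minimal long-format cohort matching the mixed model's assumptions:
    shared subject intercept, homogeneous residual SD across tests."""
    rows = []
    for lbp, label in ((0.0, "control"), (1.0, "LBP")):
        for i in range(n_per_group):
            sid = f"{label}{i:03d}"
            u = rng.normal(0.0, subject_sd)
            for test, eff in effects.items():
                rows.append(
                    {
                        "subject": sid,
                        "group": label,
                        "test": test,
                        "value": eff * lbp + u + rng.normal(0.0, residual_sd),
                    }
                )
    return pd.DataFrame(rows)
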