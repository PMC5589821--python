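import numpy as np
import pytest
from hypothesis import settings

from sepsisphase.synthetic import SimulationConfig, generate_cohort

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A default-parameter cohort small enough for unit tests."""
    return generate_cohort(SimulationConfig(n_patients=120, seed=11))


def step_integral_oracle(times, values, lo, hi, start, end, step_seconds=1.0):
    """Dense-grid numerical integration of the left-constant step function.

    Independent oracle for the excursion score: evaluates the held value
    and its percent threshold deviation on a fine regular grid and
    averages over the full window duration.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.arange(start, end, step_seconds / 60.0)
    idx = np.searchsorted(times, grid, side="right") - 1
    held = np.where(idx >= 0, values[np.clip(idx, 0, None)], np.nan)
    p = np.zeros_like(grid)
    ok = ~np.isnan(held)
    v = held[ok]
    pv = np.zeros_like(v)
    if np.isfinite(lo):
        below = v < lo
        pv[below] = (lo - v[below]) / lo
    if np.isfinite(hi):
        above = v > hi
        pv[above] = (v[above] - hi) / hi
    p[ok] = pv
    return float(np.sum(p) * (step_seconds / 60.0) / (end - start))
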