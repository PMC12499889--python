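"""Shared fixtures: small, fast simulation configs and synthetic event frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from voltmatrix import (
    DetectionParams,
    SimulationConfig,
    TraceRecording,
    make_scenario,
)
from voltmatrix.detect import EVENT_FIELDS


@pytest.fixture(scope="session")
def fast_two_marker() -> SimulationConfig:
    """two_marker at reduced scale: short runs, 50 kHz sampling."""
    return make_scenario("two_marker", duration_s=4.0, sampling_rate=50_000.0)


@pytest.fixture
def det_params() -> DetectionParams:
    return DetectionParams()


def make_flat_trace(
    level: float = -1000.0,
    n: int = 200_000,
    rate: float = 100_000.0,
    noise: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
) -> TraceRecording:
    """A constant (optionally drifting/noisy) trace with no events."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    x = level + drift * t
    if noise > 0:
        x = x + rng.normal(0, noise, n)
    return TraceRecording(
        samples=x.astype(np.float64),
        sampling_rate=rate,
        voltage=-100,
        run_id="flat",
        analyte_label="none",
    )


def inject_pulse(trace: TraceRecording, start: int, length: int, depth: float) -> TraceRecording:
    """Subtract a rectangular depression (spec sign convention) and record truth."""
    x = trace.samples.copy()
    x[start : start + length] -= depth
    return TraceRecording(
        samples=x,
        sampling_rate=trace.sampling_rate,
        voltage=trace.voltage,
        run_id=trace.run_id,
        analyte_label=trace.analyte_label,
        truth_events=trace.truth_events + [(start, start + length, "pulse")],
        baseline_offset_true=trace.baseline_offset_true,
    )


def synthetic_event_frame(
    n: int,
    rng: np.random.Generator,
    frac_mean: float = 0.2,
    dwell_ms: float = 1.0,
    i0: float = -1000.0,
    voltage: int = -100,
    run_id: str = "syn",
) -> pd.DataFrame:
    """A plausible event table drawn directly in feature space (no trace)."""
    frac = np.clip(rng.normal(frac_mean, 0.03, n), 0.01, 0.95)
    dwell = rng.lognormal(np.log(dwell_ms), 0.4, n)
    depth = frac * abs(i0)
    start = np.sort(rng.integers(0, 10_000_000, n))
    df = pd.DataFrame(
        {
            "start_index": start,
            "end_index": start + np.maximum(1, (dwell * 100).astype(int)),
            "dwell_ms": dwell,
            "delta_i_pa": depth,
            "delta_i_max_pa": depth * 1.1,
            "i0_local_pa": np.full(n, float(i0)),
            "frac_blockage": frac,
            "area_pa_ms": depth * dwell,
            "skewness": rng.normal(0, 0.3, n),
            "kurtosis": rng.normal(0, 0.5, n),
            "fwhm_ms": dwell * 0.9,
            "intra_event_sd_pa": np.full(n, 12.0),
            "baseline_rms_pa": np.full(n, 12.0),
            "drift_slope_pa_s": np.full(n, 0.5),
            "voltage": np.full(n, voltage),
            "run_id": run_id,
        },
        columns=list(EVENT_FIELDS),
    )
    return df
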