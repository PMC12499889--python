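"""Synthetic solid-state-nanopore current traces.

The generator produces seeded ionic-current recordings for protein analytes
driven through a pore under a grid of negative applied voltages.  It models
the statistical structure a downstream analysis pipeline has to cope with:

* a voltage-dependent Poisson capture process per analyte class,
  lambda(V) = alpha * |V| * exp(-V* / |V|)  (barrier-limited capture);
* run-to-run baseline offsets, white Gaussian noise and slow linear drift;
* class-specific dwell-time (log-normal, shrinking with voltage) and
  fractional-blockage (Gaussian) distributions, with an optional linear
  voltage sensitivity of the blockage used to emulate analytes whose
  conformation responds to the applied field;
* named scenarios (two biomarkers, aptamer-complex shift, baseline
  overfitting demo, equimolar mixture, serum population shift).

Blockade events are rendered as negative-going depressions of depth
``f * |I0|`` relative to the signed baseline, with exponential edges.
Every trace carries ground-truth event annotations so detectors can be
scored against the generator.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "MoleculeModel",
    "SimulationConfig",
    "TraceRecording",
    "SaturationError",
    "capture_rate_model",
    "simulate_trace",
    "make_scenario",
    "SCENARIO_NAMES",
    "write_trace",
    "read_trace",
]


class SaturationError(RuntimeError):
    """Raised when the requested event rate leaves no room for non-overlapping events."""


@dataclass(frozen=True)
class MoleculeModel:
    """Generative parameters of one analyte class (or sub-population).

    Parameters
    ----------
    name:
        Class label carried through to truth annotations.
    capture_prefactor_alpha:
        Capture prefactor, events / s / mV.
    capture_barrier_vstar:
        Capture barrier voltage V*, mV.  ``lambda(V) = alpha |V| exp(-V*/|V|)``.
    blockage_frac_mean, blockage_frac_sd:
        Mean and s.d. of the fractional blockage ``f = dI/|I0|`` at the
        100 mV reference voltage.
    dwell_median_ref_ms:
        Median dwell time at |V| = 100 mV, ms.
    dwell_log_sd:
        S.d. of log dwell (natural log).
    dwell_voltage_exponent_gamma:
        Dwell scales as ``(100/|V|)**gamma`` (faster translocation at
        stronger fields).
    blockage_voltage_slope:
        Linear shift of the mean fractional blockage per 250 mV of |V|
        beyond the 100 mV reference; 0 for a voltage-invariant analyte,
        nonzero for voltage-sensitive (e.g. aptamer-complex) behaviour.
    edge_tau_us:
        Exponential time constant of event rise/fall edges, microseconds.
    """

    name: str
    capture_prefactor_alpha: float
    capture_barrier_vstar: float
    blockage_frac_mean: float
    blockage_frac_sd: float
    dwell_median_ref_ms: float
    dwell_log_sd: float
    dwell_voltage_exponent_gamma: float = 1.0
    blockage_voltage_slope: float = 0.0
    edge_tau_us: float = 20.0

    def __post_init__(self) -> None:
        if self.capture_prefactor_alpha <= 0:
            raise ValueError("capture_prefactor_alpha must be > 0")
        if self.capture_barrier_vstar < 0:
            raise ValueError("capture_barrier_vstar must be >= 0")
        if self.dwell_median_ref_ms <= 0:
            raise ValueError("dwell_median_ref_ms must be > 0")
        if not 0 < self.blockage_frac_mean < 1:
            raise ValueError("blockage_frac_mean must lie in (0, 1)")

    def blockage_mean_at(self, voltage_mv: float) -> float:
        """Mean fractional blockage at a given voltage (slope-adjusted)."""
        shift = self.blockage_voltage_slope * (abs(voltage_mv) - 100.0) / 250.0
        return self.blockage_frac_mean + shift

    def dwell_median_at(self, voltage_mv: float) -> float:
        """Median dwell time (ms) at a given voltage."""
        return self.dwell_median_ref_ms * (100.0 / abs(voltage_mv)) ** self.dwell_voltage_exponent_gamma


def capture_rate_model(molecule: MoleculeModel, voltage_mv: float) -> float:
    """Event capture rate lambda(V) = alpha * |V| * exp(-V*/|V|), events/s.

    Strictly increasing in |V|; raises on zero voltage.
    """
    v = abs(float(voltage_mv))
    if v == 0:
        raise ValueError("capture rate is undefined at zero applied voltage")
    return molecule.capture_prefactor_alpha * v * np.exp(-molecule.capture_barrier_vstar / v)


# Default two-biomarker pair.  Capture parameters solve the two anchors the
# study design targets: equal rates at -50 mV, two-fold ratio at -300 mV.
# Dwell/blockage distributions are package defaults, exposed via config.
CEA_LIKE = MoleculeModel(
    name="cea_like",
    capture_prefactor_alpha=0.046,
    capture_barrier_vstar=61.6,
    blockage_frac_mean=0.18,
    blockage_frac_sd=0.02,
    dwell_median_ref_ms=0.5,
    dwell_log_sd=0.4,
)
CA153_LIKE = MoleculeModel(
    name="ca15_3_like",
    capture_prefactor_alpha=0.020,
    capture_barrier_vstar=20.0,
    blockage_frac_mean=0.28,
    blockage_frac_sd=0.045,
    dwell_median_ref_ms=1.5,
    dwell_log_sd=0.5,
)

DEFAULT_VOLTAGE_GRID = (-50, -100, -150, -200, -250, -300)


@dataclass
class SimulationConfig:
    """Full description of a simulated measurement campaign.

    ``samples`` maps each measurable sample (an analyte label) to molar
    fractions over ``molecules``; a pure sample is a degenerate mixture.
    When omitted, one pure sample per molecule is assumed.
    ``class_offsets`` optionally pins the run baseline offset of a given
    sample to a fixed value (pA) instead of drawing it from
    ``N(0, run_offset_sigma)``.
    """

    voltage_grid: tuple[int, ...] = DEFAULT_VOLTAGE_GRID
    sampling_rate: float = 100_000.0  # Hz
    duration_s: float = 60.0
    runs_per_condition: int = 3
    pore_conductance: float = 10.0  # nS; baseline I0 = G * V  (pA)
    noise_rms: float = 12.0  # pA
    noise_rms_jitter: float = 0.05  # fractional run-to-run spread (log-normal)
    drift_rate: float = 0.5  # pA / s
    drift_rate_jitter: float = 0.2  # fractional run-to-run spread (normal)
    run_offset_sigma: float = 25.0  # pA
    molecules: tuple[MoleculeModel, ...] = (CEA_LIKE, CA153_LIKE)
    samples: Mapping[str, tuple[float, ...]] | None = None
    class_offsets: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.voltage_grid = tuple(int(v) for v in self.voltage_grid)
        if any(v >= 0 for v in self.voltage_grid):
            raise ValueError("all grid voltages must be negative (mV)")
        if len(set(self.voltage_grid)) != len(self.voltage_grid):
            raise ValueError("grid voltages must be distinct")
        self.molecules = tuple(self.molecules)
        if self.samples is None:
            self.samples = {
                m.name: tuple(1.0 if i == j else 0.0 for j in range(len(self.molecules)))
                for i, m in enumerate(self.molecules)
            }
        self.samples = {k: tuple(float(x) for x in v) for k, v in self.samples.items()}
        for label, fr in self.samples.items():
            if len(fr) != len(self.molecules):
                raise ValueError(f"sample {label!r}: need one fraction per molecule")
            if abs(sum(fr) - 1.0) > 1e-12:
                raise ValueError(f"sample {label!r}: fractions must sum to 1")
            if any(f < 0 for f in fr):
                raise ValueError(f"sample {label!r}: fractions must be non-negative")
        for m in self.molecules:
            for v in self.voltage_grid:
                if not 0 < m.blockage_mean_at(v) < 1:
                    raise ValueError(
                        f"molecule {m.name!r}: slope-adjusted blockage leaves (0,1) at {v} mV"
                    )

    @property
    def sample_labels(self) -> tuple[str, ...]:
        return tuple(self.samples.keys())

    def sample_rates(self, label: str, voltage_mv: float) -> np.ndarray:
        """Per-class capture rates (events/s) for one sample at one voltage."""
        fr = np.asarray(self.samples[label], dtype=float)
        lam = np.array([capture_rate_model(m, voltage_mv) for m in self.molecules])
        return fr * lam


@dataclass
class TraceRecording:
    """A sampled current trace plus acquisition metadata and ground truth."""

    samples: np.ndarray  # pA, signed
    sampling_rate: float  # Hz
    voltage: int  # mV
    run_id: str
    analyte_label: str
    truth_events: list[tuple[int, int, str]] = field(default_factory=list)
    baseline_offset_true: float = 0.0
    seed: int | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    def tobytes(self) -> bytes:
        """Canonical byte serialization of the sample array (determinism checks)."""
        return np.ascontiguousarray(self.samples, dtype=np.float64).tobytes()


def _stable_hash(*parts: object) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode())


def _trace_rng(seed: int, voltage: int, run_id: str, analyte: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _stable_hash(voltage, run_id, analyte)])
    )


def _place_events(
    rng: np.random.Generator,
    config: SimulationConfig,
    voltage: int,
    analyte: str,
    n_samples: int,
) -> list[tuple[int, int, int]]:
    """Draw non-overlapping (start, end, molecule index) spans.

    Arrival times are Poisson per class; overlapping draws are rejected and
    redrawn a bounded number of times.
    """
    rate = config.sampling_rate
    duration = n_samples / rate
    rates = config.sample_rates(analyte, voltage)
    spans: list[tuple[int, int, int]] = []
    # gap of one sample between events so truth intervals stay disjoint
    occupied_starts: list[int] = []
    occupied_ends: list[int] = []

    def overlaps(s: int, e: int) -> bool:
        import bisect

        i = bisect.bisect_left(occupied_starts, e)
        if i > 0 and occupied_ends[i - 1] > s:
            return True
        if i < len(occupied_starts) and occupied_starts[i] < e:
            return True
        return False

    for k, mol in enumerate(config.molecules):
        lam = rates[k]
        if lam <= 0:
            continue
        n_events = rng.poisson(lam * duration)
        med = mol.dwell_median_at(voltage)
        for _ in range(n_events):
            dwell_ms = float(rng.lognormal(np.log(med), mol.dwell_log_sd))
            length = max(1, int(round(dwell_ms * 1e-3 * rate)))
            if length + 2 >= n_samples:
                raise SaturationError("event dwell exceeds trace length")
            placed = False
            for _attempt in range(1000):
                s = int(rng.integers(1, n_samples - length - 1))
                e = s + length
                if not overlaps(s - 1, e + 1):
                    import bisect

                    i = bisect.bisect_left(occupied_starts, s)
                    occupied_starts.insert(i, s)
                    occupied_ends.insert(i, e)
                    spans.append((s, e, k))
                    placed = True
                    break
            if not placed:
                raise SaturationError(
                    "could not place a non-overlapping event after 1000 retries; "
                    "reduce event rates or increase duration"
                )
    spans.sort()
    return spans


def simulate_trace(
    config: SimulationConfig,
    voltage: int,
    run_id: str,
    seed: int | None = None,
    analyte: str | None = None,
) -> TraceRecording:
    """Simulate one recording run for one sample at one voltage.

    Deterministic: identical ``(config, voltage, run_id, seed, analyte)``
    yield a bit-identical trace.
    """
    if seed is None:
        seed = config.seed
    if analyte is None:
        analyte = config.sample_labels[0]
    if analyte not in config.samples:
        raise ValueError(f"unknown sample label {analyte!r}; have {config.sample_labels}")
    voltage = int(voltage)
    if voltage == 0:
        raise ValueError("zero applied voltage is invalid")

    rng = _trace_rng(seed, voltage, run_id, analyte)
    rate = config.sampling_rate
    n = int(round(config.duration_s * rate))

    if config.class_offsets is not None and analyte in config.class_offsets:
        offset = float(config.class_offsets[analyte])
    else:
        offset = float(rng.normal(0.0, config.run_offset_sigma))

    baseline0 = config.pore_conductance * voltage  # nS * mV = pA, signed
    # run-level acquisition state: noise RMS and drift rate fluctuate run to run
    run_noise = config.noise_rms * float(
        np.exp(rng.normal(0.0, config.noise_rms_jitter))
    ) if config.noise_rms > 0 else 0.0
    run_drift = config.drift_rate * float(1.0 + rng.normal(0.0, config.drift_rate_jitter)) \
        if config.drift_rate != 0 else 0.0
    # traces are float32: ~1e-4 relative resolution, far below the noise floor
    t = np.arange(n, dtype=np.float32) / np.float32(rate)
    trace = np.float32(baseline0 + offset) + np.float32(run_drift) * t
    if run_noise > 0:
        trace += rng.standard_normal(n, dtype=np.float32) * np.float32(run_noise)

    spans = _place_events(rng, config, voltage, analyte, n)
    truth: list[tuple[int, int, str]] = []
    for s, e, k in spans:
        mol = config.molecules[k]
        f_mean = mol.blockage_mean_at(voltage)
        f = float(np.clip(rng.normal(f_mean, mol.blockage_frac_sd), 0.01, 0.99))
        local_base = baseline0 + offset + run_drift * (s / rate)
        depth = f * abs(local_base)
        length = e - s
        tau_samples = max(mol.edge_tau_us * 1e-6 * rate, 1e-9)
        idx = np.arange(length, dtype=np.float64)
        profile = (1.0 - np.exp(-(idx + 1.0) / tau_samples)) * (
            1.0 - np.exp(-(length - idx) / tau_samples)
        )
        trace[s:e] -= depth * profile  # negative-going blockade on the signed trace
        truth.append((s, e, mol.name))

    return TraceRecording(
        samples=trace,
        sampling_rate=rate,
        voltage=voltage,
        run_id=run_id,
        analyte_label=analyte,
        truth_events=truth,
        baseline_offset_true=offset,
        seed=seed,
    )


SCENARIO_NAMES = (
    "two_marker",
    "aptamer_shift",
    "baseline_overfit_demo",
    "equimolar_mixture",
    "serum_shift",
)


def make_scenario(name: str, **overrides) -> SimulationConfig:
    """Return a fully populated :class:`SimulationConfig` for a named scenario.

    ``two_marker``
        The default two-biomarker pair: equal capture rates at -50 mV,
        a two-fold rate advantage for the first class at -300 mV, distinct
        dwell/blockage distributions.
    ``aptamer_shift``
        Second class shares the first class's capture model but its mean
        fractional blockage drifts with voltage (voltage-sensitive complex),
        degrading cross-voltage generalization.
    ``baseline_overfit_demo``
        Two classes with identical event statistics; only the per-class run
        baseline offsets (+40 / -40 pA) differ, so only baseline-dependent
        features can separate them.
    ``equimolar_mixture``
        The two_marker pair plus a 50:50 molar mixture sample.
    ``serum_shift``
        Two heterogeneous samples ("native" vs "centrifuged") built from
        event sub-populations; centrifugation down-weights the long-dwell,
        shallow-blockage sub-population (0.4 -> 0.1) and mildly shifts the
        waveform statistics of the remaining groups.

    Keyword overrides are applied to the resulting config
    (e.g. ``duration_s=10`` for quick runs).
    """
    if name == "two_marker":
        cfg = SimulationConfig()
    elif name == "aptamer_shift":
        # the complex's blockage drifts downward with |V| and crosses the free
        # protein's level mid-grid, so rankings learned at one extreme reverse
        # at the other; dwell keeps matched-voltage separation alive
        complex_ = MoleculeModel(
            name="cea_aptamer_complex",
            capture_prefactor_alpha=CEA_LIKE.capture_prefactor_alpha,
            capture_barrier_vstar=CEA_LIKE.capture_barrier_vstar,
            blockage_frac_mean=0.216,
            blockage_frac_sd=0.03,
            dwell_median_ref_ms=0.8,
            dwell_log_sd=0.45,
            blockage_voltage_slope=-0.11,
        )
        cfg = SimulationConfig(molecules=(CEA_LIKE, complex_))
    elif name == "baseline_overfit_demo":
        a = replace(CEA_LIKE, name="class_pos")
        b = replace(CEA_LIKE, name="class_neg")
        cfg = SimulationConfig(
            molecules=(a, b),
            class_offsets={"class_pos": 40.0, "class_neg": -40.0},
        )
    elif name == "equimolar_mixture":
        cfg = SimulationConfig(
            samples={
                CEA_LIKE.name: (1.0, 0.0),
                CA153_LIKE.name: (0.0, 1.0),
                "mixture": (0.5, 0.5),
            }
        )
    elif name == "serum_shift":
        long_shallow = MoleculeModel(
            name="long_shallow",
            capture_prefactor_alpha=0.03,
            capture_barrier_vstar=40.0,
            blockage_frac_mean=0.12,
            blockage_frac_sd=0.03,
            dwell_median_ref_ms=3.0,
            dwell_log_sd=0.5,
        )
        mid_a = MoleculeModel(
            name="mid_a",
            capture_prefactor_alpha=0.03,
            capture_barrier_vstar=40.0,
            blockage_frac_mean=0.20,
            blockage_frac_sd=0.035,
            dwell_median_ref_ms=0.6,
            dwell_log_sd=0.45,
        )
        mid_b = MoleculeModel(
            name="mid_b",
            capture_prefactor_alpha=0.03,
            capture_barrier_vstar=40.0,
            blockage_frac_mean=0.30,
            blockage_frac_sd=0.035,
            dwell_median_ref_ms=1.0,
            dwell_log_sd=0.45,
        )
        # centrifugation also shifts the surviving populations' waveforms
        mid_a_c = replace(mid_a, name="mid_a_centrifuged", blockage_frac_mean=0.25, dwell_median_ref_ms=0.4)
        mid_b_c = replace(mid_b, name="mid_b_centrifuged", blockage_frac_mean=0.35, dwell_median_ref_ms=0.6)
        cfg = SimulationConfig(
            molecules=(long_shallow, mid_a, mid_b, mid_a_c, mid_b_c),
            samples={
                "native": (0.4, 0.35, 0.25, 0.0, 0.0),
                "centrifuged": (0.1, 0.0, 0.0, 0.525, 0.375),
            },
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; options: {', '.join(SCENARIO_NAMES)}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# Trace file I/O: two-column text plus a JSON metadata sidecar.

def write_trace(trace: TraceRecording, path: str | Path) -> Path:
    """Write ``time_s<TAB>current_pA`` text plus ``<name>.meta.json`` sidecar."""
    path = Path(path)
    t = np.arange(len(trace.samples)) / trace.sampling_rate
    with open(path, "w") as fh:
        fh.write("time_s\tcurrent_pA\n")
        np.savetxt(fh, np.column_stack([t, trace.samples]), fmt="%.9g", delimiter="\t")
    meta = {
        "voltage_mv": trace.voltage,
        "sampling_rate_hz": trace.sampling_rate,
        "run_id": trace.run_id,
        "analyte_label": trace.analyte_label,
        "seed": trace.seed,
        "baseline_offset_true": trace.baseline_offset_true,
        "truth_events": [[int(s), int(e), c] for s, e, c in trace.truth_events],
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> TraceRecording:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    with open(path) as fh:
        fh.readline()  # header
        if not fh.readline().strip():
            raise ValueError(f"trace file {path} contains no samples")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    t, cur = data[:, 0], data[:, 1]
    if len(t) > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = 1.0
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TraceRecording(
        samples=cur,
        sampling_rate=float(meta.get("sampling_rate_hz", rate)),
        voltage=int(meta.get("voltage_mv", -1)),
        run_id=str(meta.get("run_id", path.stem)),
        analyte_label=str(meta.get("analyte_label", "unknown")),
        truth_events=[(int(s), int(e), str(c)) for s, e, c in meta.get("truth_events", [])],
        baseline_offset_true=float(meta.get("baseline_offset_true", 0.0)),
        seed=meta.get("seed"),
    )
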