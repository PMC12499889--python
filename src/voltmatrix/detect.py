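"""Translocation-event detection on ionic current traces.

A two-threshold (Schmitt-trigger) detector over a moving-median baseline.
Blockades are negative-going excursions from the signed baseline: the
deviation analysed is ``baseline - current`` and an event is entered when
it exceeds ``threshold_k`` times the baseline RMS, extended until it falls
below ``exit_k`` times the RMS.

The baseline is estimated in two passes: a strided moving median over the
raw trace, then a second median with provisionally detected event spans
masked out, so deep or frequent events do not bias the local open-pore
level.  The RMS is computed on out-of-event residuals and the slow drift
slope by least squares on the baseline series.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .sim import TraceRecording

__all__ = [
    "DetectionParams",
    "EventRecord",
    "MatchResult",
    "estimate_baseline",
    "detect_events",
    "match_to_truth",
    "events_to_frame",
    "write_events_tsv",
    "read_events_tsv",
    "EVENT_FIELDS",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the Schmitt-trigger detector.

    ``baseline_window_ms`` sets the moving-median window; ``threshold_k``
    and ``exit_k`` are entry/exit thresholds in multiples of the baseline
    RMS; events shorter than ``min_dwell_samples`` are discarded and events
    closer than ``refractory_samples`` are merged.
    """

    baseline_window_ms: float = 50.0
    threshold_k: float = 5.0
    exit_k: float = 2.0
    min_dwell_samples: int = 5
    refractory_samples: int = 5

    def __post_init__(self) -> None:
        if not self.exit_k < self.threshold_k:
            raise ValueError("exit_k must be < threshold_k")
        if self.min_dwell_samples < 1:
            raise ValueError("min_dwell_samples must be >= 1")


# Column order of the event table on disk.
EVENT_FIELDS = (
    "start_index",
    "end_index",
    "dwell_ms",
    "delta_i_pa",
    "delta_i_max_pa",
    "i0_local_pa",
    "frac_blockage",
    "area_pa_ms",
    "skewness",
    "kurtosis",
    "fwhm_ms",
    "intra_event_sd_pa",
    "baseline_rms_pa",
    "drift_slope_pa_s",
    "voltage",
    "run_id",
)


@dataclass
class EventRecord:
    """One translocation event (0-based, half-open sample interval)."""

    start_index: int
    end_index: int
    dwell_ms: float
    delta_i_pa: float  # mean depth magnitude over the event core
    delta_i_max_pa: float
    i0_local_pa: float  # signed local open-pore baseline
    frac_blockage: float
    area_pa_ms: float  # equivalent charge deficit
    skewness: float
    kurtosis: float
    fwhm_ms: float
    intra_event_sd_pa: float
    baseline_rms_pa: float
    drift_slope_pa_s: float
    voltage: int
    run_id: str


class MatchResult(NamedTuple):
    precision: float
    recall: float
    n_matched: int
    precision_defined: bool


def _window_medians(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Medians of non-overlapping windows (finite input), and window centers.

    Partition-based (O(n) per window) rather than a full sort.
    """
    n = len(x)
    n_win = max(1, n // window)
    arr = x[: n_win * window].reshape(n_win, window)
    k = window // 2
    if window % 2:
        med = np.partition(arr, k, axis=1)[:, k]
    else:
        part = np.partition(arr, (k - 1, k), axis=1)
        med = 0.5 * (part[:, k - 1] + part[:, k])
    centers = (np.arange(n_win) + 0.5) * window
    return med.astype(np.float64), centers


def _interp_uniform(med: np.ndarray, window: int, n: int) -> np.ndarray:
    """Linear interpolation of window medians (uniform centers) to sample grid."""
    if len(med) == 1:
        return np.full(n, med[0])
    pos = (np.arange(n, dtype=np.float64) - 0.5 * window) / window  # in window units
    idx = np.clip(np.floor(pos).astype(np.int64), 0, len(med) - 2)
    frac = np.clip(pos - idx, 0.0, 1.0)
    return med[idx] * (1.0 - frac) + med[idx + 1] * frac


def _strided_median(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strided moving-median baseline, linearly interpolated to full length."""
    med, centers = _window_medians(x, window)
    return _interp_uniform(med, window, len(x)), centers, med


def estimate_baseline(
    trace: TraceRecording, params: DetectionParams = DetectionParams()
) -> tuple[np.ndarray, float, float]:
    """Estimate (baseline series [pA], residual RMS [pA], drift slope [pA/s]).

    Two-pass: provisional event spans (deviation > 3 x robust RMS toward
    blockade) are masked before the final moving median.
    """
    x = np.asarray(trace.samples)
    if x.dtype not in (np.float32, np.float64):
        x = x.astype(np.float64)
    rate = trace.sampling_rate
    window = max(3, int(round(params.baseline_window_ms * 1e-3 * rate)))
    if len(x) <= window:
        raise ValueError("trace shorter than the baseline window")

    b1, _, _ = _strided_median(x, window)
    resid = x - b1
    sub = resid[:: max(1, len(resid) // 500_000)]  # MAD needs no more precision
    mad = np.median(np.abs(sub - np.median(sub)))
    robust_rms = 1.4826 * float(mad)
    # floor avoids zero thresholds on noise-free synthetic traces
    floor = 1e-6 * max(1.0, float(np.median(np.abs(sub + b1[:: max(1, len(resid) // 500_000)]))))
    robust_rms = max(robust_rms, floor)

    mask = resid < -3.0 * robust_rms  # blockades are negative-going
    if mask.any():
        pad = max(1, window // 50)
        mask = ndimage.maximum_filter1d(mask.astype(np.uint8), size=2 * pad + 1) > 0

    # replace provisional event samples by the pass-1 baseline so the second
    # median sees event-free statistics (cheap surrogate for exclusion)
    xm = np.where(mask, b1.astype(x.dtype), x)
    b2, centers, med = _strided_median(xm, window)
    step = max(1, len(x) // 500_000)
    resid2 = (x[::step] - b2[::step])[~mask[::step]]
    rms = float(np.std(resid2)) if resid2.size else 0.0
    rms = max(rms, floor)
    slope = float(np.polyfit(centers / rate, med, 1)[0]) if len(med) > 1 else 0.0
    return b2, rms, slope


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_events(
    trace: TraceRecording, params: DetectionParams = DetectionParams()
) -> list[EventRecord]:
    """Detect translocation events; returns records sorted by start index."""
    x = np.asarray(trace.samples)
    baseline, rms, slope = estimate_baseline(trace, params)
    dev = baseline - x  # positive toward blockade
    rate = trace.sampling_rate

    lo = dev > params.exit_k * rms
    if not lo.any():
        return []
    hi_cum = np.concatenate([[0], np.cumsum(dev > params.threshold_k * rms, dtype=np.int32)])
    runs = [(s, e) for s, e in _runs_from_mask(lo) if hi_cum[e] - hi_cum[s] > 0]
    if not runs:
        return []

    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < params.refractory_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[EventRecord] = []
    for s, e in merged:
        if e - s < params.min_dwell_samples:
            continue
        seg = dev[s:e].astype(np.float64)
        depth_mean = float(np.mean(seg))
        depth_max = float(np.max(seg))
        i0 = float(np.mean(baseline[s:e]))
        dwell_ms = (e - s) / rate * 1e3
        area = float(np.sum(seg)) / rate * 1e3  # pA * ms
        fwhm = int(np.count_nonzero(seg > depth_max / 2.0)) / rate * 1e3
        d = seg - depth_mean
        m2 = float(np.mean(d * d))
        if e - s >= 3 and m2 > 0:
            skw = float(np.mean(d**3)) / m2**1.5
            krt = float(np.mean(d**4)) / m2**2 - 3.0  # Fisher convention
        else:
            skw, krt = 0.0, 0.0
        events.append(
            EventRecord(
                start_index=int(s),
                end_index=int(e),
                dwell_ms=dwell_ms,
                delta_i_pa=depth_mean,
                delta_i_max_pa=depth_max,
                i0_local_pa=i0,
                frac_blockage=depth_mean / abs(i0) if i0 != 0 else np.nan,
                area_pa_ms=area,
                skewness=skw,
                kurtosis=krt,
                fwhm_ms=fwhm,
                intra_event_sd_pa=float(np.std(seg)),
                baseline_rms_pa=rms,
                drift_slope_pa_s=slope,
                voltage=trace.voltage,
                run_id=trace.run_id,
            )
        )
    return events


def match_to_truth(
    events: Sequence[EventRecord] | Sequence[tuple[int, int]],
    truth: Sequence[tuple[int, int, str]] | Sequence[tuple[int, int]],
) -> MatchResult:
    """Greedy one-to-one interval matching at >= 50% reciprocal overlap.

    Returns precision (matched / detected), recall (matched / truth).  With
    zero detections precision is undefined; it is reported as 0 with
    ``precision_defined=False``.
    """
    det = [(ev.start_index, ev.end_index) if isinstance(ev, EventRecord) else (ev[0], ev[1]) for ev in events]
    tru = [(t[0], t[1]) for t in truth]
    if not det:
        return MatchResult(0.0, 0.0 if tru else 1.0, 0, precision_defined=False)
    if not tru:
        return MatchResult(0.0, 1.0, 0, precision_defined=True)

    pairs = []
    for i, (ds, de) in enumerate(det):
        for j, (ts, te) in enumerate(tru):
            inter = min(de, te) - max(ds, ts)
            if inter <= 0:
                continue
            if inter >= 0.5 * (de - ds) and inter >= 0.5 * (te - ts):
                pairs.append((inter, i, j))
    pairs.sort(reverse=True)
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return MatchResult(matched / len(det), matched / len(tru), matched, True)


# ---------------------------------------------------------------------------
# Event table I/O (TSV, one header row, EVENT_FIELDS column order).

def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(ev) for ev in events], columns=list(EVENT_FIELDS))
    return df


def write_events_tsv(events: Sequence[EventRecord] | pd.DataFrame, path: str | Path) -> Path:
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} is missing columns: {missing}")
    return df
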