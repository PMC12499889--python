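"""End-to-end orchestration: scenario -> traces -> events -> matrices / mixtures.

These functions wire the simulator, detector, feature extraction and
classification stages together with a single seed, and back the command
line interface.  All intermediate products (event tables, feature tables,
matrices, mixture reports) use the plain-text formats of their modules.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import DetectionParams, detect_events, events_to_frame
from .features import FeatureSetSpec, build_feature_table, get_feature_set
from .matrix import LabeledDataset, VoltageMatrixResult, build_matrix, make_dataset, train_classifier
from .mixture import MixtureEstimate, estimate_capture_rate, estimate_mixture
from .sim import MoleculeModel, SimulationConfig, make_scenario, simulate_trace

__all__ = [
    "collect_events",
    "build_datasets",
    "run_matrix",
    "run_mixture",
    "load_pipeline_config",
    "config_to_dict",
    "provenance",
]


def iter_runs(
    config: SimulationConfig,
    analyte: str,
    voltages: Sequence[int] | None = None,
    seed: int | None = None,
):
    """Yield one simulated trace per (voltage, run) for one sample."""
    voltages = config.voltage_grid if voltages is None else voltages
    seed = config.seed if seed is None else seed
    for v in voltages:
        for r in range(config.runs_per_condition):
            run_id = f"{analyte}_v{abs(int(v))}_r{r}"
            yield simulate_trace(config, v, run_id, seed=seed, analyte=analyte)


def collect_events(
    config: SimulationConfig,
    detection: DetectionParams = DetectionParams(),
    analytes: Sequence[str] | None = None,
    voltages: Sequence[int] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], float]]:
    """Simulate and detect all runs; return (event table, durations).

    The event table gains an ``analyte`` column; ``durations`` maps
    (analyte, voltage) to total recorded seconds (for capture rates).
    """
    analytes = config.sample_labels if analytes is None else analytes
    voltages = config.voltage_grid if voltages is None else [int(v) for v in voltages]
    frames = []
    durations: dict[tuple[str, int], float] = {}
    for analyte in analytes:
        for trace in iter_runs(config, analyte, voltages, seed):
            evs = detect_events(trace, detection)
            durations[(analyte, trace.voltage)] = (
                durations.get((analyte, trace.voltage), 0.0) + trace.duration_s
            )
            if evs:
                df = events_to_frame(evs)
                df["analyte"] = analyte
                frames.append(df)
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame()
    return events, durations


def build_datasets(
    events: pd.DataFrame,
    spec: FeatureSetSpec | str,
    labels: Sequence[str],
    voltages: Sequence[int] | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> dict[int, LabeledDataset]:
    """Per-voltage labeled datasets from a pooled event table.

    ``labels`` selects the two analyte labels to classify (first = positive
    class by convention).
    """
    if isinstance(spec, str):
        spec = get_feature_set(spec)
    sub = events[events["analyte"].isin(labels)]
    if voltages is None:
        voltages = sorted(sub["voltage"].unique(), key=abs)
    datasets = {}
    for v in voltages:
        ev_v = sub[sub["voltage"] == v]
        table = build_feature_table(ev_v, spec, labels=ev_v["analyte"].to_numpy(), voltage=int(v))
        datasets[int(v)] = make_dataset(table, train_fraction=train_fraction, seed=seed)
    return datasets


def run_matrix(
    config: SimulationConfig,
    detection: DetectionParams = DetectionParams(),
    feature_set: str = "A",
    algo: str = "random_forest",
    labels: Sequence[str] | None = None,
    seed: int | None = None,
    train_fraction: float = 0.7,
    min_per_class: int = 20,
    events: pd.DataFrame | None = None,
) -> VoltageMatrixResult:
    """Scenario config -> voltage matrix (positive class = first label)."""
    seed = config.seed if seed is None else seed
    if labels is None:
        labels = list(config.sample_labels[:2])
    if events is None:
        events, _ = collect_events(config, detection, analytes=labels, seed=seed)
    datasets = build_datasets(events, feature_set, labels, train_fraction=train_fraction, seed=seed)
    return build_matrix(
        datasets,
        algo=algo,
        feature_set=feature_set if isinstance(feature_set, str) else feature_set.name,
        positive_label=labels[0],
        seed=seed,
        min_per_class=min_per_class,
    )


def run_mixture(
    config: SimulationConfig,
    voltage: int,
    detection: DetectionParams = DetectionParams(),
    feature_set: str = "A",
    algo: str = "random_forest",
    mixture_label: str = "mixture",
    reference_labels: Sequence[str] | None = None,
    seed: int | None = None,
    train_fraction: float = 0.7,
    boundary_rule: str = "intersection",
    ratio_rule: str = "exceedance",
    min_per_class: int = 20,
) -> MixtureEstimate:
    """Full mixture chain at one voltage.

    Pure reference samples are simulated to (a) train the classifier and
    (b) measure per-class capture rates; the mixture sample is then scored
    and the event ratio converted into a molecular fraction via
    inverse-capture-rate weighting.  Positive class = first reference label.
    """
    seed = config.seed if seed is None else seed
    if reference_labels is None:
        reference_labels = [s for s in config.sample_labels if s != mixture_label][:2]
    pos, neg = reference_labels
    spec = get_feature_set(feature_set) if isinstance(feature_set, str) else feature_set

    ref_events, ref_dur = collect_events(
        config, detection, analytes=[pos, neg], voltages=[voltage], seed=seed
    )
    rate_pos = estimate_capture_rate(
        int((ref_events["analyte"] == pos).sum()), ref_dur[(pos, voltage)]
    ).rate
    rate_neg = estimate_capture_rate(
        int((ref_events["analyte"] == neg).sum()), ref_dur[(neg, voltage)]
    ).rate

    table = build_feature_table(
        ref_events, spec, labels=ref_events["analyte"].to_numpy(), voltage=voltage
    )
    ds = make_dataset(table, train_fraction=train_fraction, seed=seed)
    model = train_classifier(
        ds.subset(ds.train_idx), algo=algo, positive_label=pos, seed=seed, min_per_class=min_per_class
    )

    mix_events, _ = collect_events(
        config, detection, analytes=[mixture_label], voltages=[voltage], seed=seed
    )
    mix_table = build_feature_table(mix_events, spec, voltage=voltage)
    scores = model.score(mix_table)
    return estimate_mixture(
        scores, rate_pos, rate_neg, boundary_rule=boundary_rule, ratio_rule=ratio_rule
    )


# ---------------------------------------------------------------------------
# Configuration files (YAML mirroring the dataclass fields) and provenance.

def config_to_dict(
    config: SimulationConfig, detection: DetectionParams | None = None, **extra
) -> dict:
    d = {
        "simulation": {
            **{k: v for k, v in asdict(config).items() if k not in ("molecules",)},
            "molecules": [asdict(m) for m in config.molecules],
        },
    }
    d["simulation"]["voltage_grid"] = list(config.voltage_grid)
    d["simulation"]["samples"] = {k: list(v) for k, v in config.samples.items()}
    if config.class_offsets is not None:
        d["simulation"]["class_offsets"] = dict(config.class_offsets)
    if detection is not None:
        d["detection"] = asdict(detection)
    d.update(extra)
    return d


def load_pipeline_config(path: str | Path) -> dict:
    """Load a YAML pipeline config into instantiated objects.

    Returns a dict with keys ``simulation`` (SimulationConfig), ``detection``
    (DetectionParams) and any remaining top-level sections verbatim
    (``feature_set``, ``algo``, ``seed``, ``mixture`` ...).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(raw)
    sim_raw = dict(raw.get("simulation", {}))
    if "scenario" in sim_raw:
        name = sim_raw.pop("scenario")
        molecules = sim_raw.pop("molecules", None)
        if molecules is not None:
            sim_raw["molecules"] = tuple(MoleculeModel(**m) for m in molecules)
        if "samples" in sim_raw and sim_raw["samples"] is not None:
            sim_raw["samples"] = {k: tuple(v) for k, v in sim_raw["samples"].items()}
        out["simulation"] = make_scenario(name, **sim_raw)
    else:
        if "molecules" in sim_raw:
            sim_raw["molecules"] = tuple(MoleculeModel(**m) for m in sim_raw["molecules"])
        if "samples" in sim_raw and sim_raw["samples"] is not None:
            sim_raw["samples"] = {k: tuple(v) for k, v in sim_raw["samples"].items()}
        out["simulation"] = SimulationConfig(**sim_raw)
    det_raw = raw.get("detection", {})
    out["detection"] = DetectionParams(**det_raw)
    return out


def provenance(config: SimulationConfig, detection: DetectionParams, seed: int, **extra) -> dict:
    """Provenance record sufficient to regenerate every output exactly."""
    import sklearn

    cfg = config_to_dict(config, detection)
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "voltmatrix": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        **extra,
    }
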