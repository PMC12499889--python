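"""Feature-set definitions and per-event feature tables.

Two named feature sets drive the cross-voltage analysis:

* **Set A** — event-intrinsic features only: ratios and shape statistics
  that carry no information about the absolute current level of a given
  pore/run (dwell, fractional blockage, normalized area, waveform shape).
* **Set B** — set A plus the baseline-dependent features (absolute blockade
  amplitude, open-pore current, baseline RMS noise, drift slope).  These
  let a classifier fingerprint the acquisition condition instead of the
  molecule, which shows up as diagonal-only inflation in a voltage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import EventRecord, events_to_frame

__all__ = [
    "FeatureSetSpec",
    "FeatureTable",
    "BASELINE_DEPENDENT",
    "default_feature_sets",
    "build_feature_table",
    "standardize",
    "write_feature_tsv",
    "read_feature_tsv",
]

#: Features that encode the absolute current scale of a run (excluded from set A).
BASELINE_DEPENDENT = frozenset(
    {"delta_i_pa", "delta_i_max_pa", "i0_local_pa", "baseline_rms_pa", "drift_slope_pa_s"}
)

# Derived (ratio) features computed from raw EventRecord columns.
_DERIVED: Mapping[str, Callable[[pd.DataFrame], pd.Series]] = {
    "area_norm": lambda df: df["area_pa_ms"] / df["i0_local_pa"].abs(),
    "fwhm_ratio": lambda df: df["fwhm_ms"] / df["dwell_ms"],
    "rel_intra_sd": lambda df: df["intra_event_sd_pa"] / df["delta_i_pa"],
}

_SET_A = (
    "dwell_ms",
    "frac_blockage",
    "area_norm",
    "skewness",
    "kurtosis",
    "fwhm_ratio",
    "rel_intra_sd",
)
_SET_B = _SET_A + (
    "delta_i_pa",
    "delta_i_max_pa",
    "i0_local_pa",
    "baseline_rms_pa",
    "drift_slope_pa_s",
)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named, ordered list of feature columns."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate feature names in spec")


def default_feature_sets() -> tuple[FeatureSetSpec, FeatureSetSpec]:
    """The two standard specs (A: event-intrinsic; B: A + baseline-dependent)."""
    return FeatureSetSpec("A", _SET_A), FeatureSetSpec("B", _SET_B)


def get_feature_set(name: str) -> FeatureSetSpec:
    a, b = default_feature_sets()
    try:
        return {"A": a, "B": b}[name.upper()]
    except KeyError:
        raise ValueError(f"unknown feature set {name!r}; options: A, B") from None


@dataclass
class FeatureTable:
    """Per-event feature matrix under one spec, with optional labels.

    ``mean``/``sd`` hold standardization statistics; they are only ever
    learned from a designated training table (see :func:`standardize`).
    ``constant_columns`` flags zero-variance columns passed through
    unscaled.
    """

    data: pd.DataFrame
    spec: FeatureSetSpec
    labels: np.ndarray | None = None
    voltage: int | None = None
    mean: pd.Series | None = None
    sd: pd.Series | None = None
    constant_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.spec.members):
            raise ValueError("feature table columns must match spec member order")
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels length must match number of events")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def fit_standardization(self) -> None:
        """Learn per-column mean/sd from this table (training data only)."""
        self.mean = self.data.mean()
        sd = self.data.std(ddof=0)
        # float-rounding "constants" count as zero-variance too
        tol = 1e-12 * self.mean.abs().clip(lower=1.0)
        const = tuple(sd.index[sd <= tol])
        sd[list(const)] = 1.0
        self.sd = sd
        self.constant_columns = const


def build_feature_table(
    events: Sequence[EventRecord] | pd.DataFrame,
    spec: FeatureSetSpec,
    labels: Sequence | None = None,
    voltage: int | None = None,
) -> FeatureTable:
    """Build one row per event in the spec's column order.

    Raises on an empty event list.  ``labels`` are per-event class labels
    (omit for mixture samples).  ``voltage`` defaults to the single voltage
    present in the events.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if len(df) == 0:
        raise ValueError("cannot build a feature table from zero events")
    cols = {}
    for name in spec.members:
        if name in df.columns:
            cols[name] = df[name].astype(float)
        elif name in _DERIVED:
            cols[name] = _DERIVED[name](df).astype(float)
        else:
            raise ValueError(f"feature {name!r} is neither an event field nor a derived feature")
    out = pd.DataFrame(cols, columns=list(spec.members)).reset_index(drop=True)
    if voltage is None and "voltage" in df.columns and df["voltage"].nunique() == 1:
        voltage = int(df["voltage"].iloc[0])
    lab = None if labels is None else np.asarray(labels)
    return FeatureTable(out, spec, labels=lab, voltage=voltage)


def standardize(table: FeatureTable, reference: FeatureTable | None = None) -> FeatureTable:
    """Z-score ``table`` using statistics learned from ``reference``.

    ``reference`` defaults to the table itself.  Zero-variance reference
    columns pass through unscaled and are flagged.  Raises on schema
    mismatch.
    """
    if reference is None:
        reference = table
    if tuple(reference.spec.members) != tuple(table.spec.members):
        raise ValueError("reference and table feature schemas differ")
    if reference.mean is None or reference.sd is None:
        reference.fit_standardization()
    z = (table.data - reference.mean) / reference.sd
    return FeatureTable(
        z,
        table.spec,
        labels=table.labels,
        voltage=table.voltage,
        mean=reference.mean,
        sd=reference.sd,
        constant_columns=reference.constant_columns,
    )


def write_feature_tsv(table: FeatureTable, path: str | Path) -> Path:
    """TSV with a ``#featureset=`` comment line; label/voltage as trailing columns."""
    path = Path(path)
    df = table.data.copy()
    if table.labels is not None:
        df["label"] = table.labels
    if table.voltage is not None:
        df["voltage"] = table.voltage
    with open(path, "w") as fh:
        fh.write(f"#featureset={table.spec.name}\t" + "members=" + ",".join(table.spec.members) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_feature_tsv(path: str | Path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#featureset="):
            raise ValueError(f"{path} is not a feature table (missing #featureset header)")
        fields = dict(part.split("=", 1) for part in header.lstrip("#").split("\t"))
        spec = FeatureSetSpec(fields["featureset"], tuple(fields["members"].split(",")))
        df = pd.read_csv(fh, sep="\t")
    labels = df.pop("label").to_numpy() if "label" in df.columns else None
    voltage = None
    if "voltage" in df.columns:
        v = df.pop("voltage")
        if v.nunique() == 1:
            voltage = int(v.iloc[0])
    return FeatureTable(df[list(spec.members)], spec, labels=labels, voltage=voltage)
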