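"""Accelerometer recordings, the acceleration sum vector, and windowing.

All accelerations are expressed in units of g (1 g = 9.81 m/s^2); a sensor at
rest reads a sum-vector magnitude of ~1 g.  A recording is a tri-axial series
sampled at a fixed rate (100 Hz by default).  The derived quantity everything
downstream works on is the acceleration sum vector (SV): the per-sample
Euclidean magnitude of the three axes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SumVectorSeries",
    "Window",
    "compute_sv",
    "is_active_period",
    "extract_window",
    "read_recording",
    "write_recording",
    "read_manifest",
    "InvalidInputError",
    "FormatError",
]

CSV_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")
#: relative jitter tolerance when inferring the sampling rate from timestamps
JITTER_TOL = 0.01


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


class FormatError(InvalidInputError):
    """Raised when an on-disk recording violates the CSV contract."""


@dataclass
class Recording:
    """A tri-axial acceleration time series.

    Parameters
    ----------
    id : str
        Identifier of the recording (file stem by convention).
    fs : int
        Sampling frequency in Hz (positive).
    samples : (n, 3) ndarray
        Per-sample (ax, ay, az) accelerations in g.
    range_g : float, optional
        Sensor saturation magnitude in g (e.g. 2 or 6).  When present every
        axis value must satisfy ``|a| <= range_g``.
    label : {"fall", "adl", "unknown"}
    """

    id: str
    fs: int
    samples: np.ndarray
    range_g: Optional[float] = None
    label: Literal["fall", "adl", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidInputError("samples must be an (n, 3) array")
        if len(self.samples) < 1:
            raise InvalidInputError("recording must contain at least one sample")
        if not (self.fs > 0):
            raise InvalidInputError(f"fs must be positive, got {self.fs}")
        if self.range_g is not None:
            if np.abs(self.samples).max() > self.range_g + 1e-12:
                raise InvalidInputError(
                    f"axis values exceed the stated sensor range ±{self.range_g} g"
                )
        if self.label not in ("fall", "adl", "unknown"):
            raise InvalidInputError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class SumVectorSeries:
    """Per-sample root-sum-of-squares acceleration magnitude, in g."""

    fs: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise InvalidInputError("SV series must be a non-empty 1-d array")
        if np.any(self.values < 0):
            raise InvalidInputError("SV values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Window:
    """A peak-centered slice of an SV series.

    The window is half-open ``[center - L/2, center + L/2)`` with
    ``L = round(duration_s * fs)``, so the nominal center sits at offset
    ``L // 2``.
    """

    fs: int
    values: np.ndarray
    center_index: int
    duration_s: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = int(round(self.duration_s * self.fs))
        if len(self.values) != expected:
            raise InvalidInputError(
                f"window length {len(self.values)} != round(duration*fs) = {expected}"
            )


def compute_sv(rec: Recording) -> SumVectorSeries:
    """Acceleration sum vector: sqrt(ax^2 + ay^2 + az^2) per sample."""
    values = np.sqrt(np.einsum("ij,ij->i", rec.samples, rec.samples))
    return SumVectorSeries(fs=rec.fs, values=values)


def is_active_period(sv: SumVectorSeries, threshold_g: float = 1.01) -> bool:
    """True iff the SV range (max - min) strictly exceeds ``threshold_g``.

    This is the inclusion criterion used to select "active periods" from
    continuous recordings: one-minute segments whose SV excursion exceeds
    1.01 g.
    """
    return float(sv.values.max() - sv.values.min()) > threshold_g


def extract_window(
    sv: SumVectorSeries,
    center_index: int,
    duration_s: float = 2.0,
    edge_policy: Literal["skip", "reflect"] = "skip",
) -> Optional[Window]:
    """Extract the window of ``duration_s`` seconds centered on a sample.

    Returns ``None`` under the default ``skip`` policy when the window would
    overrun either end of the series; under ``reflect`` the missing samples
    are filled by reflection about the edge.
    """
    n = len(sv)
    if not (0 <= center_index < n):
        raise InvalidInputError(
            f"center_index {center_index} out of bounds for length {n}"
        )
    length = int(round(duration_s * sv.fs))
    half = length // 2
    start = center_index - half
    stop = start + length
    if start < 0 or stop > n:
        if edge_policy == "skip":
            return None
        if edge_policy != "reflect":
            raise InvalidInputError(f"unknown edge_policy {edge_policy!r}")
        idx = np.arange(start, stop)
        idx = np.abs(idx)                       # reflect about 0
        idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
        values = sv.values[idx]
    else:
        values = sv.values[start:stop]
    return Window(fs=sv.fs, values=values, center_index=center_index,
                  duration_s=duration_s)


def _infer_fs(time_s: np.ndarray) -> int:
    dt = np.diff(time_s)
    if len(dt) == 0:
        raise FormatError("cannot infer sampling rate from a single sample")
    if np.any(dt <= 0):
        raise FormatError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > JITTER_TOL * med):
        raise FormatError(
            "inconsistent sampling interval (> 1% jitter in time column)"
        )
    fs = 1.0 / med
    return int(round(fs))


def read_recording(
    path: str | Path,
    fs: Optional[int] = None,
    label: Literal["fall", "adl", "unknown"] = "unknown",
    range_g: Optional[float] = None,
) -> Recording:
    """Read a recording from CSV with header ``time_s,ax_g,ay_g,az_g``.

    When ``fs`` is not given it is inferred from the median inter-sample
    interval of the time column (rejecting > 1% jitter).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    if fs is None:
        fs = _infer_fs(df["time_s"].to_numpy(dtype=float))
    samples = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    return Recording(id=path.stem, fs=fs, samples=samples, label=label,
                     range_g=range_g)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to the CSV dialect read by :func:`read_recording`."""
    path = Path(path)
    t = np.arange(len(rec)) / rec.fs
    df = pd.DataFrame(
        {
            "time_s": t,
            "ax_g": rec.samples[:, 0],
            "ay_g": rec.samples[:, 1],
            "az_g": rec.samples[:, 2],
        }
    )
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue())


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns ``id,path,label``.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("id", "path", "label"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    bad = set(df["label"]) - {"fall", "adl"}
    if bad:
        raise FormatError(f"manifest labels must be fall/adl, got {sorted(bad)}")
    df = df.copy()
    df["path"] = [str((path.parent / p)) for p in df["path"]]
    return df


def load_dataset(manifest: str | Path) -> list[Recording]:
    """Load every recording listed in a manifest, carrying labels through."""
    df = read_manifest(manifest)
    recs = []
    for row in df.itertuples(index=False):
        rec = read_recording(row.path, label=row.label)
        rec.id = str(row.id)
        recs.append(rec)
    return recs
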