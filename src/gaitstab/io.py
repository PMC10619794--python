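"""Marker-trajectory I/O and the package-wide coordinate convention.

All kinematic data in this package live in a right-handed lab frame with

* axis 0 — mediolateral (``ml``), positive towards the participant's right,
* axis 1 — anteroposterior (``ap``), positive in the walking direction,
* axis 2 — vertical (``vert``), positive up,

in meters, with time in seconds from the start of the recording. Converters
belong at the I/O boundary only; nothing downstream re-interprets axes.

The normative on-disk format is a plain CSV with a ``time`` column and one
``<marker>_<axis>`` column per marker axis, e.g. ``heel_L_ml``. A C3D reader
is provided as an optional convenience (requires ``ezc3d``); the CSV dialect
is the bit-exact test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Axis suffixes, in storage order (columns of each marker array).
AXES = ("ml", "ap", "vert")

#: Markers every analysis in this package needs.
REQUIRED_MARKERS = ("heel_L", "heel_R", "thorax")

#: Maximum tolerated deviation from uniform sampling, seconds.
UNIFORMITY_TOL = 1e-6


class FormatError(ValueError):
    """Input file does not follow the marker-CSV dialect."""


class SamplingError(ValueError):
    """Time stamps are not uniformly spaced."""


@dataclass
class MarkerTimeSeries:
    """Uniformly sampled 3-D trajectories for a set of named markers.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz; must match the spacing of `time`.
    time : ndarray, shape (n,)
        Sample instants in seconds, strictly increasing, uniform.
    markers : dict[str, ndarray]
        Marker name -> (n, 3) array of (ml, ap, vert) positions in meters.
    metadata : dict[str, str]
        Free-form provenance (subject id, condition, ground-truth event
        times for synthetic data, ...).
    """

    sample_rate: float
    time: np.ndarray
    markers: dict[str, np.ndarray]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-D array with >= 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise SamplingError("time must be strictly increasing")
        dev = float(np.max(np.abs(dt - 1.0 / self.sample_rate)))
        if dev > UNIFORMITY_TOL:
            raise SamplingError(
                f"non-uniform sampling: max deviation {dev:.3e} s exceeds "
                f"{UNIFORMITY_TOL:.0e} s"
            )
        n = self.time.size
        clean = {}
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(
                    f"marker '{name}' has shape {arr.shape}, expected ({n}, 3)"
                )
            clean[name] = arr
        self.markers = clean

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.time[-1] - self.time[0])

    def marker(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise KeyError(f"marker '{name}' not present") from None

    def axis(self, name: str, axis: str) -> np.ndarray:
        """One scalar component, e.g. ``axis("thorax", "ml")``."""
        return self.marker(name)[:, AXES.index(axis)]

    def require(self, names=REQUIRED_MARKERS) -> None:
        missing = [m for m in names if m not in self.markers]
        if missing:
            raise FormatError(f"missing marker {missing[0]}")


def read_marker_csv(path) -> MarkerTimeSeries:
    """Read a marker CSV (``time,heel_L_ml,...,thorax_vert``).

    Unknown columns are ignored for analysis but listed in
    ``metadata["extra_columns"]`` so no information silently disappears.

    Raises
    ------
    FormatError
        If the time column or a required marker column is absent.
    SamplingError
        If the time stamps are not uniform, reporting the max deviation.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError("missing 'time' column")

    marker_cols: dict[str, dict[str, str]] = {}
    extra = []
    for col in df.columns:
        if col == "time":
            continue
        for ax in AXES:
            if col.endswith("_" + ax):
                marker_cols.setdefault(col[: -len(ax) - 1], {})[ax] = col
                break
        else:
            extra.append(col)

    markers = {}
    for name, axmap in marker_cols.items():
        if set(axmap) != set(AXES):
            raise FormatError(
                f"marker '{name}' is missing axis columns "
                f"{sorted(set(AXES) - set(axmap))}"
            )
        markers[name] = np.column_stack([df[axmap[ax]].to_numpy(float) for ax in AXES])

    for req in REQUIRED_MARKERS:
        if req not in markers:
            raise FormatError(f"missing marker {req}")

    time = df["time"].to_numpy(float)
    if time.size < 2:
        raise FormatError("need at least 2 samples")
    dt = np.median(np.diff(time))
    metadata = {}
    if extra:
        metadata["extra_columns"] = ",".join(extra)
    return MarkerTimeSeries(
        sample_rate=1.0 / dt, time=time, markers=markers, metadata=metadata
    )


def write_marker_csv(ts: MarkerTimeSeries, path) -> None:
    """Write a :class:`MarkerTimeSeries` in the normative CSV dialect.

    Floats are written with ``repr`` precision so a read-back round-trip is
    lossless for float64 values.
    """
    cols = {"time": ts.time}
    for name in sorted(ts.markers):
        for i, ax in enumerate(AXES):
            cols[f"{name}_{ax}"] = ts.markers[name][:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_outcomes(table: pd.DataFrame, path) -> None:
    """Write a tidy per-stride or per-block outcome table as CSV.

    Raises ``ValueError`` on an empty table; no file is created in that case.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty outcome table")
    table.to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_marker_c3d(path, name_map: dict[str, str]) -> MarkerTimeSeries:
    """Read marker data from a C3D file (optional; requires ``ezc3d``).

    ``name_map`` maps C3D point labels to package marker names, e.g.
    ``{"LHEE": "heel_L", "RHEE": "heel_R", "T10": "thorax"}``. C3D stores
    millimeters by convention; positions are converted to meters unless the
    file declares units of "m". Axis order in the file is taken as
    (ml, ap, vert); remap upstream if your lab convention differs.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D support requires the optional 'ezc3d' package; "
            "use the CSV format otherwise"
        ) from exc

    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [lbl.strip() for lbl in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    units = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    scale = 1.0 if units and units[0].strip().lower() == "m" else 1e-3
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    n = points.shape[2]
    time = np.arange(n) / rate
    markers = {}
    for src, dst in name_map.items():
        if src not in labels:
            raise FormatError(f"missing marker {dst} (C3D label '{src}')")
        idx = labels.index(src)
        markers[dst] = (points[:3, idx, :].T * scale).astype(float)
    return MarkerTimeSeries(sample_rate=rate, time=time, markers=markers)
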