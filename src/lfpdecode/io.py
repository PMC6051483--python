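"""Domain containers and file I/O for spikes, LFP, kinematics and fitted models.

Conventions
-----------
* Time is always seconds (float64).
* LFP channel order is defined by file header order and preserved everywhere;
  pairwise areal-velocity indices refer to this order.
* Delimited files are comma-separated, "." decimal, UTF-8, one header line.
* The binary container is a single HDF5 file holding named arrays plus scalar
  attributes (see :class:`ModelContainer`).

LFP amplitude units are arbitrary (microvolt-like); every downstream quantity
is scale-covariant and documented as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "LfpRecording",
    "KinematicsTrace",
    "ModelContainer",
    "read_spikes",
    "write_spikes",
    "read_lfp",
    "write_lfp",
    "read_kinematics",
    "write_kinematics",
    "read_model",
    "write_model",
]

_CONTAINER_VERSION = 1
_MODEL_KINDS = ("srsp", "rate_decoder", "rotation")

#: Relative tolerance on successive sample intervals when checking uniformity.
_DT_RTOL = 1e-6


class ValidationError(ValueError):
    """An input object violates a container invariant."""


class ParseError(ValueError):
    """A delimited file could not be parsed."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrainSet:
    """Sorted spike event times for a set of units.

    Parameters
    ----------
    unit_ids
        Unique unit identifiers (order defines the unit axis everywhere).
    spike_times
        One ascending float array per unit, seconds. Units with no spikes
        carry an empty array.
    t_start, t_stop
        Recording span in seconds; all spike times lie within it.
    area_labels
        Optional per-unit cortical-area label (e.g. ``"M1"``, ``"PMv"``).
    """

    unit_ids: list
    spike_times: list
    t_start: float
    t_stop: float
    area_labels: list | None = None

    def __post_init__(self):
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValidationError("unit_ids must be unique")
        if len(self.spike_times) != len(self.unit_ids):
            raise ValidationError("spike_times length must match unit_ids")
        if self.t_stop < self.t_start:
            raise ValidationError("t_stop must be >= t_start")
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        for uid, t in zip(self.unit_ids, self.spike_times):
            if t.size and np.any(np.diff(t) < 0):
                raise ValidationError(f"spike times for unit {uid!r} are not sorted")
            if t.size and (t[0] < self.t_start or t[-1] > self.t_stop):
                raise ValidationError(
                    f"spike times for unit {uid!r} fall outside [t_start, t_stop]"
                )
        if self.area_labels is not None and len(self.area_labels) != len(self.unit_ids):
            raise ValidationError("area_labels length must match unit_ids")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


@dataclass
class LfpRecording:
    """Uniformly sampled multichannel potential recording.

    ``samples`` is time x channel; ``fs`` the sampling rate in Hz. Amplitude
    units are arbitrary and all derived quantities scale with them.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list
    t_start: float = 0.0
    area_labels: list | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (time x channel)")
        if self.samples.shape[0] < 2:
            raise ValidationError("need at least 2 samples")
        if self.samples.shape[1] < 1:
            raise ValidationError("need at least 1 channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel_ids must be unique")
        if len(self.channel_ids) != self.samples.shape[1]:
            raise ValidationError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs

    def copy_with(self, samples: np.ndarray, channel_ids: list | None = None) -> "LfpRecording":
        """New recording with the same clock but different samples."""
        return LfpRecording(
            samples=samples,
            fs=self.fs,
            channel_ids=list(self.channel_ids if channel_ids is None else channel_ids),
            t_start=self.t_start,
            area_labels=None if channel_ids is not None else self.area_labels,
        )


@dataclass
class KinematicsTrace:
    """2-D cursor/kinematics trace on a uniform clock (task units)."""

    times: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] != 2:
            raise ValidationError("position must be time x 2")
        if self.times.shape[0] != self.position.shape[0]:
            raise ValidationError("times and position must have equal length")
        if self.times.size < 2:
            raise ValidationError("need at least 2 samples")
        dt = np.diff(self.times)
        if np.max(np.abs(dt - dt[0])) > _DT_RTOL * abs(dt[0]):
            raise ValidationError("times must be uniformly spaced")

    @property
    def fs(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


@dataclass
class ModelContainer:
    """Generic fitted-model artifact: named arrays + JSON metadata.

    Round-trips through :func:`write_model` / :func:`read_model` bit-exactly
    for metadata and to full floating precision for payload arrays.
    """

    model_kind: str
    metadata: dict = field(default_factory=dict)
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_kind not in _MODEL_KINDS:
            raise ValidationError(
                f"unknown model_kind {self.model_kind!r}; expected one of {_MODEL_KINDS}"
            )
        for name, arr in self.payload.items():
            arr = np.asarray(arr)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"payload array {name!r} contains non-finite values")
            self.payload[name] = arr


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def read_spikes(path, format: str = "delimited") -> SpikeTrainSet:
    """Read spike event times.

    Delimited layout: header ``unit_id,time_s``, one event per row. Units
    appear in order of first occurrence; times must be ascending per unit.
    """
    if format == "container":
        with h5py.File(path, "r") as f:
            unit_ids = [s.decode() for s in f["unit_ids"][()]]
            area = f.attrs.get("area_labels")
            times = [f[f"spikes/{i}"][()] for i in range(len(unit_ids))]
            return SpikeTrainSet(
                unit_ids=unit_ids,
                spike_times=times,
                t_start=float(f.attrs["t_start"]),
                t_stop=float(f.attrs["t_stop"]),
                area_labels=list(json.loads(area)) if area is not None else None,
            )
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")

    units: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["unit_id", "time_s"]:
            raise ParseError(f"{path}: expected header 'unit_id,time_s', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            uid, t_s = parts
            try:
                t = float(t_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: invalid time {t_s!r}") from None
            units.setdefault(uid, []).append(t)
    unit_ids = list(units)
    times = [np.asarray(units[u]) for u in unit_ids]
    for uid, t in zip(unit_ids, times):
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError(f"spike times for unit {uid!r} are not sorted")
    t_stop = max((float(t[-1]) for t in times if t.size), default=0.0)
    t_start = min(0.0, min((float(t[0]) for t in times if t.size), default=0.0))
    return SpikeTrainSet(unit_ids=unit_ids, spike_times=times, t_start=t_start, t_stop=t_stop)


def write_spikes(spikes: SpikeTrainSet, path, format: str = "delimited") -> None:
    if format == "container":
        with h5py.File(path, "w") as f:
            f.attrs["t_start"] = spikes.t_start
            f.attrs["t_stop"] = spikes.t_stop
            if spikes.area_labels is not None:
                f.attrs["area_labels"] = json.dumps(list(spikes.area_labels))
            f.create_dataset(
                "unit_ids",
                data=np.array([str(u) for u in spikes.unit_ids], dtype="S"),
                track_times=False,
            )
            for i, t in enumerate(spikes.spike_times):
                f.create_dataset(f"spikes/{i}", data=np.asarray(t), track_times=False)
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("unit_id,time_s\n")
        for uid, t in zip(spikes.unit_ids, spikes.spike_times):
            for x in t:
                fh.write(f"{uid},{float(x)!r}\n")


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------


def _check_uniform(times: np.ndarray, path) -> float:
    if times.size < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    dt = np.diff(times)
    nominal = float(np.median(dt))
    if nominal <= 0 or np.max(np.abs(dt - nominal)) > _DT_RTOL * nominal:
        raise ValidationError(f"{path}: non-uniform sampling (nominal dt={nominal:g} s)")
    return 1.0 / nominal


def read_lfp(path, format: str = "delimited") -> LfpRecording:
    """Read a multichannel LFP recording.

    Delimited layout: first column ``time_s``, remaining columns one per
    channel; the header supplies ``channel_ids``. Sampling uniformity is
    verified to a relative tolerance of 1e-6 on successive intervals.
    """
    if format == "container":
        with h5py.File(path, "r") as f:
            area = f.attrs.get("area_labels")
            return LfpRecording(
                samples=f["samples"][()],
                fs=float(f.attrs["fs"]),
                channel_ids=[s.decode() for s in f["channel_ids"][()]],
                t_start=float(f.attrs.get("t_start", 0.0)),
                area_labels=list(json.loads(area)) if area is not None else None,
            )
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise ParseError(f"{path}: expected columns 'time_s,<ch>,...'")
    times = df["time_s"].to_numpy(dtype=float)
    fs = _check_uniform(times, path)
    return LfpRecording(
        samples=df.iloc[:, 1:].to_numpy(dtype=float),
        fs=fs,
        channel_ids=list(df.columns[1:]),
        t_start=float(times[0]),
    )


def write_lfp(lfp: LfpRecording, path, format: str = "delimited") -> None:
    if format == "container":
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = lfp.fs
            f.attrs["t_start"] = lfp.t_start
            if lfp.area_labels is not None:
                f.attrs["area_labels"] = json.dumps(list(lfp.area_labels))
            f.create_dataset("samples", data=lfp.samples, track_times=False)
            f.create_dataset(
                "channel_ids",
                data=np.array([str(c) for c in lfp.channel_ids], dtype="S"),
                track_times=False,
            )
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    df = pd.DataFrame(lfp.samples, columns=[str(c) for c in lfp.channel_ids])
    df.insert(0, "time_s", lfp.times)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


def read_kinematics(path) -> KinematicsTrace:
    """Read a cursor trace (columns ``time_s,x,y``)."""
    df = pd.read_csv(path)
    if list(df.columns[:3]) != ["time_s", "x", "y"]:
        raise ParseError(f"{path}: expected columns 'time_s,x,y'")
    times = df["time_s"].to_numpy(dtype=float)
    _check_uniform(times, path)
    return KinematicsTrace(times=times, position=df[["x", "y"]].to_numpy(dtype=float))


def write_kinematics(kin: KinematicsTrace, path) -> None:
    df = pd.DataFrame({"time_s": kin.times, "x": kin.position[:, 0], "y": kin.position[:, 1]})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


def write_model(model: ModelContainer, path) -> None:
    """Persist a fitted model; arrays at full precision, metadata as JSON."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _CONTAINER_VERSION
        f.attrs["model_kind"] = model.model_kind
        f.attrs["metadata"] = json.dumps(model.metadata, sort_keys=True)
        g = f.create_group("payload")
        for name, arr in model.payload.items():
            g.create_dataset(name, data=np.asarray(arr), track_times=False)


def read_model(path) -> ModelContainer:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValidationError(f"{path}: corrupt or unreadable model file ({exc})") from exc
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != _CONTAINER_VERSION:
            raise ValidationError(
                f"{path}: container version {version} != supported {_CONTAINER_VERSION}"
            )
        kind = f.attrs["model_kind"]
        if kind not in _MODEL_KINDS:
            raise ValidationError(f"{path}: unknown model_kind {kind!r}")
        return ModelContainer(
            model_kind=str(kind),
            metadata=json.loads(f.attrs["metadata"]),
            payload={name: ds[()] for name, ds in f["payload"].items()},
        )
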