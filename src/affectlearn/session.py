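"""Session data model and lossless on-disk serialization.

A recording session couples the sensor streams of one proband (participant)
— EEG band power from a five-electrode consumer headset and a 5 Hz galvanic
skin resistance stream — with the experience-sampling schedule (a vibration
alarm every ``interval`` seconds) and the five bipolar slider responses
collected at each alarm.

Time is expressed in seconds from session start throughout, and every
interval is half-open ``[start, end)`` so boundary samples are never counted
twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IncompleteSessionError,
    InvalidArgumentError,
)

#: Electrode positions of the headset (modified combinatorial nomenclature).
ELECTRODES: tuple[str, ...] = ("AF3", "AF4", "T7", "T8", "Pz")

#: Frequency bands reported by the headset, with edges in Hz (half-open).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta_low": (12.0, 16.0),
    "beta_high": (16.0, 25.0),
    "gamma": (25.0, 45.0),
}

BANDS: tuple[str, ...] = tuple(BAND_EDGES)

#: Bipolar slider scales of the experience-sampling questionnaire.
SCALES: tuple[str, ...] = ("interest", "energy", "valence", "focus", "tension")

#: Slider endpoints.
SLIDER_MIN, SLIDER_MAX = -4000.0, 4000.0

#: Number of experience samples in the reference design (3600 s / 270 s).
N_SAMPLES_DEFAULT = 13


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidArgumentError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TimeSeries:
    """A timestamped scalar sensor stream.

    Parameters
    ----------
    t : array-like
        Timestamps in seconds from session start, strictly increasing.
    v : array-like
        Sensor values, same length as ``t``.
    nominal_rate : float
        Nominal sampling rate in Hz (must be positive). The actual
        timestamps may deviate (gaps after masking).
    """

    t: np.ndarray
    v: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.v = _as_float_array(self.v, "v")
        if len(self.t) != len(self.v):
            raise InvalidArgumentError("t and v must have equal length")
        if self.nominal_rate <= 0:
            raise InvalidArgumentError("nominal_rate must be positive")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise FormatError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, start: float, end: float) -> "TimeSeries":
        """Return the sub-stream with ``start <= t < end``."""
        i0, i1 = np.searchsorted(self.t, [start, end], side="left")
        return TimeSeries(self.t[i0:i1], self.v[i0:i1], self.nominal_rate)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return (
            self.nominal_rate == other.nominal_rate
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.v, other.v)
        )


@dataclass
class BandPowerSet:
    """The 25 aligned band-power streams of one session.

    ``streams`` maps ``(electrode, band)`` to a :class:`TimeSeries`; all 25
    streams must be present, share identical timestamp vectors and contain
    only non-negative power values.
    """

    streams: dict[tuple[str, str], TimeSeries]

    def __post_init__(self) -> None:
        expected = {(e, b) for e in ELECTRODES for b in BANDS}
        if set(self.streams) != expected:
            missing = expected - set(self.streams)
            extra = set(self.streams) - expected
            raise IncompleteSessionError(
                f"band-power set must contain exactly the 25 electrode/band "
                f"streams (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        ref = self.streams[ELECTRODES[0], BANDS[0]].t
        for key, ts in self.streams.items():
            if not np.array_equal(ts.t, ref):
                raise FormatError(f"stream {key} timestamps differ from the rest")
            if np.any(ts.v < 0):
                raise FormatError(f"stream {key} contains negative power values")

    @property
    def t(self) -> np.ndarray:
        """Shared timestamp vector."""
        return self.streams[ELECTRODES[0], BANDS[0]].t

    def __getitem__(self, key: tuple[str, str]) -> TimeSeries:
        return self.streams[key]


@dataclass
class EdaStream:
    """Galvanic skin resistance stream (kΩ), nominally 5 Hz, values > 0."""

    gsr: TimeSeries

    def __post_init__(self) -> None:
        if np.any(self.gsr.v <= 0):
            raise FormatError("GSR resistance values must be positive")


@dataclass
class SamplingSchedule:
    """Experience-sampling alarms and the recorded response windows.

    Alarms fire at ``interval * k`` for ``k = 1 .. floor(session_length /
    interval)``. Each response window starts at its alarm; a response is
    valid only if completed within ``response_limit`` seconds.
    """

    session_length: float
    interval: float
    response_limit: float
    alarms: np.ndarray
    #: ``(start, end)`` per alarm, or ``None`` if no response was recorded.
    response_windows: list[tuple[float, float] | None]
    valid: np.ndarray  # bool per alarm

    def __post_init__(self) -> None:
        self.alarms = _as_float_array(self.alarms, "alarms")
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.response_windows) != len(self.alarms):
            raise InvalidArgumentError("one response window slot per alarm required")
        if len(self.valid) != len(self.alarms):
            raise InvalidArgumentError("one validity flag per alarm required")
        for alarm, win in zip(self.alarms, self.response_windows):
            if win is None:
                continue
            start, end = win
            if start != alarm:
                raise InvalidArgumentError("response window must start at its alarm")
            if not (0 < end - start <= self.response_limit + 1e-9):
                raise InvalidArgumentError(
                    "response window duration must lie in (0, response_limit]"
                )

    @property
    def n_alarms(self) -> int:
        return len(self.alarms)

    def register_response(self, k: int, duration: float) -> None:
        """Record the response to alarm ``k`` (0-based) taking ``duration`` s.

        Durations exceeding the response limit mark the alarm invalid; the
        window is still recorded (clipped to the limit) because the proband
        was busy with the questionnaire for that long.
        """
        if duration <= 0:
            raise InvalidArgumentError("response duration must be positive")
        alarm = float(self.alarms[k])
        clipped = min(duration, self.response_limit)
        self.response_windows[k] = (alarm, alarm + clipped)
        self.valid[k] = duration <= self.response_limit


def build_schedule(
    session_length: float, interval: float, response_limit: float = 60.0
) -> SamplingSchedule:
    """Build the alarm schedule for a session.

    Alarms at ``interval * k``, ``k = 1 .. floor(session_length/interval)``;
    response windows start empty (no response registered, all alarms
    invalid) until :meth:`SamplingSchedule.register_response` is called.

    >>> build_schedule(3600, 270, 60).n_alarms
    13
    """
    if interval <= 0:
        raise InvalidArgumentError("interval must be positive")
    if session_length < interval:
        raise InvalidArgumentError("session_length must be at least one interval")
    if response_limit <= 0:
        raise InvalidArgumentError("response_limit must be positive")
    # tiny tolerance so e.g. 3600/270 -> 13 survives float division
    n = int(np.floor(session_length / interval + 1e-9))
    alarms = interval * np.arange(1, n + 1, dtype=float)
    return SamplingSchedule(
        session_length=float(session_length),
        interval=float(interval),
        response_limit=float(response_limit),
        alarms=alarms,
        response_windows=[None] * n,
        valid=np.zeros(n, dtype=bool),
    )


class ExperienceSampleSet:
    """Slider responses per experience sample.

    Stored as a DataFrame indexed by sample number (1-based) with one column
    per scale; missing responses are NaN. Values lie in [-4000, 4000].
    """

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        if list(values.columns) != list(SCALES):
            raise FormatError(f"expected columns {SCALES}, got {list(values.columns)}")
        arr = values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = (arr < SLIDER_MIN) | (arr > SLIDER_MAX)
        if np.any(out_of_range & ~np.isnan(arr)):
            raise FormatError("slider values outside [-4000, 4000]")
        self.values = values.astype(float)

    @classmethod
    def from_matrix(cls, matrix, index=None) -> "ExperienceSampleSet":
        matrix = np.asarray(matrix, dtype=float)
        if index is None:
            index = range(1, matrix.shape[0] + 1)
        return cls(pd.DataFrame(matrix, index=index, columns=list(SCALES)))

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def labels(self, scale: str) -> pd.Series:
        """Label vector for one slider scale (NaN where missing)."""
        return self.values[scale]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExperienceSampleSet):
            return NotImplemented
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return a.shape == b.shape and np.array_equal(a, b, equal_nan=True)


class OutcomeSet:
    """Item responses and derived scores for the retrospective outcome scales.

    For each scale the ordinal item-response matrix (probands x items) is
    kept alongside the derived scale score, defined as the mean of the items.
    """

    def __init__(self, items: Mapping[str, pd.DataFrame]):
        self.items: dict[str, pd.DataFrame] = {}
        self.scores: dict[str, pd.Series] = {}
        for scale, mat in items.items():
            if mat.shape[1] < 2:
                raise InvalidArgumentError(
                    f"scale {scale!r} needs >= 2 items for reliability estimation"
                )
            self.items[scale] = mat.astype(float)
            self.scores[scale] = mat.mean(axis=1)

    @property
    def scales(self) -> list[str]:
        return list(self.items)

    def score_frame(self) -> pd.DataFrame:
        """Probands x scales matrix of scale scores."""
        return pd.DataFrame(self.scores)


@dataclass
class Session:
    """All data recorded for one proband during one learning session."""

    proband_id: str
    band_power: BandPowerSet | None
    eda: EdaStream | None
    schedule: SamplingSchedule
    samples: ExperienceSampleSet

    def __post_init__(self) -> None:
        if self.band_power is None and self.eda is None:
            raise IncompleteSessionError("session carries no sensor stream")
        if self.samples.n_samples != self.schedule.n_alarms:
            raise InvalidArgumentError("one experience sample row per alarm required")
        L = self.schedule.session_length
        for ts in self._streams():
            if len(ts) and (ts.t[0] < 0 or ts.t[-1] > L):
                raise FormatError("stream extends outside [0, session_length]")
        # missing labels exactly where the alarm is invalid
        missing = self.samples.values.isna().all(axis=1).to_numpy()
        if not np.array_equal(missing, ~self.schedule.valid):
            raise InvalidArgumentError(
                "samples must be missing exactly for invalid alarms"
            )

    def _streams(self):
        if self.band_power is not None:
            yield from self.band_power.streams.values()
        if self.eda is not None:
            yield self.eda.gsr


# ---------------------------------------------------------------------------
# Serialization: one directory per session.
#   band_power.csv  long format  t,electrode,band,v
#   eda.csv         t,v
#   meta.json       proband id, schedule, slider labels, rates
# Floats are written with %.17g so the decimal text parses back bit-exactly.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _write_csv(path: Path, header: str, columns: Sequence[np.ndarray | list]) -> None:
    rows = zip(*columns)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(",".join(c if isinstance(c, str) else _fmt(c) for c in row))
            fh.write("\n")


def write_session(session: Session, out_dir: str | Path) -> list[Path]:
    """Write a session to ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    if session.band_power is not None:
        bp = session.band_power
        t = bp.t
        n = len(t)
        t_col: list = list(np.tile(t, 25))
        e_col: list[str] = []
        b_col: list[str] = []
        v_parts = []
        for e in ELECTRODES:
            for b in BANDS:
                e_col.extend([e] * n)
                b_col.extend([b] * n)
                v_parts.append(bp[e, b].v)
        v_col = np.concatenate(v_parts) if v_parts else np.empty(0)
        p = out / "band_power.csv"
        _write_csv(p, "t,electrode,band,v", [t_col, e_col, b_col, v_col])
        paths.append(p)

    if session.eda is not None:
        p = out / "eda.csv"
        _write_csv(p, "t,v", [session.eda.gsr.t, session.eda.gsr.v])
        paths.append(p)

    sched = session.schedule
    meta = {
        "proband_id": session.proband_id,
        "schedule": {
            "session_length": sched.session_length,
            "interval": sched.interval,
            "response_limit": sched.response_limit,
            "alarms": list(sched.alarms),
            "response_windows": [
                list(w) if w is not None else None for w in sched.response_windows
            ],
            "valid": [bool(x) for x in sched.valid],
        },
        "samples": {
            scale: [
                None if np.isnan(v) else v
                for v in session.samples.values[scale].to_numpy()
            ]
            for scale in SCALES
        },
        "rates": {
            "band_power": (
                session.band_power[ELECTRODES[0], BANDS[0]].nominal_rate
                if session.band_power is not None
                else None
            ),
            "eda": session.eda.gsr.nominal_rate if session.eda is not None else None,
        },
    }
    p = out / "meta.json"
    with open(p, "w") as fh:
        json.dump(meta, fh, indent=1)
    paths.append(p)
    return paths


def _read_stream_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return df


def read_session(session_dir: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    d = Path(session_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise IncompleteSessionError(f"missing {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)

    s = meta["schedule"]
    schedule = SamplingSchedule(
        session_length=s["session_length"],
        interval=s["interval"],
        response_limit=s["response_limit"],
        alarms=np.asarray(s["alarms"], dtype=float),
        response_windows=[tuple(w) if w is not None else None for w in s["response_windows"]],
        valid=np.asarray(s["valid"], dtype=bool),
    )

    n = schedule.n_alarms
    samples = ExperienceSampleSet(
        pd.DataFrame(
            {
                scale: [np.nan if v is None else float(v) for v in meta["samples"][scale]]
                for scale in SCALES
            },
            index=range(1, n + 1),
        )
    )

    band_power = None
    bp_path = d / "band_power.csv"
    if bp_path.exists():
        df = _read_stream_csv(bp_path)
        if list(df.columns) != ["t", "electrode", "band", "v"]:
            raise FormatError("band_power.csv must have columns t,electrode,band,v")
        rate = float(meta["rates"]["band_power"])
        streams = {}
        for (e, b), g in df.groupby(["electrode", "band"], sort=False):
            t = g["t"].to_numpy(dtype=float)
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise FormatError(f"non-monotone timestamps in band {e}/{b}")
            streams[(e, b)] = TimeSeries(t, g["v"].to_numpy(dtype=float), rate)
        band_power = BandPowerSet(streams)

    eda = None
    eda_path = d / "eda.csv"
    if eda_path.exists():
        df = _read_stream_csv(eda_path)
        if list(df.columns) != ["t", "v"]:
            raise FormatError("eda.csv must have columns t,v")
        t = df["t"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise FormatError("non-monotone timestamps in eda.csv")
        rate = float(meta["rates"]["eda"])
        eda = EdaStream(TimeSeries(t, df["v"].to_numpy(dtype=float), rate))

    return Session(
        proband_id=meta["proband_id"],
        band_power=band_power,
        eda=eda,
        schedule=schedule,
        samples=samples,
    )
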