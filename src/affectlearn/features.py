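"""Summary features and spectral indices for EEG band power and EDA.

Seven summary statistics are computed per stream and segment: mean, median,
standard deviation (sample, n-1), maximum, minimum, max-min range
(``maxmin``) and ``tendency`` — the median of the first 30 s minus the
median of the last 30 s of the segment's span, a within-segment drift
measure.

On top of the 25 electrode/band power streams, four index families are
derived pointwise before the statistics are taken:

* ``bla_<SITE>``        — low-beta / alpha (engagement-type ratio);
* ``nasa_<SITE>``       — (low-beta + high-beta) / (theta + alpha), the
  classic task-engagement index;
* ``lateral_T_<BAND>``  — temporal laterality, T7 - T8;
* ``lateral_AF_<BAND>`` — anterior-frontal laterality, AF3 - AF4.

That yields 45 streams x 7 statistics = 315 named EEG features per segment,
and 7 ``GSR_<stat>`` features per EDA segment. Ratio denominators are
floored at ``RATIO_EPS`` to keep the indices finite when a band power
vanishes; occurrences are logged.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .segmentation import Segment, _keep_mask, _make_segment, whole_session
from .session import BANDS, ELECTRODES, BandPowerSet, EdaStream, SamplingSchedule, Session, TimeSeries

logger = logging.getLogger(__name__)

#: The seven summary statistics, in canonical order.
STATS: tuple[str, ...] = ("mean", "median", "std", "max", "min", "maxmin", "tendency")

#: Floor applied to ratio denominators (band powers are >= 0).
RATIO_EPS = 1e-12

#: Length of the windows at either end of a segment used by ``tendency``.
TENDENCY_WINDOW = 30.0

_BAND_TOKEN = {b: b.upper() for b in BANDS}  # theta -> THETA, beta_low -> BETA_LOW
_TOKEN_BAND = {v: k for k, v in _BAND_TOKEN.items()}


def _floored(v: np.ndarray, where: str) -> np.ndarray:
    n_floor = int(np.sum(v < RATIO_EPS))
    if n_floor:
        logger.warning("%s: floored %d denominator value(s) at %g", where, n_floor, RATIO_EPS)
    return np.maximum(v, RATIO_EPS)


def bla_series(bp: BandPowerSet, site: str) -> TimeSeries:
    """Low-beta-to-alpha ratio at one electrode, pointwise."""
    beta = bp[site, "beta_low"]
    alpha = bp[site, "alpha"]
    return TimeSeries(beta.t, beta.v / _floored(alpha.v, f"bla_{site}"), beta.nominal_rate)


def nasa_series(bp: BandPowerSet, site: str) -> TimeSeries:
    """Task-engagement index beta / (theta + alpha) at one electrode.

    'beta' is the sum of the low- and high-beta streams; the headset has no
    unified beta band.
    """
    num = bp[site, "beta_low"].v + bp[site, "beta_high"].v
    den = bp[site, "theta"].v + bp[site, "alpha"].v
    t = bp[site, "theta"].t
    return TimeSeries(t, num / _floored(den, f"nasa_{site}"), bp[site, "theta"].nominal_rate)


def lateral_series(bp: BandPowerSet, axis: str, band: str) -> TimeSeries:
    """Left-minus-right laterality per band: T7-T8 (``T``) or AF3-AF4 (``AF``)."""
    if axis == "T":
        left, right = bp["T7", band], bp["T8", band]
    elif axis == "AF":
        left, right = bp["AF3", band], bp["AF4", band]
    else:
        raise InvalidArgumentError("axis must be 'T' or 'AF'")
    return TimeSeries(left.t, left.v - right.v, left.nominal_rate)


def derived_streams(bp: BandPowerSet) -> dict[str, TimeSeries]:
    """All 45 EEG-derived streams keyed by feature-name prefix."""
    out: dict[str, TimeSeries] = {}
    for e in ELECTRODES:
        for b in BANDS:
            out[f"{e}_{_BAND_TOKEN[b]}"] = bp[e, b]
    for e in ELECTRODES:
        out[f"bla_{e}"] = bla_series(bp, e)
    for e in ELECTRODES:
        out[f"nasa_{e}"] = nasa_series(bp, e)
    for axis in ("T", "AF"):
        for b in BANDS:
            out[f"lateral_{axis}_{_BAND_TOKEN[b]}"] = lateral_series(bp, axis, b)
    return out


def summary_features(seg: Segment) -> dict[str, float]:
    """The seven summary statistics of one segment.

    An empty segment yields all-NaN; ``tendency`` is NaN whenever either
    30 s end-window of the segment's span contains no sample.
    """
    v, t = seg.ts.v, seg.ts.t
    if len(v) == 0:
        return {s: float("nan") for s in STATS}
    start, end = seg.span
    first = v[(t >= start) & (t < start + TENDENCY_WINDOW)]
    last = v[(t >= end - TENDENCY_WINDOW) & (t < end)]
    tendency = (
        float(np.median(first) - np.median(last))
        if len(first) and len(last)
        else float("nan")
    )
    vmax, vmin = float(np.max(v)), float(np.min(v))
    return {
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "std": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "max": vmax,
        "min": vmin,
        "maxmin": vmax - vmin,
        "tendency": tendency,
    }


def _segment_spans(schedule: SamplingSchedule, index: int) -> tuple[float, float]:
    if index == 0:
        return (0.0, schedule.session_length)
    alarm = float(schedule.alarms[index - 1])
    return (alarm - schedule.interval, alarm)


def _stats_over_streams(
    streams: dict[str, TimeSeries],
    schedule: SamplingSchedule,
    index: int,
) -> dict[str, float]:
    """Mask + slice + summarize every stream, sharing the timestamp work.

    All EEG-derived streams share one timestamp vector, so the response-
    window mask and the segment slice are computed once.
    """
    first = next(iter(streams.values()))
    keep = _keep_mask(first.t, schedule)
    t_masked = first.t[keep]
    start, end = _segment_spans(schedule, index)
    i0, i1 = np.searchsorted(t_masked, [start, end], side="left")
    out: dict[str, float] = {}
    for prefix, ts in streams.items():
        sub = TimeSeries(t_masked[i0:i1], ts.v[keep][i0:i1], ts.nominal_rate)
        expected = (end - start) * ts.nominal_rate
        seg = Segment(
            index=index,
            source_id=prefix,
            ts=sub,
            span=(start, end),
            coverage=min(1.0, len(sub) / expected) if expected > 0 else 0.0,
        )
        for stat, value in summary_features(seg).items():
            out[f"{prefix}_{stat}"] = value
    return out


def eeg_feature_vector(
    bp: BandPowerSet, schedule: SamplingSchedule, index: int = 0
) -> dict[str, float]:
    """The 315 named EEG features of segment ``index`` (0 = whole session)."""
    return _stats_over_streams(derived_streams(bp), schedule, index)


def eda_feature_vector(
    eda: EdaStream, schedule: SamplingSchedule, index: int = 0
) -> dict[str, float]:
    """The 7 ``GSR_<stat>`` features of segment ``index`` (0 = whole session)."""
    return _stats_over_streams({"GSR": eda.gsr}, schedule, index)


def feature_table(
    sessions: Iterable[Session],
    sensor: str = "eeg",
    level: str = "outcome",
) -> pd.DataFrame:
    """Feature matrix for a cohort.

    Parameters
    ----------
    sensor : ``"eeg"`` or ``"eda"``.
    level : ``"outcome"`` (one whole-session row per proband, sample_index
        0) or ``"process"`` (one row per proband and experience sample).

    Returns a DataFrame indexed by ``(proband_id, sample_index)``.
    """
    if sensor not in ("eeg", "eda"):
        raise InvalidArgumentError("sensor must be 'eeg' or 'eda'")
    if level not in ("outcome", "process"):
        raise InvalidArgumentError("level must be 'outcome' or 'process'")
    rows = []
    keys = []
    for sess in sessions:
        if sensor == "eeg":
            if sess.band_power is None:
                continue
            streams = derived_streams(sess.band_power)
        else:
            if sess.eda is None:
                continue
            streams = {"GSR": sess.eda.gsr}
        indices = [0] if level == "outcome" else list(
            range(1, sess.schedule.n_alarms + 1)
        )
        for idx in indices:
            rows.append(_stats_over_streams(streams, sess.schedule, idx))
            keys.append((sess.proband_id, idx))
    index = pd.MultiIndex.from_tuples(keys, names=["proband_id", "sample_index"])
    return pd.DataFrame(rows, index=index)


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split a feature name into ``(stream prefix, statistic)``.

    The inverse of the naming used by the feature vectors; raises on names
    that no stream/statistic pair produces.
    """
    for stat in STATS:
        suffix = f"_{stat}"
        if name.endswith(suffix):
            prefix = name[: -len(suffix)]
            if prefix in _valid_prefixes():
                return prefix, stat
    raise InvalidArgumentError(f"unparseable feature name: {name!r}")


def _valid_prefixes() -> set[str]:
    prefixes = {f"{e}_{_BAND_TOKEN[b]}" for e in ELECTRODES for b in BANDS}
    prefixes |= {f"bla_{e}" for e in ELECTRODES}
    prefixes |= {f"nasa_{e}" for e in ELECTRODES}
    prefixes |= {f"lateral_{axis}_{_BAND_TOKEN[b]}" for axis in ("T", "AF") for b in BANDS}
    prefixes.add("GSR")
    return prefixes


def t7_derived(name: str) -> bool:
    """Whether a feature is computed from the T7 electrode's own streams."""
    prefix, _ = parse_feature_name(name)
    return prefix.startswith("T7_") or prefix in ("bla_T7", "nasa_T7")
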