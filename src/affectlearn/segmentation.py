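"""Masking of questionnaire-response windows and pre-sample segmentation.

While a proband fills in the slider questionnaire the sensors record the
act of responding, not the learning process, so those stretches are cut out
of every stream. Features are then computed either on the 270 s preceding
each experience sample (process level, 13 segments) or on the whole session
minus response windows (outcome level, one segment with index 0).

Segments are anchored to the *nominal* alarm times: segment ``k`` spans
``[alarm_k - interval, alarm_k)`` regardless of when the response was
actually completed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SamplingSchedule, TimeSeries

#: Segments whose retained coverage falls below this fraction are flagged.
LOW_COVERAGE = 0.5


@dataclass
class Segment:
    """A masked slice of one sensor stream.

    ``index`` is 1..n for pre-sample segments, 0 for the whole session.
    ``coverage`` is the retained fraction of the nominally expected samples
    over the segment's span (0 for an empty segment, at most 1).
    """

    index: int
    source_id: str
    ts: TimeSeries
    span: tuple[float, float]
    coverage: float

    @property
    def low_coverage(self) -> bool:
        return self.coverage < LOW_COVERAGE


def _keep_mask(t: np.ndarray, schedule: SamplingSchedule) -> np.ndarray:
    keep = np.ones(len(t), dtype=bool)
    for win in schedule.response_windows:
        if win is None:
            continue
        start, end = win
        keep &= ~((t >= start) & (t < end))
    return keep


def mask_response_windows(
    ts: TimeSeries, schedule: SamplingSchedule
) -> TimeSeries:
    """Drop every sample falling inside a recorded response window.

    Windows are half-open ``[start, end)``; sample order is preserved and a
    schedule without recorded responses leaves the stream untouched.
    """
    keep = _keep_mask(ts.t, schedule)
    return TimeSeries(ts.t[keep], ts.v[keep], ts.nominal_rate)


def _make_segment(
    ts: TimeSeries, index: int, start: float, end: float, source_id: str
) -> Segment:
    sub = ts.slice(start, end)
    expected = (end - start) * ts.nominal_rate
    coverage = min(1.0, len(sub) / expected) if expected > 0 else 0.0
    return Segment(index=index, source_id=source_id, ts=sub, span=(start, end), coverage=coverage)


def segment_preceding(
    ts: TimeSeries, schedule: SamplingSchedule, source_id: str = ""
) -> list[Segment]:
    """Slice a (masked) stream into the pre-alarm segments.

    Segment ``k`` holds the samples with ``t`` in ``[alarm_k - interval,
    alarm_k)``; consecutive segments tile ``[0, last alarm)`` without
    overlap. The stream should already be masked with
    :func:`mask_response_windows`.
    """
    segments = []
    for k, alarm in enumerate(schedule.alarms, start=1):
        start = alarm - schedule.interval
        segments.append(_make_segment(ts, k, start, alarm, source_id))
    return segments


def whole_session(
    ts: TimeSeries, schedule: SamplingSchedule, source_id: str = ""
) -> Segment:
    """The full-session segment (index 0) after masking.

    Coverage is relative to the nominal span ``[0, session_length)``; with
    the reference schedule (13 responses of ~16 s in 3600 s) it comes out
    near 0.94.
    """
    masked = mask_response_windows(ts, schedule)
    return _make_segment(masked, 0, 0.0, schedule.session_length, source_id)
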