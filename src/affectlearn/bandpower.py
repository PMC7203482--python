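"""Emulation of a consumer headset's on-device spectral preprocessing.

The headset never exposes raw EEG; it streams precomputed power for the
theta (4-8 Hz), alpha (8-12), low-beta (12-16), high-beta (16-25) and gamma
(25-45 Hz) bands of each electrode, computed with an FFT over a 2 s Hanning
window of the 128 Hz signal. This module reproduces that front end so that
pipelines can be exercised from raw waveforms.

Band edges are half-open ``[low, high)``: with the 0.5 Hz bin resolution of
a 2 s window, the shared 8 Hz bin belongs to alpha, not theta. Per-band
power is the *sum* of squared FFT magnitudes over the band's bins; the
absolute scale is immaterial downstream because every feature is compared
within-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InsufficientDataError, InvalidArgumentError
from .session import BAND_EDGES, BANDS, ELECTRODES, BandPowerSet, TimeSeries


@dataclass
class SpectralConfig:
    """Parameters of the on-device band-power computation.

    The default step of 16 samples yields the documented 8 Hz output rate
    at 128 Hz input; set ``step=125`` to mimic a device stepping by 125
    samples (~1 Hz output) instead.
    """

    sample_rate: float = 128.0
    window_seconds: float = 2.0
    step: int = 16
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES)
    )

    def __post_init__(self) -> None:
        n = self.sample_rate * self.window_seconds
        if abs(n - round(n)) > 1e-9:
            raise InvalidArgumentError(
                "window must span an integer number of samples"
            )
        if self.step < 1:
            raise InvalidArgumentError("step must be >= 1 sample")
        nyquist = self.sample_rate / 2
        for band, (lo, hi) in self.bands.items():
            if not (0 < lo < hi <= nyquist):
                raise InvalidArgumentError(
                    f"band {band!r} edges must satisfy 0 < low < high <= Nyquist"
                )

    @property
    def window_samples(self) -> int:
        return int(round(self.sample_rate * self.window_seconds))

    @property
    def output_rate(self) -> float:
        return self.sample_rate / self.step


def compute_band_power(
    raw: TimeSeries, cfg: SpectralConfig | None = None
) -> dict[str, TimeSeries]:
    """Sliding-window band power of one uniformly sampled raw channel.

    For each window position the Hanning-tapered window is Fourier
    transformed and, per band, the squared magnitudes of the bins with
    frequency in ``[low, high)`` are summed. The output sample is stamped
    with the window's end time (the timestamp of its last raw sample).

    Raises
    ------
    InsufficientDataError
        If the stream is shorter than one analysis window.
    """
    cfg = cfg or SpectralConfig()
    n = cfg.window_samples
    x = np.asarray(raw.v, dtype=float)
    if len(x) < n:
        raise InsufficientDataError(
            f"need at least {n} samples for one window, got {len(x)}"
        )
    step = cfg.step
    n_frames = (len(x) - n) // step + 1

    taper = np.hanning(n)
    starts = step * np.arange(n_frames)
    # frame matrix via stride tricks: (n_frames, n)
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[::step][:n_frames]
    spec = np.fft.rfft(frames * taper, axis=1)
    power = spec.real**2 + spec.imag**2  # (n_frames, n//2 + 1)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.sample_rate)

    t_out = raw.t[starts + n - 1]
    out_rate = cfg.output_rate
    result: dict[str, TimeSeries] = {}
    for band, (lo, hi) in cfg.bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        result[band] = TimeSeries(t_out, power[:, sel].sum(axis=1), out_rate)
    return result


def emulate_device(
    raw5: dict[str, TimeSeries], cfg: SpectralConfig | None = None
) -> BandPowerSet:
    """Apply :func:`compute_band_power` per electrode; assemble the 25 streams.

    ``raw5`` maps each of the five electrode names to its raw channel; all
    channels must share identical timestamps.
    """
    cfg = cfg or SpectralConfig()
    if set(raw5) != set(ELECTRODES):
        raise FormatError(f"expected exactly the electrodes {ELECTRODES}")
    ref = raw5[ELECTRODES[0]].t
    for e in ELECTRODES:
        if not np.array_equal(raw5[e].t, ref):
            raise FormatError(f"electrode {e} timestamps differ: cannot align")
    streams: dict[tuple[str, str], TimeSeries] = {}
    for e in ELECTRODES:
        per_band = compute_band_power(raw5[e], cfg)
        for b in BANDS:
            streams[(e, b)] = per_band[b]
    return BandPowerSet(streams)
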