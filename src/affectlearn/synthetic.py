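"""Synthetic cohorts with the statistical structure the analysis assumes.

The study's human recordings are not public, so the pipeline is exercised
on generated cohorts that emulate the experiment's design: a 3600 s
learning session, a vibration alarm every 270 s (13 experience samples),
slider responses taking ~16 s on average (truncated normal, capped by the
60 s validity limit), EEG band power at 8 Hz for 5 electrodes x 5 bands,
galvanic skin resistance at 5 Hz with tonic drift, and retrospective
outcome scales built from ordinal items calibrated to a target Cronbach's
alpha.

The generative model, per proband ``i``:

* latent *traits* ``z_i ~ N(0, I)`` (stable dispositions) plus a per-site
  activation trait ``a_i[site] ~ N(0, site_activation_sd^2)`` capturing how
  strongly each electrode site fires for this person;
* a latent affective *state* ``s_i(t)``: a discrete-time mean-reverting
  (AR(1)/Ornstein-Uhlenbeck) process at 1 Hz relaxing toward a
  trait-dependent level, linearly interpolated to the sensor rates;
* band power ``P(site, band, t) = baseline * exp(gain*s(t) + a_i[site])
  * lognormal noise`` — positive and right-skewed, like real power values;
* GSR = subject baseline + tonic linear drift + state coupling + noise,
  floored to stay positive;
* slider labels = affine map of the state at the alarm + noise, clipped to
  the +-4000 scale; missing when the (simulated) response came too late;
* outcome scale scores: each scale has a latent factor mixing the traits,
  the site activations named in ``outcome_effects``, and fresh noise; the
  ordinal item matrix is drawn from a one-factor model whose loading is set
  by the Spearman-Brown relation ``alpha = k*rbar / (1 + (k-1)*rbar)`` so
  the measured Cronbach's alpha matches the configured reliability.

Ground truth (traits, states, noiseless labels) is returned with every
cohort so planted effects can be verified directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .session import (
    BANDS,
    ELECTRODES,
    SCALES,
    BandPowerSet,
    EdaStream,
    ExperienceSampleSet,
    OutcomeSet,
    SamplingSchedule,
    Session,
    TimeSeries,
    build_schedule,
)

#: Outcome scales with the reliabilities the generator targets by default.
DEFAULT_OUTCOME_RELIABILITY: dict[str, float] = {
    "amotivation": 0.68,
    "external_motivation": 0.61,
    "introjected_motivation": 0.38,
    "identified_motivation": 0.60,
    "sdt_intrinsic_motivation": 0.69,
    "interest": 0.80,
    "intrinsic_motivation": 0.81,
    "workload": 0.37,
    "tense_arousal": 0.89,
    "anger_frustration": 0.87,
    "energetic_arousal": 0.90,
    "hedonic_tone": 0.88,
}

#: Coupling of each slider scale to the latent state (sign and strength).
DEFAULT_SLIDER_COUPLING: dict[str, float] = {
    "interest": 1.0,
    "energy": 0.8,
    "valence": 0.6,
    "focus": 0.7,
    "tension": -0.5,
}


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the reference experimental design: 3600 s sessions,
    270 s sampling interval (13 alarms), responses averaging 16.36 s
    (SD 7.36, truncated to (0, 60]).
    """

    n_probands: int = 54
    session_length: float = 3600.0
    interval: float = 270.0
    response_limit: float = 60.0
    response_time_mean: float = 16.36
    response_time_sd: float = 7.36
    #: probability that a response exceeds the limit / is skipped entirely
    missing_prob: float = 0.0

    band_rate: float = 8.0
    eda_rate: float = 5.0

    n_traits: int = 3
    state_tau: float = 120.0       # relaxation time of the latent state, s
    state_sd: float = 1.0          # stationary sd of the latent state
    #: coupling of the state's reversion level to its own dedicated trait.
    #: The state trait is disjoint from the outcome traits, so in the base
    #: configuration sensors and outcome scales share no latent driver and
    #: any sensor->outcome association must be planted explicitly.
    state_trait_coupling: float = 0.5

    band_baseline: float = 10.0    # nominal power level, arbitrary units
    band_state_gain: float = 0.2   # d log(power) / d state
    band_noise_sd: float = 0.3     # lognormal sigma of the power noise
    site_activation_sd: float = 0.5  # proband-level per-site log-gain sd

    eda_baseline_mean: float = 200.0   # kOhm
    eda_baseline_sd: float = 30.0
    eda_drift_per_hour: float = 40.0   # tonic drift over the session, kOhm
    eda_state_coupling: float = -10.0  # arousal lowers resistance
    eda_noise_sd: float = 3.0

    slider_gain: float = 1500.0
    slider_noise_sd: float = 500.0
    slider_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLIDER_COUPLING)
    )

    outcome_reliability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_RELIABILITY)
    )
    items_per_scale: int = 10
    item_levels: int = 7            # ordinal 1..item_levels
    outcome_trait_coupling: float = 0.6
    outcome_noise_sd: float = 0.8
    #: scale -> {site -> coefficient}: adds coef * a[site]/site_activation_sd
    #: to the scale's latent factor (the hook used to plant sensor-outcome
    #: effects)
    outcome_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probands < 1:
            raise InvalidArgumentError("n_probands must be >= 1")
        for name in ("response_time_sd", "band_noise_sd", "state_sd",
                     "slider_noise_sd", "eda_noise_sd", "outcome_noise_sd",
                     "site_activation_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        for scale, alpha in self.outcome_reliability.items():
            if not (0 < alpha < 1):
                raise InvalidArgumentError(
                    f"target reliability for {scale!r} must lie in (0, 1)"
                )
        if self.items_per_scale < 2:
            raise InvalidArgumentError("items_per_scale must be >= 2")


@dataclass
class GroundTruth:
    """Latent quantities behind a generated cohort (for recovery tests)."""

    traits: pd.DataFrame            # proband x trait
    site_activation: pd.DataFrame   # proband x electrode
    states: dict[str, np.ndarray]   # proband -> 1 Hz latent state
    noiseless_sliders: dict[str, pd.DataFrame]  # proband -> samples x scales
    outcome_factors: pd.DataFrame   # proband x scale (standardized factors)


def _truncated_normal(rng, mean, sd, low, high, size) -> np.ndarray:
    """Rejection-sampled truncated normal on (low, high]."""
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw > low) & (draw <= high)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _latent_state(rng, cfg: GeneratorConfig, level: float) -> np.ndarray:
    """Mean-reverting AR(1) state at 1 Hz over the session, stationary start."""
    n = int(cfg.session_length) + 1
    phi = np.exp(-1.0 / cfg.state_tau)
    innov_sd = cfg.state_sd * np.sqrt(1.0 - phi**2)
    s = np.empty(n)
    s[0] = level + cfg.state_sd * rng.standard_normal()
    shocks = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        s[t] = level + phi * (s[t - 1] - level) + shocks[t - 1]
    return s


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[Session], OutcomeSet, GroundTruth]:
    """Generate a full cohort: sessions, outcome questionnaires, ground truth.

    Deterministic given ``cfg.seed``; the same config yields bit-identical
    cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probands
    pids = [f"P{i:03d}" for i in range(1, n + 1)]

    traits = rng.standard_normal((n, cfg.n_traits))
    state_trait = rng.standard_normal(n)
    site_act = rng.standard_normal((n, len(ELECTRODES))) * cfg.site_activation_sd

    t_state = np.arange(int(cfg.session_length) + 1, dtype=float)
    t_band = np.arange(0.0, cfg.session_length + 0.5 / cfg.band_rate, 1.0 / cfg.band_rate)
    t_band = t_band[t_band <= cfg.session_length]
    t_eda = np.arange(0.0, cfg.session_length + 0.5 / cfg.eda_rate, 1.0 / cfg.eda_rate)
    t_eda = t_eda[t_eda <= cfg.session_length]

    sessions: list[Session] = []
    states: dict[str, np.ndarray] = {}
    noiseless_sliders: dict[str, pd.DataFrame] = {}

    for i, pid in enumerate(pids):
        level = cfg.state_trait_coupling * state_trait[i]
        s = _latent_state(rng, cfg, level)
        states[pid] = s
        s_band = np.interp(t_band, t_state, s)
        s_eda = np.interp(t_eda, t_state, s)

        # --- band power: 25 streams sharing t_band ---------------------
        streams: dict[tuple[str, str], TimeSeries] = {}
        noise = rng.standard_normal((len(ELECTRODES), len(BANDS), len(t_band)))
        for ei, e in enumerate(ELECTRODES):
            log_gain_site = site_act[i, ei]
            for bi, b in enumerate(BANDS):
                v = cfg.band_baseline * np.exp(
                    cfg.band_state_gain * s_band
                    + log_gain_site
                    + cfg.band_noise_sd * noise[ei, bi]
                )
                streams[(e, b)] = TimeSeries(t_band, v, cfg.band_rate)
        band_power = BandPowerSet(streams)

        # --- EDA --------------------------------------------------------
        base = rng.normal(cfg.eda_baseline_mean, cfg.eda_baseline_sd)
        drift = cfg.eda_drift_per_hour * (t_eda / 3600.0)
        gsr = (
            base
            + drift
            + cfg.eda_state_coupling * s_eda
            + cfg.eda_noise_sd * rng.standard_normal(len(t_eda))
        )
        eda = EdaStream(TimeSeries(t_eda, np.maximum(gsr, 1.0), cfg.eda_rate))

        # --- schedule and slider labels ---------------------------------
        schedule = build_schedule(cfg.session_length, cfg.interval, cfg.response_limit)
        n_alarms = schedule.n_alarms
        durations = _truncated_normal(
            rng, cfg.response_time_mean, cfg.response_time_sd, 0.0,
            cfg.response_limit, n_alarms,
        )
        missing = rng.random(n_alarms) < cfg.missing_prob
        clean = np.empty((n_alarms, len(SCALES)))
        noisy = np.full((n_alarms, len(SCALES)), np.nan)
        label_noise = rng.standard_normal((n_alarms, len(SCALES)))
        for k, alarm in enumerate(schedule.alarms):
            s_at = float(np.interp(alarm, t_state, s))
            for j, scale in enumerate(SCALES):
                clean[k, j] = np.clip(
                    cfg.slider_gain * cfg.slider_coupling[scale] * s_at,
                    -4000.0,
                    4000.0,
                )
                if not missing[k]:
                    noisy[k, j] = np.clip(
                        cfg.slider_gain * cfg.slider_coupling[scale] * s_at
                        + cfg.slider_noise_sd * label_noise[k, j],
                        -4000.0,
                        4000.0,
                    )
            if missing[k]:
                # response never completed within the limit
                schedule.register_response(k, cfg.response_limit + 1.0)
            else:
                schedule.register_response(k, float(durations[k]))
        samples = ExperienceSampleSet.from_matrix(noisy)
        noiseless_sliders[pid] = pd.DataFrame(
            clean, index=range(1, n_alarms + 1), columns=list(SCALES)
        )

        sessions.append(
            Session(
                proband_id=pid,
                band_power=band_power,
                eda=eda,
                schedule=schedule,
                samples=samples,
            )
        )

    # --- outcome questionnaires ------------------------------------------
    items: dict[str, pd.DataFrame] = {}
    factors = np.empty((n, len(cfg.outcome_reliability)))
    scale_names = list(cfg.outcome_reliability)
    site_index = {e: j for j, e in enumerate(ELECTRODES)}
    for m, scale in enumerate(scale_names):
        trait_j = m % cfg.n_traits
        base = cfg.outcome_trait_coupling * traits[:, trait_j]
        base = base + cfg.outcome_noise_sd * rng.standard_normal(n)
        base_var = cfg.outcome_trait_coupling**2 + cfg.outcome_noise_sd**2
        f0 = base / np.sqrt(base_var) if base_var > 0 else base

        # planted effects: each coefficient is the correlation between the
        # site's activation trait and the scale's latent factor; the base
        # factor fills the remaining variance so f stays standardized
        effects = cfg.outcome_effects.get(scale, {})
        coef_sq = sum(c**2 for c in effects.values())
        if coef_sq > 1:
            raise InvalidArgumentError(
                f"outcome effects for {scale!r} imply correlation > 1"
            )
        f = np.sqrt(1.0 - coef_sq) * f0
        for site, coef in effects.items():
            a_std = (
                site_act[:, site_index[site]] / cfg.site_activation_sd
                if cfg.site_activation_sd > 0
                else np.zeros(n)
            )
            f = f + coef * a_std
        factors[:, m] = f

        alpha = cfg.outcome_reliability[scale]
        k = cfg.items_per_scale
        rbar = alpha / (k - (k - 1) * alpha)  # Spearman-Brown inversion
        # rounding to unit-spaced ordinal levels adds ~1/12 quantization
        # variance per item, attenuating the observed inter-item
        # correlation; inflate the latent correlation to compensate
        rbar_latent = min(rbar * (1.0 + 1.0 / 12.0), 0.999)
        load = np.sqrt(rbar_latent)
        eps = rng.standard_normal((n, k)) * np.sqrt(1.0 - rbar_latent)
        latent_items = load * f[:, None] + eps
        center = (cfg.item_levels + 1) / 2.0
        ordinal = np.clip(np.rint(center + latent_items), 1, cfg.item_levels)
        items[scale] = pd.DataFrame(
            ordinal,
            index=pids,
            columns=[f"{scale}_item{j+1}" for j in range(k)],
        )

    outcomes = OutcomeSet(items)
    truth = GroundTruth(
        traits=pd.DataFrame(
            np.column_stack([traits, state_trait]),
            index=pids,
            columns=[f"trait_{j}" for j in range(cfg.n_traits)] + ["state_trait"],
        ),
        site_activation=pd.DataFrame(site_act, index=pids, columns=list(ELECTRODES)),
        states=states,
        noiseless_sliders=noiseless_sliders,
        outcome_factors=pd.DataFrame(factors, index=pids, columns=scale_names),
    )
    return sessions, outcomes, truth


def plant_t7_effect(cfg: GeneratorConfig, strength: float) -> GeneratorConfig:
    """Link the intrinsic-motivation outcome negatively to T7 activation.

    Probands whose T7 site fires more strongly (across all five bands, via
    their T7 activation trait) get a lower ``intrinsic_motivation`` latent
    factor. ``strength`` in [0, 1] is the magnitude of the planted
    correlation between the T7 activation trait and the latent factor
    (1 = fully determined by T7). All other sites and scales are
    untouched, and ``strength=0`` leaves the generated cohort bit-identical
    to the base configuration.
    """
    if not (0.0 <= strength <= 1.0):
        raise InvalidArgumentError("strength must lie in [0, 1]")
    effects = {k: dict(v) for k, v in cfg.outcome_effects.items()}
    if strength > 0:
        eff = effects.setdefault("intrinsic_motivation", {})
        eff["T7"] = eff.get("T7", 0.0) - strength
    return replace(cfg, outcome_effects=effects)
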