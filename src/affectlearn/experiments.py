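"""End-to-end experiment drivers: cohort -> features -> CV -> comparison.

These helpers wire the full pipeline together for the two study designs the
package is validated on:

* a *planted-effect* cohort, where probands with stronger T7 activation
  have lower intrinsic motivation, so an outcome-level model has a real
  signal to recover; and
* a *null* cohort (no planted effect), where sensors and outcome scales
  share no latent driver, so any significant model-vs-baseline difference
  is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CVResult, loo_cv
from .features import feature_table, t7_derived
from .models import ModelSpec
from .synthetic import GeneratorConfig, generate_cohort, plant_t7_effect

#: Outcome scale targeted by the planted effect.
TARGET_SCALE = "intrinsic_motivation"


def outcome_dataset(
    cfg: GeneratorConfig, scale: str = TARGET_SCALE, sensor: str = "eeg"
) -> pd.DataFrame:
    """Generate a cohort and build the outcome-level labeled dataset.

    Returns a frame with ``proband_id``, ``sample_index`` (all 0), one
    column per feature, and the label column ``y`` (the scale score of
    ``scale``).
    """
    sessions, outcomes, _ = generate_cohort(cfg)
    feats = feature_table(sessions, sensor=sensor, level="outcome")
    y = outcomes.scores[scale]
    df = feats.reset_index()
    df["y"] = df["proband_id"].map(y).to_numpy()
    return df


@dataclass
class PlantedRunResult:
    result: CVResult
    t7_in_top10: int
    top10: list[str]


def _top10_t7_count(df: pd.DataFrame) -> tuple[int, list[str]]:
    feature_cols = [c for c in df.columns if c not in ("proband_id", "sample_index", "y")]
    y = df["y"].to_numpy(dtype=float)
    rs = {}
    for c in feature_cols:
        x = df[c].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0 or np.any(np.isnan(x)):
            continue
        rs[c] = abs(float(np.corrcoef(x, y)[0, 1]))
    top10 = sorted(rs, key=rs.get, reverse=True)[:10]
    return sum(t7_derived(name) for name in top10), top10


def planted_t7_run(
    seed: int,
    n_probands: int = 60,
    strength: float = 0.8,
    budget: int = 20,
) -> PlantedRunResult:
    """One planted-effect cohort evaluated with LOO ridge vs. baseline."""
    cfg = plant_t7_effect(
        GeneratorConfig(n_probands=n_probands, seed=seed), strength
    )
    df = outcome_dataset(cfg)
    spec = ModelSpec(family="ridge", seed=seed, budget=budget)
    result = loo_cv(df, spec)
    count, top10 = _top10_t7_count(df)
    return PlantedRunResult(result=result, t7_in_top10=count, top10=top10)


def t7_top10_counts(
    seeds, n_probands: int = 60, strength: float = 0.8
) -> list[int]:
    """T7-derived features among the top-10 |r| list, per seed (no CV)."""
    counts = []
    for seed in seeds:
        cfg = plant_t7_effect(
            GeneratorConfig(n_probands=n_probands, seed=int(seed)), strength
        )
        df = outcome_dataset(cfg)
        counts.append(_top10_t7_count(df)[0])
    return counts


def null_calibration(
    seeds, n_probands: int = 30, budget: int = 10
) -> list[float]:
    """Model-vs-baseline comparisons on null cohorts (no planted effect).

    Each seed generates an independent cohort with no sensor-outcome link;
    :func:`declares_significance` should fire on the returned comparisons
    only at (or below) the nominal rate.
    """
    out = []
    for seed in seeds:
        cfg = GeneratorConfig(n_probands=n_probands, seed=int(seed))
        df = outcome_dataset(cfg)
        spec = ModelSpec(family="ridge", seed=int(seed), budget=budget)
        res = loo_cv(df, spec)
        out.append(res.comparison)
    return out


def declares_significance(comparison) -> bool:
    """The pipeline's decision rule for 'predicts above baseline'.

    True when the paired test is significant at the 5% level *and* the
    model's errors are the smaller ones (positive effect size); a model that
    is significantly worse than the baseline is not a positive finding.
    """
    return bool(
        np.isfinite(comparison.p) and comparison.p < 0.05 and comparison.d > 0
    )
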