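"""Null distributions, percentile tests, and model discriminability.

Each constraint model, with its pull constant calibrated to the observed
cross-sex correlation, is simulated many times (1000 by default); the
(DSD, SK, DRS) statistics of each run form per-model null distributions.
Observed statistics are located within those distributions (midrank
percentile, two-tailed P); a model is rejected when the observed value
falls outside the two-tailed 95% confidence interval of its simulated
outcomes.  Pairwise discriminability is the probability that a statistic
generated under one model falls inside the 95% CI of another — the type
II error of assigning a statistic to a single model; 1 minus it is the
power to discriminate the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny
from .simulate import ModelName, MODELS, _as_model, simulate_tip_matrix
from .stats import STATISTIC_NAMES, SummaryStatistics, batch_statistics

ALPHA = 0.05


@dataclass
class NullDistribution:
    """Simulated values of one statistic under one model, with 95% CI."""

    model: ModelName
    statistic: str
    values: np.ndarray
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ci_low, self.ci_high = ci95(self.values)

    @property
    def n_runs(self) -> int:
        return len(self.values)

    def contains(self, x) -> np.ndarray:
        """Elementwise: inside the closed 95% CI?"""
        x = np.asarray(x, dtype=float)
        return (x >= self.ci_low) & (x <= self.ci_high)


def ci95(values) -> tuple[float, float]:
    """Empirical two-tailed 95% CI: 2.5th and 97.5th percentiles.

    Linear interpolation between order statistics (at 1000 runs the
    difference from nearest-rank quantiles is negligible).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 40:
        raise ValueError("95% CI ill-defined for fewer than 40 values")
    low, high = np.percentile(values, [2.5, 97.5])
    return float(low), float(high)


def percentile_of(observed: float, values) -> float:
    """Midrank percentile of observed within values, in [0, 1]."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty null distribution")
    below = np.count_nonzero(values < observed)
    ties = np.count_nonzero(values == observed)
    return (below + 0.5 * ties) / values.size


def two_tailed_p(percentile: float, n_runs: int | None = None) -> float:
    """Two-tailed P from a percentile: 2*min(pct, 1-pct).

    Floored at 1/n_runs when the observed value lies outside every
    simulated one (an empirical P of exactly 0 is not meaningful),
    capped at 1.
    """
    if not 0.0 <= percentile <= 1.0:
        raise ValueError(f"percentile {percentile} outside [0, 1]")
    p = 2.0 * min(percentile, 1.0 - percentile)
    if p == 0.0 and n_runs:
        p = 1.0 / n_runs
    return min(p, 1.0)


def build_null(tree: Phylogeny, model, c: float, n_runs: int = 1000,
               seed: int = 0) -> dict[str, NullDistribution]:
    """n_runs simulations under one calibrated model -> three nulls.

    Returns {"DSD": ..., "SK": ..., "DRS": ...}; deterministic given
    the seed.
    """
    model = _as_model(model)
    if n_runs < 40:
        raise ValueError("need n_runs >= 40 for a 95% CI")
    rng = np.random.default_rng(seed)
    male, female = simulate_tip_matrix(tree, model, c, n_runs, rng=rng)
    stats = batch_statistics(male, female)
    return {
        name: NullDistribution(model=model, statistic=name,
                               values=stats[name])
        for name in STATISTIC_NAMES
    }


@dataclass
class TestOutcome:
    model: ModelName
    statistic: str
    observed: float
    percentile: float
    p_two_tailed: float
    rejected: bool


def assess_models(observed: SummaryStatistics,
                  nulls: dict[ModelName, dict[str, NullDistribution]]
                  ) -> pd.DataFrame:
    """Locate observed statistics in every model's null distributions.

    Returns a table shaped like the percentile/(P) report: rows =
    statistics, one (percentile, P, rejected) triple per model.  A
    model×statistic cell is rejected when the observed value falls
    outside the model's two-tailed 95% CI.
    """
    rows = []
    for model in MODELS:
        if model not in nulls:
            raise ValueError(f"missing null distributions for {model.value}")
        for stat in STATISTIC_NAMES:
            null = nulls[model][stat]
            obs = observed[stat]
            pct = percentile_of(obs, null.values)
            p = two_tailed_p(pct, n_runs=null.n_runs)
            rejected = not bool(null.contains(obs))
            rows.append(TestOutcome(model, stat, obs, pct, p, rejected))
    df = pd.DataFrame(
        [
            {
                "model": o.model.value,
                "statistic": o.statistic,
                "observed": o.observed,
                "percentile": o.percentile,
                "p_two_tailed": o.p_two_tailed,
                "rejected": o.rejected,
            }
            for o in rows
        ]
    )
    return df


def discrimination_matrix(
        nulls: dict[ModelName, dict[str, NullDistribution]]
) -> pd.DataFrame:
    """Type-II-error table for every ordered model pair and statistic.

    Cell value: fraction of the generating model's simulated statistic
    values that fall inside the reference model's 95% CI.  For a model
    against itself this is ~0.95 by construction; 1 minus the value is
    the power to discriminate the pair.
    """
    rows = []
    for gen, gen_nulls in nulls.items():
        for ref, ref_nulls in nulls.items():
            for stat in STATISTIC_NAMES:
                frac = float(
                    ref_nulls[stat].contains(gen_nulls[stat].values).mean()
                )
                rows.append(
                    {
                        "generating": _as_model(gen).value,
                        "reference": _as_model(ref).value,
                        "statistic": stat,
                        "type2_probability": frac,
                        "power": 1.0 - frac,
                    }
                )
    return pd.DataFrame(rows)


def verdicts(assessment: pd.DataFrame) -> dict[str, str]:
    """Per-model verdict applying the joint decision rule.

    A model is "rejected" if any statistic rejects it.  The best support
    for a model requires both surviving and all alternatives being
    rejected: a unique survivor is "supported"; when no model or several
    models survive, the survivors are "indeterminate".
    """
    out = {}
    survivors = []
    for model in assessment["model"].unique():
        sub = assessment[assessment["model"] == model]
        if sub["rejected"].any():
            out[model] = "rejected"
        else:
            survivors.append(model)
    label = "supported" if len(survivors) == 1 else "indeterminate"
    for model in survivors:
        out[model] = label
    return out
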