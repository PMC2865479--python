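"""Descriptive statistics that discriminate the constraint models.

Three statistics are computed from the standardized joint distribution
of male and female extant scores:

- DSD: SD(male) - SD(female).  The constrained sex diversifies less, so
  DSD tends positive when females are constrained and negative when
  males are.
- SK: the D'Agostino-Pearson normalized skewness Zg1 of the pooled
  male + female values; the pooled distribution skews toward the more
  variable, independently evolving sex.
- DRS: slope of the female-on-male OLS regression minus the slope of
  the male-on-female regression; equivalently r*(SDf/SDm - SDm/SDf).

All three are invariant to species permutation and to common affine
transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TipPhenotypes

STATISTIC_NAMES = ("DSD", "SK", "DRS")


@dataclass(frozen=True)
class SummaryStatistics:
    dsd: float
    sk: float
    drs: float

    def as_dict(self) -> dict[str, float]:
        return {"DSD": self.dsd, "SK": self.sk, "DRS": self.drs}

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


def standardize_joint(tips: TipPhenotypes) -> TipPhenotypes:
    """Standardize the pooled 2N male+female values to mean 0, SD 1.

    The male/female pairing and species order are preserved; the
    transform is affine-invariant (standardizing a*x + b gives the same
    result as standardizing x).
    """
    pooled = np.concatenate([tips.male, tips.female])
    mu = pooled.mean()
    sd = pooled.std(ddof=1)
    if sd == 0:
        raise ValueError("pooled scores have zero variance")
    return TipPhenotypes(
        species=list(tips.species),
        male=(tips.male - mu) / sd,
        female=(tips.female - mu) / sd,
    )


def dsd(tips: TipPhenotypes) -> float:
    """Difference of sample standard deviations, male minus female."""
    return float(tips.male.std(ddof=1) - tips.female.std(ddof=1))


def _zg1_core(sqrt_b1: np.ndarray, n: int) -> np.ndarray:
    """D'Agostino (1970) normalizing transformation of sample skewness."""
    y = sqrt_b1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (3.0 * (n ** 2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
             / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0)))
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(np.log(np.sqrt(w2)))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    ya = y / alpha
    return delta * np.log(ya + np.sqrt(ya * ya + 1.0))


def skew_zg1(values) -> float:
    """Normalized sample skewness Zg1, ~N(0,1) under normality.

    sqrt(b1) = m3 / m2^(3/2) with central moments using denominator n,
    then the D'Agostino normalizing transformation.  Requires n >= 8
    (the transformation constants are undefined below that) and nonzero
    variance.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"Zg1 requires n >= 8, got {n}")
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 == 0:
        raise ValueError("Zg1 undefined for zero-variance input")
    sqrt_b1 = np.mean(d ** 3) / m2 ** 1.5
    return float(_zg1_core(np.asarray(sqrt_b1), n))


def drs(tips: TipPhenotypes) -> float:
    """Difference of the reciprocal regression slopes.

    OLS slope of female on male minus OLS slope of male on female;
    closed form r*(SDf/SDm) - r*(SDm/SDf).
    """
    if tips.n_species < 3:
        raise ValueError("DRS requires at least 3 species")
    sm = tips.male.std(ddof=1)
    sf = tips.female.std(ddof=1)
    if sm == 0 or sf == 0:
        raise ValueError("DRS undefined with zero variance in either sex")
    r = float(np.corrcoef(tips.male, tips.female)[0, 1])
    return r * (sf / sm) - r * (sm / sf)


def compute_statistics(tips: TipPhenotypes) -> SummaryStatistics:
    """Standardize jointly, then compute (DSD, SK, DRS).

    DSD and DRS are themselves invariant to the joint standardization,
    as are the higher moments inside SK; standardization is retained so
    the reported values live on the standardized scale.
    """
    if tips.n_species < 4:
        raise ValueError(
            "need >= 4 species so the pooled sample has >= 8 values"
        )
    std = standardize_joint(tips)
    pooled = np.concatenate([std.male, std.female])
    return SummaryStatistics(
        dsd=dsd(std), sk=skew_zg1(pooled), drs=drs(std)
    )


# -- vectorized forms used for 1000-run null distributions ------------


def batch_zg1(values: np.ndarray) -> np.ndarray:
    """Zg1 along the last axis of a (runs, n) array."""
    x = np.asarray(values, dtype=float)
    n = x.shape[-1]
    if n < 8:
        raise ValueError(f"Zg1 requires n >= 8, got {n}")
    d = x - x.mean(axis=-1, keepdims=True)
    m2 = np.mean(d ** 2, axis=-1)
    sqrt_b1 = np.mean(d ** 3, axis=-1) / m2 ** 1.5
    return _zg1_core(sqrt_b1, n)


def batch_statistics(male: np.ndarray, female: np.ndarray
                     ) -> dict[str, np.ndarray]:
    """(DSD, SK, DRS) per run for (runs, n_tips) score matrices.

    Equivalent to calling compute_statistics on each run: each run's
    pooled 2N values are standardized jointly before the statistics are
    taken (DSD scales with the pooled SD; SK and DRS are affine
    invariant but computed on the same standardized values).
    """
    if male.shape != female.shape or male.ndim != 2:
        raise ValueError("male and female must be (runs, n_tips) arrays")
    if male.shape[1] < 4:
        raise ValueError("need >= 4 tips")
    pooled_raw = np.concatenate([male, female], axis=1)
    mu = pooled_raw.mean(axis=1, keepdims=True)
    sd = pooled_raw.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("pooled scores have zero variance in some run")
    male = (male - mu) / sd
    female = (female - mu) / sd
    sm = male.std(axis=1, ddof=1)
    sf = female.std(axis=1, ddof=1)
    mc = male - male.mean(axis=1, keepdims=True)
    fc = female - female.mean(axis=1, keepdims=True)
    num = (mc * fc).sum(axis=1)
    den = np.sqrt((mc * mc).sum(axis=1) * (fc * fc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den == 0, 1.0, num / den)
        dsd_v = sm - sf
        drs_v = r * (sf / sm) - r * (sm / sf)
    sk_v = batch_zg1(np.concatenate([male, female], axis=1))
    return {"DSD": dsd_v, "SK": sk_v, "DRS": drs_v}
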