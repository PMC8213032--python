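"""Salt -> blood pressure -> stroke-incidence exposure modelling.

Three pieces:

* :class:`SaltEffectModel` — the linear salt/SBP dose-response (pooled slope
  4.18 mmHg per 4.4 g/day) split into hypertensive and normotensive stratum
  slopes, rescaled at construction so their prevalence-weighted mean equals
  the pooled slope at a reference hypertension prevalence.
* :class:`SBPStratifiedDistribution` — a normal SBP distribution whose two
  strata (SBP < 140 vs >= 140 mmHg, membership fixed by pre-shift SBP) are
  shifted downward by stratum-specific amounts.
* :func:`pif` — the distribution-shift potential impact fraction

      PIF = 1 - ∫ RR(x - s(x)) P(x) dx / ∫ RR(x) P(x) dx

  over [90, 220] mmHg with the stratum split at 140 mmHg, where s(x) is the
  stratum shift.  Writing the shifted-distribution integral in pre-shift
  exposure space keeps the truncation limits on the original distribution,
  so a null shift or a flat relative risk gives exactly zero.

The relative risk is log-linear per 10 mmHg above a theoretical minimum of
115 mmHg, the convention used by comparative-risk-assessment studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .errors import InvalidConfigError

#: default pooled dose-response: 4.18 mmHg SBP per 4.4 g/day of salt
POOLED_SLOPE = 4.18 / 4.4
#: default raw stratum effects, mmHg per 4.4 g/day, before calibration
RAW_SLOPE_HYP = 5.39 / 4.4
RAW_SLOPE_NORM = 2.42 / 4.4
#: reference hypertension prevalence used for slope calibration (adult
#: survey value, 30-69-year-olds)
REFERENCE_HYPERTENSION_PREVALENCE = 0.306

HYPERTENSION_THRESHOLD = 140.0


@dataclass(frozen=True)
class RRFunction:
    """Log-linear relative risk of stroke per 10 mmHg of SBP above TMREL."""

    rr_per_10mmhg: float
    tmrel: float = 115.0
    x_min: float = 90.0
    x_max: float = 220.0
    split: float = HYPERTENSION_THRESHOLD

    def __post_init__(self) -> None:
        if self.rr_per_10mmhg < 1.0:
            raise InvalidConfigError(
                f"rr_per_10mmhg must be >= 1, got {self.rr_per_10mmhg}")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        excess = np.clip(x - self.tmrel, 0.0, None)
        return np.power(self.rr_per_10mmhg, excess / 10.0)


@dataclass(frozen=True)
class SaltEffectModel:
    """Linear salt/SBP dose-response with hypertension-stratified slopes.

    Slopes are mmHg per g/day of salt reduced.  Invariant enforced at
    construction: the prevalence-weighted mean of the stratum slopes at
    ``reference_prevalence`` equals ``slope_overall``.
    """

    slope_overall: float
    slope_hyp: float
    slope_norm: float
    reference_prevalence: float = REFERENCE_HYPERTENSION_PREVALENCE
    proportional_reduction: bool = True

    def __post_init__(self) -> None:
        if not (self.slope_hyp >= self.slope_norm >= 0.0):
            raise InvalidConfigError(
                "stratum slopes must satisfy slope_hyp >= slope_norm >= 0")
        p = self.reference_prevalence
        weighted = p * self.slope_hyp + (1.0 - p) * self.slope_norm
        if abs(weighted - self.slope_overall) > 1e-9:
            raise InvalidConfigError(
                "stratum slopes are not calibrated: prevalence-weighted mean "
                f"{weighted!r} != slope_overall {self.slope_overall!r}")

    @classmethod
    def calibrated(cls,
                   slope_overall: float = POOLED_SLOPE,
                   raw_slope_hyp: float = RAW_SLOPE_HYP,
                   raw_slope_norm: float = RAW_SLOPE_NORM,
                   reference_prevalence: float = REFERENCE_HYPERTENSION_PREVALENCE,
                   ) -> "SaltEffectModel":
        """Rescale raw stratum slopes so their weighted mean is the pooled slope."""
        if slope_overall < 0:
            raise InvalidConfigError("slope_overall must be >= 0")
        weighted = (reference_prevalence * raw_slope_hyp
                    + (1.0 - reference_prevalence) * raw_slope_norm)
        if weighted <= 0:
            raise InvalidConfigError("raw stratum slopes must be positive")
        c = slope_overall / weighted
        return cls(slope_overall=slope_overall,
                   slope_hyp=raw_slope_hyp * c,
                   slope_norm=raw_slope_norm * c,
                   reference_prevalence=reference_prevalence)


def delta_sbp(delta_salt: float, effect: SaltEffectModel, stratum: str = "overall",
              prevalence: float | None = None) -> float:
    """Mean SBP reduction (mmHg) for a salt reduction of ``delta_salt`` g/day.

    ``stratum`` is ``"norm"``, ``"hyp"`` or ``"overall"``; the overall effect
    is the prevalence-weighted combination of the stratum slopes (defaulting
    to the effect model's reference prevalence).  Salt increases are out of
    scope and rejected.
    """
    if delta_salt < 0:
        raise ValueError(f"delta_salt must be >= 0, got {delta_salt}")
    if stratum == "norm":
        slope = effect.slope_norm
    elif stratum == "hyp":
        slope = effect.slope_hyp
    elif stratum == "overall":
        p = effect.reference_prevalence if prevalence is None else prevalence
        slope = p * effect.slope_hyp + (1.0 - p) * effect.slope_norm
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    return slope * delta_salt


@dataclass(frozen=True)
class SBPStratifiedDistribution:
    """Normal SBP distribution with stratum-specific downward shifts.

    ``shift_norm`` applies to people whose pre-shift SBP is below 140 mmHg,
    ``shift_hyp`` to those at or above; stratum membership is fixed by the
    pre-shift value, so shifted hypertensive individuals may end below 140.
    """

    mu: float
    sigma: float
    shift_norm: float = 0.0
    shift_hyp: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidConfigError(f"sigma must be > 0, got {self.sigma}")
        if self.shift_norm < 0 or self.shift_hyp < 0:
            raise InvalidConfigError("shifts must be >= 0 for salt reductions")

    def shifted(self, shift_norm: float, shift_hyp: float) -> "SBPStratifiedDistribution":
        return replace(self, shift_norm=shift_norm, shift_hyp=shift_hyp)

    @property
    def truncation_mass(self) -> float:
        """Pre-shift probability mass outside the [90, 220] mmHg window."""
        z_lo = (90.0 - self.mu) / self.sigma
        z_hi = (220.0 - self.mu) / self.sigma
        return float(norm.cdf(z_lo) + norm.sf(z_hi))


def hypertension_prevalence(dist: SBPStratifiedDistribution) -> float:
    """Fraction of the post-shift distribution at SBP >= 140 mmHg.

    Only the hypertensive stratum can remain above the threshold (shifts are
    non-negative), so this is the pre-shift mass above 140 + shift_hyp.
    """
    z = (HYPERTENSION_THRESHOLD + dist.shift_hyp - dist.mu) / dist.sigma
    return float(norm.sf(z))


def hypertension_prevalence_batch(mu: np.ndarray, sigma: np.ndarray | float,
                                  shift_hyp: np.ndarray | float = 0.0) -> np.ndarray:
    """Vectorised :func:`hypertension_prevalence` over cohort arrays."""
    z = (HYPERTENSION_THRESHOLD + np.asarray(shift_hyp) - np.asarray(mu)) / np.asarray(sigma)
    return norm.sf(z)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.linspace(lo, hi, n + 1)


def _rr_weighted_mass(rr: RRFunction, mu: np.ndarray, sigma: np.ndarray,
                      shift_norm: np.ndarray, shift_hyp: np.ndarray,
                      step: float) -> np.ndarray:
    """∫ RR(x - s(x)) P(x) dx over [x_min, x_max], split exactly at 140.

    Composite trapezoid on a fixed mmHg grid; ``mu``/``sigma``/shifts
    broadcast over a leading case axis.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), mu.shape[:1])[:, None]
    shift_norm = np.broadcast_to(np.asarray(shift_norm, dtype=float), mu.shape[:1])[:, None]
    shift_hyp = np.broadcast_to(np.asarray(shift_hyp, dtype=float), mu.shape[:1])[:, None]

    total = 0.0
    for lo, hi, shift in ((rr.x_min, rr.split, shift_norm),
                          (rr.split, rr.x_max, shift_hyp)):
        x = _grid(lo, hi, step)[None, :]
        dens = np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
        f = rr(x - shift) * dens
        total = total + np.trapezoid(f, dx=step, axis=1)
    return total


def pif(rr: RRFunction, before: SBPStratifiedDistribution,
        after: SBPStratifiedDistribution, grid_step: float = 0.1) -> float:
    """Potential impact fraction of the SBP shift on stroke incidence.

    ``before`` and ``after`` must share ``mu`` and ``sigma``; ``after``
    carries the stratum shifts.  PIF < 1 always; PIF = 0 when the shifts
    are zero or the relative risk is flat.
    """
    if before.mu != after.mu or before.sigma != after.sigma:
        raise ValueError("before/after distributions must share mu and sigma")
    den = _rr_weighted_mass(rr, before.mu, before.sigma,
                            before.shift_norm, before.shift_hyp, grid_step)
    num = _rr_weighted_mass(rr, after.mu, after.sigma,
                            after.shift_norm, after.shift_hyp, grid_step)
    return float(1.0 - num[0] / den[0])


def _pif_core(mu, sigma, shift_norm, shift_hyp, rr: RRFunction,
              step: float) -> np.ndarray:
    """Single-pass PIF on a case axis: shared density, closed-form log-linear RR."""
    k = np.log(rr.rr_per_10mmhg) / 10.0
    num = 0.0
    den = 0.0
    for lo, hi, shift in ((rr.x_min, rr.split, shift_norm),
                          (rr.split, rr.x_max, shift_hyp)):
        x = _grid(lo, hi, step)
        dens = np.exp(-0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2) \
            / (sigma[:, None] * np.sqrt(2.0 * np.pi))
        rr0 = np.exp(k * np.clip(x - rr.tmrel, 0.0, None))
        rrs = np.exp(k * np.clip(x[None, :] - shift[:, None] - rr.tmrel, 0.0, None))
        den = den + np.trapezoid(rr0[None, :] * dens, dx=step, axis=1)
        num = num + np.trapezoid(rrs * dens, dx=step, axis=1)
    return 1.0 - num / den


def pif_batch(mu: np.ndarray, sigma: np.ndarray | float,
              shift_norm: np.ndarray, shift_hyp: np.ndarray,
              rr: RRFunction, grid_step: float = 0.1,
              chunk: int = 4000) -> np.ndarray:
    """Vectorised PIF for arrays of cohorts/years (null shifts in denominator).

    Duplicate (mu, sigma, shift) cases — common when single-year cohorts share
    an age band — are computed once.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    n = mu.size
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    shift_norm = np.broadcast_to(np.asarray(shift_norm, dtype=float).ravel(), (n,))
    shift_hyp = np.broadcast_to(np.asarray(shift_hyp, dtype=float).ravel(), (n,))
    cases = np.column_stack([mu, sigma, shift_norm, shift_hyp])
    uniq, inverse = np.unique(cases, axis=0, return_inverse=True)
    out = np.empty(uniq.shape[0])
    for i in range(0, uniq.shape[0], chunk):
        s = slice(i, min(i + chunk, uniq.shape[0]))
        out[s] = _pif_core(uniq[s, 0], uniq[s, 1], uniq[s, 2], uniq[s, 3],
                           rr, grid_step)
    return out[inverse.ravel()]


def incidence_multiplier_schedule(salt_by_year: np.ndarray,
                                  effect: SaltEffectModel,
                                  rr: RRFunction,
                                  dist: SBPStratifiedDistribution,
                                  effect_fraction: np.ndarray | None = None,
                                  grid_step: float = 0.1) -> np.ndarray:
    """Per-year (1 - PIF) incidence multipliers along a salt trajectory.

    The first entry of ``salt_by_year`` is the baseline intake; every later
    entry must not exceed it.  ``effect_fraction`` optionally attenuates the
    achieved SBP shift year by year (intervention decay).  The multiplier is
    1 in the base year and non-increasing while salt declines.
    """
    salt = np.asarray(salt_by_year, dtype=float)
    delta = salt[0] - salt
    if (delta < -1e-9).any():
        raise ValueError("salt trajectory rises above its baseline value")
    delta = np.clip(delta, 0.0, None)
    if effect_fraction is not None:
        frac = np.asarray(effect_fraction, dtype=float)
        if frac.shape != salt.shape:
            raise ValueError("effect_fraction must align with salt_by_year")
        delta = delta * frac
    shifts_norm = effect.slope_norm * delta
    shifts_hyp = effect.slope_hyp * delta
    pifs = pif_batch(np.full(salt.shape, dist.mu), dist.sigma,
                     shifts_norm, shifts_hyp, rr, grid_step=grid_step)
    return 1.0 - pifs
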