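"""Five-state stroke Markov model, run per disease, sex and age cohort.

States: healthy, diseased (chronic stroke survivor), dead within 28 days of
an incident event (acute), dead from chronic stroke, dead from other causes.
Death states are absorbing; there is no remission or recurrence.

Within one annual cycle the event order is:

1. incidence among the healthy (rate ``incidence`` times the intervention
   multiplier, converted to a probability),
2. 28-day case fatality ``acute_cf`` among that cycle's incident cases,
3. first-year (months 2-12) chronic excess mortality ``chronic_cf_year1``
   among the acute survivors, and long-term chronic excess mortality
   ``chronic_excess`` among the previously diseased,
4. cause-deleted background mortality (all-cause minus this disease's own
   contribution) among the remaining healthy and previously diseased.

Persons are conserved exactly at every step; a negative compartment raises
rather than being clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConservationError, InvalidConfigError


@dataclass(frozen=True)
class DiseaseRates:
    """Transition hazards for one cohort-year of one disease.

    ``incidence``, ``chronic_cf_year1``, ``chronic_excess`` and ``all_cause``
    are rates per person-year; ``acute_cf`` is the fraction of incident cases
    dying within 28 days.  ``disease_mortality`` is this disease's own
    contribution to all-cause mortality, subtracted to obtain the
    cause-deleted background rate.  Remission is structurally zero.
    """

    incidence: float
    acute_cf: float
    chronic_cf_year1: float
    chronic_excess: float
    all_cause: float
    disease_mortality: float = 0.0
    remission: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.acute_cf <= 1.0:
            raise InvalidConfigError(f"acute_cf must be in [0,1], got {self.acute_cf}")
        for name in ("incidence", "chronic_cf_year1", "chronic_excess",
                     "all_cause", "disease_mortality"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.remission != 0.0:
            raise InvalidConfigError("remission is fixed at 0 in this model")

    @property
    def background(self) -> float:
        """Cause-deleted background mortality rate."""
        return max(self.all_cause - self.disease_mortality, 0.0)


@dataclass
class StateVector:
    """Occupancy of the five health states (persons); death states cumulative."""

    healthy: float
    diseased: float = 0.0
    dead_acute: float = 0.0
    dead_disease: float = 0.0
    dead_other: float = 0.0

    @property
    def total(self) -> float:
        return (self.healthy + self.diseased + self.dead_acute
                + self.dead_disease + self.dead_other)

    @property
    def alive(self) -> float:
        return self.healthy + self.diseased


def rate_to_prob(rate: float | np.ndarray, dt: float = 1.0) -> float | np.ndarray:
    """Convert a hazard rate to a per-cycle probability: 1 - exp(-rate*dt)."""
    rate = np.asarray(rate, dtype=float)
    if (rate < 0).any():
        raise ValueError("rates must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = -np.expm1(-rate * dt)
    return float(out) if out.ndim == 0 else out


def _step_arrays(healthy, diseased, incidence, acute_cf, chronic_cf_year1,
                 chronic_excess, background, multiplier):
    """One annual cycle on (broadcastable) arrays.

    Returns (healthy', diseased', incident, deaths_acute, deaths_chronic,
    deaths_other).  Background mortality applies to the remaining healthy and
    the previously diseased; the incident-year cohort faces acute and
    first-year chronic case fatality instead.
    """
    incident = healthy * rate_to_prob(incidence * multiplier)
    deaths_acute = incident * acute_cf
    survivors = incident - deaths_acute
    deaths_year1 = survivors * rate_to_prob(chronic_cf_year1)
    deaths_old = diseased * rate_to_prob(chronic_excess)
    p_bg = rate_to_prob(background)
    healthy_rem = healthy - incident
    diseased_rem = diseased - deaths_old
    deaths_other = (healthy_rem + diseased_rem) * p_bg
    healthy_next = healthy_rem * (1.0 - p_bg)
    diseased_next = diseased_rem * (1.0 - p_bg) + survivors - deaths_year1
    deaths_chronic = deaths_year1 + deaths_old
    return (healthy_next, diseased_next, incident, deaths_acute,
            deaths_chronic, deaths_other)


def step_cohort(state: StateVector, rates: DiseaseRates,
                incidence_multiplier: float = 1.0) -> StateVector:
    """Advance one cohort by one annual cycle.

    The multiplier scales incidence (1 - PIF from the exposure model) and
    must lie in (0, 1].  Conservation of persons is checked to 1e-9 relative;
    a negative compartment raises :class:`ConservationError`.
    """
    if not 0.0 < incidence_multiplier <= 1.0:
        raise ValueError(
            f"incidence_multiplier must be in (0, 1], got {incidence_multiplier}")
    if state.healthy < 0 or state.diseased < 0:
        raise ValueError("state occupancies must be >= 0")
    h, d, inc, da, dc, do = _step_arrays(
        state.healthy, state.diseased, rates.incidence, rates.acute_cf,
        rates.chronic_cf_year1, rates.chronic_excess, rates.background,
        incidence_multiplier)
    new = StateVector(healthy=float(h), diseased=float(d),
                      dead_acute=state.dead_acute + float(da),
                      dead_disease=state.dead_disease + float(dc),
                      dead_other=state.dead_other + float(do))
    if min(new.healthy, new.diseased) < 0:
        raise ConservationError("negative compartment after cycle")
    scale = max(abs(state.total), 1.0)
    if abs(new.total - state.total) > 1e-9 * scale:
        raise ConservationError(
            f"persons not conserved: {state.total} -> {new.total}")
    return new


@dataclass
class DiseaseTrajectories:
    """Per cohort-year outputs of :func:`simulate_disease` (arrays (C, T))."""

    incident: np.ndarray
    deaths_acute: np.ndarray
    deaths_chronic: np.ndarray
    deaths_other: np.ndarray
    alive_start: np.ndarray
    prevalent_end: np.ndarray
    #: mid-cycle diseased fraction among the alive, for HALY weighting
    prevalence_proportion: np.ndarray

    @property
    def deaths_disease(self) -> np.ndarray:
        return self.deaths_acute + self.deaths_chronic

    def mortality_rate(self) -> np.ndarray:
        """Disease-attributable mortality rate per cohort-year (hazard scale)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(self.alive_start > 0,
                         self.deaths_disease / np.maximum(self.alive_start, 1e-300),
                         0.0)
        q = np.clip(q, 0.0, 1.0 - 1e-12)
        return -np.log1p(-q)


def simulate_disease(healthy0: np.ndarray, diseased0: np.ndarray,
                     rates: dict[str, np.ndarray],
                     multipliers: np.ndarray,
                     active: np.ndarray | None = None) -> DiseaseTrajectories:
    """Run the Markov model for C cohorts over T annual cycles (vectorised).

    ``rates`` maps ``incidence``, ``acute_cf``, ``chronic_cf_year1``,
    ``chronic_excess`` and ``background`` to (C, T) arrays already aligned to
    each cohort's current age (the caller handles ageing across bands).
    ``multipliers`` is the (C, T) intervention incidence multiplier;
    ``active`` marks cohort-years still being simulated (e.g. age <= 99) —
    inactive cells freeze the cohort.  Missing (NaN) rates for an active
    cohort-year raise.
    """
    healthy = np.asarray(healthy0, dtype=float).copy()
    diseased = np.asarray(diseased0, dtype=float).copy()
    C = healthy.shape[0]
    T = multipliers.shape[1]
    required = ("incidence", "acute_cf", "chronic_cf_year1",
                "chronic_excess", "background")
    for key in required:
        if key not in rates:
            raise ValueError(f"missing rate table {key!r}")
        if rates[key].shape != (C, T):
            raise ValueError(f"rate table {key!r} has shape {rates[key].shape}, "
                             f"expected {(C, T)}")
    if active is None:
        active = np.ones((C, T), dtype=bool)
    for key in required:
        if np.isnan(rates[key][active]).any():
            raise ValueError(f"missing (NaN) {key} for an active cohort-year")
    if ((multipliers[active] <= 0) | (multipliers[active] > 1)).any():
        raise ValueError("incidence multipliers must lie in (0, 1]")

    out = {name: np.zeros((C, T)) for name in
           ("incident", "deaths_acute", "deaths_chronic", "deaths_other",
            "alive_start", "prevalent_end", "prevalence_proportion")}
    total0 = healthy + diseased
    dead = np.zeros(C)
    for t in range(T):
        act = active[:, t]
        out["alive_start"][:, t] = healthy + diseased
        h2, d2, inc, da, dc, do = _step_arrays(
            healthy, diseased,
            np.where(act, rates["incidence"][:, t], 0.0),
            np.where(act, rates["acute_cf"][:, t], 0.0),
            np.where(act, rates["chronic_cf_year1"][:, t], 0.0),
            np.where(act, rates["chronic_excess"][:, t], 0.0),
            np.where(act, rates["background"][:, t], 0.0),
            np.where(act, multipliers[:, t], 1.0))
        if (h2 < 0).any() or (d2 < 0).any():
            raise ConservationError("negative compartment during simulation")
        alive_mid = (healthy + diseased + h2 + d2) / 2.0
        dis_mid = (diseased + d2 + inc - da) / 2.0
        with np.errstate(invalid="ignore"):
            prop = np.where(alive_mid > 0, dis_mid / np.maximum(alive_mid, 1e-300), 0.0)
        healthy, diseased = h2, d2
        dead = dead + da + dc + do
        drift = np.abs(healthy + diseased + dead - total0)
        if (drift > 1e-9 * np.maximum(total0, 1.0)).any():
            raise ConservationError("persons not conserved during simulation")
        out["incident"][:, t] = inc
        out["deaths_acute"][:, t] = da
        out["deaths_chronic"][:, t] = dc
        out["deaths_other"][:, t] = do
        out["prevalent_end"][:, t] = diseased
        out["prevalence_proportion"][:, t] = prop
    return DiseaseTrajectories(**out)
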