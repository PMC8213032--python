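"""Multi-cohort lifetable: life years, HALYs and discounting.

Two identical populations are aged forward; the intervention arm's all-cause
mortality differs only by the disease-mortality deltas handed over from the
disease models.  Person-years use the half-cycle correction (mid-cycle alive
count); health-adjusted life years down-weight person-years for background
comorbidity and for time lived with each modelled disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Lifetable:
    """Arrays per cohort (axis 0) and cycle year (axis 1)."""

    alive: np.ndarray          # (C, T+1), cohort survivors at cycle starts
    person_years: np.ndarray   # (C, T), half-cycle corrected
    mortality: np.ndarray      # (C, T), adjusted rates actually applied


def build_lifetable(population: np.ndarray, all_cause: np.ndarray,
                    delta_disease_mortality: np.ndarray | None = None,
                    active: np.ndarray | None = None) -> Lifetable:
    """Age C cohorts through T annual cycles under adjusted mortality.

    ``all_cause`` is the (C, T) baseline mortality rate;
    ``delta_disease_mortality`` (<= 0 for beneficial interventions) is added
    for the intervention arm.  Adjusted rates that would fall below zero are
    clipped to zero with a logged warning.  ``active`` masks cohort-years
    beyond the simulation's age cap; inactive cells accrue no person-years.
    """
    population = np.asarray(population, dtype=float)
    all_cause = np.asarray(all_cause, dtype=float)
    C, T = all_cause.shape
    if delta_disease_mortality is None:
        delta_disease_mortality = np.zeros((C, T))
    rate = all_cause + np.asarray(delta_disease_mortality, dtype=float)
    n_neg = int((rate < 0).sum())
    if n_neg:
        logger.warning("clipped %d negative adjusted mortality rates to 0", n_neg)
        rate = np.clip(rate, 0.0, None)
    if active is None:
        active = np.ones((C, T), dtype=bool)
    rate = np.where(active, rate, 0.0)

    alive = np.empty((C, T + 1))
    alive[:, 0] = population
    for t in range(T):
        alive[:, t + 1] = alive[:, t] * np.exp(-rate[:, t])
    person_years = (alive[:, :-1] + alive[:, 1:]) / 2.0 * active
    return Lifetable(alive=alive, person_years=person_years, mortality=rate)


def compute_halys(person_years: np.ndarray,
                  stroke_prevalence: Mapping[str, np.ndarray],
                  dw_stroke: Mapping[str, float],
                  dw_background: np.ndarray) -> np.ndarray:
    """Health-adjusted life years per cohort-year.

    halys = PY * (1 - dw_background) - sum_d PY * prevalence_d * dw_d.
    ``dw_background`` broadcasts over years ((C,) or (C, T)).  A combined
    disability rate reaching 1 anywhere is an error.
    """
    py = np.asarray(person_years, dtype=float)
    bg = np.asarray(dw_background, dtype=float)
    if bg.ndim == 1:
        bg = bg[:, None]
    combined = np.broadcast_to(bg, py.shape).copy()
    for disease, prev in stroke_prevalence.items():
        w = dw_stroke[disease]
        if not 0.0 <= w < 1.0:
            raise ValueError(f"disability weight for {disease} must be in [0,1)")
        combined = combined + np.asarray(prev, dtype=float) * w
    if (combined >= 1.0).any():
        raise ValueError("combined disability (YLD) rate reaches 1")
    return py * (1.0 - combined)


def discount_stream(values: np.ndarray, rate: float, base_year: int,
                    years: np.ndarray) -> np.ndarray:
    """Discount per-year amounts to the base year at a constant annual rate.

    ``years`` are calendar years aligned with the last axis of ``values``;
    base-year amounts are undiscounted.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    years = np.asarray(years)
    factors = (1.0 + rate) ** (years - base_year)
    return np.asarray(values, dtype=float) / factors
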