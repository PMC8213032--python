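"""Scenario definitions, model orchestration and probabilistic uncertainty.

Nine policy scenarios: linear reduction of each cohort's salt intake to a
target (8, 7 or 5 g/day) by a target year (2025 or 2030), evaluated to the
target year (scenarios 1-3), sustained over the remaining lifetime (4-6), or
phased out in 5-year blocks after the target year (7-9).

The proportional multistate lifetable couples the modules: exposure shifts ->
potential impact fractions -> disease Markov models (both arms) -> mortality
deltas into the lifetable -> life years, HALYs and cost offsets.  The
probabilistic sensitivity analysis redraws the salt-SBP slope (normal), the
relative risks (lognormal) and unit costs (gamma) and reports empirical
2.5/97.5 percentile uncertainty intervals; draws are shared across scenarios
so per-draw scenario differences are coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .disease import DiseaseTrajectories, simulate_disease
from .economics import CostModel, cost_savings, summarise_costs
from .errors import InvalidConfigError, SchemaError
from .exposure import (RRFunction, SaltEffectModel,
                       hypertension_prevalence_batch, pif_batch)
from .fixtures import (AGE_BAND_LOWER, DISEASES, N_AGE_BANDS, SEXES,
                       FixtureConfig, FixtureTables, generate_fixtures)
from .lifetable import build_lifetable, compute_halys, discount_stream

BASE_YEAR = 2019
MAX_AGE = 100
_T_MAX = MAX_AGE - 25  # youngest cohort (25) reaches the age cap in 75 cycles

#: central relative risks per 10 mmHg of SBP above TMREL; haemorrhagic
#: stroke carries the steeper blood-pressure gradient
DEFAULT_RR = {"ischaemic": 1.45, "haemorrhagic": 1.6}


@dataclass(frozen=True)
class ScenarioSpec:
    """One salt-reduction policy scenario."""

    id: int
    target: float             # g/day
    target_year: int
    horizon: str = "to_target_year"   # or "lifetime"
    decay: bool = False
    decay_mode: str = "linear"        # "linear" 100/75/50/25/0 or "geometric"

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise InvalidConfigError(f"target must be > 0, got {self.target}")
        if self.target_year <= BASE_YEAR:
            raise InvalidConfigError(
                f"target_year must be > {BASE_YEAR}, got {self.target_year}")
        if self.horizon not in ("to_target_year", "lifetime"):
            raise InvalidConfigError(f"unknown horizon {self.horizon!r}")
        if self.decay_mode not in ("linear", "geometric"):
            raise InvalidConfigError(f"unknown decay_mode {self.decay_mode!r}")
        if self.decay and self.horizon != "lifetime":
            raise InvalidConfigError("decay scenarios require a lifetime horizon")


DEFAULT_SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, 8.0, 2025),
    2: ScenarioSpec(2, 7.0, 2030),
    3: ScenarioSpec(3, 5.0, 2030),
    4: ScenarioSpec(4, 8.0, 2025, horizon="lifetime"),
    5: ScenarioSpec(5, 7.0, 2030, horizon="lifetime"),
    6: ScenarioSpec(6, 5.0, 2030, horizon="lifetime"),
    7: ScenarioSpec(7, 8.0, 2025, horizon="lifetime", decay=True),
    8: ScenarioSpec(8, 7.0, 2030, horizon="lifetime", decay=True),
    9: ScenarioSpec(9, 5.0, 2030, horizon="lifetime", decay=True),
}


def salt_target_trajectory(baseline: float, spec: ScenarioSpec,
                           base_year: int = BASE_YEAR,
                           n_years: int | None = None) -> np.ndarray:
    """Per-year salt intake from the base year under a scenario.

    Equal annual decrements from the baseline to the target by the target
    year; cohorts already at or below the target are unchanged; after the
    target year intake stays at the achieved level (decay attenuates the
    blood-pressure effect, not the intake itself).
    """
    if baseline <= 0:
        raise ValueError(f"baseline intake must be > 0, got {baseline}")
    if spec.target_year <= base_year:
        raise ValueError("target_year must be after the base year")
    span = spec.target_year - base_year
    if n_years is None:
        n_years = span + 1
    decrement = max(baseline - spec.target, 0.0) / span
    t = np.arange(n_years)
    return baseline - decrement * np.minimum(t, span)


def decay_schedule(spec: ScenarioSpec, years: np.ndarray) -> np.ndarray:
    """Per-calendar-year effect fraction for the decay scenarios (7-9).

    Full effect through 5 years after the target year, then stepping down
    each 5-year block (100/75/50/25/0 % in the default ladder, or 25 % of the
    previous block in the ``geometric`` reading), applied multiplicatively to
    the achieved SBP shift.
    """
    if not spec.decay:
        raise ValueError(f"scenario {spec.id} has no decay schedule")
    years = np.asarray(years)
    k = years - spec.target_year           # years past the target year
    block = np.clip(np.ceil(k / 5.0), 0, None).astype(int)  # 0 during ramp
    if spec.decay_mode == "linear":
        ladder = np.array([1.0, 1.0, 0.75, 0.5, 0.25])
    else:
        ladder = np.array([1.0, 1.0, 0.25, 0.0625, 0.015625])
    frac = np.where(block >= len(ladder), 0.0, ladder[np.minimum(block, len(ladder) - 1)])
    return frac


# ---------------------------------------------------------------------------
# table schema validation

_SCHEMAS = {
    "population": {"sex", "age_band", "age_lo", "age_hi", "population",
                   "yld_background"},
    "exposure": {"sex", "age_band", "salt_mean", "sbp_mean", "sbp_sd"},
    "disease_rates": {"sex", "age_band", "disease", "incidence", "acute_cf",
                      "chronic_cf_year1", "chronic_excess",
                      "all_cause_mortality", "disease_mortality",
                      "prevalence", "disability_weight"},
    "costs": {"disease", "sex", "cost_per_case"},
}


def validate_tables(tables: FixtureTables) -> None:
    """Fail fast on schema violations, with row-level diagnostics."""
    problems: list[str] = []
    for name, required in _SCHEMAS.items():
        df = getattr(tables, name)
        missing = required - set(df.columns)
        if missing:
            problems.append(f"{name}: missing columns {sorted(missing)}")
            continue
        numeric = [c for c in required
                   if c not in ("sex", "age_band", "disease")]
        for col in numeric:
            bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))].tolist()
            neg = df.index[df[col].to_numpy(dtype=float) < 0].tolist()
            if bad:
                problems.append(f"{name}.{col}: non-finite values at rows {bad[:5]}")
            if neg:
                problems.append(f"{name}.{col}: negative values at rows {neg[:5]}")
    dr = tables.disease_rates
    if "acute_cf" in dr.columns:
        bad = dr.index[(dr["acute_cf"] < 0) | (dr["acute_cf"] > 1)].tolist()
        if bad:
            problems.append(f"disease_rates.acute_cf outside [0,1] at rows {bad[:5]}")
    if problems:
        raise SchemaError("input table validation failed:\n  " + "\n  ".join(problems))


# ---------------------------------------------------------------------------
# results containers

@dataclass
class ScenarioResult:
    """All reportable outputs of one scenario run."""

    spec: ScenarioSpec
    years: np.ndarray
    hypertension: pd.DataFrame   # sex-level SBP / prevalence reductions
    incidence: pd.DataFrame      # disease x sex cumulative averted cases
    mortality: pd.DataFrame      # disease x sex cumulative averted deaths
    halys: pd.DataFrame          # sex-level LY / HALY gains
    costs: pd.DataFrame          # disease x sex cost savings (millions US$)

    def headline(self) -> dict[str, float]:
        """Flat metric dict used for PSA percentile summaries."""
        out: dict[str, float] = {}
        for r in self.hypertension.itertuples():
            out[f"sbp_reduction_mmhg_{r.sex}"] = r.mean_sbp_reduction_mmhg
            out[f"hypertension_prevalence_reduction_pct_{r.sex}"] = (
                r.prevalence_reduction_pct)
            out[f"hypertension_cases_averted_{r.sex}"] = r.cases_averted
        for name, df in (("incident", self.incidence), ("deaths", self.mortality)):
            for r in df.itertuples():
                out[f"averted_{name}_{r.disease}_{r.sex}"] = r.averted
                out[f"relative_{name}_reduction_pct_{r.disease}_{r.sex}"] = (
                    r.relative_reduction_pct)
        for r in self.halys.itertuples():
            out[f"ly_gained_{r.sex}"] = r.ly_gained
            out[f"haly_gained_{r.sex}"] = r.haly_gained_discounted
        for r in self.costs.itertuples():
            out[f"cost_savings_musd_{r.disease}_{r.sex}"] = r.savings_musd
        return out


# ---------------------------------------------------------------------------
# the coupled model

class PMSLTModel:
    """Proportional multistate lifetable over sex x single-year-of-age cohorts.

    Five-year input bands are expanded to single years of age by uniform
    within-band allocation; each cohort ages one year per cycle until death
    or age 100.  The reference (baseline) arm is computed once at
    construction and reused by every scenario and PSA draw.
    """

    def __init__(self, tables: FixtureTables,
                 effect: SaltEffectModel | None = None,
                 rr: Mapping[str, float] | None = None,
                 discount_rate: float = 0.03,
                 base_year: int = BASE_YEAR):
        validate_tables(tables)
        self.tables = tables
        self.effect = effect or SaltEffectModel.calibrated()
        rr = dict(rr or DEFAULT_RR)
        self.rr = {d: RRFunction(rr[d]) for d in DISEASES}
        self.discount_rate = discount_rate
        self.base_year = base_year
        self.cost_model = CostModel.from_table(tables.costs)
        self._expand_cohorts()
        self._run_baseline()

    # -- cohort expansion ---------------------------------------------------
    def _band_lookup(self, df: pd.DataFrame, col: str,
                     disease: str | None = None) -> np.ndarray:
        """(2, n_bands) array of a column ordered by (sex, age band)."""
        out = np.empty((2, N_AGE_BANDS))
        for i, sex in enumerate(SEXES):
            sub = df[df["sex"] == sex]
            if disease is not None:
                sub = sub[sub["disease"] == disease]
            sub = sub.set_index("age_band")
            out[i] = [sub.at[f"{lo}-{lo + 4}", col] for lo in AGE_BAND_LOWER]
        return out

    def _expand_cohorts(self) -> None:
        ages = np.arange(25, MAX_AGE)
        self.cohort_sex = np.repeat(np.arange(2), ages.size)      # 0 male, 1 female
        self.cohort_age0 = np.tile(ages, 2)
        C = self.cohort_sex.size
        T = _T_MAX
        age = self.cohort_age0[:, None] + np.arange(T)[None, :]
        self.active = age < MAX_AGE
        band = np.clip((age - 25) // 5, 0, N_AGE_BANDS - 1)
        sex_idx = self.cohort_sex[:, None]

        band_pop = self._band_lookup(self.tables.population, "population")
        self.population = band_pop[self.cohort_sex,
                                   np.clip((self.cohort_age0 - 25) // 5, 0,
                                           N_AGE_BANDS - 1)] / 5.0
        self.yld_background = self._band_lookup(
            self.tables.population, "yld_background")[
            self.cohort_sex, (self.cohort_age0 - 25) // 5]

        exp_t = self.tables.exposure
        self.mu = self._band_lookup(exp_t, "sbp_mean")[sex_idx, band]
        self.sigma = self._band_lookup(exp_t, "sbp_sd")[sex_idx, band]
        self.salt0 = self._band_lookup(exp_t, "salt_mean")[
            self.cohort_sex, (self.cohort_age0 - 25) // 5]

        dr = self.tables.disease_rates
        self.mac = self._band_lookup(
            dr[dr["disease"] == DISEASES[0]].drop(columns="disease"),
            "all_cause_mortality")[sex_idx, band]
        self.disease_arrays: dict[str, dict[str, np.ndarray]] = {}
        self.baseline_prevalence: dict[str, np.ndarray] = {}
        self.dw: dict[str, float] = {}
        for d in DISEASES:
            arrays = {}
            for col, key in (("incidence", "incidence"), ("acute_cf", "acute_cf"),
                             ("chronic_cf_year1", "chronic_cf_year1"),
                             ("chronic_excess", "chronic_excess")):
                arrays[key] = self._band_lookup(dr, col, d)[sex_idx, band]
            dmort = self._band_lookup(dr, "disease_mortality", d)[sex_idx, band]
            arrays["background"] = np.clip(self.mac - dmort, 0.0, None)
            self.disease_arrays[d] = arrays
            self.baseline_prevalence[d] = self._band_lookup(dr, "prevalence", d)[
                self.cohort_sex, (self.cohort_age0 - 25) // 5]
            self.dw[d] = float(dr.loc[dr["disease"] == d, "disability_weight"].iloc[0])
        self.C, self.T_max = C, T

    # -- baseline (reference) arm -------------------------------------------
    def _run_disease(self, disease: str, multipliers: np.ndarray,
                     T: int) -> DiseaseTrajectories:
        prev0 = self.baseline_prevalence[disease]
        return simulate_disease(
            healthy0=self.population * (1.0 - prev0),
            diseased0=self.population * prev0,
            rates={k: v[:, :T] for k, v in self.disease_arrays[disease].items()},
            multipliers=multipliers,
            active=self.active[:, :T])

    def _run_baseline(self) -> None:
        ones = np.ones((self.C, self.T_max))
        self.baseline_disease = {d: self._run_disease(d, ones, self.T_max)
                                 for d in DISEASES}
        self.baseline_lifetable = build_lifetable(
            self.population, self.mac, None, self.active)

    # -- scenario evaluation -------------------------------------------------
    def _horizon(self, spec: ScenarioSpec) -> int:
        if spec.horizon == "to_target_year":
            return min(spec.target_year - self.base_year + 1, self.T_max)
        return self.T_max

    def run_scenario(self, spec: ScenarioSpec,
                     effect: SaltEffectModel | None = None,
                     rr: Mapping[str, RRFunction] | None = None,
                     cost_model: CostModel | None = None) -> ScenarioResult:
        effect = effect or self.effect
        rr = rr or self.rr
        cost_model = cost_model or self.cost_model
        T = self._horizon(spec)
        years = self.base_year + np.arange(T)

        span = spec.target_year - self.base_year
        decrement = np.clip(self.salt0 - spec.target, 0.0, None) / span
        ramp = np.minimum(np.arange(T), span)
        delta_salt = decrement[:, None] * ramp[None, :]
        if spec.decay:
            delta_salt = delta_salt * decay_schedule(spec, years)[None, :]

        shift_norm = effect.slope_norm * delta_salt
        shift_hyp = effect.slope_hyp * delta_salt

        act = self.active[:, :T]
        need = act & (delta_salt > 0)
        multipliers = {}
        for d in DISEASES:
            mult = np.ones((self.C, T))
            if need.any():
                pifs = pif_batch(self.mu[:, :T][need], self.sigma[:, :T][need],
                                 shift_norm[need], shift_hyp[need], rr[d])
                mult[need] = 1.0 - pifs
            multipliers[d] = mult

        intervention = {d: self._run_disease(d, multipliers[d], T) for d in DISEASES}
        baseline = {d: _slice_traj(self.baseline_disease[d], T) for d in DISEASES}

        delta_mort = np.zeros((self.C, T))
        for d in DISEASES:
            delta_mort += (intervention[d].mortality_rate()
                           - baseline[d].mortality_rate())
        lt_int = build_lifetable(self.population, self.mac[:, :T],
                                 delta_mort, act)
        py_base = self.baseline_lifetable.person_years[:, :T]
        py_int = lt_int.person_years

        halys_base = compute_halys(
            py_base, {d: baseline[d].prevalence_proportion for d in DISEASES},
            self.dw, self.yld_background)
        halys_int = compute_halys(
            py_int, {d: intervention[d].prevalence_proportion for d in DISEASES},
            self.dw, self.yld_background)

        male = self.cohort_sex == 0
        sex_masks = {"male": male, "female": ~male,
                     "both": np.ones(self.C, dtype=bool)}

        haly_rows = []
        for sex, m in sex_masks.items():
            ly = (py_int - py_base)[m].sum(axis=0)
            hg = (halys_int - halys_base)[m].sum(axis=0)
            haly_rows.append({
                "sex": sex,
                "ly_gained": float(ly.sum()),
                "haly_gained": float(hg.sum()),
                "ly_gained_discounted": float(discount_stream(
                    ly, self.discount_rate, self.base_year, years).sum()),
                "haly_gained_discounted": float(discount_stream(
                    hg, self.discount_rate, self.base_year, years).sum()),
            })

        # hypertension / SBP reporting at the target year
        idx = min(span, T - 1)
        alive_w = self.baseline_lifetable.alive[:, idx] * self.active[:, idx]
        hyp_rows = []
        for sex, m in sex_masks.items():
            w = alive_w[m]
            pb = hypertension_prevalence_batch(self.mu[m, idx], self.sigma[m, idx])
            pi = hypertension_prevalence_batch(self.mu[m, idx], self.sigma[m, idx],
                                               shift_hyp[m, idx])
            wsum = w.sum()
            sbp_red = (w * (pb * shift_hyp[m, idx]
                            + (1.0 - pb) * shift_norm[m, idx])).sum() / wsum
            hyp_rows.append({
                "sex": sex,
                "mean_sbp_reduction_mmhg": float(sbp_red),
                "prevalence_reduction_pct": float(100.0 * (w * (pb - pi)).sum() / wsum),
                "cases_averted": float((w * (pb - pi)).sum()),
            })

        incidence_df = _burden_table(baseline, intervention, "incident",
                                     sex_masks, years)
        mortality_df = _burden_table(baseline, intervention, "deaths", sex_masks, years)

        base_counts = _incident_frame(baseline, sex_masks, years)
        int_counts = _incident_frame(intervention, sex_masks, years)
        savings = cost_savings(base_counts, int_counts, cost_model,
                               self.discount_rate, self.base_year)
        costs_df = summarise_costs(savings)
        both = costs_df.groupby("disease", sort=True)[
            ["averted", "savings_musd", "savings_undiscounted_musd"]].sum().reset_index()
        both["sex"] = "both"
        costs_df = pd.concat([costs_df, both], ignore_index=True)

        return ScenarioResult(
            spec=spec, years=years,
            hypertension=pd.DataFrame(hyp_rows),
            incidence=incidence_df, mortality=mortality_df,
            halys=pd.DataFrame(haly_rows), costs=costs_df)

    def run_many(self, scenario_ids: Iterable[int] | None = None,
                 **kwargs) -> dict[int, ScenarioResult]:
        ids = sorted(scenario_ids or DEFAULT_SCENARIOS)
        return {i: self.run_scenario(DEFAULT_SCENARIOS[i], **kwargs) for i in ids}


def _slice_traj(traj: DiseaseTrajectories, T: int) -> DiseaseTrajectories:
    return DiseaseTrajectories(
        incident=traj.incident[:, :T],
        deaths_acute=traj.deaths_acute[:, :T],
        deaths_chronic=traj.deaths_chronic[:, :T],
        deaths_other=traj.deaths_other[:, :T],
        alive_start=traj.alive_start[:, :T],
        prevalent_end=traj.prevalent_end[:, :T],
        prevalence_proportion=traj.prevalence_proportion[:, :T])


def _counts(traj: DiseaseTrajectories, what: str) -> np.ndarray:
    if what == "incident":
        return traj.incident
    if what == "deaths":
        return traj.deaths_acute + traj.deaths_chronic
    raise ValueError(what)


def _burden_table(baseline, intervention, what, sex_masks, years) -> pd.DataFrame:
    rows = []
    for d in DISEASES:
        for sex, m in sex_masks.items():
            b = float(_counts(baseline[d], what)[m].sum())
            i = float(_counts(intervention[d], what)[m].sum())
            rows.append({
                "disease": d, "sex": sex, "baseline": b,
                "intervention": i, "averted": b - i,
                "relative_reduction_pct": 100.0 * (b - i) / b if b > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def _incident_frame(runs, sex_masks, years) -> pd.DataFrame:
    rows = []
    for d in DISEASES:
        for sex in ("male", "female"):
            m = sex_masks[sex]
            counts = runs[d].incident[m].sum(axis=0)
            for y, c in zip(years, counts):
                rows.append({"disease": d, "sex": sex, "year": int(y),
                             "incident": float(c)})
    return pd.DataFrame(rows)


def run_deterministic(tables: FixtureTables | FixtureConfig | None = None,
                      scenario_ids: Sequence[int] | None = None,
                      **model_kwargs) -> dict[int, ScenarioResult]:
    """Evaluate scenarios at central parameter values on one set of inputs."""
    if tables is None or isinstance(tables, FixtureConfig):
        tables = generate_fixtures(tables)
    model = PMSLTModel(tables, **model_kwargs)
    return model.run_many(scenario_ids)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

_FAMILIES = ("normal", "lognormal", "gamma")


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain input: distribution family plus its parameters."""

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidConfigError(f"unknown distribution family {self.family!r}")
        p = self.params
        try:
            if self.family == "normal":
                if p["sd"] < 0:
                    raise InvalidConfigError("normal sd must be >= 0")
            elif self.family == "lognormal":
                if p["median"] <= 0 or p["sigma_log"] < 0:
                    raise InvalidConfigError(
                        "lognormal needs median > 0 and sigma_log >= 0")
            elif self.family == "gamma":
                if p["mean"] <= 0 or p["cv"] < 0:
                    raise InvalidConfigError("gamma needs mean > 0 and cv >= 0")
        except KeyError as e:
            raise InvalidConfigError(
                f"missing parameter {e} for {self.family} distribution") from e

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], n)
        if self.family == "lognormal":
            return np.exp(rng.normal(np.log(p["median"]), p["sigma_log"], n))
        shape_cv = p["cv"]
        if shape_cv == 0:
            return np.full(n, p["mean"])
        shape = 1.0 / shape_cv ** 2
        return rng.gamma(shape, p["mean"] / shape, n)

    def central(self) -> float:
        p = self.params
        if self.family == "normal":
            return p["mean"]
        if self.family == "lognormal":
            return p["median"]
        return p["mean"]


@dataclass(frozen=True)
class PSASpec:
    """Probabilistic sensitivity analysis configuration."""

    n_draws: int = 2000
    seed: int = 0
    distributions: Mapping[str, ParameterDistribution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise InvalidConfigError(f"n_draws must be >= 2, got {self.n_draws}")


def default_psa_spec(tables: FixtureTables, n_draws: int = 2000,
                     seed: int = 0) -> PSASpec:
    """Default uncertain-parameter set matching the study's families."""
    cfg = tables.config
    dists = {
        "salt_bp_slope": ParameterDistribution(
            "normal", {"mean": 4.18 / 4.4, "sd": 0.16}),
        "rr_ischaemic": ParameterDistribution(
            "lognormal", {"median": DEFAULT_RR["ischaemic"], "sigma_log": 0.06}),
        "rr_haemorrhagic": ParameterDistribution(
            "lognormal", {"median": DEFAULT_RR["haemorrhagic"], "sigma_log": 0.06}),
        "cost_ischaemic": ParameterDistribution(
            "gamma", {"mean": cfg.cost_per_case["ischaemic"], "cv": 0.25}),
        "cost_haemorrhagic": ParameterDistribution(
            "gamma", {"mean": cfg.cost_per_case["haemorrhagic"], "cv": 0.25}),
    }
    return PSASpec(n_draws=n_draws, seed=seed, distributions=dists)


@dataclass
class PSAResult:
    """Point estimates plus empirical uncertainty intervals."""

    point: dict[int, ScenarioResult]
    draws: pd.DataFrame     # one row per (scenario, draw), columns = metrics
    summary: pd.DataFrame   # scenario, metric, point, mean, ui_low, ui_high


def run_psa(tables: FixtureTables | None, spec: PSASpec,
            scenario_ids: Sequence[int] | None = None,
            model: PMSLTModel | None = None) -> PSAResult:
    """Monte-Carlo uncertainty analysis over the full coupled model.

    Point estimates come from central parameter values; uncertainty intervals
    are the empirical 2.5/97.5 percentiles of ``n_draws`` full-model
    evaluations.  Within each draw the same parameter values are applied to
    every scenario (common random numbers).  Identical seeds give identical
    summaries.
    """
    if model is None:
        if tables is None:
            tables = generate_fixtures()
        model = PMSLTModel(tables)
    ids = sorted(scenario_ids or DEFAULT_SCENARIOS)
    dists = dict(spec.distributions) or dict(
        default_psa_spec(model.tables, spec.n_draws, spec.seed).distributions)

    rng = np.random.default_rng(spec.seed)
    samples = {name: dists[name].sample(rng, spec.n_draws)
               for name in sorted(dists)}

    point = {i: model.run_scenario(DEFAULT_SCENARIOS[i]) for i in ids}

    rows = []
    base_costs = model.cost_model
    for k in range(spec.n_draws):
        slope = max(float(samples["salt_bp_slope"][k]), 0.0)
        effect = SaltEffectModel.calibrated(slope_overall=slope)
        rr = {"ischaemic": RRFunction(max(float(samples["rr_ischaemic"][k]), 1.0)),
              "haemorrhagic": RRFunction(max(float(samples["rr_haemorrhagic"][k]), 1.0))}
        cost_map = {}
        for (d, sex), v in base_costs.cost_per_case.items():
            central = dists[f"cost_{d}"].central()
            cost_map[(d, sex)] = v * float(samples[f"cost_{d}"][k]) / central
        cost_model = replace(base_costs, cost_per_case=cost_map)
        for i in ids:
            res = model.run_scenario(DEFAULT_SCENARIOS[i], effect=effect,
                                     rr=rr, cost_model=cost_model)
            rows.append({"scenario": i, "draw": k, **res.headline()})
    draws = pd.DataFrame(rows)

    summary_rows = []
    metrics = [c for c in draws.columns if c not in ("scenario", "draw")]
    for i in ids:
        sub = draws[draws["scenario"] == i]
        central = point[i].headline()
        for metric in metrics:
            vals = sub[metric].to_numpy()
            summary_rows.append({
                "scenario": i, "metric": metric,
                "point": central.get(metric, np.nan),
                "mean": float(vals.mean()),
                "ui_low": float(np.percentile(vals, 2.5)),
                "ui_high": float(np.percentile(vals, 97.5)),
            })
    return PSAResult(point=point, draws=draws, summary=pd.DataFrame(summary_rows))
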