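"""Synthetic input tables for the salt-reduction stroke model.

The model's original inputs (a national risk-factor survey, burden-of-disease
estimates and a single-centre hospital costing study) are not publicly
deposited.  This module generates internally consistent stand-ins with the
same structure and the published summary anchors:

* ~61 million adults aged >=25 (29.5 M men, 31.5 M women),
* mean salt intake 10.5 g/day in men and 8.3 g/day in women
  (10.3 / 8.2 g/day among the 30-49-year-olds),
* hypertension prevalence around 30% in 30-69-year-olds,
* crude first-ever stroke incidence of 115.7 per 100,000 person-years,
* higher 28-day case fatality for haemorrhagic than ischaemic stroke.

Every table is a plain pandas DataFrame written as UTF-8 CSV; a YAML manifest
records the seed and all ground-truth parameters.  The generator is seeded and
byte-reproducible: the same (seed, config) always yields identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError

SEXES = ("male", "female")
DISEASES = ("ischaemic", "haemorrhagic")

#: 5-year age bands from 25-29 to 95-99; cohorts are simulated to age 100.
AGE_BAND_LOWER = np.arange(25, 100, 5)
AGE_BAND_LABELS = tuple(f"{lo}-{lo + 4}" for lo in AGE_BAND_LOWER)
N_AGE_BANDS = len(AGE_BAND_LOWER)

# Adult age-structure weights per 5-year band (young-heavy pyramid typical of
# a middle-income country in 2019); normalised at use.
_BAND_WEIGHTS = np.array(
    [0.100, 0.105, 0.100, 0.095, 0.090, 0.085, 0.080, 0.070,
     0.055, 0.040, 0.030, 0.020, 0.012, 0.006, 0.002]
)


def _sex_map(male: float, female: float) -> dict[str, float]:
    return {"male": float(male), "female": float(female)}


def _disease_map(ischaemic: float, haemorrhagic: float) -> dict[str, float]:
    return {"ischaemic": float(ischaemic), "haemorrhagic": float(haemorrhagic)}


@dataclass(frozen=True)
class FixtureConfig:
    """Ground-truth parameters for the synthetic input tables.

    Defaults encode the study conditions: the published population, salt and
    incidence anchors, plus plausible values for quantities the source data do
    not print (SBP standard deviation, age gradients, chronic excess mortality
    multipliers, disability weights, unit costs).
    """

    seed: int = 2019
    total_population: float = 61_000_000.0
    #: fraction male, chosen so 61 M splits into 29.5 M men / 31.5 M women
    sex_split: float = 29.5 / 61.0
    #: population-weighted mean salt intake over all adults >=25, g/day
    salt_mean_adult: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(10.5, 8.3))
    #: population-weighted mean salt intake among 30-49-year-olds, g/day
    salt_mean_30_49: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(10.3, 8.2))
    #: mean SBP at age 50, mmHg
    sbp_mean_at_50: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(136.0, 132.0))
    #: mmHg of mean SBP per year of age
    sbp_gradient: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(0.45, 0.55))
    sbp_sd: float = 15.0
    #: events/person-year at the age-60 reference; None = calibrate so the
    #: crude all-stroke rate equals crude_incidence_target
    incidence_scale: float | None = None
    crude_incidence_target: float = 115.7e-5
    ischaemic_share: float = 0.55
    incidence_age_slope: float = 0.09
    incidence_sex_factor: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(1.15, 0.87))
    #: haemorrhagic 28-day case fatality as a multiple of ischaemic (>=1)
    acute_cf_ratio_haem_vs_isch: float = 2.0
    acute_cf_isch_at_25: float = 0.08
    acute_cf_isch_age_slope: float = 0.002
    #: first-year (months 2-12) excess mortality as multiple of background
    chronic_cf_multiplier: Mapping[str, float] = field(
        default_factory=lambda: _disease_map(2.0, 2.5))
    #: long-term chronic excess mortality as multiple of background
    chronic_excess_multiplier: Mapping[str, float] = field(
        default_factory=lambda: _disease_map(0.8, 1.0))
    #: Gompertz all-cause mortality: rate = scale * exp(slope * age)
    mortality_scale: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(1.2e-4, 0.8e-4))
    mortality_age_slope: float = 0.08
    #: lognormal sd of the seeded jitter on band population weights
    population_jitter_sd: float = 0.02
    #: background comorbidity YLD rate, linear in age
    yld_background_at_25: float = 0.05
    yld_background_at_95: float = 0.20
    disability_weight: Mapping[str, float] = field(
        default_factory=lambda: _disease_map(0.266, 0.320))
    #: US$ per first-ever incident case, by disease (same for both sexes
    #: unless overridden in cost_sex_factor)
    cost_per_case: Mapping[str, float] = field(
        default_factory=lambda: _disease_map(600.0, 700.0))
    cost_sex_factor: Mapping[str, float] = field(
        default_factory=lambda: _sex_map(1.0, 1.0))
    currency_year: int = 2019

    def __post_init__(self) -> None:
        if not self.total_population > 0:
            raise InvalidConfigError(
                f"total_population must be positive, got {self.total_population}")
        if not 0.0 < self.sex_split < 1.0:
            raise InvalidConfigError(
                f"sex_split must lie in (0, 1), got {self.sex_split}")
        if self.sbp_sd <= 0:
            raise InvalidConfigError(f"sbp_sd must be > 0, got {self.sbp_sd}")
        if self.acute_cf_ratio_haem_vs_isch < 1.0:
            raise InvalidConfigError(
                "acute_cf_ratio_haem_vs_isch must be >= 1, got "
                f"{self.acute_cf_ratio_haem_vs_isch}")
        if self.incidence_scale is not None and self.incidence_scale < 0:
            raise InvalidConfigError("incidence_scale must be >= 0")
        if not 0.0 < self.ischaemic_share < 1.0:
            raise InvalidConfigError("ischaemic_share must lie in (0, 1)")
        for name in ("crude_incidence_target", "acute_cf_isch_at_25",
                     "acute_cf_isch_age_slope", "population_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for m in (self.salt_mean_adult, self.sbp_mean_at_50,
                  self.mortality_scale, self.cost_per_case,
                  self.chronic_cf_multiplier, self.chronic_excess_multiplier):
            for k, v in m.items():
                if v < 0:
                    raise InvalidConfigError(f"negative parameter {k}={v}")

    def to_manifest(self) -> dict:
        """Plain-serialisable dict of all ground-truth parameters."""
        d = dataclasses.asdict(self)
        return {k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in d.items()}


def _band_mid_ages() -> np.ndarray:
    # uniform within-band allocation => band mean age is the midpoint
    return AGE_BAND_LOWER + 2.0


def generate_population(config: FixtureConfig) -> pd.DataFrame:
    """One row per sex x 5-year age band with population counts.

    Counts sum exactly to ``total_population`` split by ``sex_split``; band
    weights carry a small seeded lognormal jitter so different seeds give
    different (but always internally consistent) age structures.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    mids = _band_mid_ages()
    yld = (config.yld_background_at_25
           + (config.yld_background_at_95 - config.yld_background_at_25)
           * (mids - 25.0) / 70.0)
    for sex in SEXES:
        jitter = rng.lognormal(0.0, config.population_jitter_sd, N_AGE_BANDS)
        w = _BAND_WEIGHTS * jitter
        w = w / w.sum()
        sex_total = config.total_population * (
            config.sex_split if sex == "male" else 1.0 - config.sex_split)
        for i, label in enumerate(AGE_BAND_LABELS):
            rows.append({
                "sex": sex,
                "age_band": label,
                "age_lo": int(AGE_BAND_LOWER[i]),
                "age_hi": int(AGE_BAND_LOWER[i] + 4),
                "population": sex_total * w[i],
                "yld_background": yld[i],
            })
    return pd.DataFrame(rows)


def _solve_linear_profile(band_pop: np.ndarray, mids: np.ndarray,
                          overall_mean: float, sub_mean_30_49: float) -> tuple[float, float]:
    """Intercept/slope of a linear-in-age profile hitting two weighted means.

    The profile value of band b is alpha + beta * mid_age(b); the
    population-weighted mean over all bands must equal ``overall_mean`` and
    over the 30-49 bands ``sub_mean_30_49``.
    """
    w_all = band_pop / band_pop.sum()
    sub = (AGE_BAND_LOWER >= 30) & (AGE_BAND_LOWER < 50)
    w_sub = np.where(sub, band_pop, 0.0)
    w_sub = w_sub / w_sub.sum()
    a_all = float(w_all @ mids)
    a_sub = float(w_sub @ mids)
    if abs(a_all - a_sub) < 1e-9:
        raise InvalidConfigError("degenerate age structure: cannot solve salt profile")
    beta = (overall_mean - sub_mean_30_49) / (a_all - a_sub)
    alpha = sub_mean_30_49 - beta * a_sub
    return alpha, beta


def generate_exposure(config: FixtureConfig,
                      population: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cohort salt intake and SBP distribution parameters.

    Salt follows a linear age profile solved so the population-weighted
    all-adult and 30-49-year means reproduce the configured anchors exactly.
    Mean SBP rises linearly with age.
    """
    if population is None:
        population = generate_population(config)
    mids = _band_mid_ages()
    rows = []
    for sex in SEXES:
        pop = population.loc[population["sex"] == sex, "population"].to_numpy()
        alpha, beta = _solve_linear_profile(
            pop, mids, config.salt_mean_adult[sex], config.salt_mean_30_49[sex])
        salt = alpha + beta * mids
        if (salt <= 0).any():
            raise InvalidConfigError(f"solved salt profile non-positive for {sex}")
        sbp = config.sbp_mean_at_50[sex] + config.sbp_gradient[sex] * (mids - 50.0)
        for i, label in enumerate(AGE_BAND_LABELS):
            rows.append({
                "sex": sex,
                "age_band": label,
                "salt_mean": salt[i],
                "sbp_mean": sbp[i],
                "sbp_sd": config.sbp_sd,
            })
    return pd.DataFrame(rows)


def generate_disease_inputs(config: FixtureConfig,
                            population: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per sex x age band x disease transition hazards.

    Incidence rises exponentially with age and is calibrated (unless
    ``incidence_scale`` is given) so the crude all-stroke rate over the
    generated population equals ``crude_incidence_target``.  Haemorrhagic
    28-day case fatality is exactly ``acute_cf_ratio_haem_vs_isch`` times
    ischaemic in every cohort.  Chronic excess mortality is a constant
    per-disease multiple of background mortality.
    """
    if population is None:
        population = generate_population(config)
    mids = _band_mid_ages()
    shape = np.exp(config.incidence_age_slope * (mids - 60.0))

    if config.incidence_scale is None:
        num = 0.0
        den = 0.0
        for sex in SEXES:
            pop = population.loc[population["sex"] == sex, "population"].to_numpy()
            num += float(pop @ shape) * config.incidence_sex_factor[sex]
            den += float(pop.sum())
        scale = config.crude_incidence_target * den / num
    else:
        scale = config.incidence_scale

    acf_isch = (config.acute_cf_isch_at_25
                + config.acute_cf_isch_age_slope * (mids - 25.0))
    acf = {
        "ischaemic": acf_isch,
        "haemorrhagic": config.acute_cf_ratio_haem_vs_isch * acf_isch,
    }
    if (acf["haemorrhagic"] >= 1.0).any():
        raise InvalidConfigError(
            "haemorrhagic acute case fatality reaches 1; lower the ratio or slope")
    split = {"ischaemic": config.ischaemic_share,
             "haemorrhagic": 1.0 - config.ischaemic_share}

    rows = []
    for sex in SEXES:
        mac = config.mortality_scale[sex] * np.exp(
            config.mortality_age_slope * mids)
        inc_all = scale * shape * config.incidence_sex_factor[sex]
        disease_mort_total = np.zeros(N_AGE_BANDS)
        sex_rows = []
        for disease in DISEASES:
            inc = split[disease] * inc_all
            cf1 = config.chronic_cf_multiplier[disease] * mac
            excess = config.chronic_excess_multiplier[disease] * mac
            prevalence = np.minimum(inc * (1.0 - acf[disease]) * 8.0, 0.04)
            dmort = inc * acf[disease] + prevalence * excess
            disease_mort_total += dmort
            for i, label in enumerate(AGE_BAND_LABELS):
                sex_rows.append({
                    "sex": sex,
                    "age_band": label,
                    "disease": disease,
                    "incidence": inc[i],
                    "acute_cf": acf[disease][i],
                    "chronic_cf_year1": cf1[i],
                    "chronic_excess": excess[i],
                    "all_cause_mortality": mac[i],
                    "disease_mortality": dmort[i],
                    "prevalence": prevalence[i],
                    "disability_weight": config.disability_weight[disease],
                })
        if (disease_mort_total >= mac).any():
            raise InvalidConfigError(
                f"disease-specific mortality exceeds all-cause mortality for {sex}")
        rows.extend(sex_rows)
    return pd.DataFrame(rows)


def generate_costs(config: FixtureConfig) -> pd.DataFrame:
    """Unit healthcare cost per first-ever incident case, by disease and sex."""
    rows = []
    for disease in DISEASES:
        for sex in SEXES:
            rows.append({
                "disease": disease,
                "sex": sex,
                "cost_per_case": config.cost_per_case[disease]
                * config.cost_sex_factor[sex],
                "currency_year": config.currency_year,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FixtureTables:
    """Bundle of the four generated input tables plus their config."""

    config: FixtureConfig
    population: pd.DataFrame
    exposure: pd.DataFrame
    disease_rates: pd.DataFrame
    costs: pd.DataFrame


def generate_fixtures(config: FixtureConfig | None = None) -> FixtureTables:
    """Generate all four input tables from one config."""
    config = config or FixtureConfig()
    population = generate_population(config)
    return FixtureTables(
        config=config,
        population=population,
        exposure=generate_exposure(config, population),
        disease_rates=generate_disease_inputs(config, population),
        costs=generate_costs(config),
    )


_TABLE_FILES = {
    "population": "population.csv",
    "exposure": "exposure.csv",
    "disease_rates": "disease_rates.csv",
    "costs": "costs.csv",
}


def write_fixtures(tables: FixtureTables, outdir: str | Path) -> Path:
    """Write the four CSV tables plus a YAML manifest of ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        getattr(tables, attr).to_csv(outdir / fname, index=False)
    manifest = {"generator": "saltshift.fixtures", **tables.config.to_manifest()}
    with open(outdir / "fixture_manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def load_fixtures(indir: str | Path) -> FixtureTables:
    """Read tables previously written by :func:`write_fixtures`."""
    indir = Path(indir)
    with open(indir / "fixture_manifest.yaml", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    manifest.pop("generator", None)
    config = FixtureConfig(**manifest)
    frames = {attr: pd.read_csv(indir / fname)
              for attr, fname in _TABLE_FILES.items()}
    return FixtureTables(config=config, **frames)
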