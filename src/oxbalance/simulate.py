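"""Synthetic survival cohorts with a known oxidative-balance-score effect.

The generator emulates the structure of a large prospective cohort (UK
Biobank-like): 22 raw dietary/lifestyle exposures drawn from sex-stratified
marginals, standard covariates, three serum biomarkers acting as mediators,
and time-to-event colorectal-cancer (CRC) outcomes by subsite with
administrative censoring.  Every effect size is configurable and the
generating truth (true OBS, linear predictors, uncensored event times) is
returned in a *separate* ground-truth table so downstream estimators can be
validated without leakage.

Causal structure
----------------
OBS is computed from the raw exposures by the same scoring rules as the
analysis (``oxbalance.scoring``).  Each mediator M follows

    M = M_ref + a * (OBS - OBS_ref) + eps,     eps ~ N(0, sigma_M)

and each CRC subsite s is a competing exponential (optionally Weibull)
process with log-hazard

    eta_s = beta_dir_s * (OBS - OBS_ref) + sum_m b_m * (M_m - M_ref_m)
            + sum_c gamma_c * (c - c_ref)

``SimulationConfig.beta_obs`` entries are the *total* per-OBS-unit
log-hazard effects; the generator backs out ``beta_dir_s = beta_total_s -
sum_m a_m * b_m`` so that an analysis model omitting the mediators targets
exactly the configured total.  The default total for CRC is ln(0.974), the
scale reported for this exposure in large cohorts.

All marginal distributions are artifact choices (documented in the methods
note); published cohort means/SDs are used where available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring
from .components import ComponentSpec, default_components


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# --- reference (centering) values; means/SDs follow the published cohort ---
OBS_REF = 22.5
COVARIATE_REFS = {
    "age": 55.9,
    "tdi": -1.6,
    "education": 11.7,
    "bmi": 26.9,
    "crp": 2.3,
    "energy_intake": 8862.8,
    "nsaids": 0.34,
}
MEDIATOR_REFS = {"albumin": 45.4, "uric_acid": 306.4, "neutrophils": 4.1}
MEDIATOR_SDS = {"albumin": 2.6, "uric_acid": 79.1, "neutrophils": 1.4}

ETHNICITY_LEVELS = ("European", "Mixed-race", "Asian", "African", "Chinese", "Others")
ETHNICITY_PROBS = (0.9554, 0.0060, 0.0142, 0.0118, 0.0028, 0.0098)

SUBSITES = ("proximal", "distal", "rectal")
#: share of the baseline CRC hazard attributed to each subsite
SUBSITE_SHARES = {"proximal": 0.34, "distal": 0.34, "rectal": 0.32}

#: complication / death probabilities among incident CRC cases (cohort
#: case-fraction scale: ~10-25%)
CASE_FLAG_RATES = {
    "obstruction": 0.105,
    "abdominal_pain": 0.112,
    "metastasis": 0.252,
    "death_crc": 0.194,
}

DEFAULT_BETA_OBS = {"crc": math.log(0.974)}
DEFAULT_COVARIATE_EFFECTS = {"age": 0.06}
DEFAULT_MEDIATOR_PATHS = {
    "albumin": {"a": 0.05, "b": -0.005},
    "uric_acid": {"a": -1.5, "b": 0.002},
    "neutrophils": {"a": -0.02, "b": 0.05},
}
#: published-cohort missingness fractions (components left complete: the real
#: cohort excluded anyone whose OBS could not be computed)
DEFAULT_MISSING_RATES = {
    "tdi": 0.0013,
    "education": 0.0255,
    "ethnicity": 0.0028,
    "crp": 0.058,
    "albumin": 0.138,
    "uric_acid": 0.057,
    "neutrophils": 0.039,
}

# raw exposure marginals, sex-stratified through a male median multiplier and
# sex-specific abstention probabilities (female, male); log-normal positive
# parts unless noted.  Units are conventional dietary/lifestyle units.
_EXPOSURES = {
    # name: (median, log-sd, male_scale, p_zero_female, p_zero_male)
    "total_fat": (72.0, 0.30, 1.15, 0.0, 0.0),  # g/day
    "iron": (12.0, 0.28, 1.12, 0.0, 0.0),  # mg/day
    "pufa": (13.0, 0.32, 1.12, 0.0, 0.0),  # g/day
    "sfa": (27.0, 0.33, 1.15, 0.0, 0.0),  # g/day
    "beef": (55.0, 0.55, 1.25, 0.32, 0.22),  # g/day
    "lamb": (35.0, 0.60, 1.20, 0.55, 0.45),
    "pork": (40.0, 0.60, 1.25, 0.45, 0.35),
    "smoking": (12.0, 0.70, 1.10, 0.62, 0.52),  # cigarettes/day
    "alcohol": (8.0, 0.80, 1.40, 0.24, 0.12),  # units/week
    "calcium": (900.0, 0.28, 1.10, 0.0, 0.0),  # mg/day
    "magnesium": (320.0, 0.25, 1.10, 0.0, 0.0),  # mg/day
    "vitamin_b6": (2.0, 0.30, 1.08, 0.0, 0.0),  # mg/day
    "vitamin_b12": (6.0, 0.45, 1.10, 0.0, 0.0),  # ug/day
    "vitamin_c": (95.0, 0.50, 0.95, 0.0, 0.0),  # mg/day
    "vitamin_d": (3.0, 0.55, 1.05, 0.0, 0.0),  # ug/day
    "vitamin_e": (9.0, 0.40, 1.05, 0.0, 0.0),  # mg/day
    "total_folate": (300.0, 0.32, 1.05, 0.0, 0.0),  # ug/day
    "carotenoids": (2500.0, 0.55, 0.95, 0.0, 0.0),  # ug/day
    "fiber": (16.0, 0.35, 1.02, 0.0, 0.0),  # g/day
    "retinol": (450.0, 0.50, 1.08, 0.0, 0.0),  # ug/day
    "raw_vegetables": (2.0, 0.60, 0.90, 0.0, 0.0),  # tablespoons/day
    "cooked_vegetables": (2.5, 0.50, 0.95, 0.0, 0.0),
    "tea": (3.0, 0.55, 0.92, 0.0, 0.0),  # cups/day
    "met_light": (600.0, 0.70, 1.05, 0.0, 0.0),  # MET-min/week
    "met_moderate": (500.0, 0.80, 1.10, 0.0, 0.0),
    "met_vigorous": (240.0, 0.95, 1.25, 0.0, 0.0),
}

EVENT_FLAGS = (
    "crc",
    "proximal",
    "distal",
    "rectal",
    "obstruction",
    "abdominal_pain",
    "metastasis",
    "death_crc",
)


def _check_finite(name: str, mapping: dict) -> None:
    for k, v in mapping.items():
        if isinstance(v, dict):
            _check_finite(f"{name}.{k}", v)
        elif not math.isfinite(float(v)):
            raise ConfigurationError(f"non-finite value in {name}[{k!r}]: {v}")


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic cohort."""

    n_participants: int = 20_000
    seed: int = 0
    beta_obs: dict = field(default_factory=lambda: dict(DEFAULT_BETA_OBS))
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    mediator_paths: dict = field(
        default_factory=lambda: {
            m: dict(p) for m, p in DEFAULT_MEDIATOR_PATHS.items()
        }
    )
    complication_effects: dict = field(default_factory=dict)  # flag -> log-odds/OBS
    baseline_hazard_scale: float = 0.0019  # events per person-year at reference
    weibull_shape: float = 1.0  # 1.0 = exponential
    censor_year: float = 8.0  # administrative horizon, years
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    female_fraction: float = 0.535

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not math.isfinite(self.baseline_hazard_scale) or self.baseline_hazard_scale <= 0:
            raise ConfigurationError("baseline_hazard_scale must be positive")
        if not math.isfinite(self.weibull_shape) or self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be positive")
        if not math.isfinite(self.censor_year) or self.censor_year <= 0:
            raise ConfigurationError("censor_year must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        for col, rate in self.missing_rates.items():
            if not 0.0 <= float(rate) <= 1.0:
                raise ConfigurationError(f"missing rate for {col!r} not in [0, 1]")
        if "crc" not in self.beta_obs:
            raise ConfigurationError("beta_obs must include a 'crc' entry")
        _check_finite("beta_obs", self.beta_obs)
        _check_finite("covariate_effects", self.covariate_effects)
        _check_finite("mediator_paths", self.mediator_paths)
        _check_finite("complication_effects", self.complication_effects)

    @classmethod
    def null(cls, n_participants: int = 5000, seed: int = 0, **kwargs):
        """A no-effect configuration (zero OBS effect on every outcome)."""
        return cls(
            n_participants=n_participants,
            seed=seed,
            beta_obs={"crc": 0.0},
            **kwargs,
        )

    def mediated_sum(self) -> float:
        return sum(float(p["a"]) * float(p["b"]) for p in self.mediator_paths.values())

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "beta_obs": dict(self.beta_obs),
            "covariate_effects": dict(self.covariate_effects),
            "mediator_paths": {m: dict(p) for m, p in self.mediator_paths.items()},
            "complication_effects": dict(self.complication_effects),
            "baseline_hazard_scale": self.baseline_hazard_scale,
            "weibull_shape": self.weibull_shape,
            "censor_year": self.censor_year,
            "missing_rates": dict(self.missing_rates),
            "female_fraction": self.female_fraction,
        }


@dataclass
class SimulatedCohort:
    """Analysis table plus the ground-truth side table (never merged)."""

    cohort: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, path: str | Path) -> tuple[Path, Path]:
        """Write ``<path>`` and ``<stem>_truth.csv`` (missing = empty field)."""
        path = Path(path)
        truth_path = path.with_name(path.stem + "_truth" + path.suffix)
        self.cohort.to_csv(path, index=False, na_rep="")
        self.truth.to_csv(truth_path, index=False, na_rep="")
        return path, truth_path


def _draw_exposures(rng: np.random.Generator, male: np.ndarray) -> dict[str, np.ndarray]:
    n = male.size
    cols = {}
    for name, (median, sigma, male_scale, pz_f, pz_m) in _EXPOSURES.items():
        med = np.where(male, median * male_scale, median)
        vals = med * np.exp(sigma * rng.standard_normal(n))
        p_zero = np.where(male, pz_m, pz_f)
        if (p_zero > 0).any():
            vals = np.where(rng.random(n) < p_zero, 0.0, vals)
        cols[name] = vals
    return cols


def generate_cohort(
    config: SimulationConfig, specs: list[ComponentSpec] | None = None
) -> SimulatedCohort:
    """Draw one cohort table and its ground-truth side table."""
    specs = default_components() if specs is None else specs
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    male = rng.random(n) >= config.female_fraction
    df = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "sex": np.where(male, "male", "female"),
        }
    )
    df["age"] = np.clip(rng.normal(55.9, 8.0, n), 40.0, 69.0)
    df["ethnicity"] = rng.choice(
        ETHNICITY_LEVELS, size=n, p=np.asarray(ETHNICITY_PROBS) / sum(ETHNICITY_PROBS)
    )
    df["tdi"] = rng.normal(-1.6, 2.9, n)
    df["education"] = np.clip(rng.normal(11.7, 13.8, n), 0.0, None)
    df["bmi"] = np.clip(rng.normal(26.9, 4.6, n), 15.0, 55.0)
    # CRP is right-skewed; log-normal matched to a ~2.3 mg/L mean
    df["crp"] = np.minimum(rng.lognormal(mean=0.35, sigma=0.9, size=n), 60.0)
    df["energy_intake"] = np.clip(rng.normal(8862.8, 3036.6, n), 2000.0, None)
    df["nsaids"] = (rng.random(n) < 0.34).astype(np.int64)

    for name, vals in _draw_exposures(rng, male).items():
        df[name] = vals

    # true OBS from the same scoring rules the analysis uses
    scored = scoring.score_cohort(df, specs, stratify="sex")
    obs_true = scored.data["obs_total"].to_numpy(dtype=float)
    centered_obs = obs_true - OBS_REF

    # mediators: linear in true OBS plus noise at the published dispersion;
    # all three biomarkers are always generated (a = b = 0 when unconfigured)
    mediator_terms = np.zeros(n)
    med_means = {}
    for m in MEDIATOR_REFS:
        path = config.mediator_paths.get(m, {"a": 0.0, "b": 0.0})
        a, b = float(path["a"]), float(path["b"])
        mean = MEDIATOR_REFS[m] + a * centered_obs
        vals = np.clip(mean + rng.normal(0.0, MEDIATOR_SDS[m], n), 0.0, None)
        df[m] = vals
        med_means[m] = mean
        mediator_terms = mediator_terms + b * (vals - MEDIATOR_REFS[m])

    covariate_terms = np.zeros(n)
    for cov, gamma in config.covariate_effects.items():
        ref = COVARIATE_REFS.get(cov, 0.0)
        covariate_terms = covariate_terms + float(gamma) * (
            df[cov].to_numpy(dtype=float) - ref
        )

    # competing subsite event times
    mediated = config.mediated_sum()
    k = config.weibull_shape
    site_times = np.empty((n, len(SUBSITES)))
    etas = {}
    for j, site in enumerate(SUBSITES):
        beta_total = float(config.beta_obs.get(site, config.beta_obs["crc"]))
        beta_dir = beta_total - mediated
        eta = beta_dir * centered_obs + mediator_terms + covariate_terms
        etas[site] = eta
        rate = config.baseline_hazard_scale * SUBSITE_SHARES[site] * np.exp(eta)
        e = rng.exponential(1.0, n)
        site_times[:, j] = (e / rate) ** (1.0 / k)

    t_event = site_times.min(axis=1)
    which = site_times.argmin(axis=1)
    event = t_event <= config.censor_year
    follow_up = np.minimum(t_event, config.censor_year)
    df["follow_up"] = follow_up
    df["crc"] = event.astype(np.int64)
    for j, site in enumerate(SUBSITES):
        df[site] = (event & (which == j)).astype(np.int64)

    # case-level complication flags (Bernoulli among incident cases)
    for flag, p0 in CASE_FLAG_RATES.items():
        beta_c = float(config.complication_effects.get(flag, 0.0))
        logit = math.log(p0 / (1.0 - p0)) + beta_c * centered_obs
        p = np.where(event, 1.0 / (1.0 + np.exp(-logit)), 0.0)
        df[flag] = (rng.random(n) < p).astype(np.int64)

    truth = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "obs_true": obs_true.astype(np.int64),
            "event_time_uncensored": t_event,
            "true_subsite": np.asarray(SUBSITES)[which],
            **{f"eta_{s}": etas[s] for s in SUBSITES},
            **{f"mean_{m}": med_means[m] for m in med_means},
        }
    )

    if config.missing_rates:
        missing_seed = int(
            np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0]
            % 2**31
        )
        df = inject_missingness(df, config.missing_rates, seed=missing_seed)

    return SimulatedCohort(cohort=df, truth=truth, config=config)


def inject_missingness(
    cohort: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Replace an MCAR fraction of each named column with the missing sentinel."""
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for col, rate in rates.items():
        if col not in out.columns:
            raise KeyError(f"cannot inject missingness: unknown column {col!r}")
        rate = float(rate)
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missing rate for {col!r} not in [0, 1]")
        mask = rng.random(len(out)) < rate
        if mask.any():
            if out[col].dtype.kind in "iub":
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out
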