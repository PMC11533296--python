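"""Synthetic full cohorts with a known true risk model.

A cohort is a :class:`pandas.DataFrame` with one row per subject and the
columns

``subject_id``
    unique integer identifier
``time``
    observed follow-up time, the minimum of the event time, the censoring
    time and the administrative end of study
``event``
    1 if the subject experienced the event of interest within follow-up
    (a *case*), 0 otherwise (a *control*)
covariate columns
    one column per covariate named in the configuration
``match_<name>``
    categorical matching variables (added by :mod:`nccvalidate.experiment`)
``lp``
    linear predictor of the model being evaluated
``risk``
    predicted absolute risk at the configured horizon, in [0, 1]

Event times follow a Weibull (or exponential) proportional-hazards model,
S(t | x) = exp(-(t/scale)^shape * exp(lp)), inverted analytically so that
closed-form cumulative incidences are available as test oracles.  Censoring
times are exponential and may depend on one (categorical or binary)
covariate, which distorts the covariate distribution of the subjects who
leave the study early -- the mechanism that makes unweighted validation of
a prediction model biased in a nested case-control subsample.

The linear predictor / risk stored in the cohort belong to the *evaluated*
model, which equals the data-generating model unless a deliberate
miscalibration (``lp_scale``, ``risk_multiplier``) is configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class CensoringSpec:
    """Exponential censoring, optionally with a different rate per level
    of one covariate.

    Parameters
    ----------
    rate : float
        Censoring rate used when ``by`` is None.
    by : str, optional
        Name of a covariate whose levels get separate rates.
    rates : dict, optional
        Mapping level -> rate, required when ``by`` is given.
    """

    rate: float = 0.0
    by: str | None = None
    rates: dict | None = None

    def validate(self) -> None:
        if self.by is not None:
            if not self.rates:
                raise ConfigurationError("censoring.rates required when censoring.by is set")
            if any(r < 0 for r in self.rates.values()):
                raise ConfigurationError("censoring.rates must be non-negative")
        elif self.rate < 0:
            raise ConfigurationError("censoring.rate must be non-negative")


@dataclass
class RiskModel:
    """An absolute-risk model: log hazard ratios plus baseline survival
    at the prediction horizon."""

    coefficients: dict[str, float]
    baseline_survival_at_horizon: float

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival_at_horizon <= 1.0:
            raise ConfigurationError(
                "baseline_survival_at_horizon must be in (0, 1], got "
                f"{self.baseline_survival_at_horizon}"
            )

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        lp = np.zeros(len(covariates))
        for name, beta in self.coefficients.items():
            if name not in covariates:
                raise KeyError(f"covariate {name!r} missing from input")
            lp = lp + beta * np.asarray(covariates[name], dtype=float)
        return lp


def true_risk(model: RiskModel, covariates: pd.DataFrame) -> np.ndarray:
    """Absolute risk at the horizon, ``1 - S0(t_h) ** exp(lp)``.

    Monotone increasing in the linear predictor; 0 when the baseline
    survival is 1 regardless of the predictor.
    """
    lp = model.linear_predictor(covariates)
    return 1.0 - model.baseline_survival_at_horizon ** np.exp(lp)


@dataclass
class CohortConfig:
    """Parameters of the simulated source population.

    Defaults describe a population-based cohort of moderate size with a
    rare outcome: ~5% cumulative incidence at a 10-year horizon, three
    risk factors (a binary one standing in for sex, a continuous clinical
    score and a continuous genetic score), and censoring that removes
    sex = 0 subjects about three times faster than sex = 1 subjects, so
    that late-followed-up controls over-represent sex = 1.
    """

    n_subjects: int = 3000
    # Weibull baseline hazard; shape 1.0 == exponential with rate 1/scale.
    baseline_shape: float = 1.0
    baseline_scale: float = 1.0 / 0.0035
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.5, "clin": 0.3, "prs": 0.4}
    )
    covariate_spec: list[tuple] = field(
        default_factory=lambda: [
            ("sex", "binary", {"p": 0.5}),
            ("clin", "normal", {"mu": 0.0, "sd": 1.0}),
            ("prs", "normal", {"mu": 0.0, "sd": 1.0}),
        ]
    )
    censoring: CensoringSpec = field(
        default_factory=lambda: CensoringSpec(by="sex", rates={0: 0.09, 1: 0.03})
    )
    admin_end: float = 15.0
    horizon: float = 10.0
    # Deliberate miscalibration of the *evaluated* model relative to the
    # data-generating truth: stored lp = lp_scale * true lp, stored
    # risk = clip(risk_multiplier * true risk).  Both 1.0 => the evaluated
    # model is the true model.
    lp_scale: float = 1.0
    risk_multiplier: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.horizon > self.admin_end:
            raise ConfigurationError("horizon must not exceed admin_end")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ConfigurationError("baseline_shape and baseline_scale must be positive")
        for name, dist, params in self.covariate_spec:
            if dist == "binary":
                p = params.get("p")
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"covariate {name!r}: binary p must be in [0,1]")
            elif dist == "normal":
                if params.get("sd", 1.0) < 0:
                    raise ConfigurationError(f"covariate {name!r}: sd must be non-negative")
            elif dist == "categorical":
                probs = params.get("probs")
                levels = params.get("levels")
                if not levels or probs is None or len(levels) != len(probs):
                    raise ConfigurationError(
                        f"covariate {name!r}: levels and probs must align"
                    )
                if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                    raise ConfigurationError(
                        f"covariate {name!r}: probs must be a probability vector"
                    )
            else:
                raise ConfigurationError(f"covariate {name!r}: unknown distribution {dist!r}")
        self.censoring.validate()

    @property
    def baseline_survival_at_horizon(self) -> float:
        return math.exp(-((self.horizon / self.baseline_scale) ** self.baseline_shape))

    def true_model(self) -> RiskModel:
        return RiskModel(dict(self.coefficients), self.baseline_survival_at_horizon)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "censoring" in raw:
            raw["censoring"] = CensoringSpec(**raw["censoring"])
        if "covariate_spec" in raw:
            raw["covariate_spec"] = [tuple(item) for item in raw["covariate_spec"]]
        return cls(**raw)


def _draw_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    n = config.n_subjects
    for name, dist, params in config.covariate_spec:
        if dist == "binary":
            cols[name] = rng.binomial(1, params["p"], size=n)
        elif dist == "normal":
            cols[name] = rng.normal(params.get("mu", 0.0), params.get("sd", 1.0), size=n)
        else:  # categorical
            cols[name] = rng.choice(params["levels"], size=n, p=params["probs"])
    return pd.DataFrame(cols)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a full cohort under the configured model.

    Returns a DataFrame with the schema documented in the module
    docstring.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    covariates = _draw_covariates(config, rng)
    model = config.true_model()
    lp = model.linear_predictor(covariates)

    # Invert S(t|x) = exp(-(t/b)^a exp(lp)): T = b * (-log U / exp(lp))^(1/a)
    u = rng.uniform(size=n)
    event_time = config.baseline_scale * (
        (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)
    )

    cens = config.censoring
    if cens.by is not None:
        group = np.asarray(covariates[cens.by])
        rate = np.array([cens.rates[g] for g in group], dtype=float)
    else:
        rate = np.full(n, cens.rate)
    with np.errstate(divide="ignore"):
        cens_time = np.where(rate > 0, rng.exponential(1.0, size=n) / np.where(rate > 0, rate, 1.0), np.inf)

    time = np.minimum(np.minimum(event_time, cens_time), config.admin_end)
    event = (event_time <= np.minimum(cens_time, config.admin_end)).astype(int)

    risk = true_risk(model, covariates)
    cohort = pd.DataFrame({"subject_id": np.arange(n)})
    cohort = pd.concat([cohort, covariates], axis=1)
    cohort["time"] = time
    cohort["event"] = event
    cohort["lp"] = config.lp_scale * lp
    cohort["risk"] = np.clip(config.risk_multiplier * risk, 0.0, 1.0)
    return cohort


def cohort_summary(cohort: pd.DataFrame, horizon: float) -> dict:
    """Counts and Kaplan-Meier cumulative incidence at ``horizon``."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    # local import avoids a hard dependency cycle with the metrics module
    from .metrics import weighted_km

    n = len(cohort)
    n_cases = int(cohort["event"].sum())
    incidence = 1.0 - weighted_km(
        cohort["time"], cohort["event"], np.ones(n), horizon
    )
    return {
        "n": n,
        "n_cases": n_cases,
        "n_controls": n - n_cases,
        "km_cumulative_incidence": float(incidence),
    }


def write_cohort(cohort: pd.DataFrame, path, sep: str = ",") -> None:
    cohort.to_csv(path, sep=sep, index=False)


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    cohort = pd.read_csv(path, sep=sep)
    required = {"subject_id", "time", "event"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return cohort
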