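"""Potential-outcome cohort simulator with a known, optionally heterogeneous CATE.

Cohorts follow the obesity-lifestyle schema (mixed continuous/categorical
covariates, a binary treatment embedded in one schema variable, and a
continuous BMI outcome) so the same validation, encoding and learner code
paths run on synthetic and real data alike.  Every latent quantity that a
real study never observes -- both potential outcomes, the true CATE
tau(x), and the true assignment probability -- is carried in ``truth_*``
columns alongside the observables.

The outcome model is

    Y(0) = mu0(x) + eps,   Y(1) = mu0(x) + tau(x) + eps,
    Y    = T * Y(1) + (1 - T) * Y(0),      eps ~ N(0, sigma^2), E(eps|x)=0,

with BMI = Y; Weight is back-computed as Y * Height**2 so the BMI
invariant holds on synthetic records.  mu0 and tau are functions of
standardized continuous covariates (z-scores under the design
distribution, not the sample), so their expectations are known in closed
form: E[tau(X)] equals the linear form's intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_data import CATEGORICAL, CONTINUOUS, TREATMENTS, Cohort, TreatmentSpec, validate_cohort

# design means/sds used to standardize continuous covariates inside mu0/tau;
# chosen once to mirror the observed summary of the overweight/obese table
_DESIGN_MOMENTS: dict[str, tuple[float, float]] = {
    "Age": (25.6, 6.48),
    "FCVC": (2.0, 0.577),   # uniform(1,3)
    "NCP": (2.5, 0.866),    # uniform(1,4)
    "CH2O": (2.0, 0.577),   # uniform(1,3)
    "FAF": (1.5, 0.866),    # uniform(0,3)
    "TUE": (1.0, 0.577),    # uniform(0,2)
}

# categorical frequencies mirroring the overweight/obese cohort summary
_CAT_PROBS: dict[str, dict[str, float]] = {
    "Gender": {"Female": 720 / 1544, "Male": 824 / 1544},
    "FHWO": {"Yes": 1442 / 1544, "No": 102 / 1544},
    "FAVC": {"Yes": 1429 / 1544, "No": 115 / 1544},
    "SCC": {"Yes": 38 / 1544, "No": 1506 / 1544},
    "SMOKE": {"Yes": 30 / 1544, "No": 1514 / 1544},
    "CAEC": {"Always": 17 / 1544, "Frequently": 38 / 1544,
             "No": 38 / 1544, "Sometimes": 1451 / 1544},
    "CALC": {"Frequently": 51 / 1544, "No": 414 / 1544, "Sometimes": 1079 / 1544},
    "MTRANS": {"Automobile": 364 / 1544, "Bike": 3 / 1544, "Motorbike": 5 / 1544,
               "Public_Transportation": 1154 / 1544, "Walking": 18 / 1544},
}

#: baseline BMI model: intercept + coefficients on z-scored covariates /
#: indicator of family history; keeps most of the cohort above the
#: overweight threshold, as in the population the method targets
DEFAULT_BASELINE: dict[str, float] = {
    "intercept": 32.0,
    "Age": 1.8,
    "FCVC": 1.2,
    "FAF": -0.8,
    "FHWO=Yes": 1.5,
}

#: default linear CATE: intercept + coefficients on z-scored covariates.
#: The mix of signs makes the optimal decision genuinely person-specific.
DEFAULT_LINEAR_CATE: dict[str, float] = {
    "intercept": -0.5,
    "FCVC": 1.2,
    "FAF": 0.8,
    "CH2O": 0.6,
}

#: default logistic assignment coefficients (on z-scores); the logistic
#: link guarantees overlap
DEFAULT_ASSIGNMENT: dict[str, float] = {
    "intercept": 0.3,
    "Age": 0.4,
    "FCVC": -0.4,
}


@dataclass
class SyntheticConfig:
    """Stated world for the simulator.

    Parameters
    ----------
    n : sample size.
    cate : "zero", "constant", "linear" or "nonlinear".
    cate_params : coefficients for the chosen form ("constant" reads key
        ``c``; "linear" reads intercept + per-covariate coefficients on
        z-scores; "nonlinear" reads ``amplitude``).
    noise_sd : sigma of the additive error (kg/m^2); 1.0 by default, a
        moderate residual scale relative to CATE magnitudes ~1-2.
    assignment : constant P(T=1) in (0,1), or "logistic" for
        covariate-dependent assignment.
    treatment : which schema variable carries the treatment.
    """

    n: int = 2000
    treatment: str = "CALC"
    baseline: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    cate: str = "linear"
    cate_params: Mapping[str, float] | None = None
    noise_sd: float = 1.0
    assignment: str | float = "logistic"
    assignment_params: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ASSIGNMENT))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if isinstance(self.assignment, (int, float)) and not 0 < float(self.assignment) < 1:
            raise ValueError("constant assignment probability must lie strictly in (0,1)")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.cate not in ("zero", "constant", "linear", "nonlinear"):
            raise ValueError(f"unknown cate form {self.cate!r}")
        tv = self.treatment

        def _prune(coefs: Mapping[str, float]) -> dict[str, float]:
            # the treatment column is overwritten by the drawn T, so no
            # structural function may reference it
            return {k: v for k, v in coefs.items()
                    if k != tv and k.split("=", 1)[0] != tv}

        user_supplied = self.cate_params is not None
        if not user_supplied:
            defaults = {"constant": {"c": 2.0},
                        "linear": _prune(DEFAULT_LINEAR_CATE),
                        "nonlinear": {"amplitude": 2.0}, "zero": {}}
            self.cate_params = defaults[self.cate]
        for attr, had_default in (("baseline", True), ("assignment_params", True),
                                  ("cate_params", not user_supplied)):
            coefs = dict(getattr(self, attr))
            if _prune(coefs) != coefs:
                if not had_default:
                    raise ValueError(
                        f"{attr} may not reference the treatment variable {tv!r}")
                coefs = _prune(coefs)
            setattr(self, attr, coefs)

    @property
    def treatment_spec(self) -> TreatmentSpec:
        return TREATMENTS[self.treatment]


def _zscores(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        name: (df[name].to_numpy(dtype=float) - mu) / sd
        for name, (mu, sd) in _DESIGN_MOMENTS.items()
    }


def _linear_form(coefs: Mapping[str, float], z: dict[str, np.ndarray],
                 df: pd.DataFrame, n: int) -> np.ndarray:
    out = np.full(n, float(coefs.get("intercept", 0.0)))
    for key, beta in coefs.items():
        if key == "intercept":
            continue
        if "=" in key:  # categorical indicator, e.g. "FHWO=Yes"
            col, level = key.split("=", 1)
            out += beta * (df[col].to_numpy() == level).astype(float)
        else:
            out += beta * z[key]
    return out


def cate_function(config: SyntheticConfig, df: pd.DataFrame) -> np.ndarray:
    """Evaluate the configured true CATE tau(x) on covariate rows."""
    n = len(df)
    z = _zscores(df)
    p = config.cate_params
    if config.cate == "zero":
        return np.zeros(n)
    if config.cate == "constant":
        return np.full(n, float(p["c"]))
    if config.cate == "linear":
        return _linear_form(p, z, df, n)
    # nonlinear: smooth, sign-switching in two lifestyle covariates
    # (skipping the treatment variable)
    amp = float(p.get("amplitude", 2.0))
    a, b = [v for v in ("FCVC", "FAF", "NCP") if v != config.treatment][:2]
    return amp * np.sin(z[a] + z[b])


def _propensity1(config: SyntheticConfig, df: pd.DataFrame) -> np.ndarray:
    """True P(T=1 | x); the logistic link keeps it strictly inside (0,1)."""
    if isinstance(config.assignment, (int, float)):
        return np.full(len(df), float(config.assignment))
    if config.assignment != "logistic":
        raise ValueError(f"unknown assignment {config.assignment!r}")
    eta = _linear_form(config.assignment_params, _zscores(df), df, len(df))
    return 1.0 / (1.0 + np.exp(-eta))


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort; observables plus ``truth_*`` latent columns.

    Reproducible bit-for-bit from (config, seed).  The treatment variable
    named in the config is written from the drawn T via the treatment
    spec's representative raw values, and Weight is set to BMI * Height^2
    so validation invariants hold.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    df = pd.DataFrame(index=range(n))

    df["Age"] = np.clip(rng.normal(25.6, 6.48, n), 15.0, 56.0).round(2)
    for name in ("FCVC", "NCP", "CH2O", "FAF", "TUE"):
        lo, hi = CONTINUOUS[name]
        df[name] = rng.uniform(lo, hi, n).round(3)
    for name, probs in _CAT_PROBS.items():
        levels = list(probs)
        df[name] = rng.choice(levels, size=n, p=np.asarray(list(probs.values())))
    df["Height"] = rng.uniform(1.45, 1.98, n).round(3)

    prop1 = _propensity1(config, df)
    if np.any(prop1 <= 0) or np.any(prop1 >= 1):
        raise ValueError("assignment violates overlap: P(T=1|x) hits 0 or 1")
    t = (rng.uniform(size=n) < prop1).astype(int)

    # embed T into the treatment schema column
    spec = config.treatment_spec
    df[spec.variable] = np.where(t == 1, spec.value1, spec.value0)
    if spec.variable in CONTINUOUS:
        df[spec.variable] = df[spec.variable].astype(float)

    mu0 = _linear_form(config.baseline, _zscores(df), df, n)
    tau = cate_function(config, df)
    eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    y0 = mu0 + eps
    y1 = mu0 + tau + eps
    y = np.where(t == 1, y1, y0)

    df["Weight"] = y * df["Height"] ** 2
    df["truth_y0"] = y0
    df["truth_y1"] = y1
    df["truth_tau"] = tau
    df["truth_propensity1"] = prop1

    return validate_cohort(df)


TIE = -1


def true_optimal(config: SyntheticConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Ground-truth optimal decision from the configured tau(x).

    Lower outcome is preferred: 0 where tau(x) > 0, 1 where tau(x) < 0,
    TIE (-1) where tau(x) == 0.
    """
    tau = cate_function(config, covariates)
    out = np.full(len(tau), TIE, dtype=int)
    out[tau > 0] = 0
    out[tau < 0] = 1
    return out
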