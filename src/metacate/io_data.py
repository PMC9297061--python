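"""Cohort IO: validation, BMI derivation, treatment binarization, encoding, splits.

The expected schema is the 17-column obesity-lifestyle table: demographic
and dietary covariates, Height (m) and Weight (kg) from which BMI is
derived, and an optional obesity-level label that is ignored (BMI is
always recomputed from Weight/Height**2).

Synthetic cohorts may carry extra latent-truth columns prefixed
``truth_``; these are passed through untouched and never enter the
covariate design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRUTH_PREFIX = "truth_"

#: the 14 lifestyle/demographic features usable as covariates or treatments
FEATURES: tuple[str, ...] = (
    "Age", "Gender", "FHWO", "FAVC", "FCVC", "NCP", "CAEC",
    "SMOKE", "CH2O", "SCC", "FAF", "TUE", "CALC", "MTRANS",
)

CONTINUOUS: dict[str, tuple[float, float]] = {
    "Age": (0.0, 130.0),
    "FCVC": (1.0, 3.0),
    "NCP": (1.0, 4.0),
    "CH2O": (1.0, 3.0),
    "FAF": (0.0, 3.0),
    "TUE": (0.0, 2.0),
}

CATEGORICAL: dict[str, tuple[str, ...]] = {
    "Gender": ("Female", "Male"),
    "FHWO": ("No", "Yes"),
    "FAVC": ("No", "Yes"),
    "SCC": ("No", "Yes"),
    "SMOKE": ("No", "Yes"),
    "CAEC": ("Always", "Frequently", "No", "Sometimes"),
    "CALC": ("Always", "Frequently", "No", "Sometimes"),
    "MTRANS": ("Automobile", "Bike", "Motorbike", "Public_Transportation", "Walking"),
}

#: common raw-file column names mapped onto the canonical schema
DEFAULT_SYNONYMS: dict[str, str] = {
    "family_history_with_overweight": "FHWO",
    "CH2O": "CH2O",
    "CH_2_O": "CH2O",
    "height": "Height",
    "weight": "Weight",
}

BMI_CATEGORIES: tuple[str, ...] = (
    "underweight", "normal", "overweight", "obese_I", "obese_II", "obese_III",
)
#: left-closed, right-open category edges (kg/m^2)
BMI_EDGES: tuple[float, ...] = (18.5, 25.0, 30.0, 35.0, 40.0)

#: overweight/obese screening threshold: records with BMI strictly above
#: this are candidates for BMI reduction
OVERWEIGHT_THRESHOLD = 24.9


class ValidationError(ValueError):
    """Raised when a cohort fails schema validation."""


# ---------------------------------------------------------------------------
# BMI

def compute_bmi(weight, height):
    """BMI = weight / height**2 (kg/m^2), elementwise.

    Raises :class:`ValidationError` naming the offending records when
    weight or height is non-positive.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    bad = ~((w > 0) & (h > 0))
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))[:10].tolist()
        raise ValidationError(
            f"non-positive weight or height at record positions {idx}"
        )
    return w / h**2


def categorize_bmi(bmi):
    """Assign the six obesity categories by half-open intervals.

    [0, 18.5) underweight, [18.5, 25) normal, [25, 30) overweight,
    [30, 35) obese_I, [35, 40) obese_II, [40, inf) obese_III.
    """
    b = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise ValidationError("BMI values must be finite and positive")
    codes = np.digitize(b, BMI_EDGES, right=False)
    if b.ndim == 0:
        return BMI_CATEGORIES[int(codes)]
    return np.asarray(BMI_CATEGORIES, dtype=object)[codes]


# ---------------------------------------------------------------------------
# Cohort

@dataclass
class Cohort:
    """A validated cohort table with derived ``BMI`` and ``BMI_category``."""

    data: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def bmi(self) -> np.ndarray:
        return self.data["BMI"].to_numpy(dtype=float)

    def truth_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(TRUTH_PREFIX)]

    def without_truths(self) -> "Cohort":
        return Cohort(self.data.drop(columns=self.truth_columns()))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _normalize_categorical(series: pd.Series, levels: Sequence[str]) -> pd.Series:
    """Map raw strings onto canonical levels, case/underscore-insensitively."""
    canon = {lv.lower().replace(" ", "_"): lv for lv in levels}
    out = series.astype(str).str.strip().map(
        lambda v: canon.get(v.lower().replace(" ", "_"), v)
    )
    return out


def validate_cohort(df: pd.DataFrame) -> Cohort:
    """Validate a raw table against the obesity schema and derive BMI.

    Rejects (never imputes) missing values, unknown categorical levels,
    out-of-range continuous values and non-positive Height/Weight.
    """
    df = df.copy()
    required = list(FEATURES) + ["Height", "Weight"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns: {missing_cols}")

    core = [c for c in df.columns if not c.startswith(TRUTH_PREFIX)]
    if df[core].isna().any().any():
        bad = df[core].columns[df[core].isna().any()].tolist()
        raise ValidationError(f"missing values in columns {bad}; imputation is not supported")

    for col, levels in CATEGORICAL.items():
        df[col] = _normalize_categorical(df[col], levels)
        unknown = sorted(set(df[col]) - set(levels))
        if unknown:
            raise ValidationError(f"column {col} has unknown levels {unknown}")

    for col, (lo, hi) in CONTINUOUS.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"column {col} has non-numeric values")
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"column {col} outside declared range [{lo}, {hi}]")
        df[col] = vals.astype(float)

    df["Height"] = pd.to_numeric(df["Height"])
    df["Weight"] = pd.to_numeric(df["Weight"])
    df["BMI"] = compute_bmi(df["Weight"], df["Height"])
    df["BMI_category"] = categorize_bmi(df["BMI"])
    return Cohort(df.reset_index(drop=True))


def load_cohort(path, column_map: Mapping[str, str] | str | Path | None = None) -> Cohort:
    """Read a cohort CSV, renaming columns via synonyms plus an optional map.

    ``column_map`` maps raw column names to canonical ones and may be a
    dict or a path to a YAML file holding one.
    """
    df = pd.read_csv(path)
    mapping = dict(DEFAULT_SYNONYMS)
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh) or {}
        mapping.update(column_map)
    df = df.rename(columns={c: mapping[c] for c in df.columns if c in mapping})
    # the obesity-level label, if present, is ignored: BMI is recomputed
    df = df.drop(columns=[c for c in ("NObeyesdad", "ObesityLevel") if c in df.columns])
    return validate_cohort(df)


def filter_overweight(cohort: Cohort) -> Cohort:
    """Keep the overweight/obese records (BMI strictly above 24.9), order preserved."""
    keep = cohort.data["BMI"] > OVERWEIGHT_THRESHOLD
    out = cohort.data.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("overweight filter produced an empty cohort", stacklevel=2)
    return Cohort(out)


# ---------------------------------------------------------------------------
# Treatments

@dataclass(frozen=True)
class TreatmentSpec:
    """Maps one schema variable onto a binary treatment T in {0, 1}.

    Lower outcome (BMI) is always preferred, so the personalized optimal
    decision is T=0 whenever tau(x) > 0.
    """

    variable: str
    rule: Callable[[object], int]
    label1: str
    label0: str
    #: raw values the rule accepts, used for error reporting and for the
    #: synthetic generator's inverse map (observable value for T=1 / T=0)
    value1: object = None
    value0: object = None


def _calc_rule(v):
    return 0 if v == "No" else 1


TREATMENTS: dict[str, TreatmentSpec] = {
    # any positive drinking frequency counts as treated
    "CALC": TreatmentSpec("CALC", _calc_rule, "alcohol: Yes", "alcohol: No",
                          value1="Sometimes", value0="No"),
    "FCVC": TreatmentSpec("FCVC", lambda v: 1 if float(v) > 2 else 0,
                          "vegetables every meal", "vegetables not every meal",
                          value1=2.5, value0=1.5),
    "FAVC": TreatmentSpec("FAVC", lambda v: 1 if v == "Yes" else 0,
                          "high-caloric food: Yes", "high-caloric food: No",
                          value1="Yes", value0="No"),
    "CH2O": TreatmentSpec("CH2O", lambda v: 1 if float(v) > 2 else 0,
                          "water > 2 L/day", "water <= 2 L/day",
                          value1=2.5, value0=1.5),
}


def binarize_treatment(cohort: Cohort, spec: TreatmentSpec) -> np.ndarray:
    """Apply the spec's rule to the treatment column, returning T in {0,1}^n."""
    if spec.variable not in cohort.data.columns:
        raise ValidationError(f"treatment variable {spec.variable!r} not in cohort")
    raw = cohort.data[spec.variable]
    out = np.empty(len(raw), dtype=int)
    bad = []
    for i, v in enumerate(raw):
        try:
            t = int(spec.rule(v))
        except Exception:
            t = -1
        if t not in (0, 1):
            bad.append(v)
        else:
            out[i] = t
    if bad:
        raise ValidationError(
            f"treatment rule for {spec.variable!r} cannot map values: {sorted(set(map(str, bad)))[:10]}"
        )
    return out


# ---------------------------------------------------------------------------
# Encoding

def encode_covariates(
    cohort: Cohort,
    spec: TreatmentSpec | None = None,
    drop_constant: bool = True,
) -> pd.DataFrame:
    """Build the numeric covariate design matrix.

    Covariates are the 14 lifestyle/demographic features minus the
    treatment variable (when ``spec`` is given).  Weight, Height, BMI and
    latent-truth columns are never covariates.  Categorical features are
    one-hot encoded with drop-first under lexicographic order of the
    *observed* levels (unobserved declared levels would only contribute
    constant, collinear columns), so designs are bit-for-bit reproducible
    for a given cohort.
    """
    feats = [f for f in FEATURES if spec is None or f != spec.variable]
    blocks: list[pd.DataFrame] = []
    for f in feats:
        col = cohort.data[f]
        if f in CATEGORICAL:
            levels = sorted(col.unique())
            cat = pd.Categorical(col, categories=levels)
            dummies = pd.get_dummies(cat, prefix=f, drop_first=True, dtype=float)
            blocks.append(dummies.set_axis(cohort.data.index))
        else:
            blocks.append(col.astype(float).to_frame(f))
    design = pd.concat(blocks, axis=1)
    if drop_constant:
        const = [c for c in design.columns if design[c].nunique() <= 1]
        if const:
            logger.warning("dropping constant covariate columns: %s", const)
            design = design.drop(columns=const)
    return design


# ---------------------------------------------------------------------------
# Splits

@dataclass
class SplitPlan:
    """Named ordered fractions plus a seed controlling the shuffle."""

    fractions: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(f <= 0 for f in self.fractions.values()):
            raise ValueError("all fractions must be positive")


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    short = n - sum(sizes)
    # distribute leftovers to the largest fractional remainders, earlier
    # parts win ties
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def split_cohort(n_or_cohort, plan: SplitPlan) -> dict[str, np.ndarray]:
    """Shuffle indices with the plan's seed and cut by largest-remainder sizes.

    Returns named, disjoint, exhaustive integer index arrays.
    """
    n = n_or_cohort if isinstance(n_or_cohort, (int, np.integer)) else n_or_cohort.n
    names = list(plan.fractions)
    sizes = _largest_remainder_sizes(n, [plan.fractions[k] for k in names])
    if any(s == 0 for s in sizes):
        raise ValueError(f"split produced an empty part for n={n}: {dict(zip(names, sizes))}")
    perm = np.random.default_rng(plan.seed).permutation(n)
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, size in zip(names, sizes):
        out[name] = np.sort(perm[start:start + size])
        start += size
    return out
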