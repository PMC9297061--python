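"""The five CATE metalearners and the personalized decision rule.

All learners estimate tau(x) = E[Y(1) - Y(0) | X = x] for a binary
treatment and convert it to a decision: because a *lower* outcome (BMI)
is preferred, tau(x) > 0 means T=0 is personalized optimal, tau(x) < 0
means T=1, and tau(x) == 0 is a tie.

Learners
--------
T       two outcome models, one per arm; tau = mu1 - mu0.
S       one joint model mu(x, t) on the design [x, t, x*t]; interaction
        columns are mandatory, since without them a linear joint model
        forces a constant (non-personalized) effect.
X       arm models as in T, then imputed individual effects
        D0 = mu1(x) - Y(0) on controls and D1 = Y(1) - mu0(x) on treated,
        regressed on x to give tau0, tau1; blended with the propensity.
SX      joint model (no interactions) fit on a *training* split, imputed
        effects computed on a disjoint *re-training* split.
SXwint  SX with treatment-covariate interaction columns in the joint model.

Propensity convention: g(x) = P(T = 0 | X = x) -- the control
probability -- and the blend is tau = g*tau0 + (1-g)*tau1.  Much of the
literature uses P(T=1); here g weights tau0 (fit on controls, where the
*treated* outcome was imputed) by the chance of being a control.
Estimated propensities are clipped to [delta, 1-delta], delta = 0.01.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

TIE = -1
PROPENSITY_CLIP = 0.01

LEARNER_KINDS = ("T", "S", "X", "SX", "SXwint")


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from a pipeline seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class BaseLearnerSpec:
    """Factories for the supervised components every metalearner plugs in.

    ``regressor``/``classifier`` are callables accepting a
    ``random_state`` keyword and returning unfitted scikit-learn style
    estimators.  Defaults are random forests with 100 trees and a minimum
    of 7 observations per split.
    """

    regressor: Callable = field(default_factory=lambda: _default_regressor)
    classifier: Callable = field(default_factory=lambda: _default_classifier)

    def make_regressor(self, seed: int, label: str):
        return self.regressor(random_state=derive_seed(seed, label))

    def make_classifier(self, seed: int, label: str):
        return self.classifier(random_state=derive_seed(seed, label))


def _default_regressor(random_state=0):
    return RandomForestRegressor(
        n_estimators=100, min_samples_split=7, random_state=random_state
    )


def _default_classifier(random_state=0):
    return RandomForestClassifier(
        n_estimators=100, min_samples_split=7, random_state=random_state
    )


def default_spec() -> BaseLearnerSpec:
    return BaseLearnerSpec()


def linear_spec() -> BaseLearnerSpec:
    """Linear bases: exact algebra on noiseless linear data; used in tests."""
    return BaseLearnerSpec(
        regressor=lambda random_state=0: LinearRegression(),
        classifier=lambda random_state=0: LogisticRegression(max_iter=1000),
    )


# ---------------------------------------------------------------------------
# design helpers

def _as_matrix(X, columns=None):
    if isinstance(X, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in X.columns]
            if missing:
                raise ValueError(f"covariate schema mismatch; missing columns {missing}")
            X = X[list(columns)]
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), columns


def build_interactions(X, t) -> np.ndarray:
    """Augmented design [x, t, x*t]; 2p+1 columns for p covariates."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(t)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("treatment must be binary {0,1}")
    t = t.astype(float)
    return np.hstack([X, t[:, None], X * t[:, None]])


def _joint_design(X, t, interactions: bool) -> np.ndarray:
    if interactions:
        return build_interactions(X, t)
    t = np.asarray(t, dtype=float)
    return np.hstack([np.asarray(X, dtype=float), t[:, None]])


# ---------------------------------------------------------------------------
# fitted model container

@dataclass
class CateModel:
    """A fitted metalearner: kind tag plus the fitted components it needs."""

    kind: str
    components: dict
    columns: list | None = None
    interactions: bool = False
    #: forces g(x) to a constant; bypasses clipping (testing/diagnostic knob)
    propensity_override: float | None = None

    def predict_cate(self, X) -> np.ndarray:
        """tau-hat, one finite value per record."""
        M, _ = _as_matrix(X, self.columns)
        c = self.components
        if self.kind == "T":
            tau = c["mu1"].predict(M) - c["mu0"].predict(M)
        elif self.kind == "S":
            mu = c["mu"]
            tau = (mu.predict(_joint_design(M, np.ones(len(M)), self.interactions))
                   - mu.predict(_joint_design(M, np.zeros(len(M)), self.interactions)))
        elif self.kind in ("X", "SX", "SXwint"):
            g = self._propensity(M)
            tau = g * c["tau0"].predict(M) + (1.0 - g) * c["tau1"].predict(M)
        else:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        tau = np.asarray(tau, dtype=float)
        if not np.all(np.isfinite(tau)):
            raise ValueError("non-finite tau-hat prediction")
        return tau

    def predict_outcomes(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(mu-hat(x,0), mu-hat(x,1)) for learners that model outcomes directly."""
        M, _ = _as_matrix(X, self.columns)
        c = self.components
        if self.kind == "T":
            return c["mu0"].predict(M), c["mu1"].predict(M)
        if self.kind in ("S", "SX", "SXwint"):
            mu = c["mu"]
            return (mu.predict(_joint_design(M, np.zeros(len(M)), self.interactions)),
                    mu.predict(_joint_design(M, np.ones(len(M)), self.interactions)))
        raise ValueError(f"{self.kind} learner has no joint outcome model")

    def decide(self, X) -> np.ndarray:
        return decide_optimal(self.predict_cate(X))

    def _propensity(self, M: np.ndarray) -> np.ndarray:
        if self.propensity_override is not None:
            return np.full(len(M), float(self.propensity_override))
        return self.components["g"].predict_control_probability(M)


# ---------------------------------------------------------------------------
# propensity

class PropensityModel:
    """Wraps a classifier to output clipped g(x) = P(T=0 | X=x)."""

    def __init__(self, clf, delta: float = PROPENSITY_CLIP):
        self.clf = clf
        self.delta = delta

    def predict_control_probability(self, M) -> np.ndarray:
        M = np.asarray(M, dtype=float)
        idx = list(self.clf.classes_).index(0)
        g = self.clf.predict_proba(M)[:, idx]
        return np.clip(g, self.delta, 1.0 - self.delta)


def estimate_propensity(X, t, spec: BaseLearnerSpec | None = None, *,
                        seed: int = 0, delta: float = PROPENSITY_CLIP,
                        label: str = "propensity") -> PropensityModel:
    """Fit g(x) = P(T=0 | X=x), clipped to [delta, 1-delta]."""
    spec = spec or default_spec()
    M, _ = _as_matrix(X)
    t = np.asarray(t)
    if len(np.unique(t)) < 2:
        raise ValueError("cannot estimate a propensity score with a single treatment arm")
    clf = spec.make_classifier(seed, label)
    clf.fit(M, t)
    return PropensityModel(clf, delta)


# ---------------------------------------------------------------------------
# learners

def _check_arms(t, where: str) -> None:
    t = np.asarray(t)
    for arm in (0, 1):
        if not np.any(t == arm):
            raise ValueError(f"treatment arm T={arm} is empty in {where}")


def fit_t_learner(X, y, t, spec: BaseLearnerSpec | None = None, *,
                  seed: int = 0, columns=None) -> CateModel:
    """Separate outcome models per arm; tau-hat = mu1-hat - mu0-hat."""
    spec = spec or default_spec()
    M, columns = _as_matrix(X, columns)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    _check_arms(t, "training data")
    mu0 = spec.make_regressor(seed, "T.mu0").fit(M[t == 0], y[t == 0])
    mu1 = spec.make_regressor(seed, "T.mu1").fit(M[t == 1], y[t == 1])
    return CateModel("T", {"mu0": mu0, "mu1": mu1}, columns=columns)


def fit_s_learner(X, y, t, spec: BaseLearnerSpec | None = None, *,
                  interactions: bool = True, seed: int = 0, columns=None) -> CateModel:
    """Single joint model mu(x,t) on [x, t, x*t].

    ``interactions`` must be True: without the x*t block a linear joint
    model can only express a constant treatment effect, so the estimated
    policy would not be personalized.
    """
    if not interactions:
        raise ValueError(
            "S learner requires treatment-covariate interaction terms; "
            "without them the estimated effect is constant in x and the "
            "policy is not personalized"
        )
    spec = spec or default_spec()
    M, columns = _as_matrix(X, columns)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    mu = spec.make_regressor(seed, "S.mu").fit(_joint_design(M, t, True), y)
    return CateModel("S", {"mu": mu}, columns=columns, interactions=True)


def fit_x_learner(X, y, t, spec: BaseLearnerSpec | None = None, *,
                  seed: int = 0, columns=None,
                  propensity_override: float | None = None) -> CateModel:
    """X learner: arm models, imputed effects, propensity blend."""
    spec = spec or default_spec()
    M, columns = _as_matrix(X, columns)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    _check_arms(t, "training data")

    mu0 = spec.make_regressor(seed, "X.mu0").fit(M[t == 0], y[t == 0])
    mu1 = spec.make_regressor(seed, "X.mu1").fit(M[t == 1], y[t == 1])
    # imputed individual effects on each arm
    d0 = mu1.predict(M[t == 0]) - y[t == 0]
    d1 = y[t == 1] - mu0.predict(M[t == 1])
    tau0 = spec.make_regressor(seed, "X.tau0").fit(M[t == 0], d0)
    tau1 = spec.make_regressor(seed, "X.tau1").fit(M[t == 1], d1)

    components = {"mu0": mu0, "mu1": mu1, "tau0": tau0, "tau1": tau1}
    if propensity_override is None:
        components["g"] = estimate_propensity(M, t, spec, seed=seed, label="X.g")
    return CateModel("X", components, columns=columns,
                     propensity_override=propensity_override)


def fit_sx_learner(X_train, y_train, t_train, X_retrain, y_retrain, t_retrain,
                   spec: BaseLearnerSpec | None = None, *,
                   interactions: bool = False, seed: int = 0, columns=None,
                   propensity_override: float | None = None,
                   train_index=None, retrain_index=None) -> CateModel:
    """SX (no interactions) / SXwint (with interactions) hybrid learner.

    The joint model mu(x,t) is fit on the training split; imputed effects
    D0 = mu-hat(x,1) - Y(0) and D1 = Y(1) - mu-hat(x,0) are computed on
    the disjoint re-training split, where tau0/tau1 are fit; the
    propensity is fit on the union of both splits.  Pass
    ``train_index``/``retrain_index`` to assert split disjointness.
    """
    if train_index is not None and retrain_index is not None:
        overlap = np.intersect1d(np.asarray(train_index), np.asarray(retrain_index))
        if overlap.size:
            raise ValueError(f"training and re-training splits overlap at indices {overlap[:10].tolist()}")
    spec = spec or default_spec()
    kind = "SXwint" if interactions else "SX"
    Mtr, columns = _as_matrix(X_train, columns)
    Mre, _ = _as_matrix(X_retrain, columns)
    ytr = np.asarray(y_train, dtype=float)
    yre = np.asarray(y_retrain, dtype=float)
    ttr = np.asarray(t_train)
    tre = np.asarray(t_retrain)
    _check_arms(tre, "re-training data")

    mu = spec.make_regressor(seed, f"{kind}.mu").fit(_joint_design(Mtr, ttr, interactions), ytr)
    M0, M1 = Mre[tre == 0], Mre[tre == 1]
    d0 = mu.predict(_joint_design(M0, np.ones(len(M0)), interactions)) - yre[tre == 0]
    d1 = yre[tre == 1] - mu.predict(_joint_design(M1, np.zeros(len(M1)), interactions))
    tau0 = spec.make_regressor(seed, f"{kind}.tau0").fit(M0, d0)
    tau1 = spec.make_regressor(seed, f"{kind}.tau1").fit(M1, d1)

    components = {"mu": mu, "tau0": tau0, "tau1": tau1}
    if propensity_override is None:
        M_union = np.vstack([Mtr, Mre])
        t_union = np.concatenate([ttr, tre])
        components["g"] = estimate_propensity(M_union, t_union, spec, seed=seed,
                                              label=f"{kind}.g")
    return CateModel(kind, components, columns=columns, interactions=interactions,
                     propensity_override=propensity_override)


def predict_cate(model: CateModel, X) -> np.ndarray:
    return model.predict_cate(X)


def save_model(model: CateModel, directory) -> None:
    """Persist a fitted model: JSON manifest + joblib component blobs."""
    import json
    from pathlib import Path

    import joblib

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": model.kind,
        "columns": model.columns,
        "interactions": model.interactions,
        "propensity_override": model.propensity_override,
        "components": sorted(model.components),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(model.components, d / "components.joblib")


def load_model(directory) -> CateModel:
    import json
    from pathlib import Path

    import joblib

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    components = joblib.load(d / "components.joblib")
    return CateModel(manifest["kind"], components, columns=manifest["columns"],
                     interactions=manifest["interactions"],
                     propensity_override=manifest["propensity_override"])


def decide_optimal(tau) -> np.ndarray:
    """Decision per record: 0 if tau>0, 1 if tau<0, TIE (-1) if tau==0."""
    tau = np.asarray(tau, dtype=float)
    if np.any(np.isnan(tau)):
        raise ValueError("tau-hat contains NaN")
    out = np.full(tau.shape, TIE, dtype=int)
    out[tau > 0] = 0
    out[tau < 0] = 1
    return out
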