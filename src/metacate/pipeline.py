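"""Config-driven end-to-end analysis runs.

A run loads or simulates a cohort, restricts it to overweight/obese
records (BMI > 24.9), screens features with the covariance test, and for
each requested treatment fits the requested metalearners, converts
tau-hat to personalized decisions on a held-out testing half, and
evaluates the decomposition into personalized-optimal / non-optimal /
general-optimal groups with two KS tests.

Split topology: every learner shares one testing half per run.  T, X and
S train on the complementary half; SX and SXwint split that half again
into equal training and re-training parts (so overall 1/4 : 1/4 : 1/2),
and their propensity is fit on the union -- the same records the other
learners train on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covtest, evaluation, io_data, metalearners
from .io_data import Cohort, SplitPlan, TreatmentSpec
from .metalearners import BaseLearnerSpec, derive_seed
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

ALL_LEARNERS = list(metalearners.LEARNER_KINDS)


@dataclass
class RunConfig:
    source: str | Path | SyntheticConfig
    treatments: list[str] = field(default_factory=lambda: ["CALC"])
    learners: list[str] = field(default_factory=lambda: list(ALL_LEARNERS))
    seed: int = 0
    base_spec: BaseLearnerSpec | None = None
    outdir: str | Path | None = None
    filter_overweight: bool = True
    #: re-shuffle the split for every treatment instead of sharing one split
    resplit_per_treatment: bool = False
    exact_ks: bool = False

    def __post_init__(self) -> None:
        if not self.learners:
            raise ValueError("at least one learner must be requested")
        unknown = [l for l in self.learners if l not in ALL_LEARNERS]
        if unknown:
            raise ValueError(f"unknown learners {unknown}; choose from {ALL_LEARNERS}")


def _load(config: RunConfig) -> Cohort:
    if isinstance(config.source, SyntheticConfig):
        return generate_cohort(config.source)
    return io_data.load_cohort(config.source)


def _encode_with_blocks(cohort: Cohort, spec: TreatmentSpec | None):
    design = io_data.encode_covariates(cohort, spec)
    blocks = {
        f: [c for c in design.columns if c == f or c.startswith(f + "_")]
        for f in io_data.FEATURES
    }
    blocks = {f: cols for f, cols in blocks.items() if cols}
    return design, blocks


def _fit_all(learners, X, y, t, idx, spec, seed, treatment):
    """Fit the requested learners on the shared training half."""
    train, train_a, retrain = idx["train"], idx["train_a"], idx["retrain"]
    models: dict[str, metalearners.CateModel] = {}
    for kind in learners:
        s = derive_seed(seed, f"{treatment}.{kind}")
        if kind == "T":
            models[kind] = metalearners.fit_t_learner(
                X.iloc[train], y[train], t[train], spec, seed=s)
        elif kind == "S":
            models[kind] = metalearners.fit_s_learner(
                X.iloc[train], y[train], t[train], spec, seed=s)
        elif kind == "X":
            models[kind] = metalearners.fit_x_learner(
                X.iloc[train], y[train], t[train], spec, seed=s)
        else:
            models[kind] = metalearners.fit_sx_learner(
                X.iloc[train_a], y[train_a], t[train_a],
                X.iloc[retrain], y[retrain], t[retrain],
                spec, interactions=(kind == "SXwint"), seed=s,
                train_index=train_a, retrain_index=retrain)
    return models


def _splits(n: int, seed: int) -> dict[str, np.ndarray]:
    """train:test = 1/2:1/2, with train further halved into train_a/retrain."""
    top = io_data.split_cohort(n, SplitPlan({"train": 0.5, "test": 0.5}, seed=seed))
    train = top["train"]
    sub = io_data.split_cohort(
        len(train), SplitPlan({"train_a": 0.5, "retrain": 0.5},
                              seed=derive_seed(seed, "retrain-split")))
    idx = {"train": train, "test": top["test"],
           "train_a": train[sub["train_a"]], "retrain": train[sub["retrain"]]}
    for name, part in idx.items():
        logger.info("split %s: %d records", name, len(part))
    return idx


def analyze_treatment(cohort: Cohort, treatment: str | TreatmentSpec,
                      *, learners=None, seed: int = 0,
                      base_spec: BaseLearnerSpec | None = None,
                      exact_ks: bool = False) -> dict:
    """Fit the learners for one treatment and evaluate on the testing half."""
    spec = io_data.TREATMENTS[treatment] if isinstance(treatment, str) else treatment
    learners = learners or ALL_LEARNERS
    t = io_data.binarize_treatment(cohort, spec)
    X, _ = _encode_with_blocks(cohort, spec)
    y = cohort.bmi
    n_arm = np.bincount(t, minlength=2)
    logger.info("treatment %s: arms T=0 %d / T=1 %d", spec.variable, n_arm[0], n_arm[1])

    idx = _splits(cohort.n, seed)
    models = _fit_all(learners, X, y, t, idx, base_spec, seed, spec.variable)

    test = idx["test"]
    X_test, y_test, t_test = X.iloc[test], y[test], t[test]
    general = evaluation.general_rule(y_test, t_test)

    per_learner: dict[str, dict] = {}
    for kind, model in models.items():
        tau = model.predict_cate(X_test)
        decisions = metalearners.decide_optimal(tau)
        res = evaluation.evaluate_learner(y_test, t_test, decisions, general,
                                          exact_ks=exact_ks)
        res.update(tau=tau, decisions=decisions, model=model)
        g = res["groups"]
        res["ratios"] = {
            "O": evaluation.treatment_ratio(t_test[g.O]),
            "NO": evaluation.treatment_ratio(t_test[g.NO]),
            "testing": evaluation.treatment_ratio(t_test),
            "cohort": evaluation.treatment_ratio(t),
        }
        if "truth_tau" in cohort.data.columns:
            truth = metalearners.decide_optimal(
                cohort.data["truth_tau"].to_numpy()[test])
            comparable = truth != metalearners.TIE
            res["truth_agreement"] = float(
                np.mean(decisions[comparable] == truth[comparable]))
        per_learner[kind] = res

    table = evaluation.results_table(per_learner)
    overlaps = evaluation.overlap_matrix(
        {k: per_learner[k]["groups"].O for k in per_learner})
    return {"treatment": spec.variable, "general_decision": general,
            "splits": idx, "observed_t": t, "per_learner": per_learner,
            "table": table, "overlaps": overlaps}


def run_analysis(config: RunConfig) -> dict:
    """Full pipeline: load, filter, screen, fit, evaluate, optionally write reports."""
    cohort = _load(config)
    if config.filter_overweight:
        cohort = io_data.filter_overweight(cohort)
    logger.info("cohort size after filtering: %d", cohort.n)

    design, blocks = _encode_with_blocks(cohort, spec=None)
    screen = covtest.feature_report(design, cohort.bmi, blocks=blocks)

    results: dict = {"cohort": cohort, "screen": screen, "treatments": {}}
    for i, name in enumerate(config.treatments):
        seed = (derive_seed(config.seed, f"treatment:{name}")
                if config.resplit_per_treatment else config.seed)
        results["treatments"][name] = analyze_treatment(
            cohort, name, learners=config.learners, seed=seed,
            base_spec=config.base_spec, exact_ks=config.exact_ks)

    if config.outdir is not None:
        _write_reports(results, Path(config.outdir))
    return results


def _write_reports(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["screen"].to_csv(outdir / "feature_screen.csv", index=False)
    for name, res in results["treatments"].items():
        d = outdir / name
        d.mkdir(exist_ok=True)
        res["table"].to_csv(d / "ks_report.csv", index=False)
        res["overlaps"].to_csv(d / "overlap_matrix.csv")
        ratios = pd.DataFrame(
            {k: v["ratios"] for k, v in res["per_learner"].items()}
        ).T.rename_axis("learner")
        ratios.to_csv(d / "treatment_ratios.csv")
        test = res["splits"]["test"]
        dec = pd.DataFrame({"record": test})
        for kind, r in res["per_learner"].items():
            dec[f"tau_{kind}"] = r["tau"]
            dec[f"decision_{kind}"] = r["decisions"]
        dec.to_csv(d / "decisions.csv", index=False)
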