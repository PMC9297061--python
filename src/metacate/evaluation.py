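"""Group decomposition and distributional comparison of personalized decisions.

On the testing data, three groups are compared:

* O  (personalized optimal): observed treatment equals the learner's
  personalized optimal decision;
* NO (non-optimal): observed treatment differs from it;
* G  (general optimal): observed treatment equals the single
  "one-for-all" recommendation (the arm with lower mean outcome).

Records whose estimated effect is exactly zero (tie decisions) belong to
neither O nor NO and are reported separately, so |O| + |NO| + |ties|
always equals the testing size.  Two-sample Kolmogorov-Smirnov tests
compare the outcome distributions of O vs NO (test 1) and O vs G
(test 2); lower outcomes in O support the personalized rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metalearners import TIE


@dataclass
class GroupDecomposition:
    """Positional index sets over the testing data."""

    O: np.ndarray
    NO: np.ndarray
    G: np.ndarray
    ties: np.ndarray

    def sizes(self) -> dict[str, int]:
        return {"O": len(self.O), "NO": len(self.NO), "G": len(self.G),
                "ties": len(self.ties)}


@dataclass
class KSResult:
    """Two-sample KS statistic D, its p-value and the sample sizes."""

    D: float
    p: float
    m: int
    n: int


def general_rule(bmi, t) -> int:
    """The one-for-all decision: the arm with lower mean outcome.

    An exact tie is broken toward 0 with a warning.
    """
    bmi = np.asarray(bmi, dtype=float)
    t = np.asarray(t)
    means = {}
    for arm in (0, 1):
        vals = bmi[t == arm]
        if vals.size == 0:
            raise ValueError(f"treatment arm T={arm} is empty; cannot form a general rule")
        means[arm] = vals.mean()
    if means[0] == means[1]:
        warnings.warn("arm means are exactly equal; breaking the tie toward T=0",
                      stacklevel=2)
        return 0
    return 0 if means[0] < means[1] else 1


def decompose_groups(observed_t, decisions, general_decision: int) -> GroupDecomposition:
    """Partition testing records into O / NO / ties and pick out G."""
    observed_t = np.asarray(observed_t)
    decisions = np.asarray(decisions)
    if observed_t.shape != decisions.shape:
        raise ValueError(
            f"length mismatch: observed {observed_t.shape} vs decisions {decisions.shape}")
    tie_mask = decisions == TIE
    o_mask = ~tie_mask & (decisions == observed_t)
    no_mask = ~tie_mask & (decisions != observed_t)
    g_mask = observed_t == general_decision
    return GroupDecomposition(
        O=np.flatnonzero(o_mask),
        NO=np.flatnonzero(no_mask),
        G=np.flatnonzero(g_mask),
        ties=np.flatnonzero(tie_mask),
    )


def ks_two_sample(sample_a, sample_b, *, exact: bool = False) -> KSResult:
    """Two-sample KS test: D = max |ECDF_a - ECDF_b| over merged points.

    The p-value comes from the asymptotic Kolmogorov distribution with
    effective size mn/(m+n) by default; ``exact=True`` switches to the
    exact small-sample distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    # the asymptotic tail underflows to 0 for extreme D; keep p in (0, 1]
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return KSResult(D=float(res.statistic), p=p, m=a.size, n=b.size)


def treatment_ratio(t) -> float | None:
    """Ratio of level-1 to level-0 counts, 3 decimals; None when undefined."""
    t = np.asarray(t)
    n1 = int(np.sum(t == 1))
    n0 = int(np.sum(t == 0))
    if n0 == 0:
        return None
    return round(n1 / n0, 3)


def learner_overlap(o_a, o_b) -> float | None:
    """Percent of the first learner's optimal group shared with the second."""
    a, b = set(np.asarray(o_a).tolist()), set(np.asarray(o_b).tolist())
    if not a:
        return None
    return 100.0 * len(a & b) / len(a)


def overlap_matrix(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise overlap percentages; entry (row a, col b) = % of O_a in O_b."""
    names = list(groups)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = learner_overlap(groups[a], groups[b])
    return mat


def evaluate_learner(bmi_test, observed_t, decisions, general_decision: int,
                     *, exact_ks: bool = False) -> dict:
    """KS tests 1 (O vs NO) and 2 (O vs G) plus group sizes for one learner."""
    bmi_test = np.asarray(bmi_test, dtype=float)
    groups = decompose_groups(observed_t, decisions, general_decision)
    ks1 = ks_two_sample(bmi_test[groups.O], bmi_test[groups.NO], exact=exact_ks)
    ks2 = ks_two_sample(bmi_test[groups.O], bmi_test[groups.G], exact=exact_ks)
    return {"groups": groups, "ks1": ks1, "ks2": ks2}


def results_table(per_learner: dict[str, dict]) -> pd.DataFrame:
    """Assemble the per-learner summary (KS D/p, group sizes) as a table."""
    rows = []
    for name, res in per_learner.items():
        g: GroupDecomposition = res["groups"]
        rows.append({
            "learner": name,
            "ks1_D": res["ks1"].D, "ks1_p": res["ks1"].p,
            "ks2_D": res["ks2"].D, "ks2_p": res["ks2"].p,
            "n_O": len(g.O), "n_NO": len(g.NO), "n_G": len(g.G),
            "n_ties": len(g.ties),
        })
    return pd.DataFrame(rows)
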