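"""Lasso solution path and the covariance test for entering variables.

The lasso path is piecewise linear in the penalty lambda; at a knot
lambda_k a new variable joins the active set.  The covariance test
assigns the k-th entering variable the statistic

    T_k = ( <y, X b(lambda_{k+1})> - <y, X_A b_A(lambda_{k+1})> ) / sigma^2

where b(.) is the lasso solution on all variables, b_A(.) the lasso
solution restricted to the active set A *before* the variable entered,
both evaluated at the next knot.  Under the null that all signal
variables are already in A, T_k is asymptotically standard exponential,
so p = P(Exp(1) > T_k) = exp(-T_k).  On an orthonormal design the knots
are the sorted |x_j' y| and T_1 = lambda_1 (lambda_1 - lambda_2) /
sigma^2, which the tests use as a closed-form oracle.

Columns are standardized to unit variance and the outcome centered
before the path, so knots are comparable across variables; knots are
reported on the inner-product scale lambda = max_j |x_j' r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.linear_model import lars_path


@dataclass
class LassoPath:
    """Knots (strictly decreasing, inner-product scale) and path coefficients.

    ``entering[k]`` is the column index that joins the active set at
    ``knots[k]``; ``coefs`` has one column per event including the final
    lambda = 0 (least-squares) endpoint.
    """

    knots: np.ndarray
    entering: np.ndarray
    #: per entry event, the active set just before the variable entered
    #: (lasso paths can drop and re-admit variables, so this is read off
    #: the path rather than accumulated)
    active_before: list
    alphas: np.ndarray          # all event lambdas, decreasing, ends at 0
    coefs: np.ndarray           # (p, n_events) piecewise-linear path
    columns: list[str]
    X: np.ndarray               # standardized design used for the path
    y: np.ndarray               # centered outcome

    @property
    def n_entries(self) -> int:
        return len(self.knots)


@dataclass
class CovTestResult:
    """Per-entering-variable covariance statistic and Exp(1) p-value."""

    table: pd.DataFrame  # columns: variable, statistic, p_value, entry_order
    sigma2: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _standardize(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = y - y.mean()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return X / sd, y


def lasso_path_fit(design, outcome, *, standardize: bool = True,
                   max_entries: int | None = None,
                   check_rank: bool = True) -> LassoPath:
    """Compute the lasso (LARS) solution path.

    Raises on a rank-deficient design, listing the collinear columns;
    ``check_rank=False`` skips the O(n p^2) rank test for hot loops on
    designs known to be full rank.
    """
    if isinstance(design, pd.DataFrame):
        columns = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        columns = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)

    if standardize:
        X, y = _standardize(X, y)

    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = sla.qr(X, mode="economic", pivoting=True)
            bad = sorted(columns[j] for j in piv[rank:])
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    # scikit-learn returns alphas = max_j |x_j' r| / n; rescale to the
    # inner-product convention
    n = X.shape[0]
    kwargs = {} if max_entries is None else {"max_iter": max_entries}
    alphas, _, coefs = lars_path(X, y, method="lasso", **kwargs)
    alphas = alphas * n

    entering: list[int] = []
    knots: list[float] = []
    active_before: list[tuple[int, ...]] = []
    for k in range(1, coefs.shape[1]):
        prev = set(np.flatnonzero(coefs[:, k - 1]))
        new = set(np.flatnonzero(coefs[:, k])) - prev
        for j in sorted(new):
            entering.append(j)
            knots.append(alphas[k - 1])
            active_before.append(tuple(sorted(prev)))
    return LassoPath(np.asarray(knots), np.asarray(entering, dtype=int),
                     active_before, alphas, coefs, columns, X, y)


#: preferred public name
lasso_path = lasso_path_fit


def _coef_at(alphas: np.ndarray, coefs: np.ndarray, lam: float) -> np.ndarray:
    """Interpolate the piecewise-linear path at penalty lam (>= 0)."""
    if lam >= alphas[0]:
        return np.zeros(coefs.shape[0])
    # np.interp needs increasing x
    rev_a = alphas[::-1]
    return np.array([np.interp(lam, rev_a, coefs[j, ::-1]) for j in range(coefs.shape[0])])


def covariance_test(path: LassoPath, sigma2: float | None = None) -> CovTestResult:
    """Covariance-test statistics and Exp(1) p-values along the path.

    ``sigma2`` defaults to the residual variance of the full
    least-squares fit (valid in the n > p regime).
    """
    X, y = path.X, path.y
    n, p = X.shape
    if sigma2 is None:
        beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta_ls) ** 2))
        dof = n - p - 1
        if dof <= 0:
            raise ValueError("cannot estimate sigma^2: n <= p + 1")
        sigma2 = rss / dof
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")

    rows = []
    for k, (j, lam) in enumerate(zip(path.entering, path.knots)):
        # next event lambda strictly below this knot (0 at the path end)
        below = path.alphas[path.alphas < lam - 1e-12]
        lam_next = float(below[0]) if below.size else 0.0

        beta_full = _coef_at(path.alphas, path.coefs, lam_next)
        fit_full = float(y @ (X @ beta_full))
        if path.active_before[k]:
            sub = np.asarray(path.active_before[k], dtype=int)
            sub_path = lasso_path_fit(X[:, sub], y, standardize=False,
                                      check_rank=False)
            beta_sub = _coef_at(sub_path.alphas, sub_path.coefs, lam_next)
            fit_sub = float(y @ (X[:, sub] @ beta_sub))
        else:
            fit_sub = 0.0
        stat = (fit_full - fit_sub) / sigma2
        stat = max(stat, 0.0)  # guard tiny negative round-off
        rows.append({
            "variable": path.columns[j],
            "statistic": stat,
            "p_value": float(np.exp(-stat)),
            "entry_order": k + 1,
        })

    table = pd.DataFrame(rows, columns=["variable", "statistic", "p_value", "entry_order"])
    return CovTestResult(table, float(sigma2))


def screen_features(result: CovTestResult, alpha: float = 0.05,
                    blocks: dict[str, list[str]] | None = None) -> list[str]:
    """Variables significant at level alpha, in entry order.

    ``blocks`` maps an original feature to its one-hot column names; a
    block's p-value is that of its first entering column, and the block
    name is reported once.
    """
    tab = result.table.sort_values("entry_order")
    if blocks:
        col_to_block = {c: b for b, cols in blocks.items() for c in cols}
        seen: set[str] = set()
        out = []
        for _, row in tab.iterrows():
            name = col_to_block.get(row["variable"], row["variable"])
            if name in seen:
                continue
            seen.add(name)
            if row["p_value"] < alpha:
                out.append(name)
        return out
    return [r["variable"] for _, r in tab.iterrows() if r["p_value"] < alpha]


def feature_report(design: pd.DataFrame, outcome, *,
                   blocks: dict[str, list[str]] | None = None,
                   sigma2: float | None = None) -> pd.DataFrame:
    """One-row-per-feature screening report (feature, statistic, p-value).

    With ``blocks``, a categorical feature is summarized by its first
    entering one-hot column.
    """
    path = lasso_path_fit(design, outcome)
    result = covariance_test(path, sigma2=sigma2)
    tab = result.table.copy()
    if blocks:
        col_to_block = {c: b for b, cols in blocks.items() for c in cols}
        tab["feature"] = tab["variable"].map(lambda c: col_to_block.get(c, c))
        tab = tab.sort_values("entry_order").drop_duplicates("feature")
    else:
        tab["feature"] = tab["variable"]
    return tab[["feature", "statistic", "p_value", "entry_order"]].reset_index(drop=True)
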