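"""Testing stage: formal interaction models for selected feature pairs.

For a binary disease the model is the four-parameter logistic regression

    logit P[D] = a + b1*g1 + b2*g2 + b3*g1*g2

fit by maximum likelihood; for a continuous trait (the within-diseased
design, e.g. BMI among obese study participants) it is the analogous
ordinary least-squares model.  Three null patterns are supported:

- interaction_1df            H0: b3 = 0
- main1_plus_interaction_2df H0: b_main = b3 = 0 (which main is configurable)
- joint_3df                  H0: b1 = b2 = b3 = 0

The canonical statistic is the likelihood-ratio chi-square (logistic) or
the partial F statistic (linear), with a Wald variant available as a
cross-check.  Note the deliberate scale mismatch with the simulator: data
generated on the relative-risk scale are analyzed on the odds scale, as a
case-control analysis would do in practice; no correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestRecord",
    "fit_logistic_interaction",
    "fit_linear_joint",
    "SeparationError",
    "TEST_KINDS",
]

TestKind = Literal["interaction_1df", "main1_plus_interaction_2df", "joint_3df"]
TEST_KINDS: tuple[str, ...] = (
    "interaction_1df",
    "main1_plus_interaction_2df",
    "joint_3df",
)

# columns of the full design (1, g1, g2, g1*g2) dropped under each null
_NULL_DROPS = {
    ("interaction_1df", 1): [3],
    ("main1_plus_interaction_2df", 1): [1, 3],
    ("main1_plus_interaction_2df", 2): [2, 3],
    ("joint_3df", 1): [1, 2, 3],
}

# statsmodels raises PerfectSeparationWarning-or-Error depending on version
try:  # pragma: no cover - version shim
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    PerfectSeparationError = RuntimeError


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in the logistic fit."""


@dataclass(frozen=True)
class TestRecord:
    """Testing-stage result for one feature pair."""

    pair: tuple[int, int]
    coefficients: np.ndarray  # (intercept, b1, b2, b3) on the logit/linear scale
    test_kind: str
    statistic: float
    df: int
    p_value: float
    adjusted_p: float | None = None


def _hypothesis_df(test_kind: str) -> int:
    return {"interaction_1df": 1, "main1_plus_interaction_2df": 2, "joint_3df": 3}[
        test_kind
    ]


def _design(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(g1), g1, g2, g1 * g2])


def _validate(g1, g2, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (g1.shape == g2.shape == y.shape) or g1.ndim != 1:
        raise ValueError("g1, g2 and the outcome must be 1-d vectors of equal length")
    if np.isnan(g1).any() or np.isnan(g2).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before testing")
    return g1, g2, y


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design matrix (1, g1, g2, g1*g2); "
            "the pair cannot be tested"
        )


def _null_columns(test_kind: str, main_effect: int) -> list[int]:
    if test_kind not in TEST_KINDS:
        raise ValueError(f"unknown test_kind {test_kind!r}; expected one of {TEST_KINDS}")
    if main_effect not in (1, 2):
        raise ValueError("main_effect must be 1 or 2")
    key = (test_kind, main_effect if test_kind == "main1_plus_interaction_2df" else 1)
    drops = _NULL_DROPS[key]
    return [c for c in range(4) if c not in drops]


def _fit_logit(y: np.ndarray, X: np.ndarray):
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"logistic fit failed ({exc}); check for empty or separated "
            "genotype-by-disease cells"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            "logistic fit did not converge in 100 Newton iterations; the "
            "likelihood is likely unbounded (complete or quasi-complete "
            "separation in some genotype cell)"
        )
    if np.abs(res.params).max() > 30:
        raise SeparationError(
            "diverging coefficient (|beta| > 30) indicates quasi-complete "
            "separation in a genotype-by-disease cell"
        )
    return res


def fit_logistic_interaction(
    g1: Sequence[float],
    g2: Sequence[float],
    disease: Sequence[int],
    test_kind: TestKind = "interaction_1df",
    *,
    main_effect: int = 1,
    pair: tuple[int, int] = (0, 1),
    statistic: Literal["lr", "wald"] = "lr",
) -> TestRecord:
    """Fit the logistic interaction model and test one null pattern.

    The statistic is the likelihood-ratio chi-square comparing the full
    four-parameter model to the restricted model for `test_kind` (Wald
    available via `statistic="wald"` as a cross-check), referred to a
    chi-square with 1, 2 or 3 df.
    """
    g1, g2, y = _validate(g1, g2, disease)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("disease must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("both disease classes must be present to fit the model")
    X = _design(g1, g2)
    _check_rank(X)
    full = _fit_logit(y, X)
    df = _hypothesis_df(test_kind)
    keep = _null_columns(test_kind, main_effect)
    if statistic == "lr":
        null = _fit_logit(y, X[:, keep])
        stat = float(2.0 * (full.llf - null.llf))
        stat = max(stat, 0.0)
    elif statistic == "wald":
        drop = [c for c in range(4) if c not in keep]
        b = full.params[drop]
        V = full.cov_params()[np.ix_(drop, drop)]
        stat = float(b @ np.linalg.solve(V, b))
    else:
        raise ValueError(f"statistic must be 'lr' or 'wald', got {statistic!r}")
    p = float(stats.chi2.sf(stat, df))
    return TestRecord(
        pair=pair,
        coefficients=np.asarray(full.params, dtype=float),
        test_kind=test_kind,
        statistic=stat,
        df=df,
        p_value=p,
    )


def fit_linear_joint(
    g1: Sequence[float],
    g2: Sequence[float],
    trait: Sequence[float],
    test_kind: TestKind = "joint_3df",
    *,
    main_effect: int = 1,
    pair: tuple[int, int] = (0, 1),
) -> TestRecord:
    """OLS fit of trait ~ 1 + g1 + g2 + g1*g2 with a partial F test.

    Intended for the within-diseased two-stage design, where pairs screened
    for unexpected dependence among affected individuals are tested for
    joint effects on a continuous trait in the same sample.
    """
    g1, g2, y = _validate(g1, g2, trait)
    X = _design(g1, g2)
    _check_rank(X)
    if g1.size - 4 < 1:
        raise ValueError("residual degrees of freedom < 1")
    if np.ptp(y) == 0.0:
        raise ValueError("constant trait: no variance to model")
    full = sm.OLS(y, X).fit()
    df = _hypothesis_df(test_kind)
    keep = _null_columns(test_kind, main_effect)
    null = sm.OLS(y, X[:, keep]).fit()
    tol = 1e-10 * float(y @ y)
    if full.ssr <= tol:
        # perfect fit: F diverges unless the restricted model fits exactly too
        stat, p = (0.0, 1.0) if null.ssr <= tol else (np.inf, 0.0)
    else:
        f_res = full.compare_f_test(null)
        stat, p = float(f_res[0]), float(f_res[1])
    return TestRecord(
        pair=pair,
        coefficients=np.asarray(full.params, dtype=float),
        test_kind=test_kind,
        statistic=stat,
        df=df,
        p_value=p,
    )
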