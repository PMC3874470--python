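"""Screening stage: composite LD between feature pairs.

Composite LD between two loci is operationalized as the Pearson
product-moment correlation of their additive 0/1/2 codings (continuous
exposures pass through the same statistic unchanged).  Significance comes
from the exact t transform, t = r * sqrt((n-2) / (1 - r^2)), referred to a
t distribution with n-2 degrees of freedom, two-sided.

Crucially the statistic is a function of the features only: given a pooled
case-control sample it never looks at the disease column, which is what
makes downstream testing-stage multiplicity correction over the selected
pairs alone valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .simmodel import Scheme

__all__ = [
    "ScreenRecord",
    "composite_ld_screen",
    "screen_all_pairs",
    "CompositeLDScreen",
    "UnscreenablePairError",
]


class UnscreenablePairError(ValueError):
    """A pair cannot be screened (constant feature in the selected rows)."""


@dataclass(frozen=True)
class ScreenRecord:
    """Screening result for one unordered feature pair."""

    pair: tuple[int, int]
    r: float
    t_stat: float
    df: int
    p_value: float
    scheme: Scheme
    n: int
    screenable: bool = True


def _pearson_t(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, int, float]:
    n = g1.size
    x = g1 - g1.mean()
    y = g2 - g2.mean()
    sx = np.sqrt(x @ x)
    sy = np.sqrt(y @ y)
    if sx == 0.0 or sy == 0.0:
        raise UnscreenablePairError(
            "constant feature vector: composite LD is undefined"
        )
    r = float(np.clip((x @ y) / (sx * sy), -1.0, 1.0))
    df = n - 2
    if abs(r) >= 1.0:
        # degenerate perfect correlation: t diverges, tail mass is 0
        return r, np.inf if r > 0 else -np.inf, df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), df, float(p)


def composite_ld_screen(
    g1: Sequence[float], g2: Sequence[float], scheme: Scheme = "pooled"
) -> ScreenRecord:
    """Screen a single feature pair for composite LD.

    Missing values (NaN) are dropped pairwise; the record carries the
    effective n.  Raises `UnscreenablePairError` for a constant vector.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("g1 and g2 must be 1-d vectors of equal length")
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep], g2[keep]
    if g1.size < 3:
        raise ValueError(f"need at least 3 complete observations, got {g1.size}")
    r, t, df, p = _pearson_t(g1, g2)
    return ScreenRecord(
        pair=(0, 1), r=r, t_stat=t, df=df, p_value=p, scheme=scheme, n=int(g1.size)
    )


def _select_rows(
    G: np.ndarray, scheme: Scheme, disease: np.ndarray | None
) -> np.ndarray:
    if scheme == "pooled":
        return G  # pooled uses every sampled row; the disease column is ignored
    if disease is None:
        # the matrix is taken to be a single-stratum sample already
        return G
    disease = np.asarray(disease)
    want = 1 if scheme == "cases_only" else 0
    return G[disease == want]


def screen_all_pairs(
    G: np.ndarray,
    scheme: Scheme = "pooled",
    disease: np.ndarray | None = None,
) -> list[ScreenRecord]:
    """Screen every unordered column pair of `G` under a sampling scheme.

    Rows are restricted to the stratum named by `scheme` (pooled keeps all
    rows and ignores `disease` entirely).  Pairs are enumerated in (j, k)
    order with j < k.  A pair with a monomorphic column in the selected
    stratum is returned flagged `screenable=False` with NaN statistics so
    callers can exclude it from selection and from multiplicity counts.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("G must be a 2-d (individuals x features) matrix")
    sub = _select_rows(G, scheme, disease)
    n, p = sub.shape
    if n < 3:
        raise ValueError(f"selected stratum has {n} rows; need at least 3")
    has_nan = bool(np.isnan(sub).any())
    records: list[ScreenRecord] = []
    if not has_nan:
        # vectorized path: one pass over standardized columns
        sd = sub.std(axis=0, ddof=0)
        ok = sd > 0
        Z = np.zeros_like(sub)
        Z[:, ok] = (sub[:, ok] - sub[:, ok].mean(axis=0)) / sd[ok]
        R = np.clip((Z.T @ Z) / n, -1.0, 1.0)
        df = n - 2
        for j, k in combinations(range(p), 2):
            if not (ok[j] and ok[k]):
                records.append(
                    ScreenRecord((j, k), np.nan, np.nan, df, np.nan, scheme, n, False)
                )
                continue
            r = float(R[j, k])
            if abs(r) >= 1.0:
                t, pv = (np.inf if r > 0 else -np.inf), 0.0
            else:
                t = float(r * np.sqrt(df / (1.0 - r * r)))
                pv = float(2.0 * stats.t.sf(abs(t), df))
            records.append(ScreenRecord((j, k), r, t, df, pv, scheme, n, True))
        return records
    for j, k in combinations(range(p), 2):
        try:
            rec = composite_ld_screen(sub[:, j], sub[:, k], scheme=scheme)
        except UnscreenablePairError:
            records.append(
                ScreenRecord((j, k), np.nan, np.nan, n - 2, np.nan, scheme, n, False)
            )
        else:
            records.append(
                ScreenRecord(
                    (j, k), rec.r, rec.t_stat, rec.df, rec.p_value, scheme, rec.n
                )
            )
    return records


class CompositeLDScreen(BaseEstimator):
    """Pairwise composite-LD screen as a fittable scanner.

    Parameters
    ----------
    scheme : {"pooled", "cases_only", "controls_only"}
        Which rows of the ascertained sample enter the correlation.
    alpha : float
        Nominal level used by `selected_pairs_`.

    Attributes
    ----------
    records_ : list of ScreenRecord
    pvalues_ : ndarray, NaN for unscreenable pairs
    selected_pairs_ : list of (j, k) with p <= alpha
    """

    def __init__(self, scheme: Scheme = "pooled", alpha: float = 0.05):
        self.scheme = scheme
        self.alpha = alpha

    def fit(self, X, y=None):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.records_ = screen_all_pairs(X, scheme=self.scheme, disease=y)
        self.pvalues_ = np.array([rec.p_value for rec in self.records_])
        self.selected_pairs_ = [
            rec.pair
            for rec in self.records_
            if rec.screenable and rec.p_value <= self.alpha
        ]
        return self
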