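"""Screen -> select -> test -> adjust orchestration.

The validity contract: the screening statistic is a function of the
features alone (given the ascertained sample), so under the global null of
feature-trait independence the selected subset is a function of variables
independent of the trait, and multiplicity correction needs to count only
the tests actually conducted in the testing stage.  Bonferroni over
`n_tested` is therefore exact-level, regardless of whether the pairwise
independence assumption motivating the screen holds in the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .screening import ScreenRecord, screen_all_pairs
from .simmodel import Scheme
from .testing import (
    TEST_KINDS,
    TestRecord,
    fit_linear_joint,
    fit_logistic_interaction,
)

__all__ = ["TwoStageConfig", "TwoStageResult", "TwoStageScan", "run_two_stage"]


@dataclass(frozen=True)
class TwoStageConfig:
    """Configuration of a two-stage scan.

    Exactly one of `alpha_screen` / `m` is active, matching `selection`.
    Screening level and testing-stage family level are independent knobs:
    screening costs no testing-stage alpha.
    """

    screen_scheme: Scheme = "pooled"
    selection: Literal["p_threshold", "top_m"] = "p_threshold"
    alpha_screen: float = 0.05
    m: int | None = None
    test_kind: str = "interaction_1df"
    main_effect: int = 1
    family_alpha: float = 0.05
    correction: Literal["bonferroni"] = "bonferroni"

    def __post_init__(self) -> None:
        if self.selection == "p_threshold":
            if not 0.0 < self.alpha_screen <= 1.0:
                raise ValueError(
                    f"alpha_screen must be in (0, 1], got {self.alpha_screen}"
                )
        elif self.selection == "top_m":
            if self.m is None or self.m < 0:
                raise ValueError("selection='top_m' requires m >= 0")
        else:
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.test_kind not in TEST_KINDS:
            raise ValueError(f"unknown test_kind {self.test_kind!r}")
        if not 0.0 < self.family_alpha < 1.0:
            raise ValueError("family_alpha must be in (0, 1)")
        if self.correction != "bonferroni":
            raise ValueError("bonferroni is the only built-in correction")


@dataclass(frozen=True)
class TwoStageResult:
    screened: list[ScreenRecord]
    tested: list[TestRecord]
    n_tested: int
    discoveries: list[tuple[int, int]]
    config: TwoStageConfig = field(default_factory=TwoStageConfig)


def _select(records: list[ScreenRecord], config: TwoStageConfig) -> list[ScreenRecord]:
    screenable = [rec for rec in records if rec.screenable]
    if config.selection == "p_threshold":
        return [rec for rec in screenable if rec.p_value <= config.alpha_screen]
    # top_m: m smallest screening p-values, ties at the boundary broken by
    # pair index order (records arrive already sorted by pair)
    ranked = sorted(screenable, key=lambda rec: (rec.p_value, rec.pair))
    return sorted(ranked[: config.m], key=lambda rec: rec.pair)


class TwoStageScan(BaseEstimator):
    """Two-stage interaction scan as a fittable estimator.

    Screens all feature pairs for composite LD under `screen_scheme`,
    selects survivors by p-value threshold or top-m rank, tests each
    survivor in a formal interaction model (logistic for binary disease,
    linear when a continuous trait is supplied), and Bonferroni-adjusts
    over the number of tests actually conducted.

    Attributes (after fit)
    ----------------------
    screened_ : list of ScreenRecord for every pair
    tested_ : list of TestRecord for the selected pairs
    n_tested_ : int
    discoveries_ : list of pairs with adjusted p <= family_alpha
    result_ : TwoStageResult bundling the above
    """

    def __init__(
        self,
        screen_scheme: Scheme = "pooled",
        selection: Literal["p_threshold", "top_m"] = "p_threshold",
        alpha_screen: float = 0.05,
        m: int | None = None,
        test_kind: str = "interaction_1df",
        main_effect: int = 1,
        family_alpha: float = 0.05,
        correction: str = "bonferroni",
    ):
        self.screen_scheme = screen_scheme
        self.selection = selection
        self.alpha_screen = alpha_screen
        self.m = m
        self.test_kind = test_kind
        self.main_effect = main_effect
        self.family_alpha = family_alpha
        self.correction = correction

    def _config(self) -> TwoStageConfig:
        return TwoStageConfig(
            screen_scheme=self.screen_scheme,
            selection=self.selection,
            alpha_screen=self.alpha_screen,
            m=self.m,
            test_kind=self.test_kind,
            main_effect=self.main_effect,
            family_alpha=self.family_alpha,
            correction=self.correction,  # type: ignore[arg-type]
        )

    def fit(self, X, y=None, trait=None):
        """Run the scan on features `X` with disease labels `y`.

        If `trait` is given the testing stage is the linear joint model on
        the supplied (possibly single-stratum) sample; otherwise the
        logistic interaction model on `y`.
        """
        config = self._config()
        X = np.asarray(X, dtype=float)
        if y is not None:
            y = np.asarray(y)
        if trait is None and y is None:
            raise ValueError("need disease labels y and/or a continuous trait")
        self.n_features_in_ = X.shape[1]
        screened = screen_all_pairs(X, scheme=config.screen_scheme, disease=y)
        selected = _select(screened, config)
        tested: list[TestRecord] = []
        for rec in selected:
            j, k = rec.pair
            if trait is not None:
                tr = fit_linear_joint(
                    X[:, j], X[:, k], trait,
                    test_kind=config.test_kind,
                    main_effect=config.main_effect,
                    pair=(j, k),
                )
            else:
                tr = fit_logistic_interaction(
                    X[:, j], X[:, k], y,
                    test_kind=config.test_kind,
                    main_effect=config.main_effect,
                    pair=(j, k),
                )
            tested.append(tr)
        n_tested = len(tested)
        adjusted = [
            TestRecord(
                pair=tr.pair,
                coefficients=tr.coefficients,
                test_kind=tr.test_kind,
                statistic=tr.statistic,
                df=tr.df,
                p_value=tr.p_value,
                adjusted_p=min(1.0, tr.p_value * n_tested),
            )
            for tr in tested
        ]
        discoveries = [
            tr.pair for tr in adjusted if tr.adjusted_p <= config.family_alpha
        ]
        self.screened_ = screened
        self.tested_ = adjusted
        self.n_tested_ = n_tested
        self.discoveries_ = discoveries
        self.result_ = TwoStageResult(
            screened=screened,
            tested=adjusted,
            n_tested=n_tested,
            discoveries=discoveries,
            config=config,
        )
        return self


def run_two_stage(
    G: np.ndarray,
    disease: Sequence[int] | None,
    trait: Sequence[float] | None = None,
    config: TwoStageConfig | None = None,
) -> TwoStageResult:
    """Functional wrapper over `TwoStageScan`; see the class for semantics."""
    config = config or TwoStageConfig()
    scan = TwoStageScan(**asdict(config))
    scan.fit(G, y=disease, trait=trait)
    return scan.result_
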