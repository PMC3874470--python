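"""Plug-in permutation estimator of the FDR for two-stage scans.

Under exchangeability of observations and the null of independence between
the feature matrix and the trait, permuting the trait labels generates
draws from the null distribution of the whole screening-testing scan.  The
plug-in estimate at a p-value threshold t is

    fdr_hat(t) = mean_perm #{null p <= t} / #{observed p <= t},

capped at 1 and without a pi0 correction (conservative).  The estimator is
usable with very few permutations (the default is 10).

When the screening scheme ignores trait labels within the fixed sample
(the pooled scheme), the screen and hence the selected pair set are
invariant under label permutation, so only the testing stage needs to be
recomputed per permutation — an exact optimization, not an approximation.
For cases_only / controls_only screens the stratum itself changes with the
labels and the full scan is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .testing import fit_logistic_interaction
from .twostage import TwoStageConfig, _select, run_two_stage

__all__ = ["FdrEstimate", "permutation_fdr", "PermutationFDR"]


@dataclass(frozen=True)
class FdrEstimate:
    """Plug-in FDR estimate at one p-value threshold."""

    threshold: float
    n_observed: int
    mean_null: float
    fdr_hat: float
    n_perm: int
    undefined: bool = False  # no observed discoveries at this threshold
    mc_se: float = 0.0  # Monte-Carlo SE of mean_null / n_observed over permutations


def _tested_pvalues_fixed_selection(
    G: np.ndarray,
    disease: np.ndarray,
    config: TwoStageConfig,
    selected_pairs: Sequence[tuple[int, int]],
) -> np.ndarray:
    out = np.empty(len(selected_pairs))
    for i, (j, k) in enumerate(selected_pairs):
        rec = fit_logistic_interaction(
            G[:, j], G[:, k], disease,
            test_kind=config.test_kind,
            main_effect=config.main_effect,
            pair=(j, k),
        )
        out[i] = rec.p_value
    return out


def permutation_fdr(
    G: np.ndarray,
    disease: Sequence[int],
    config: TwoStageConfig | None = None,
    n_perm: int = 10,
    thresholds: Sequence[float] = (0.05, 0.01, 0.001),
    seed: int = 0,
    *,
    force_naive: bool = False,
) -> list[FdrEstimate]:
    """Estimate the FDR of a two-stage scan at each p-value threshold.

    Observed testing-stage p-values come from the scan on the real labels;
    null p-values from scans on uniformly permuted labels.  Deterministic
    given `seed`.  `force_naive=True` disables the pooled-scheme shortcut
    and recomputes the full scan per permutation (used for verification;
    results are identical for the pooled scheme by construction).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    config = config or TwoStageConfig()
    G = np.asarray(G, dtype=float)
    disease = np.asarray(disease)
    rng = np.random.default_rng(seed)

    observed = run_two_stage(G, disease, config=config)
    obs_p = np.array([tr.p_value for tr in observed.tested])

    can_shortcut = config.screen_scheme == "pooled" and not force_naive
    if can_shortcut:
        selected_pairs = [rec.pair for rec in _select(observed.screened, config)]

    null_counts = np.zeros((n_perm, len(thresholds)))
    for b in range(n_perm):
        perm = rng.permutation(disease)
        if can_shortcut:
            null_p = _tested_pvalues_fixed_selection(G, perm, config, selected_pairs)
        else:
            null_p = np.array(
                [tr.p_value for tr in run_two_stage(G, perm, config=config).tested]
            )
        for it, t in enumerate(thresholds):
            null_counts[b, it] = np.count_nonzero(null_p <= t)

    estimates: list[FdrEstimate] = []
    for it, t in enumerate(thresholds):
        n_obs = int(np.count_nonzero(obs_p <= t))
        mean_null = float(null_counts[:, it].mean())
        if n_perm > 1:
            se_counts = float(null_counts[:, it].std(ddof=1) / np.sqrt(n_perm))
        else:
            se_counts = 0.0
        if n_obs == 0:
            estimates.append(
                FdrEstimate(float(t), 0, mean_null, 0.0, n_perm, undefined=True)
            )
        else:
            estimates.append(
                FdrEstimate(
                    float(t), n_obs, mean_null,
                    min(1.0, mean_null / n_obs), n_perm,
                    mc_se=se_counts / n_obs,
                )
            )
    return estimates


class PermutationFDR(BaseEstimator):
    """Permutation FDR for a two-stage scan, as a fittable estimator.

    Parameters mirror `TwoStageConfig` plus `n_perm`, `thresholds` and
    `random_state`.  After `fit(X, y)` the attribute `estimates_` holds one
    `FdrEstimate` per threshold.
    """

    def __init__(
        self,
        config: TwoStageConfig | None = None,
        n_perm: int = 10,
        thresholds: Sequence[float] = (0.05, 0.01, 0.001),
        random_state: int = 0,
        force_naive: bool = False,
    ):
        self.config = config
        self.n_perm = n_perm
        self.thresholds = thresholds
        self.random_state = random_state
        self.force_naive = force_naive

    def fit(self, X, y):
        self.estimates_ = permutation_fdr(
            X, y,
            config=self.config,
            n_perm=self.n_perm,
            thresholds=self.thresholds,
            seed=self.random_state,
            force_naive=self.force_naive,
        )
        return self
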