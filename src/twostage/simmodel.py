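"""Generative log relative-risk model for two interacting biallelic SNPs.

The population model is

    log P[D] = lambda + beta1*g1 + beta2*g2 + beta3*g1*g2

with g1, g2 the minor-allele counts (0/1/2) of two SNPs that are drawn
independently under Hardy-Weinberg equilibrium.  Disease status is Bernoulli
with the per-individual risk, clamped at 1.  Case-control samples are drawn
by simple random sampling without replacement within each disease stratum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PopulationModel",
    "Population",
    "CaseControlSample",
    "simulate_population",
    "sample_case_control",
    "expected_prevalence",
    "hwe_probs",
]

Scheme = Literal["cases_only", "controls_only", "pooled"]


@dataclass(frozen=True)
class PopulationModel:
    """Parameters of the log relative-risk disease model.

    Parameters
    ----------
    baseline_log_risk : float
        lambda; exp(lambda) is the disease risk for a (0, 0) genotype and
        must lie in (0, 1).
    beta1, beta2 : float
        Per-allele log relative risks of the two SNPs.
    beta3 : float
        Interaction log relative risk (departure from multiplicativity on
        the relative-risk scale).
    maf1, maf2 : float
        Minor allele frequencies, in (0, 0.5] by convention.
    """

    baseline_log_risk: float
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    maf1: float = 0.2
    maf2: float = 0.2

    def __post_init__(self) -> None:
        coefs = (self.baseline_log_risk, self.beta1, self.beta2, self.beta3)
        if not all(math.isfinite(c) for c in coefs):
            raise ValueError(f"model coefficients must be finite, got {coefs}")
        base = math.exp(self.baseline_log_risk)
        if not 0.0 < base < 1.0:
            raise ValueError(
                f"exp(baseline_log_risk) must be in (0, 1), got {base:g}"
            )
        for name, q in (("maf1", self.maf1), ("maf2", self.maf2)):
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {q!r}")
            if q > 0.5:
                raise ValueError(
                    f"{name}={q!r}: frequencies refer to the minor allele "
                    "and must not exceed 0.5"
                )

    def risk(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        """Per-individual disease risk, clamped at 1."""
        g1 = np.asarray(g1, dtype=float)
        g2 = np.asarray(g2, dtype=float)
        log_risk = (
            self.baseline_log_risk
            + self.beta1 * g1
            + self.beta2 * g2
            + self.beta3 * g1 * g2
        )
        return np.minimum(1.0, np.exp(log_risk))


@dataclass(frozen=True)
class Population:
    """A simulated cohort: genotype matrix (n_pop x 2) plus disease status."""

    genotypes: np.ndarray
    disease: np.ndarray
    model: PopulationModel
    seed: int

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def prevalence(self) -> float:
        return float(self.disease.mean())


@dataclass(frozen=True)
class CaseControlSample:
    """An ascertained sample; `scheme` records which strata are present."""

    genotypes: np.ndarray
    disease: np.ndarray
    scheme: Scheme = field(default="pooled")

    def __post_init__(self) -> None:
        d = np.asarray(self.disease)
        if self.scheme == "cases_only" and not np.all(d == 1):
            raise ValueError("cases_only sample contains controls")
        if self.scheme == "controls_only" and not np.all(d == 0):
            raise ValueError("controls_only sample contains cases")
        if self.scheme == "pooled" and (np.all(d == 1) or np.all(d == 0)):
            raise ValueError("pooled sample must contain both cases and controls")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for counts (0, 1, 2)."""
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def expected_prevalence(model: PopulationModel) -> float:
    """Exact population prevalence by enumeration of the 9 genotype cells.

    Sum over (g1, g2) in {0,1,2}^2 of HWE cell probability times the clamped
    risk.  Serves as the closed-form counterpart of `simulate_population`.
    """
    p1 = hwe_probs(model.maf1)
    p2 = hwe_probs(model.maf2)
    g = np.arange(3)
    risk = model.risk(g[:, None], g[None, :])
    return float(np.sum(p1[:, None] * p2[None, :] * risk))


def simulate_population(
    model: PopulationModel, n_pop: int, seed: int
) -> Population:
    """Simulate a population of `n_pop` individuals under `model`.

    Genotypes are binomial(2, maf) per SNP (HWE), the two SNPs independent.
    Disease is Bernoulli with risk min(1, exp(lambda + b1*g1 + b2*g2 +
    b3*g1*g2)).  The master seed is split into independent genotype and
    disease streams, so the same genotypes recur across risk-coefficient
    grids that share a seed.
    """
    if n_pop < 1:
        raise ValueError(f"n_pop must be >= 1, got {n_pop}")
    geno_rng, dis_rng = _split_rng(seed)
    g1 = geno_rng.binomial(2, model.maf1, size=n_pop)
    g2 = geno_rng.binomial(2, model.maf2, size=n_pop)
    genotypes = np.column_stack([g1, g2]).astype(np.int8)
    risk = model.risk(g1, g2)
    log_risk_raw = (
        model.baseline_log_risk
        + model.beta1 * g1
        + model.beta2 * g2
        + model.beta3 * g1 * g2
    )
    n_clamped = int(np.count_nonzero(log_risk_raw > 0))
    if n_clamped:
        warnings.warn(
            f"risk clamped at 1 for {n_clamped}/{n_pop} individuals "
            f"({n_clamped / n_pop:.2%})",
            RuntimeWarning,
            stacklevel=2,
        )
    disease = (dis_rng.random(n_pop) < risk).astype(np.int8)
    return Population(genotypes=genotypes, disease=disease, model=model, seed=seed)


def sample_case_control(
    pop: Population, n_cases: int, n_controls: int, seed: int
) -> CaseControlSample:
    """Draw a case-control sample from `pop` by within-stratum SRS.

    `scheme` is inferred: cases_only if n_controls == 0, controls_only if
    n_cases == 0, pooled otherwise.  Raises if a stratum is too small rather
    than silently resampling.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("n_cases and n_controls must be non-negative")
    if n_cases == 0 and n_controls == 0:
        raise ValueError("requested an empty sample")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(pop.disease == 1)
    ctrl_idx = np.flatnonzero(pop.disease == 0)
    if n_cases > case_idx.size:
        raise ValueError(
            f"requested {n_cases} cases but population has only "
            f"{case_idx.size} affected individuals"
        )
    if n_controls > ctrl_idx.size:
        raise ValueError(
            f"requested {n_controls} controls but population has only "
            f"{ctrl_idx.size} unaffected individuals"
        )
    chosen = []
    if n_cases:
        chosen.append(rng.choice(case_idx, size=n_cases, replace=False))
    if n_controls:
        chosen.append(rng.choice(ctrl_idx, size=n_controls, replace=False))
    idx = np.concatenate(chosen)
    if n_cases == 0:
        scheme: Scheme = "controls_only"
    elif n_controls == 0:
        scheme = "cases_only"
    else:
        scheme = "pooled"
    return CaseControlSample(
        genotypes=pop.genotypes[idx], disease=pop.disease[idx], scheme=scheme
    )


def _split_rng(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    geno_ss, dis_ss = ss.spawn(2)
    return np.random.default_rng(geno_ss), np.random.default_rng(dis_ss)
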