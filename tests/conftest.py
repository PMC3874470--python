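"""Shared simulation helpers for the test suite.

Everything here is generated programmatically at test time; the seeds fix
the study conditions, not the outcomes.
"""

from __future__ import annotations

import numpy as np
import pytest


def hwe_matrix(rng: np.random.Generator, n: int, p: int, maf: float = 0.2):
    """n x p genotype matrix, independent SNPs under HWE."""
    return rng.binomial(2, maf, size=(n, p)).astype(float)


def global_null_sample(seed: int, n_cases: int = 300, n_controls: int = 300,
                       n_snps: int = 5, maf: float = 0.2):
    """Balanced case-control sample with disease independent of all SNPs."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    G = hwe_matrix(rng, n, n_snps, maf)
    disease = rng.permutation(
        np.r_[np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return G, disease


def spiked_sample(seed: int, n_cases: int = 500, n_controls: int = 500,
                  n_snps: int = 15, n_true_pairs: int = 5,
                  interaction_rr: float = 2.5, baseline_risk: float = 0.05,
                  n_pop: int = 30_000, maf: float = 0.2):
    """Case-control sample where the first `n_true_pairs` disjoint SNP pairs
    carry a pure interaction effect on disease risk.

    Risk is multiplicative over the true pairs on the relative-risk scale,
    log P[D] = log(baseline) + sum_i log(RR) * g_{2i} * g_{2i+1}, clamped at
    1; the remaining SNPs are pure noise.  Returns (G, disease, true_pairs).
    """
    rng = np.random.default_rng(seed)
    G = hwe_matrix(rng, n_pop, n_snps, maf)
    true_pairs = [(2 * i, 2 * i + 1) for i in range(n_true_pairs)]
    log_risk = np.full(n_pop, np.log(baseline_risk))
    for j, k in true_pairs:
        log_risk += np.log(interaction_rr) * G[:, j] * G[:, k]
    risk = np.minimum(1.0, np.exp(log_risk))
    disease = (rng.random(n_pop) < risk).astype(np.int8)
    case_idx = np.flatnonzero(disease == 1)
    ctrl_idx = np.flatnonzero(disease == 0)
    idx = np.concatenate([
        rng.choice(case_idx, size=n_cases, replace=False),
        rng.choice(ctrl_idx, size=n_controls, replace=False),
    ])
    return G[idx], disease[idx], true_pairs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The packaged four-scenario fixture set, generated once per session."""
    from twostage.io import generate_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    paths = generate_fixtures(seed=1, outdir=outdir)
    return outdir, paths
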