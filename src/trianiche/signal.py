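"""Phylogenetic signal: Blomberg's K, Pagel's λ by ML, permutation p-values.

Both statistics ask whether related species resemble each other more
than species drawn at random from the tree. K compares the observed
ratio of cross-species variance to phylogenetically-corrected variance
against its Brownian-motion expectation (K ≈ 1 under BM, K ≈ 0 with no
structure). λ is the off-diagonal multiplier of the Brownian covariance
that maximizes the Gaussian likelihood of the tip data (λ = 1 is BM,
λ = 0 phylogenetic independence).

P-values come from tip-label permutation by default: trait values are
shuffled across tips, the statistic recomputed, and the add-one estimate
p = (1 + #{stat_perm >= stat_obs}) / (1 + n_sims) reported. A parametric
likelihood-ratio p for λ (χ²₁ against λ = 0) is available as an
alternative. All randomness is driven by an explicit seed.

Per-trait species missing from a trait vector are handled by restricting
C to the trait's species (equivalent to pruning the tree); this is
logged, never silent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .errors import DegenerateTraitError, SingularCovarianceError
from .phylo import (
    CovarianceMatrix,
    RootedTree,
    TopologySet,
    brownian_covariance,
    lambda_transform,
)

logger = logging.getLogger("trianiche.signal")

#: Absolute convergence tolerance for the λ line search.
LAMBDA_XTOL = 1e-8
#: Log-likelihood spread below which the λ profile is treated as flat
#: (star tree): λ̂ is reported as 0 with the non-identifiable flag.
FLAT_LOGLIK_TOL = 1e-10


@dataclass(frozen=True)
class SignalResult:
    """One trait × one index: the statistic and its permutation p."""

    trait: str
    index: str  # "K" | "lambda"
    statistic: float
    p_value: float | None
    n_sims: int
    loglik: float | None = None
    non_identifiable: bool = False


@dataclass(frozen=True)
class LambdaML:
    """Profile-ML fit of Pagel's λ for a single trait."""

    lambda_hat: float
    loglik: float
    sigma2_hat: float
    mu_hat: float
    non_identifiable: bool = False


def _as_covariance(tree: RootedTree | CovarianceMatrix) -> CovarianceMatrix:
    if isinstance(tree, CovarianceMatrix):
        return tree
    return brownian_covariance(tree)


def _align(C: CovarianceMatrix, x: Mapping[str, float] | pd.Series):
    """Restrict C to the trait's species and return (matrix, values).

    Trait species must be a subset of the tree tips; tips without trait
    data are dropped by restriction of C (logged).
    """
    if isinstance(x, pd.Series):
        x = x.dropna().to_dict()
    species = sorted(x)
    extra = set(species) - set(C.tip_order)
    if extra:
        raise KeyError(f"trait species not in tree: {sorted(extra)}")
    if len(species) < 3:
        raise DegenerateTraitError(
            f"signal estimation needs >= 3 species, got {len(species)}"
        )
    dropped = len(C.tip_order) - len(species)
    if dropped:
        logger.info("restricting covariance: %d tip(s) lack trait data", dropped)
        C = C.restrict(species)
    vals = np.array([float(x[s]) for s in C.tip_order])
    if not np.all(np.isfinite(vals)):
        raise ValueError("trait contains non-finite values")
    if np.all(vals == vals[0]):
        raise DegenerateTraitError("trait is constant across species")
    return C.matrix, vals


def _chol(V: np.ndarray):
    try:
        return cho_factor(V, lower=True)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            "phylogenetic covariance is singular (zero-length branches?)"
        ) from exc


def blomberg_k(tree: RootedTree | CovarianceMatrix, x: Mapping[str, float]) -> float:
    """Blomberg's K for one continuous trait.

    K = (MSE0/MSE)_obs / (MSE0/MSE)_BM with the phylogenetic GLS mean
    â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), MSE0 the ordinary mean squared deviation from
    â, MSE the C-weighted one, and the Brownian expectation
    [tr(C) − n/(1ᵀC⁻¹1)]/(n−1). Invariant to affine trait rescaling.
    """
    C = _as_covariance(tree)
    M, vals = _align(C, x)
    cf = _chol(M)
    return float(_k_from_columns(M, cf, vals[:, None])[0])


def _k_from_columns(M: np.ndarray, cf, X: np.ndarray) -> np.ndarray:
    """Vectorized K over trait columns sharing one covariance factorization."""
    n = M.shape[0]
    Y = cho_solve(cf, X)  # C^{-1} X
    s11 = float(cho_solve(cf, np.ones(n)).sum())  # 1' C^{-1} 1
    sx = Y.sum(axis=0)  # 1' C^{-1} x per column
    a_hat = sx / s11
    # MSE0 deviates from the GLS mean â, not the arithmetic mean
    mse0 = ((X - a_hat) ** 2).sum(axis=0) / (n - 1)
    mse = ((X * Y).sum(axis=0) - sx**2 / s11) / (n - 1)
    if np.any(mse0 <= 0):
        raise DegenerateTraitError("trait is constant across species")
    expected = (np.trace(M) - n / s11) / (n - 1)
    return (mse0 / mse) / expected


def _profile_loglik(M: np.ndarray, vals: np.ndarray, lam: float) -> float:
    """Concentrated log-likelihood of λ with μ and σ² profiled out."""
    n = len(vals)
    V = M * lam
    np.fill_diagonal(V, np.diag(M))
    cf = _chol(V)
    u = cho_solve(cf, np.ones(n))
    w = cho_solve(cf, vals)
    mu = float(vals @ u / u.sum())
    r = vals - mu
    sigma2 = float(r @ cho_solve(cf, r)) / n
    if sigma2 <= 0:
        raise DegenerateTraitError("zero residual variance in λ profile")
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def pagel_lambda_ml(
    tree: RootedTree | CovarianceMatrix, x: Mapping[str, float]
) -> LambdaML:
    """Maximum-likelihood Pagel's λ on [0, 1] for one trait.

    Maximizes the profile log-likelihood by bounded Brent search plus
    exact evaluation of both endpoints; near-ties are broken toward the
    smaller λ. A flat profile (star phylogeny) is reported as λ̂ = 0 with
    ``non_identifiable=True``.
    """
    C = _as_covariance(tree)
    M, vals = _align(C, x)

    def neg(lam: float) -> float:
        return -_profile_loglik(M, vals, lam)

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": LAMBDA_XTOL}
    )
    candidates = [(0.0, -neg(0.0)), (float(res.x), -res.fun), (1.0, -neg(1.0))]
    best_ll = max(ll for _, ll in candidates)
    # ties toward the smaller λ
    lam_hat, loglik = min(
        (lam, ll) for lam, ll in candidates if best_ll - ll <= FLAT_LOGLIK_TOL
    )
    flat = max(ll for _, ll in candidates) - min(ll for _, ll in candidates) <= FLAT_LOGLIK_TOL
    if flat:
        lam_hat, loglik = 0.0, candidates[0][1]

    n = len(vals)
    V = M * lam_hat
    np.fill_diagonal(V, np.diag(M))
    cf = _chol(V)
    u = cho_solve(cf, np.ones(n))
    mu = float(vals @ u / u.sum())
    r = vals - mu
    sigma2 = float(r @ cho_solve(cf, r)) / n
    return LambdaML(lam_hat, loglik, sigma2, mu, non_identifiable=flat)


def permutation_pvalue(
    tree: RootedTree | CovarianceMatrix,
    x: Mapping[str, float],
    index: str = "K",
    n_sims: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Tip-label permutation p-value for K or λ.

    Returns ``(statistic, p)`` with the add-one estimator
    p = (1 + #{stat_perm >= stat_obs}) / (1 + n_sims); p is never exactly
    0 and equals 1 when the observed statistic sits at the null floor
    (e.g. λ̂ = 0). Reproducible given ``seed`` (mandatory).
    """
    if seed is None:
        raise ValueError("seed is mandatory for permutation p-values")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if index not in ("K", "lambda"):
        raise ValueError(f"unknown index {index!r}")
    C = _as_covariance(tree)
    M, vals = _align(C, x)
    rng = np.random.default_rng(seed)
    n = len(vals)
    perms = np.stack([rng.permutation(vals) for _ in range(n_sims)], axis=1)

    if index == "K":
        cf = _chol(M)
        obs = float(_k_from_columns(M, cf, vals[:, None])[0])
        null = _k_from_columns(M, cf, perms)
    else:
        labels = sorted(x) if not isinstance(x, pd.Series) else sorted(x.dropna().index)
        Csub = C.restrict(labels) if len(labels) < len(C.tip_order) else C
        obs = pagel_lambda_ml(Csub, dict(zip(Csub.tip_order, vals))).lambda_hat
        null = np.array(
            [
                pagel_lambda_ml(Csub, dict(zip(Csub.tip_order, perms[:, j]))).lambda_hat
                for j in range(n_sims)
            ]
        )
    # >= with a hair of tolerance so exchangeable-null ties (star tree)
    # count as ties instead of splitting on floating-point noise
    ge = (null > obs) | np.isclose(null, obs, rtol=1e-9, atol=1e-12)
    p = (1 + int(ge.sum())) / (1 + n_sims)
    return obs, p


def lambda_lr_pvalue(tree: RootedTree | CovarianceMatrix, x: Mapping[str, float]) -> tuple[float, float]:
    """Likelihood-ratio p for λ̂ against λ = 0 (χ²₁); parametric alternative."""
    C = _as_covariance(tree)
    M, vals = _align(C, x)
    fit = pagel_lambda_ml(C, x)
    ll0 = _profile_loglik(M, vals, 0.0)
    lr = max(0.0, 2.0 * (fit.loglik - ll0))
    return fit.lambda_hat, float(stats.chi2.sf(lr, df=1))


def signal_table(
    trees: TopologySet | RootedTree,
    traits: pd.DataFrame,
    n_sims: int = 1000,
    seed: int | None = None,
    indices: Sequence[str] = ("K", "lambda"),
) -> pd.DataFrame:
    """Per-trait signal summarized over a topology set.

    ``traits`` is a species × trait DataFrame (index = species labels).
    For every trait × index the statistic and permutation p are computed
    on each topology; the table reports the median and 2.5/97.5
    percentiles across topologies, one row per trait × index, with
    columns trait, index, median, q2.5, q97.5, p_median, p_q2.5, p_q97.5,
    n_topologies, n_failed. Failures on individual topologies are logged
    and excluded, never silently dropped.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if isinstance(trees, RootedTree):
        trees = TopologySet([trees])
    rows = []
    for ti, trait in enumerate(traits.columns):
        x = traits[trait].dropna()
        for ii, index in enumerate(indices):
            stats_, ps, failed = [], [], 0
            # one permutation stream per trait × index, shared across
            # topologies: identical topologies then give identical results
            for k, tree in enumerate(trees):
                sub_seed = np.random.SeedSequence([seed, ti, ii]).generate_state(1)[0]
                try:
                    C = brownian_covariance(tree)
                    s, p = permutation_pvalue(
                        C, x, index=index, n_sims=n_sims, seed=int(sub_seed)
                    )
                except (SingularCovarianceError, DegenerateTraitError) as exc:
                    failed += 1
                    logger.warning(
                        "topology %d failed for %s/%s: %s", k, trait, index, exc
                    )
                    continue
                stats_.append(s)
                ps.append(p)
            if not stats_:
                raise DegenerateTraitError(
                    f"all topologies failed for trait {trait!r}, index {index}"
                )
            stats_, ps = np.array(stats_), np.array(ps)
            rows.append(
                {
                    "trait": trait,
                    "index": index,
                    "median": float(np.median(stats_)),
                    "q2.5": float(np.percentile(stats_, 2.5)),
                    "q97.5": float(np.percentile(stats_, 97.5)),
                    "p_median": float(np.median(ps)),
                    "p_q2.5": float(np.percentile(ps, 2.5)),
                    "p_q97.5": float(np.percentile(ps, 97.5)),
                    "n_topologies": len(stats_),
                    "n_failed": failed,
                }
            )
    return pd.DataFrame(rows)
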