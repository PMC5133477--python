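"""Model-space prior, plug-in marginal likelihood and the exact posterior oracle.

A model is a binary inclusion vector ``gamma`` over the p variants. Its
un-normalised log posterior score is

    log p(gamma) + log p(Y | gamma, beta_hat, sigma2_hat)

where the prior is independent Bernoulli(pi) per variant and the marginal
likelihood p(Y | gamma) is approximated by the Gaussian likelihood evaluated
at the maximum-likelihood estimates of the intercept, the group (risk-index)
coefficients and the residual variance. With sigma2_hat = RSS / n the
maximised Gaussian log likelihood reduces to

    -(n/2) * log(2 * pi * sigma2_hat) - n/2.

Because the maximised likelihood never decreases when a column is added,
all sparsity comes from the prior inclusion probability pi < 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variant_data import (
    GenotypeMatrix,
    PhenotypeVector,
    VariantGrouping,
    build_risk_design,
)

__all__ = [
    "PriorSpec",
    "IndicatorState",
    "ExactPosterior",
    "log_prior",
    "plug_in_log_likelihood",
    "score_state",
    "enumerate_exact_posterior",
]

#: Relative floor applied to sigma2_hat, as a fraction of var(Y). Rare-variant
#: designs with a handful of carriers can interpolate Y exactly; the floor
#: keeps the log likelihood finite in that degenerate case.
VARIANCE_FLOOR_FRACTION = 1e-12


@dataclass(frozen=True)
class PriorSpec:
    """Bernoulli model-space prior; ``pip`` is the prior inclusion probability."""

    pip: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.pip < 1.0):
            raise ValueError("prior inclusion probability must lie strictly in (0, 1)")


@dataclass
class IndicatorState:
    """A scored point of the model space."""

    gamma: np.ndarray
    log_prior: float
    log_lik: float
    log_score: float
    intercept: float
    coefficients: np.ndarray  # one per active group
    sigma2: float
    active_groups: list[int]


def log_prior(gamma: np.ndarray, prior: PriorSpec) -> float:
    """log p(gamma) = sum_j gamma_j log(pi) + (1 - gamma_j) log(1 - pi)."""
    g = np.asarray(gamma)
    if not np.isin(g, (0, 1)).all():
        raise ValueError("gamma components must be 0 or 1")
    k = int(g.sum())
    return k * np.log(prior.pip) + (g.size - k) * np.log(1.0 - prior.pip)


def plug_in_log_likelihood(
    y: np.ndarray, design: np.ndarray
) -> tuple[float, float, np.ndarray, float]:
    """Gaussian log likelihood maximised over intercept, slopes and variance.

    Fits Y on ``[1, design]`` by (minimum-norm) least squares; rank-deficient
    designs are allowed since only the RSS enters the likelihood. Returns
    ``(log_lik, intercept, coefficients, sigma2)`` with the MLE
    ``sigma2 = RSS / n`` floored at a small fraction of var(Y).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    var_y = float(np.var(y))
    floor = max(VARIANCE_FLOOR_FRACTION * var_y, np.finfo(float).tiny)

    m = design.shape[1] if design.ndim == 2 else 0
    if m == 0:
        beta0 = float(y.mean())
        beta = np.empty(0)
        rss = float(np.sum((y - beta0) ** 2))
    else:
        A = np.column_stack([np.ones(n), design])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        rss = float(resid @ resid)
        beta0 = float(coef[0])
        beta = coef[1:]
    sigma2 = max(rss / n, floor)
    ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * n
    return float(ll), beta0, beta, float(sigma2)


def score_state(
    phenotype: PhenotypeVector,
    genotypes: GenotypeMatrix,
    grouping: VariantGrouping,
    gamma: np.ndarray,
    prior: PriorSpec,
) -> IndicatorState:
    """Fully scored IndicatorState for one inclusion vector."""
    design, active = build_risk_design(genotypes, grouping, gamma)
    lp = log_prior(gamma, prior)
    ll, beta0, beta, sigma2 = plug_in_log_likelihood(phenotype.values, design)
    return IndicatorState(
        gamma=np.asarray(gamma, dtype=np.uint8).copy(),
        log_prior=lp,
        log_lik=ll,
        log_score=lp + ll,
        intercept=beta0,
        coefficients=beta,
        sigma2=sigma2,
        active_groups=active,
    )


@dataclass
class ExactPosterior:
    """Exhaustively enumerated posterior over all 2**p models."""

    gammas: np.ndarray  # (2**p, p) uint8
    log_scores: np.ndarray
    posterior: np.ndarray
    mpp: np.ndarray  # per-variant marginal posterior probability


def enumerate_exact_posterior(
    phenotype: PhenotypeVector,
    genotypes: GenotypeMatrix,
    grouping: VariantGrouping,
    prior: PriorSpec,
    max_p: int = 20,
) -> ExactPosterior:
    """Score every model, normalise exactly, and sum out per-variant MPPs.

    Only feasible for small p (guarded by ``max_p``); serves as the ground
    truth the Metropolis-Hastings sampler is validated against.
    """
    p = genotypes.p
    if p > max_p:
        raise ValueError(f"exact enumeration requires p <= {max_p}, got {p}")
    n_models = 1 << p
    gammas = (
        (np.arange(n_models)[:, None] >> np.arange(p)[None, :]) & 1
    ).astype(np.uint8)
    log_scores = np.empty(n_models)
    for i in range(n_models):
        st = score_state(phenotype, genotypes, grouping, gammas[i], prior)
        log_scores[i] = st.log_score
    w = np.exp(log_scores - log_scores.max())
    posterior = w / w.sum()
    mpp = posterior @ gammas
    return ExactPosterior(
        gammas=gammas, log_scores=log_scores, posterior=posterior, mpp=mpp
    )
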