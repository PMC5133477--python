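"""Metropolis-Hastings search of the inclusion-vector space.

The proposal flips one uniformly chosen bit, so the Hastings ratio is 1 and
acceptance reduces to min(1, exp(score' - score)). A paired "null" chain is
run on a randomly permuted phenotype under the identical configuration; its
marginal posterior probabilities act as per-variant empirical thresholds for
the true-positive decision rule. Convergence of the scalar log-score trace
is monitored with a Geweke z-test using AR-fit spectral variances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import PriorSpec, plug_in_log_likelihood
from .variant_data import GenotypeMatrix, PhenotypeVector, VariantGrouping

__all__ = [
    "SamplerConfig",
    "ChainSamples",
    "propose",
    "mh_accept",
    "run_chain",
    "permute_phenotype",
    "run_paired_chains",
    "geweke_z",
]

logger = logging.getLogger("bvsri")

#: Offset added to the chain seed for the null chain's RNG stream so the
#: observed chain's draws are unchanged by whether the null chain runs.
NULL_STREAM_OFFSET = 1_000_003
#: Default offset for deriving a permutation seed from the chain seed.
PERMUTATION_SEED_OFFSET = 7_919
#: How often (iterations) chain progress is logged.
LOG_EVERY = 1000


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-length protocol and prior settings.

    Defaults follow the analysis protocol this method was introduced with:
    5000 burn-in iterations, thinning 1-in-10, 5000 retained draws, hence
    5000 + 5000 * 10 = 55,000 total iterations, and a prior inclusion
    probability of 0.1 (one in ten variants included a priori).
    """

    burn_in: int = 5000
    n_keep: int = 5000
    thin: int = 10
    pip: float = 0.1
    seed: int = 0
    permutation_seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_keep < 1 or self.thin < 1:
            raise ValueError("need burn_in >= 0, n_keep >= 1, thin >= 1")

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.n_keep * self.thin


@dataclass
class ChainSamples:
    """Post-burn-in, thinned draws of the inclusion vector."""

    draws: np.ndarray  # (n_keep, p) uint8
    log_score_trace: np.ndarray
    acceptance_rate: float
    config: SamplerConfig
    label: str = "observed"
    n_iterations: int = 0


def propose(gamma: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Flip one uniformly chosen bit; symmetric, so the log proposal ratio is 0."""
    j = int(rng.integers(gamma.size))
    out = gamma.copy()
    out[j] = 1 - out[j]
    return out, 0.0


def mh_accept(
    current_score: float, proposed_score: float, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, exp(proposed - current))."""
    if not (math.isfinite(current_score) and math.isfinite(proposed_score)):
        raise ValueError("model scores must be finite")
    delta = proposed_score - current_score
    if delta >= 0:
        return True
    return math.log(rng.random()) < delta


class _StateScorer:
    """Memoised log-score evaluation for one (Y, X, grouping, prior) problem.

    The chain revisits a small set of high-probability states; caching by the
    byte representation of gamma makes long default-protocol runs cheap.
    """

    def __init__(
        self,
        y: np.ndarray,
        genotypes: GenotypeMatrix,
        grouping: VariantGrouping,
        prior: PriorSpec,
    ) -> None:
        if float(np.var(y)) == 0.0:
            raise ValueError("phenotype has zero variance; nothing to model")
        self.y = np.asarray(y, dtype=float)
        self.X = genotypes.values
        self.members = grouping.members
        self.log_pip = math.log(prior.pip)
        self.log_1m_pip = math.log(1.0 - prior.pip)
        self.p = genotypes.p
        self._cache: dict[bytes, float] = {}

    def __call__(self, gamma: np.ndarray) -> float:
        key = gamma.tobytes()
        s = self._cache.get(key)
        if s is None:
            k = int(gamma.sum())
            lp = k * self.log_pip + (self.p - k) * self.log_1m_pip
            cols = [
                self.X[:, idx] @ gamma[idx].astype(float)
                for idx in self.members
                if gamma[idx].any()
            ]
            design = (
                np.column_stack(cols) if cols else np.empty((self.y.size, 0))
            )
            ll, _, _, _ = plug_in_log_likelihood(self.y, design)
            s = lp + ll
            self._cache[key] = s
        return s


def run_chain(
    phenotype: PhenotypeVector,
    genotypes: GenotypeMatrix,
    grouping: VariantGrouping,
    config: SamplerConfig,
    label: str = "observed",
    init: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ChainSamples:
    """Run one MH chain and return the retained draws.

    The chain starts from the empty model (all gammas zero) unless ``init``
    is given, runs ``burn_in + n_keep * thin`` iterations, and retains every
    ``thin``-th post-burn-in state. Identical seeds give bit-identical output.
    """
    if phenotype.n != genotypes.n:
        raise ValueError("phenotype and genotypes are not aligned")
    prior = PriorSpec(pip=config.pip)
    scorer = _StateScorer(phenotype.values, genotypes, grouping, prior)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    p = genotypes.p
    gamma = (
        np.zeros(p, dtype=np.uint8)
        if init is None
        else np.asarray(init, dtype=np.uint8).copy()
    )
    score = scorer(gamma)

    total = config.total_iterations
    flip_idx = rng.integers(0, p, size=total)
    log_u = np.log(rng.random(size=total))

    draws = np.empty((config.n_keep, p), dtype=np.uint8)
    trace = np.empty(config.n_keep)
    n_accept = 0
    kept = 0
    for it in range(total):
        j = flip_idx[it]
        gamma[j] ^= 1
        new_score = scorer(gamma)
        if new_score - score >= 0 or log_u[it] < new_score - score:
            score = new_score
            n_accept += 1
        else:
            gamma[j] ^= 1  # reject: undo the flip
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            draws[kept] = gamma
            trace[kept] = score
            kept += 1
        if (it + 1) % LOG_EVERY == 0:
            logger.debug(
                "%s chain: iteration %d/%d, acceptance %.3f",
                label, it + 1, total, n_accept / (it + 1),
            )
    assert kept == config.n_keep
    return ChainSamples(
        draws=draws,
        log_score_trace=trace,
        acceptance_rate=n_accept / total,
        config=config,
        label=label,
        n_iterations=total,
    )


def permute_phenotype(
    phenotype: PhenotypeVector, rng: np.random.Generator
) -> PhenotypeVector:
    """Uniform random rearrangement of the trait values (genotypes untouched)."""
    if phenotype.n < 1:
        raise ValueError("empty phenotype")
    perm = rng.permutation(phenotype.n)
    return PhenotypeVector(
        values=phenotype.values[perm],
        sample_ids=list(phenotype.sample_ids),
        transform_applied=phenotype.transform_applied,
    )


def run_paired_chains(
    phenotype: PhenotypeVector,
    genotypes: GenotypeMatrix,
    grouping: VariantGrouping,
    config: SamplerConfig,
) -> tuple[ChainSamples, ChainSamples]:
    """Observed chain on Y plus a null chain on one fixed permutation of Y.

    Both chains use the same protocol; the null chain draws from an
    independent RNG stream (seed + offset) so the observed chain's output
    does not depend on whether the null chain is run.
    """
    perm_seed = (
        config.permutation_seed
        if config.permutation_seed is not None
        else config.seed + PERMUTATION_SEED_OFFSET
    )
    observed = run_chain(phenotype, genotypes, grouping, config, label="observed")
    y_star = permute_phenotype(phenotype, np.random.default_rng(perm_seed))
    null_cfg = replace(config, seed=config.seed + NULL_STREAM_OFFSET)
    null = run_chain(y_star, genotypes, grouping, null_cfg, label="permuted")
    return observed, null


def _spectral_variance(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via an AIC-selected AR fit.

    Yule-Walker/Levinson-Durbin recursion up to ``max_order`` (default
    ~n**(1/3)); the zero-frequency density of an AR(k) process is
    sigma2_k / (1 - sum(phi))**2. Order 0 reduces to the sample variance,
    which keeps the diagnostic calibrated on independent draws while longer
    orders absorb MCMC autocorrelation.
    """
    n = x.size
    v0 = float(np.var(x))
    if n < 4 or v0 == 0.0:
        return v0
    if max_order is None:
        max_order = min(int(round(n ** (1 / 3))), n // 4, 20)
    xc = x - x.mean()
    acov = np.array(
        [xc[: n - k] @ xc[k:] / n for k in range(max_order + 1)]
    )
    # Levinson-Durbin with AIC order selection
    best_sv, best_aic = acov[0], n * math.log(acov[0]) + 2.0
    sigma2 = acov[0]
    phi = np.zeros(max_order + 1)
    for k in range(1, max_order + 1):
        kappa = (acov[k] - phi[1:k] @ acov[1:k][::-1]) / sigma2
        phi_new = phi.copy()
        phi_new[k] = kappa
        phi_new[1:k] = phi[1:k] - kappa * phi[1:k][::-1]
        sigma2 = sigma2 * (1.0 - kappa**2)
        phi = phi_new
        if sigma2 <= 0:
            break
        aic = n * math.log(sigma2) + 2.0 * (k + 1)
        if aic < best_aic:
            best_aic = aic
            denom = 1.0 - float(phi[1 : k + 1].sum())
            best_sv = sigma2 / denom**2 if denom != 0 else acov[0]
    return float(max(best_sv, 0.0))


def geweke_z(
    trace: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5
) -> tuple[float, bool]:
    """Geweke convergence diagnostic on a scalar trace.

    Compares the mean of the first ``first_frac`` of the trace with the mean
    of the last ``last_frac`` via
    ``z = (mean_A - mean_B) / sqrt(sv_A/n_A + sv_B/n_B)`` where ``sv`` are
    AR-fit estimates of the spectral density at frequency zero. A constant
    trace returns ``z = 0`` (converged) by convention.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 20:
        raise ValueError("trace too short for the Geweke diagnostic")
    a = x[: max(1, int(first_frac * x.size))]
    b = x[-max(1, int(last_frac * x.size)):]
    denom = _spectral_variance(a) / a.size + _spectral_variance(b) / b.size
    if denom <= 0.0:
        return 0.0, True
    z = float((a.mean() - b.mean()) / math.sqrt(denom))
    return z, abs(z) < 1.96
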