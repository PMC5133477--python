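"""Synthetic genotype/phenotype generation with the structure the model assumes.

Genotypes are Hardy-Weinberg binomial dosage draws at independent variants
(no linkage disequilibrium), with a minor-allele-frequency spectrum spanning
extreme-rare (~3e-4) to common (~0.35) sites, as seen in deep-sequenced
single-gene studies of unrelated individuals. The quantitative trait follows
the additive linear model Y = b0 + sum_j beta_j X_j + N(0, sigma^2), with
effect sizes expressed in trait-SD units. Optional missing genotypes and
singleton variants exercise the complete-case and low-count filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .variant_data import GenotypeMatrix, PhenotypeVector

__all__ = [
    "SimulationScenario",
    "default_maf_spectrum",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "make_null_replicate",
]


def default_maf_spectrum(
    p: int = 22, low: float = 3e-4, high: float = 0.35, seed: int = 20_160_101
) -> np.ndarray:
    """Log-uniform MAF spectrum over [low, high], sorted descending.

    The fixed internal seed makes the default spectrum a reproducible study
    condition rather than a per-run random quantity.
    """
    rng = np.random.default_rng(seed)
    maf = np.exp(rng.uniform(np.log(low), np.log(high), size=p))
    return np.sort(maf)[::-1]


@dataclass
class SimulationScenario:
    """Generative settings for one synthetic association study.

    Defaults: n = 1000 unrelated individuals, 22 independent variants with a
    log-uniform MAF spectrum over [3e-4, 0.35], no causal variants, unit
    Gaussian trait noise, no missingness.
    """

    n: int = 1000
    maf_spectrum: np.ndarray = field(default_factory=default_maf_spectrum)
    causal_ids: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()  # trait-SD units, one per causal id
    intercept: float = 0.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "3"
    base_position: int = 47_900_000

    def __post_init__(self) -> None:
        self.maf_spectrum = np.asarray(self.maf_spectrum, dtype=float)
        if not ((self.maf_spectrum > 0) & (self.maf_spectrum <= 0.5)).all():
            raise ValueError("all MAFs must lie in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.causal_ids) != len(self.effect_sizes):
            raise ValueError("one effect size per causal variant required")
        if any(j < 0 or j >= self.p for j in self.causal_ids):
            raise ValueError("causal_ids out of range")

    @property
    def p(self) -> int:
        return self.maf_spectrum.size


def simulate_genotypes(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw dosages ~ Binomial(2, maf_j) independently per variant.

    Missing genotypes (when ``missing_rate`` > 0) are masked and their
    dosage zeroed so downstream burden sums ignore them.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    vals = rng.binomial(2, scenario.maf_spectrum, size=(scenario.n, scenario.p))
    vals = vals.astype(float)
    mask = np.zeros_like(vals, dtype=bool)
    if scenario.missing_rate > 0:
        mask = rng.random(vals.shape) < scenario.missing_rate
        vals[mask] = 0.0
    positions = scenario.base_position + 1000 * np.arange(scenario.p)
    ids = [f"{scenario.chrom}_{pos}" for pos in positions]
    return GenotypeMatrix(
        values=vals,
        variant_ids=ids,
        positions=positions,
        missing_mask=mask,
        region=np.array([scenario.chrom] * scenario.p),
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> PhenotypeVector:
    """Additive trait: Y_i = b0 + sum_{j causal} beta_j X_ij + N(0, sigma^2)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    y = np.full(genotypes.n, scenario.intercept, dtype=float)
    for j, beta in zip(scenario.causal_ids, scenario.effect_sizes):
        y += beta * scenario.noise_sd * genotypes.values[:, j]
    y += rng.normal(0.0, scenario.noise_sd, size=genotypes.n)
    return PhenotypeVector(values=y, sample_ids=list(genotypes.sample_ids))


def simulate_dataset(
    scenario: SimulationScenario,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes and matching phenotype from one seeded scenario."""
    gm = simulate_genotypes(scenario)
    ph = simulate_phenotype(gm, scenario)
    return gm, ph


def make_null_replicate(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Effect-free replicate of a scenario (all betas dropped); type-I fixture."""
    null = replace(
        scenario,
        causal_ids=(),
        effect_sizes=(),
        seed=scenario.seed if seed is None else seed,
    )
    return simulate_dataset(null)
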