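"""Marginal posterior probabilities, the two-stage decision rule, and the MAF sweep.

The marginal posterior probability (MPP) of a variant is the posterior mass
of all models that include it, estimated as the fraction of retained chain
draws with that variant switched on. Selection is two-staged: a variant is
*selected* when its MPP strictly exceeds the prior inclusion probability,
and *declared a true positive* when it additionally strictly exceeds the
empirical MPP obtained from the permuted-phenotype chain. Because the choice
of rare/common MAF cutoff is arbitrary, the analysis can be repeated over a
grid of thresholds and the per-threshold MPPs averaged before the rule is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mh_sampler import ChainSamples, SamplerConfig, run_paired_chains
from .variant_data import GenotypeMatrix, PhenotypeVector, partition_by_maf

__all__ = [
    "DEFAULT_MAF_THRESHOLDS",
    "SweepResult",
    "compute_mpp",
    "select_variants",
    "rank_report",
    "maf_sweep",
    "plot_mpp_profiles",
]

#: Default MAF-threshold grid for the sensitivity sweep, starting at 5%.
DEFAULT_MAF_THRESHOLDS = (0.05, 0.04, 0.03, 0.02, 0.01)

#: Deterministic seed spacing between the paired chains of successive
#: thresholds in a sweep.
THRESHOLD_SEED_STRIDE = 10_007


def compute_mpp(samples: ChainSamples) -> np.ndarray:
    """Per-variant MPP: fraction of retained draws including the variant."""
    if samples.draws.size == 0:
        raise ValueError("chain contains no retained draws")
    return samples.draws.mean(axis=0)


def select_variants(
    mpp: np.ndarray,
    empirical_mpp: np.ndarray,
    pip: float,
    variant_ids: list[str] | None = None,
    maf: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply the two-stage rule and return one row per variant.

    ``passes_pip``  : MPP > pip (strict).
    ``true_positive``: passes_pip and MPP > empirical MPP (strict).
    """
    mpp = np.asarray(mpp, dtype=float)
    empirical_mpp = np.asarray(empirical_mpp, dtype=float)
    if mpp.shape != empirical_mpp.shape:
        raise ValueError("mpp and empirical_mpp lengths differ")
    p = mpp.size
    df = pd.DataFrame(
        {
            "variant": variant_ids if variant_ids is not None else [f"v{j}" for j in range(p)],
            "maf": maf if maf is not None else np.full(p, np.nan),
            "mpp": mpp,
            "empirical_mpp": empirical_mpp,
            "position": positions if positions is not None else np.arange(p),
        }
    )
    df["passes_pip"] = df["mpp"] > pip
    df["true_positive"] = df["passes_pip"] & (df["mpp"] > df["empirical_mpp"])
    return df


def rank_report(report: pd.DataFrame, by: str = "mpp") -> pd.DataFrame:
    """Order rows by descending MPP; ties broken by ascending position.

    Adds a ``rank`` column (1 = strongest evidence) and returns the sorted
    frame.
    """
    out = report.sort_values(
        [by, "position"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class SweepResult:
    """Per-threshold chain summaries plus the threshold-averaged report."""

    thresholds: list[float]
    mpp_by_threshold: pd.DataFrame  # variants x thresholds
    empirical_by_threshold: pd.DataFrame
    report: pd.DataFrame  # averaged MPPs, selection flags, ranks
    chains: list[tuple[ChainSamples, ChainSamples]] = field(default_factory=list)


def maf_sweep(
    phenotype: PhenotypeVector,
    genotypes: GenotypeMatrix,
    config: SamplerConfig,
    thresholds: tuple[float, ...] = DEFAULT_MAF_THRESHOLDS,
    keep_chains: bool = False,
) -> SweepResult:
    """Re-partition and re-run paired chains at each MAF threshold.

    The per-variant observed and empirical MPPs are averaged arithmetically
    across thresholds (every variant is present at every threshold, so there
    are no missing cells) and the two-stage rule is applied to the averages.
    Chain seeds are offset deterministically per threshold.
    """
    if len(thresholds) == 0:
        raise ValueError("need at least one MAF threshold")
    for t in thresholds:
        if not (0.0 < t <= 0.5):
            raise ValueError(f"threshold {t} outside (0, 0.5]")

    mpp_cols: dict[float, np.ndarray] = {}
    emp_cols: dict[float, np.ndarray] = {}
    chains: list[tuple[ChainSamples, ChainSamples]] = []
    for i, t in enumerate(thresholds):
        grouping = partition_by_maf(genotypes, t)
        cfg = replace(config, seed=config.seed + i * THRESHOLD_SEED_STRIDE)
        observed, null = run_paired_chains(phenotype, genotypes, grouping, cfg)
        mpp_cols[t] = compute_mpp(observed)
        emp_cols[t] = compute_mpp(null)
        if keep_chains:
            chains.append((observed, null))

    idx = pd.Index(genotypes.variant_ids, name="variant")
    mpp_df = pd.DataFrame(mpp_cols, index=idx)
    emp_df = pd.DataFrame(emp_cols, index=idx)
    avg_mpp = mpp_df.mean(axis=1).to_numpy()
    avg_emp = emp_df.mean(axis=1).to_numpy()

    report = select_variants(
        avg_mpp,
        avg_emp,
        config.pip,
        variant_ids=list(genotypes.variant_ids),
        maf=genotypes.maf,
        positions=genotypes.positions,
    )
    report = report.rename(
        columns={"mpp": "averaged_mpp", "empirical_mpp": "averaged_empirical_mpp"}
    )
    report = rank_report(report, by="averaged_mpp")
    return SweepResult(
        thresholds=list(thresholds),
        mpp_by_threshold=mpp_df,
        empirical_by_threshold=emp_df,
        report=report,
        chains=chains,
    )


def plot_mpp_profiles(sweep: SweepResult, pip: float, path: str) -> None:
    """MPP-vs-variant profile plot: one line per MAF threshold.

    A solid horizontal line marks the prior inclusion probability and a
    dotted line the variant-wise mean empirical (permutation) MPP.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, sweep.mpp_by_threshold.shape[0] * 0.35), 4))
    x = np.arange(sweep.mpp_by_threshold.shape[0])
    for t in sweep.thresholds:
        ax.plot(x, sweep.mpp_by_threshold[t], marker="o", ms=3, label=f"MAF < {t:g}")
    ax.plot(
        x,
        sweep.empirical_by_threshold.mean(axis=1),
        "k:",
        label="empirical MPP",
    )
    ax.axhline(pip, color="grey", lw=1, label=f"PIP = {pip:g}")
    ax.set_xticks(x)
    ax.set_xticklabels(sweep.mpp_by_threshold.index, rotation=90, fontsize=7)
    ax.set_ylabel("marginal posterior probability")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
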