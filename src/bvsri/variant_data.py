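"""Genotype/phenotype containers, filters, MAF partitioning and the risk-index design.

Genotypes are additively coded: each entry counts copies of the minor allele
(0, 1 or 2). If the coded allele turns out to be the major one (frequency
> 0.5) the column is recoded as ``2 - x`` so that the coding always counts
the minor allele. Variants with minor-allele frequency below a chosen
threshold are pooled into one "rare" group per region; every common variant
forms its own singleton group. The risk-index design matrix collapses each
group's currently included variants into a single burden column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "VariantGrouping",
    "FilterReport",
    "compute_maf",
    "filter_data",
    "log_transform",
    "partition_by_maf",
    "build_risk_design",
]


class DataError(ValueError):
    """Raised for unusable or inconsistent genotype/phenotype input."""


def compute_maf(column: np.ndarray, missing: np.ndarray | None = None) -> float:
    """Minor-allele frequency of one dosage column.

    Parameters
    ----------
    column
        Dosages in {0, 1, 2}, length >= 1.
    missing
        Optional boolean mask, True where the genotype is missing.

    Returns
    -------
    float
        ``min(f, 1 - f)`` where ``f`` is the coded-allele frequency among
        non-missing genotypes; always in [0, 0.5].
    """
    col = np.asarray(column, dtype=float)
    if col.ndim != 1 or col.size == 0:
        raise DataError("genotype column must be a non-empty 1-D array")
    if missing is not None:
        keep = ~np.asarray(missing, dtype=bool)
        col = col[keep]
    if col.size == 0:
        raise DataError("all genotypes missing for this variant: unusable")
    f = float(col.sum()) / (2.0 * col.size)
    return min(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """Additively coded genotypes for ``n`` individuals at ``p`` variants.

    ``values[i, j]`` is the minor-allele dosage of individual ``i`` at
    variant ``j``; entries under ``missing_mask`` are meaningless. ``region``
    labels drive the one-rare-group-per-region partition (a single-gene
    analysis has one label everywhere).
    """

    values: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    region: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("genotype values must be an n x p matrix")
        n, p = self.values.shape
        if len(self.variant_ids) != p:
            raise DataError("variant_ids length must equal the number of columns")
        if len(set(self.variant_ids)) != p:
            raise DataError("variant_ids must be unique")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (p,):
            raise DataError("positions must have one entry per variant")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, p), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, p):
            raise DataError("missing_mask shape must match values")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if self.region is None:
            self.region = np.array(["region0"] * p)
        self.region = np.asarray(self.region)
        obs = self.values[~self.missing_mask]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise DataError("non-missing dosages must be 0, 1 or 2")
        self._orient_minor()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def _orient_minor(self) -> None:
        """Recode columns whose coded allele is the major one, then refresh MAF."""
        for j in range(self.p):
            keep = ~self.missing_mask[:, j]
            if not keep.any():
                raise DataError(
                    f"variant {self.variant_ids[j]} has all genotypes missing"
                )
            f = self.values[keep, j].sum() / (2.0 * keep.sum())
            if f > 0.5:
                self.values[keep, j] = 2.0 - self.values[keep, j]
        self.maf = np.array(
            [
                compute_maf(self.values[:, j], self.missing_mask[:, j])
                for j in range(self.p)
            ]
        )

    def minor_allele_counts(self) -> np.ndarray:
        """Per-variant minor-allele count over non-missing genotypes."""
        vals = np.where(self.missing_mask, 0.0, self.values)
        return vals.sum(axis=0)

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values[idx],
            variant_ids=list(self.variant_ids),
            positions=self.positions.copy(),
            missing_mask=self.missing_mask[idx],
            sample_ids=[self.sample_ids[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool
            else [self.sample_ids[i] for i in idx],
            region=self.region.copy(),
        )

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        cols = np.flatnonzero(idx) if np.asarray(idx).dtype == bool else np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[:, cols],
            variant_ids=[self.variant_ids[j] for j in cols],
            positions=self.positions[cols],
            missing_mask=self.missing_mask[:, cols],
            sample_ids=list(self.sample_ids),
            region=self.region[cols],
        )


@dataclass
class PhenotypeVector:
    """Quantitative trait values, one per individual."""

    values: np.ndarray
    sample_ids: list[str] = None  # type: ignore[assignment]
    transform_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("phenotype must be a 1-D vector")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(self.values.size)]

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class FilterReport:
    removed_individuals: list[str]
    removed_variants: list[str]
    n_individuals_removed: int = 0
    n_variants_removed: int = 0

    def __post_init__(self) -> None:
        self.n_individuals_removed = len(self.removed_individuals)
        self.n_variants_removed = len(self.removed_variants)


def filter_data(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    drop_missing_individuals: bool = True,
    min_minor_allele_count: int = 1,
) -> tuple[GenotypeMatrix, PhenotypeVector, FilterReport]:
    """Complete-case and low-count variant filtering.

    Individuals with any missing genotype or a non-finite phenotype are
    removed first (when ``drop_missing_individuals``); minor-allele counts
    are then recomputed and variants with MAC <= ``min_minor_allele_count``
    (singletons at the default of 1, monomorphic always) are dropped.
    """
    if genotypes.n != phenotype.n:
        raise DataError("genotypes and phenotype are not aligned")

    keep_ind = np.ones(genotypes.n, dtype=bool)
    if drop_missing_individuals:
        keep_ind = ~genotypes.missing_mask.any(axis=1) & np.isfinite(phenotype.values)
    removed_ind = [genotypes.sample_ids[i] for i in np.flatnonzero(~keep_ind)]
    if not keep_ind.any():
        raise DataError("no individuals remain after filtering")

    gm = genotypes.take_individuals(keep_ind) if removed_ind else genotypes
    ph = PhenotypeVector(
        values=phenotype.values[keep_ind],
        sample_ids=[phenotype.sample_ids[i] for i in np.flatnonzero(keep_ind)],
        transform_applied=phenotype.transform_applied,
    )

    mac = gm.minor_allele_counts()
    keep_var = mac > min_minor_allele_count
    removed_var = [gm.variant_ids[j] for j in np.flatnonzero(~keep_var)]
    if not keep_var.any():
        raise DataError("no variants remain after filtering")
    if removed_var:
        gm = gm.take_variants(keep_var)

    return gm, ph, FilterReport(removed_ind, removed_var)


def log_transform(phenotype: PhenotypeVector) -> PhenotypeVector:
    """Natural-log transform of a strictly positive trait (skew correction)."""
    bad = np.flatnonzero(~(phenotype.values > 0))
    if bad.size:
        raise DataError(
            f"log transform requires strictly positive values; offending "
            f"individual(s): {[phenotype.sample_ids[i] for i in bad[:5]]}"
        )
    return PhenotypeVector(
        values=np.log(phenotype.values),
        sample_ids=list(phenotype.sample_ids),
        transform_applied=True,
    )


@dataclass
class VariantGrouping:
    """Partition of variants into rare groups (one per region) and common singletons."""

    threshold: float
    group_of: np.ndarray
    group_sizes: np.ndarray
    members: list[np.ndarray]

    @property
    def n_groups(self) -> int:
        return len(self.members)


def partition_by_maf(genotypes: GenotypeMatrix, threshold: float) -> VariantGrouping:
    """Pool rare variants (MAF < threshold) into one group per region.

    Common variants (MAF >= threshold) each form their own group. Groups are
    numbered by the genomic position of their first member, which makes the
    numbering deterministic.
    """
    if not (0.0 < threshold <= 0.5):
        raise DataError("MAF threshold must lie in (0, 0.5]")
    rare = genotypes.maf < threshold

    groups: list[np.ndarray] = []
    for reg in dict.fromkeys(genotypes.region.tolist()):  # stable order
        idx = np.flatnonzero((genotypes.region == reg) & rare)
        if idx.size:
            groups.append(idx)
    for j in np.flatnonzero(~rare):
        groups.append(np.array([j]))

    groups.sort(key=lambda idx: int(genotypes.positions[idx].min()))
    group_of = np.empty(genotypes.p, dtype=np.int64)
    for g, idx in enumerate(groups):
        group_of[idx] = g
    sizes = np.array([idx.size for idx in groups], dtype=np.int64)
    assert sizes.sum() == genotypes.p
    return VariantGrouping(
        threshold=threshold, group_of=group_of, group_sizes=sizes, members=groups
    )


def build_risk_design(
    genotypes: GenotypeMatrix,
    grouping: VariantGrouping,
    gamma: np.ndarray,
) -> tuple[np.ndarray, list[int]]:
    """Risk-index design matrix for an inclusion state.

    Each group with at least one included variant contributes one column
    equal to the per-individual sum of its included dosage columns
    (``G_g = X_g @ gamma_g``); for a common singleton group that is the
    variant's own column. Returns the n x m design and the indices of the
    active groups in column order.
    """
    gamma = np.asarray(gamma)
    if gamma.shape != (genotypes.p,):
        raise DataError("gamma length must equal the number of variants")
    cols = []
    active: list[int] = []
    for g, idx in enumerate(grouping.members):
        w = gamma[idx]
        if w.any():
            cols.append(genotypes.values[:, idx] @ w.astype(float))
            active.append(g)
    design = (
        np.column_stack(cols) if cols else np.empty((genotypes.n, 0), dtype=float)
    )
    return design, active
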