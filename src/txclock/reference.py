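"""Training of the clock reference.

The reference is built in three steps: raw counts are normalized to
per-sample relative frequencies (each gene's count divided by the sample's
library size), genes are ranked by the absolute Spearman rank correlation
of their frequency with chronological age, and the top-ranked genes' trends
are fit with LOWESS and tabulated at the discrete age grid.  The result — a
matrix of fitted frequencies per selected gene per grid age, plus the
smoothing fraction tau and the rho values — is the trained clock.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AgeAnnotation, CountMatrix
from .smoothing import lowess_fit

__all__ = [
    "FrequencyMatrix",
    "GeneRanking",
    "ReferenceModel",
    "normalize_counts",
    "spearman_rho",
    "rank_and_select",
    "build_reference",
]

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.7
DEFAULT_N_GENES = 12
DEFAULT_FREQ_FLOOR = 1e-12


@dataclass
class FrequencyMatrix:
    """Genes x samples matrix of relative frequencies; columns sum to 1."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    freqs: np.ndarray


@dataclass
class GeneRanking:
    """Genes ordered by |rho| (non-increasing); undefined rho excluded."""

    gene_ids: tuple[str, ...]
    rho: np.ndarray
    n_positive: int = 0
    n_negative: int = 0
    n_undefined: int = 0


@dataclass
class ReferenceModel:
    """A trained clock: fitted gene frequencies tabulated on the age grid."""

    tau: float
    age_grid: np.ndarray
    gene_ids: tuple[str, ...]
    rho: np.ndarray
    fitted_freq: np.ndarray            # (n_genes, n_grid)
    freq_floor: float = DEFAULT_FREQ_FLOOR
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.fitted_freq = np.asarray(self.fitted_freq, dtype=float)
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if self.age_grid.size < 2 or (np.diff(self.age_grid) <= 0).any():
            raise ValueError("age grid must have >= 2 strictly increasing ages")
        if self.fitted_freq.shape != (len(self.gene_ids), self.age_grid.size):
            raise ValueError("fitted_freq shape does not match genes x grid")
        if not (self.freq_floor > 0):
            raise ValueError("freq_floor must be > 0")
        if (self.fitted_freq < self.freq_floor).any():
            raise ValueError("fitted frequencies below freq_floor")
        if (~np.isfinite(self.rho)).any() or (self.rho == 0).any():
            raise ValueError("rho must be finite and nonzero for all genes")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceModel):
            return NotImplemented
        return (self.tau == other.tau
                and self.gene_ids == other.gene_ids
                and np.array_equal(self.age_grid, other.age_grid)
                and np.array_equal(self.rho, other.rho)
                and np.array_equal(self.fitted_freq, other.fitted_freq)
                and self.freq_floor == other.freq_floor)


def normalize_counts(cm: CountMatrix) -> FrequencyMatrix:
    """Convert raw counts to per-sample relative frequencies.

    Each count is divided by its sample's total count (library size), so
    every column of the result sums to 1.  Samples with zero total are
    rejected.
    """
    totals = cm.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [cm.sample_ids[j] for j in zero]
        raise ValueError(f"samples with zero total counts: {bad}")
    freqs = cm.counts / totals[None, :].astype(float)
    return FrequencyMatrix(cm.gene_ids, cm.sample_ids, freqs)


def spearman_rho(values, ages) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (the undefined marker) when either input is constant.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and ages must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(v, a).statistic
    return float(rho) if np.isfinite(rho) else float("nan")


def _spearman_matrix(freqs: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho of a genes x samples matrix against ages."""
    rv = stats.rankdata(freqs, axis=1)
    ra = stats.rankdata(ages)
    rv_c = rv - rv.mean(axis=1, keepdims=True)
    ra_c = ra - ra.mean()
    denom = np.sqrt((rv_c ** 2).sum(axis=1) * (ra_c ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rv_c @ ra_c) / denom
    rho[denom == 0.0] = np.nan
    return rho


def rank_and_select(fm: FrequencyMatrix, ann: AgeAnnotation,
                    n_top: int) -> GeneRanking:
    """Rank genes by |rho| (frequency vs. age) and keep the top ``n_top``.

    Genes whose rho is undefined (constant input) or exactly zero are
    excluded.  Ties in |rho| break by lexicographic gene ID so the selection
    is deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    ages = ann.ages_for(fm.sample_ids)
    rho = _spearman_matrix(fm.freqs, ages)
    defined = np.isfinite(rho) & (rho != 0.0)
    n_undef = int((~np.isfinite(rho)).sum())
    if defined.sum() < n_top:
        raise ValueError(
            f"n_top={n_top} exceeds the {int(defined.sum())} genes with a "
            "defined, nonzero Spearman rho")
    order = sorted(np.flatnonzero(defined),
                   key=lambda i: (-abs(rho[i]), fm.gene_ids[i]))
    top = order[:n_top]
    return GeneRanking(
        gene_ids=tuple(fm.gene_ids[i] for i in top),
        rho=rho[top].copy(),
        n_positive=int((rho[np.isfinite(rho)] > 0).sum()),
        n_negative=int((rho[np.isfinite(rho)] < 0).sum()),
        n_undefined=n_undef)


def build_reference(cm: CountMatrix, ann: AgeAnnotation,
                    tau: float = DEFAULT_TAU, n_top: int = DEFAULT_N_GENES,
                    age_grid="auto", freq_floor: float = DEFAULT_FREQ_FLOOR,
                    robust_iters: int = 3) -> ReferenceModel:
    """Train a clock reference from counts and ages.

    ``age_grid="auto"`` tabulates the fitted frequencies at the sorted
    unique annotated ages; an explicit grid must lie within the training age
    range.  LOWESS fits that dip to or below zero at a grid age are clamped
    at ``freq_floor`` so downstream Poisson rates stay positive.
    """
    fm = normalize_counts(cm)
    ages = ann.ages_for(fm.sample_ids)
    if isinstance(age_grid, str):
        if age_grid != "auto":
            raise ValueError(f"age_grid must be 'auto' or an array, got {age_grid!r}")
        grid = np.unique(ages)
    else:
        grid = np.asarray(age_grid, dtype=float)
    ranking = rank_and_select(fm, ann, n_top)
    logger.info("gene ranking: %d positive, %d negative, %d undefined rho",
                ranking.n_positive, ranking.n_negative, ranking.n_undefined)
    pos = {g: i for i, g in enumerate(fm.gene_ids)}
    fitted = np.empty((len(ranking.gene_ids), grid.size))
    for i, g in enumerate(ranking.gene_ids):
        fitted[i] = lowess_fit(ages, fm.freqs[pos[g]], tau, grid,
                               robust_iters=robust_iters)
    fitted = np.maximum(fitted, freq_floor)
    return ReferenceModel(
        tau=tau, age_grid=grid, gene_ids=ranking.gene_ids,
        rho=ranking.rho, fitted_freq=fitted, freq_floor=freq_floor,
        diagnostics={"n_positive_rho": ranking.n_positive,
                     "n_negative_rho": ranking.n_negative,
                     "n_undefined_rho": ranking.n_undefined})
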