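"""Poisson maximum-likelihood age estimation.

Given a trained reference, a test sample's observed gene counts k_g are
scored at every grid age x under independent Poisson models with rates
lambda_g(x) = fitted frequency of gene g at age x, times the sample's
library size.  Summing log-probabilities over genes gives a log-likelihood
profile over the grid; its argmax is the transcriptomic age.  Genes present
in the model but missing from the sample are simply dropped (the profile is
computed over the intersection), which is what makes the clock tolerant of
missing features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import CountMatrix
from .reference import ReferenceModel

__all__ = [
    "AgeLikelihood",
    "PredictionResult",
    "poisson_log_pmf",
    "expected_counts",
    "log_likelihood_profile",
    "predict_age",
]


@dataclass
class AgeLikelihood:
    """Per-sample log-likelihood profile over the age grid.

    ``posterior`` is the profile normalized via log-sum-exp (a flat prior
    over grid ages); ``point_estimate`` is the grid age with maximal
    log-likelihood, ties resolved to the youngest age.
    """

    age_grid: np.ndarray
    log_lik: np.ndarray
    posterior: np.ndarray
    point_estimate: float
    n_genes_used: int
    sample_id: str | None = None


@dataclass
class PredictionResult:
    """Predictions for a batch of samples, with per-sample error isolation."""

    results: list[AgeLikelihood] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)


def poisson_log_pmf(k, lam):
    """Log Poisson pmf ``-lam + k*ln(lam) - ln(k!)`` (log-gamma for k!).

    Vectorized over both arguments; ``k`` must be non-negative integral and
    ``lam`` strictly positive.
    """
    k_arr = np.asarray(k, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if (k_arr < 0).any() or (np.rint(k_arr) != k_arr).any():
        raise ValueError("k must be non-negative integers")
    if (lam_arr <= 0).any():
        raise ValueError("lam must be strictly positive")
    out = -lam_arr + k_arr * np.log(lam_arr) - gammaln(k_arr + 1.0)
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


def expected_counts(model: ReferenceModel, grid_index: int,
                    library_size: float) -> np.ndarray:
    """Poisson rates for all model genes at one grid age.

    The rate of gene g is its fitted reference frequency at the grid age
    scaled by the test sample's library size.
    """
    if not 0 <= grid_index < model.age_grid.size:
        raise ValueError(f"grid_index {grid_index} out of range")
    if not library_size > 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return model.fitted_freq[:, grid_index] * float(library_size)


def log_likelihood_profile(gene_ids, counts, model: ReferenceModel,
                           lambda_scale: str = "full",
                           sample_id: str | None = None) -> AgeLikelihood:
    """Log-likelihood profile of one sample over the model's age grid.

    Parameters
    ----------
    gene_ids, counts
        The sample's gene list and matching count vector (one column of a
        count matrix).
    lambda_scale
        ``"full"`` scales rates by the total count over all the sample's
        genes (the library size the reference frequencies are defined
        against); ``"intersection"`` uses the total over the intersected
        genes only.
    """
    if lambda_scale not in ("full", "intersection"):
        raise ValueError(f"unknown lambda_scale {lambda_scale!r}")
    counts = np.asarray(counts)
    gene_ids = list(gene_ids)
    if counts.shape != (len(gene_ids),):
        raise ValueError("counts must match gene_ids in length")
    pos = {g: i for i, g in enumerate(gene_ids)}
    model_idx, sample_idx = [], []
    for i, g in enumerate(model.gene_ids):
        j = pos.get(g)
        if j is not None:
            model_idx.append(i)
            sample_idx.append(j)
    if not model_idx:
        raise ValueError("sample shares no genes with the reference model")
    k = counts[sample_idx].astype(np.int64)
    total = counts.sum() if lambda_scale == "full" else k.sum()
    if total <= 0:
        raise ValueError("sample has zero library size")
    lam = model.fitted_freq[model_idx, :] * float(total)   # (n_used, n_grid)
    log_lik = poisson_log_pmf(k[:, None], lam).sum(axis=0)
    posterior = np.exp(log_lik - logsumexp(log_lik))
    point = float(model.age_grid[int(np.argmax(log_lik))])
    return AgeLikelihood(age_grid=model.age_grid.copy(), log_lik=log_lik,
                         posterior=posterior, point_estimate=point,
                         n_genes_used=len(model_idx), sample_id=sample_id)


def predict_age(samples: CountMatrix, model: ReferenceModel,
                lambda_scale: str = "full") -> PredictionResult:
    """Profile every sample in a count matrix against a trained reference.

    Per-sample errors (empty gene intersection, zero library) are recorded
    in ``failures`` and do not abort the remaining samples.
    """
    out = PredictionResult()
    for j, sid in enumerate(samples.sample_ids):
        try:
            out.results.append(log_likelihood_profile(
                samples.gene_ids, samples.counts[:, j], model,
                lambda_scale=lambda_scale, sample_id=sid))
        except ValueError as exc:
            out.failures[sid] = str(exc)
    return out
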