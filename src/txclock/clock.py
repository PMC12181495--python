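"""scikit-learn style estimator interface to the clock.

:class:`PoissonAgeClock` follows the sklearn estimator contract (``fit`` /
``predict``, ``get_params`` / ``set_params``, trailing-underscore fitted
attributes) so it composes with pipelines and model selection.  ``X`` is in
sklearn orientation — samples as rows, genes as columns — the transpose of
the genes-by-samples convention the file formats use; the wrapper functions
in :mod:`txclock.reference` and :mod:`txclock.likelihood` bridge the two.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import AgeAnnotation, CountMatrix
from .likelihood import AgeLikelihood, log_likelihood_profile
from .reference import (DEFAULT_FREQ_FLOOR, DEFAULT_N_GENES, DEFAULT_TAU,
                        build_reference)

__all__ = ["PoissonAgeClock"]


class PoissonAgeClock(RegressorMixin, BaseEstimator):
    """Transcriptomic age clock: LOWESS reference + Poisson ML estimation.

    Parameters
    ----------
    tau : float, default 0.7
        LOWESS smoothing fraction used when fitting per-gene frequency
        trends against age.
    n_genes : int, default 12
        Number of top |Spearman rho| genes kept in the reference.
    age_grid : "auto" or array-like, default "auto"
        Discrete ages (months) at which the reference is tabulated and the
        likelihood evaluated; "auto" uses the sorted unique training ages.
    freq_floor : float, default 1e-12
        Lower clamp on fitted frequencies, keeping Poisson rates positive.
    lambda_scale : {"full", "intersection"}, default "full"
        Which library size scales the Poisson rates at predict time.
    robust_iters : int, default 3
        LOWESS bisquare robustifying iterations.

    Attributes
    ----------
    reference_ : ReferenceModel
        The trained reference (gene IDs, rho, fitted frequencies, grid).
    gene_ids_, rho_, age_grid_, fitted_freq_
        Convenience views of the reference fields.
    """

    def __init__(self, tau: float = DEFAULT_TAU,
                 n_genes: int = DEFAULT_N_GENES, age_grid="auto",
                 freq_floor: float = DEFAULT_FREQ_FLOOR,
                 lambda_scale: str = "full", robust_iters: int = 3) -> None:
        self.tau = tau
        self.n_genes = n_genes
        self.age_grid = age_grid
        self.freq_floor = freq_floor
        self.lambda_scale = lambda_scale
        self.robust_iters = robust_iters

    # -- helpers ------------------------------------------------------------
    def _feature_names(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        return [f"feature_{i}" for i in range(np.asarray(X).shape[1])]

    def _as_count_matrix(self, X, names: list[str]) -> CountMatrix:
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-D samples x genes array")
        if isinstance(X, pd.DataFrame):
            sample_ids = [str(s) for s in X.index]
        else:
            sample_ids = [f"sample_{i}" for i in range(arr.shape[0])]
        return CountMatrix(names, sample_ids, arr.T)

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y) -> "PoissonAgeClock":
        """Train the reference from counts ``X`` (samples x genes) and ages ``y``."""
        names = self._feature_names(X)
        cm = self._as_count_matrix(X, names)
        y = np.asarray(y, dtype=float)
        if y.shape != (cm.n_samples,):
            raise ValueError("y must hold one age per sample")
        ann = AgeAnnotation(dict(zip(cm.sample_ids, y)))
        self.reference_ = build_reference(
            cm, ann, tau=self.tau, n_top=self.n_genes,
            age_grid=self.age_grid, freq_floor=self.freq_floor,
            robust_iters=self.robust_iters)
        self.n_features_in_ = len(names)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self.gene_ids_ = self.reference_.gene_ids
        self.rho_ = self.reference_.rho
        self.age_grid_ = self.reference_.age_grid
        self.fitted_freq_ = self.reference_.fitted_freq
        return self

    def predict_profile(self, X) -> list[AgeLikelihood]:
        """Full log-likelihood profile and posterior for each sample.

        A DataFrame ``X`` is intersected with the model genes by column
        name, so columns may be missing; a plain array must carry all
        training features in order.
        """
        check_is_fitted(self, "reference_")
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            arr = X.to_numpy()
            ids = [str(s) for s in X.index]
        else:
            arr = np.asarray(X)
            if arr.ndim != 2 or arr.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X must have {self.n_features_in_} columns (training "
                    "feature order); pass a DataFrame for partial gene sets")
            names = (list(self.feature_names_in_)
                     if hasattr(self, "feature_names_in_")
                     else [f"feature_{i}" for i in range(arr.shape[1])])
            ids = [f"sample_{i}" for i in range(arr.shape[0])]
        return [log_likelihood_profile(names, arr[i], self.reference_,
                                       lambda_scale=self.lambda_scale,
                                       sample_id=ids[i])
                for i in range(arr.shape[0])]

    def predict(self, X) -> np.ndarray:
        """Maximum-likelihood age (months) for each sample."""
        return np.array([p.point_estimate for p in self.predict_profile(X)])
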