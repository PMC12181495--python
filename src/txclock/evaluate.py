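"""Leave-one-out cross-validation, accuracy metrics and residual-bias
analysis.

LOOCV retrains the whole clock — frequency normalization, gene re-selection
and LOWESS refitting — on every training fold, so the held-out sample never
influences the model that predicts it.  Accuracy is summarized by Pearson R,
two R-squared variants (squared correlation and coefficient of
determination; a constant prediction offset separates them) and the MAE in
months.  A LOWESS fit of residuals against true age exposes systematic
age-associated bias, which would contaminate any "age acceleration"
interpretation of the residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AgeAnnotation, CountMatrix
from .likelihood import log_likelihood_profile
from .reference import (DEFAULT_FREQ_FLOOR, DEFAULT_N_GENES, DEFAULT_TAU,
                        build_reference, spearman_rho)
from .smoothing import lowess_fit

__all__ = [
    "EvaluationReport",
    "metrics",
    "residual_trend",
    "loocv_clock",
    "ElasticNetConfig",
    "elastic_net_loocv",
]


@dataclass
class EvaluationReport:
    """Per-sample truth/prediction pairs plus summary metrics."""

    samples: pd.DataFrame          # sample_id, true_age, predicted_age, residual
    metrics: dict
    residual_trend: pd.DataFrame | None = None
    residual_rho: float = float("nan")
    failures: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    fold_models: list | None = None


def metrics(true_ages, predicted_ages) -> dict:
    """Pearson R, both R-squared variants, and MAE (months).

    ``r_squared_corr`` is the squared Pearson correlation;
    ``r_squared_cod`` is the coefficient of determination
    ``1 - SS_res/SS_tot``.  With constant truth the correlation quantities
    are undefined and reported as NaN; the MAE is always returned.
    """
    t = np.asarray(true_ages, dtype=float)
    p = np.asarray(predicted_ages, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted ages must be equal-length vectors")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    mae = float(np.mean(np.abs(p - t)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    ss_res = float(np.sum((t - p) ** 2))
    denom = math.sqrt(ss_tot * np.sum((p - p.mean()) ** 2))
    r = float((np.sum((t - t.mean()) * (p - p.mean()))) / denom) \
        if denom > 0 else float("nan")
    r2_cod = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"pearson_r": r, "r_squared_corr": r * r,
            "r_squared_cod": r2_cod, "mae": mae}


def residual_trend(true_ages, residuals, tau: float = DEFAULT_TAU,
                   eval_ages=None) -> tuple[pd.DataFrame, float]:
    """LOWESS fit of residuals against true age, plus their Spearman rho.

    Evaluated at ``eval_ages`` (default: the sorted unique true ages).  A
    flat curve near zero and a near-zero rho indicate an unbiased clock.
    """
    t = np.asarray(true_ages, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if eval_ages is None:
        eval_ages = np.unique(t)
    fitted = lowess_fit(t, r, tau, eval_ages)
    rho = spearman_rho(r, t)
    return (pd.DataFrame({"age": np.atleast_1d(eval_ages),
                          "fitted_residual": fitted}), rho)


def loocv_clock(cm: CountMatrix, ann: AgeAnnotation,
                tau: float = DEFAULT_TAU, n_top: int = DEFAULT_N_GENES,
                age_grid="auto", freq_floor: float = DEFAULT_FREQ_FLOOR,
                lambda_scale: str = "full", robust_iters: int = 3,
                keep_fold_models: bool = False) -> EvaluationReport:
    """Leave-one-out evaluation of the Poisson clock.

    Each fold rebuilds the reference from scratch (including gene
    re-selection) on all other samples and predicts the held-out one.
    Failing folds are recorded and excluded from the metrics.
    """
    if cm.n_samples < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    rows = []
    failures: dict[str, str] = {}
    fold_models = [] if keep_fold_models else None
    for sid in cm.sample_ids:
        train = cm.drop_sample(sid)
        try:
            model = build_reference(train, ann, tau=tau, n_top=n_top,
                                    age_grid=age_grid, freq_floor=freq_floor,
                                    robust_iters=robust_iters)
            prof = log_likelihood_profile(cm.gene_ids, cm.column(sid), model,
                                          lambda_scale=lambda_scale,
                                          sample_id=sid)
        except ValueError as exc:
            failures[sid] = str(exc)
            continue
        if keep_fold_models:
            fold_models.append((sid, model))
        rows.append({"sample_id": sid, "true_age": ann[sid],
                     "predicted_age": prof.point_estimate,
                     "residual": prof.point_estimate - ann[sid]})
    df = pd.DataFrame(rows)
    report = EvaluationReport(samples=df, metrics={}, failures=failures,
                              fold_models=fold_models,
                              extras={"n_fold_failures": len(failures)})
    if len(df) >= 2:
        report.metrics = metrics(df["true_age"], df["predicted_age"])
        if np.unique(df["true_age"]).size >= 3:
            trend, rho = residual_trend(df["true_age"].to_numpy(),
                                        df["residual"].to_numpy(), tau=tau)
            report.residual_trend = trend
            report.residual_rho = rho
    return report


def __getattr__(name):
    # elastic_net_loocv and its config live in the baseline module; exposed
    # here as well since they belong to the evaluation surface.
    if name in ("ElasticNetConfig", "elastic_net_loocv"):
        from . import baseline
        return getattr(baseline, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
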