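"""Internal/external validation battery and applicability domain for MLR
activity models.

Implements the classical regression-model acceptability toolkit used in
activity prediction: leave-one-out cross-validation via the leverage
shortcut (PRESS), regression-through-origin statistics (r0^2, r0'^2, k, k'),
the rm^2 family, the external Q^2_f1/Q^2_f2 coefficients, error-based
(MAE) model-quality verdicts, the Golbraikh-Tropsha acceptability
conditions, and the leverage-based (Williams plot) applicability domain.

A note on r0-type statistics: the through-origin coefficients are NOT
bounded below by zero and can go negative for poor fits. That behavior is
preserved here -- no clamping -- except inside the rm^2 radicand, where a
negative value (possible only through rounding) is clamped at zero and
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .build import ols_stats
from .datasets import (
    AdReport,
    ConfigurationError,
    DatasetValidationError,
    MlrModel,
    QsarDataset,
    ValidationReport,
)

__all__ = [
    "internal_metrics",
    "regression_through_origin",
    "rm2_metrics",
    "external_metrics",
    "golbraikh_tropsha_check",
    "applicability_domain",
    "mae_based_verdict",
]


def _model_design(model: MlrModel, dataset: QsarDataset) -> np.ndarray:
    X = model.design(dataset.descriptor_matrix(model.descriptor_names))
    return np.column_stack([np.ones(X.shape[0]), X])


def _leverages(model: MlrModel, train: QsarDataset, query: np.ndarray | None = None) -> np.ndarray:
    Z = _model_design(model, train)
    XtX = Z.T @ Z
    try:
        A = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as err:
        raise DatasetValidationError("singular normal-equations matrix X'X") from err
    target = Z if query is None else query
    return np.einsum("ij,jk,ik->i", target, A, target)


def internal_metrics(model: MlrModel, train: QsarDataset) -> ValidationReport:
    """Training-set fit statistics and leave-one-out cross-validation.

    SEE uses the ``n - p`` denominator (p = model terms including intercept).
    PRESS is computed by the exact leverage shortcut ``e_i / (1 - h_i)``,
    identical to refitting the model n times; Q^2_LOO = 1 - PRESS / SS_tot.
    The rm^2 (LOO) metrics are evaluated on the LOO predictions.
    """
    y = train.y
    n, p = train.n, model.p
    if n <= p:
        raise ConfigurationError(f"need n > {p} training compounds, got {n}")
    Z = _model_design(model, train)
    yhat = Z @ np.concatenate([[model.intercept], model.coefficients])
    resid = y - yhat
    h = _leverages(model, train)
    sstot = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / sstot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    see = math.sqrt(rss / (n - p))
    loo_resid = resid / (1.0 - h)
    press = float(np.sum(loo_resid**2))
    q2_loo = 1.0 - press / sstot
    y_loo = y - loo_resid
    if np.allclose(resid, 0.0):
        avg_rm2, delta_rm2 = (1.0, 0.0)
    else:
        _, _, avg_rm2, delta_rm2 = rm2_metrics(y, y_loo, scale=False)
    return ValidationReport(
        r2=r2,
        r2_adj=r2_adj,
        see=see,
        press=press,
        q2_loo=q2_loo,
        avg_rm2_loo=avg_rm2,
        delta_rm2_loo=delta_rm2,
    )


def regression_through_origin(
    y_obs: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, float]:
    """Through-origin slopes and determination coefficients.

    ``k = sum(y_obs * y_pred) / sum(y_pred^2)`` and
    ``k' = sum(y_obs * y_pred) / sum(y_obs^2)``. The r0^2 coefficient uses the
    through-origin prediction ``k * y_pred`` against ``y_pred``'s spread, and
    r0'^2 symmetrically uses ``k' * y_obs`` against ``y_obs``'s spread.
    Returns ``(r0_2, r0_prime_2, k, k_prime)``.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 3:
        raise ConfigurationError("need two equal-length vectors of size >= 3")
    sp2 = float(np.sum(y_pred**2))
    so2 = float(np.sum(y_obs**2))
    var_p = float(np.sum((y_pred - y_pred.mean()) ** 2))
    var_o = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sp2 == 0 or so2 == 0 or var_p == 0 or var_o == 0:
        raise DatasetValidationError("zero denominator in through-origin regression")
    cross = float(np.sum(y_obs * y_pred))
    k = cross / sp2
    k_prime = cross / so2
    r0_2 = 1.0 - float(np.sum((y_pred - k * y_pred) ** 2)) / var_p
    r0_prime_2 = 1.0 - float(np.sum((y_obs - k_prime * y_obs) ** 2)) / var_o
    return r0_2, r0_prime_2, k, k_prime


def _pearson_r2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    return float(r * r)


def rm2_metrics(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    scale: bool = False,
) -> tuple[float, float, float, float]:
    """rm^2 family: ``rm^2 = r^2 * (1 - sqrt(r^2 - r0^2))`` and its primed
    counterpart using r0'^2; returns (rm2, rm2_prime, average, |difference|).

    With ``scale`` set, both vectors are min-max scaled to [0, 1] using their
    combined range before computation (the "after scaling" convention).
    A radicand pushed below zero by rounding is clamped at 0.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 3:
        raise ConfigurationError("need two equal-length vectors of size >= 3")
    if scale:
        lo = min(y_obs.min(), y_pred.min())
        hi = max(y_obs.max(), y_pred.max())
        if hi == lo:
            raise DatasetValidationError("degenerate range: cannot min-max scale")
        y_obs = (y_obs - lo) / (hi - lo)
        y_pred = (y_pred - lo) / (hi - lo)
    r2 = _pearson_r2(y_obs, y_pred)
    r0_2, r0_prime_2, _, _ = regression_through_origin(y_obs, y_pred)
    rm2 = r2 * (1.0 - math.sqrt(max(r2 - r0_2, 0.0)))
    rm2_prime = r2 * (1.0 - math.sqrt(max(r2 - r0_prime_2, 0.0)))
    avg = 0.5 * (rm2 + rm2_prime)
    delta = abs(rm2 - rm2_prime)
    return rm2, rm2_prime, avg, delta


def mae_based_verdict(mae_95: float, sd_95: float, y_range: float) -> str:
    """Error-based model-quality verdict from trimmed test-set errors.

    GOOD iff MAE_95 <= 0.1 * (training y-range) and
    MAE_95 + 3 * SD_95 <= 0.2 * range; BAD iff MAE_95 > 0.15 * range or
    MAE_95 + 3 * SD_95 > 0.25 * range; otherwise MODERATE.
    """
    if mae_95 <= 0.1 * y_range and mae_95 + 3.0 * sd_95 <= 0.2 * y_range:
        return "GOOD"
    if mae_95 > 0.15 * y_range or mae_95 + 3.0 * sd_95 > 0.25 * y_range:
        return "BAD"
    return "MODERATE"


def external_metrics(
    model: MlrModel,
    test: QsarDataset,
    train_mean: float,
    y_range: float | None = None,
) -> ValidationReport:
    """Test-set predictivity metrics.

    r^2 is the squared Pearson correlation of observed vs predicted;
    Q^2_f1 = 1 - SSE / sum((y - mean_train)^2) and Q^2_f2 uses the test mean.
    MAE_95/SD_95 trim the ceil(5%) largest absolute errors before averaging.
    The rm^2 (test) block is computed on combined-range min-max scaled values.
    Fewer than 3 test compounds flags the report unreliable.
    """
    if test.n == 0:
        raise ConfigurationError("test set is empty")
    y = test.y
    yhat = model.predict_dataset(test)
    report = ValidationReport()
    if test.n < 3:
        report.unreliable = True
        report.rmsep = float(np.sqrt(np.mean((yhat - y) ** 2)))
        return report
    err = yhat - y
    sse = float(err @ err)
    report.r2_ext = _pearson_r2(y, yhat)
    report.r0_2, report.r0_prime_2, report.k, report.k_prime = regression_through_origin(y, yhat)
    report.rmsep = math.sqrt(sse / test.n)
    report.q2_f1 = 1.0 - sse / float(np.sum((y - train_mean) ** 2))
    report.q2_f2 = 1.0 - sse / float(np.sum((y - y.mean()) ** 2))
    abs_err = np.sort(np.abs(err))
    n_drop = math.ceil(0.05 * test.n)
    kept = abs_err[: test.n - n_drop] if n_drop else abs_err
    report.mae_95 = float(kept.mean())
    report.sd_95 = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    if np.allclose(err, 0.0):
        report.avg_rm2_test, report.delta_rm2_test = 1.0, 0.0
    else:
        _, _, report.avg_rm2_test, report.delta_rm2_test = rm2_metrics(y, yhat, scale=True)
    if y_range is None:
        training = model.training or {}
        if "y_min" in training and "y_max" in training:
            y_range = float(training["y_max"]) - float(training["y_min"])
    if y_range:
        report.mae_verdict = mae_based_verdict(report.mae_95, report.sd_95, y_range)
    return report


_GT_FIELDS = ("q2_loo", "r2_ext", "r0_2", "r0_prime_2", "k", "k_prime")


def golbraikh_tropsha_check(report: ValidationReport | dict) -> list[tuple[str, float, str, bool]]:
    """Evaluate the five model-acceptability conditions.

    I.   Q^2 > 0.5
    II.  R^2 > 0.6
    III. ((R^2 - R0^2)/R^2 < 0.1 and 0.85 <= k <= 1.15) or the primed/k'
         branch of the same test
    IV.  |R0^2 - R0'^2| < 0.3
    V.   R0^2 or R0'^2 close to R^2 (the ratio test of III without the slope
         constraint)

    Returns ``(criterion, value, threshold, passed)`` tuples; raises naming
    any missing input field.
    """
    values = report if isinstance(report, dict) else report.to_dict()
    missing = [f for f in _GT_FIELDS if values.get(f) is None]
    if missing:
        raise ConfigurationError(f"report missing fields required for the check: {missing}")
    q2, r2 = values["q2_loo"], values["r2_ext"]
    r0_2, r0p_2 = values["r0_2"], values["r0_prime_2"]
    k, k_prime = values["k"], values["k_prime"]
    ratio = (r2 - r0_2) / r2
    ratio_prime = (r2 - r0p_2) / r2
    branch = (ratio < 0.1 and 0.85 <= k <= 1.15) or (ratio_prime < 0.1 and 0.85 <= k_prime <= 1.15)
    checks = [
        ("I: Q2 > 0.5", q2, "> 0.5", q2 > 0.5),
        ("II: R2 > 0.6", r2, "> 0.6", r2 > 0.6),
        (
            "III: slope/ratio branch",
            min(ratio, ratio_prime),
            "(R2-R0^2)/R2 < 0.1 with 0.85 <= k <= 1.15 (either branch)",
            bool(branch),
        ),
        ("IV: |R0^2 - R0'^2| < 0.3", abs(r0_2 - r0p_2), "< 0.3", abs(r0_2 - r0p_2) < 0.3),
        (
            "V: R0^2 or R0'^2 close to R2",
            min(ratio, ratio_prime),
            "< 0.1",
            min(ratio, ratio_prime) < 0.1,
        ),
    ]
    return checks


def applicability_domain(
    model: MlrModel,
    train: QsarDataset,
    query: QsarDataset | None = None,
    residual_limit: float = 3.0,
) -> AdReport:
    """Leverage / standardized-residual applicability domain (Williams plot).

    Leverages are ``h_i = x_i' (X'X)^-1 x_i`` with X the training design
    (model descriptors plus intercept column, on the model's scaling);
    the warning leverage is ``h* = 3p/n``. Standardized residuals divide by
    the training SEE for training compounds and by the test RMSEP for query
    compounds. A compound is in-domain iff ``h <= h*`` and
    ``|standardized residual| <= residual_limit``.
    """
    p, n = model.p, train.n
    h_star = 3.0 * p / n
    h_train = _leverages(model, train)
    yhat = model.predict_dataset(train)
    resid = train.y - yhat
    see = math.sqrt(float(resid @ resid) / (n - p))
    std_resid = resid / see if see > 0 else np.zeros_like(resid)
    frames = [
        pd.DataFrame(
            {
                "id": train.ids,
                "leverage": h_train,
                "std_residual": std_resid,
                "set": "train",
            }
        )
    ]
    if query is not None:
        Xq = model.design(query.descriptor_matrix(model.descriptor_names))
        Zq = np.column_stack([np.ones(Xq.shape[0]), Xq])
        h_query = _leverages(model, train, query=Zq)
        yq_hat = model.predict_dataset(query)
        resid_q = query.y - yq_hat
        rmsep = math.sqrt(float(np.mean(resid_q**2)))
        denom = rmsep if rmsep > 0 else (see if see > 0 else 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "id": query.ids,
                    "leverage": h_query,
                    "std_residual": resid_q / denom,
                    "set": "query",
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["in_domain"] = (table["leverage"] <= h_star) & (
        table["std_residual"].abs() <= residual_limit
    )
    return AdReport(table=table, h_star=h_star, residual_limit=residual_limit)
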