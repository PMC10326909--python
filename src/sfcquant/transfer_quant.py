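"""Calibration transfer, concentration prediction and error-factor scoring.

Predicted ionization efficiencies (log10 IE, relative scale anchored at
benzoic acid = 0 in positive mode) are mapped onto instrument-specific
response factors by a robust line fitted on a small calibrant set:

    log10 RF = slope * log10 IE_pred + intercept

fitted by iteratively reweighted least squares with Huber weights (tuning
constant 1.345, scale estimated from the MAD of the residuals), the standard
M-estimator default.  Concentrations then follow from the calibration model
inverse, c = corrected_area / RF, and accuracy is scored with the symmetric
fold error

    EF = max(c_pred / c_spiked, c_spiked / c_pred) >= 1,

which treats over- and underestimation equally and is comparable across
concentration levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransferLine",
    "QuantResult",
    "fit_transfer",
    "rf_from_ie",
    "predict_concentration",
    "error_factor",
    "summarize_errors",
]

HUBER_C = 1.345
_MAD_TO_SD = 1.0 / 0.6744897501960817  # MAD of a standard normal


@dataclass(frozen=True)
class TransferLine:
    slope: float
    intercept: float  # log10 M^-1
    robust_weights: np.ndarray
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("transfer line needs at least 2 calibrants")
        w = np.asarray(self.robust_weights)
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise ValueError("robust weights must lie in [0, 1]")


@dataclass(frozen=True)
class QuantResult:
    chemical_id: str
    level: float  # mol/L spiked
    predicted_conc: float  # mol/L
    error_factor: float

    def __post_init__(self) -> None:
        if self.predicted_conc <= 0:
            raise ValueError("predicted concentration must be positive")
        if self.error_factor < 1:
            raise ValueError("error factor is >= 1 by construction")


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    A = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    return beta  # (intercept, slope)


def fit_transfer(
    log_ie_pred: np.ndarray,
    log_rf_measured: np.ndarray,
    huber_c: float = HUBER_C,
    max_iter: int = 50,
    rtol: float = 1e-8,
) -> TransferLine:
    """Robust (Huber IRLS) fit of log10 RF on predicted log10 IE.

    ``max_iter = 0`` gives plain OLS (all weights 1).  Raises ``ValueError``
    on a degenerate design (all x identical) or non-finite input.
    """
    x = np.asarray(log_ie_pred, dtype=float)
    y = np.asarray(log_rf_measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need aligned 1-d arrays with at least 2 calibrants")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("calibrant values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all predicted log IE identical")
    w = np.ones_like(x)
    beta = _wls(x, y, w)
    converged = max_iter == 0
    for _ in range(max_iter):
        resid = y - (beta[0] + beta[1] * x)
        scale = np.median(np.abs(resid)) * _MAD_TO_SD
        if scale <= np.finfo(float).tiny:
            w = np.ones_like(x)
            converged = True
            break
        u = np.abs(resid) / scale
        w = np.minimum(1.0, huber_c / np.maximum(u, np.finfo(float).tiny))
        beta_new = _wls(x, y, w)
        if np.max(np.abs(beta_new - beta)) <= rtol * max(1.0, float(np.max(np.abs(beta)))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return TransferLine(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        robust_weights=w,
        n_points=x.size,
        converged=converged,
    )


def rf_from_ie(log_ie_pred: np.ndarray | float, line: TransferLine) -> np.ndarray | float:
    """Instrument-specific RF (M^-1): 10^(slope * log IE + intercept)."""
    out = np.power(10.0, line.slope * np.asarray(log_ie_pred, dtype=float) + line.intercept)
    return float(out) if out.ndim == 0 else out


def predict_concentration(
    corrected_area: np.ndarray | float, rf: np.ndarray | float
) -> np.ndarray | float:
    """Concentration (mol/L) = isotope-corrected area / response factor."""
    rf = np.asarray(rf, dtype=float)
    if np.any(rf <= 0):
        raise ValueError("response factor must be positive")
    out = np.asarray(corrected_area, dtype=float) / rf
    return float(out) if out.ndim == 0 else out


def error_factor(
    predicted: np.ndarray | float, spiked: np.ndarray | float
) -> np.ndarray | float:
    """Symmetric fold error max(pred/spiked, spiked/pred); always >= 1."""
    p = np.asarray(predicted, dtype=float)
    s = np.asarray(spiked, dtype=float)
    if np.any(p <= 0) or np.any(s <= 0):
        raise ValueError("concentrations must be positive")
    out = np.maximum(p / s, s / p)
    return float(out) if out.ndim == 0 else out


def summarize_errors(results: "list[QuantResult] | pd.DataFrame") -> dict[str, float]:
    """Aggregate error factors over chemicals and levels.

    Returns the median and mean EF over all (chemical, level) predictions and
    the fraction of chemicals whose EF is below 10 at *every* level.
    """
    if isinstance(results, pd.DataFrame):
        df = results[["chemical_id", "error_factor"]]
    else:
        if not results:
            raise ValueError("no quantification results to summarize")
        df = pd.DataFrame(
            {"chemical_id": [r.chemical_id for r in results],
             "error_factor": [r.error_factor for r in results]}
        )
    if df.empty:
        raise ValueError("no quantification results to summarize")
    ef = df["error_factor"].to_numpy(dtype=float)
    under10 = df.groupby("chemical_id")["error_factor"].max() < 10.0
    return {
        "median_ef": float(np.median(ef)),
        "mean_ef": float(np.mean(ef)),
        "frac_under_10": float(under10.mean()),
    }
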