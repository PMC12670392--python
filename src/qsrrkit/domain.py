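"""Leverage-based applicability domain and Williams-plot data.

A linear QSRR model only interpolates reliably inside the descriptor-space
region spanned by its training compounds.  The leverage approach measures a
query's distance from the training centroid through the hat matrix:
``h = x'(X'X)⁻¹x`` with an intercept column appended.  Predictions with
``h`` below the warning leverage ``h* = 3p/n`` (p parameters including the
intercept, n training compounds) are interpolations; at or above ``h*`` the
prediction is an extrapolation and flagged unreliable.

Combined with standardized residuals ``(y − ŷ)/RMSEC`` this yields the
Williams plot: leverage on x, standardized residual on y, with vertical
line at ``h*`` and horizontal lines at ±2 marking response outliers (the
±2·RMSEC rule on raw residuals).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import QSRRModel, predict

__all__ = ["ADResult", "warning_leverage", "leverages", "williams"]


@dataclass
class ADResult:
    """Per-compound applicability-domain assessment."""

    compound_ids: list[str]
    leverage: np.ndarray
    h_star: float
    predicted: np.ndarray
    standardized_residual: np.ndarray   # NaN where no observed RI
    in_domain: np.ndarray               # h < h*
    outlier: np.ndarray                 # |std resid| > 2 (False if no RI)

    @property
    def n_in(self) -> int:
        return int(self.in_domain.sum())

    @property
    def n_out(self) -> int:
        return int((~self.in_domain).sum())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["compound_id", "leverage", "predicted_ri",
                             "standardized_residual", "in_domain", "outlier"])
            for i, cid in enumerate(self.compound_ids):
                sr = self.standardized_residual[i]
                writer.writerow([
                    cid, f"{self.leverage[i]:.6g}",
                    f"{self.predicted[i]:.6g}",
                    "" if np.isnan(sr) else f"{sr:.6g}",
                    bool(self.in_domain[i]), bool(self.outlier[i]),
                ])


def warning_leverage(p_params: int, n_train: int) -> float:
    """Warning leverage ``h* = 3·p/n`` (``p`` counts the intercept)."""
    if p_params < 1:
        raise ValueError("p_params must be >= 1")
    if n_train <= p_params:
        raise ValueError("n_train must exceed p_params")
    return 3.0 * p_params / n_train


def leverages(X_train: np.ndarray, X_query: np.ndarray | None = None
              ) -> np.ndarray:
    """Hat-matrix diagonal values for query rows against a training design.

    An intercept column is appended internally; with no query the training
    self-leverages are returned (they sum to the number of parameters).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    A = np.column_stack([np.ones(len(X_train)), X_train])
    xtx = A.T @ A
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient training design")
    xtx_inv = np.linalg.inv(xtx)
    if X_query is None:
        Q = A
    else:
        X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
        Q = np.column_stack([np.ones(len(X_query)), X_query])
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def williams(model: QSRRModel, X_train: np.ndarray,
             X_query: np.ndarray, y_query: np.ndarray | None = None,
             compound_ids: Sequence[str] | None = None,
             h_star: float | None = None) -> ADResult:
    """Applicability-domain assessment of query compounds.

    Standardized residuals divide raw residuals by the model's training
    RMSEC, so the ±2 band is the ±2·RMSEC raw-residual outlier rule.
    ``in_domain`` uses strict ``h < h*`` (the boundary itself is treated as
    extrapolation).
    """
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    h = leverages(X_train, X_query)
    if h_star is None:
        h_star = warning_leverage(model.p_params, model.n_train)
    pred = predict(model, X_query)
    sr = np.full(len(pred), np.nan)
    if y_query is not None:
        y_query = np.asarray(y_query, dtype=float)
        raw = y_query - pred
        # an (essentially) exact calibration has no residual scale; declare
        # matching predictions exact rather than dividing rounding error by
        # rounding error
        eps = 1e-9 * max(1.0, float(np.max(np.abs(y_query), initial=0.0)))
        if model.rmsec > eps:
            sr = raw / model.rmsec
        else:
            sr = np.where(np.abs(raw) <= eps, 0.0, np.inf)
    if compound_ids is None:
        compound_ids = [f"q{i + 1}" for i in range(len(pred))]
    return ADResult(
        compound_ids=list(compound_ids),
        leverage=h,
        h_star=h_star,
        predicted=pred,
        standardized_residual=sr,
        in_domain=h < h_star,
        outlier=np.where(np.isnan(sr), False, np.abs(sr) > 2),
    )
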