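"""OLS retention-index models and their validation battery.

The modelling core is deliberately plain multiple linear regression: a
retention index is predicted as ``RI = b0 + Σ b_j x_j`` over a handful of
topological descriptors.  What makes such a model publishable is the
validation battery around it, implemented here:

* calibration statistics R² and RMSEC (RMSEC uses divisor ``n``, the
  chemometrics convention, so calibration and cross-validation errors are
  directly comparable);
* five cross-validation protocols — leave-one-out, 5-fold venetian blinds
  (interleaved folds), 5-fold continuous blocks, Monte Carlo resampling, and
  bootstrap (out-of-bag scoring);
* Y-randomization (response permutation) to rule out chance correlation;
* external predictivity via Q²F3 (training-variance denominator) and RMSEP;
* standardized regression coefficients for mechanistic interpretation.

A frozen built-in model (``builtin("hp5ms")``) carries the published
three-descriptor calibration for the HP-5ms stationary phase
(Eta_betaS, MDEC-22, MATS1p) for prediction-only use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "QSRRModel",
    "ValidationReport",
    "fit_ols",
    "predict",
    "standardized_coefficients",
    "crossvalidate",
    "y_randomization",
    "external_stats",
    "builtin",
    "BUILTIN_MODELS",
]


@dataclass
class QSRRModel:
    """A fitted (or frozen) multiple-linear-regression RI model."""

    descriptor_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    n_train: int
    y_train_mean: float
    y_train_ss: float        # Σ (y − ȳ)² over the training set
    r2: float
    rmsec: float
    standardized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("one coefficient per descriptor required")

    @property
    def p_params(self) -> int:
        """Number of fitted parameters, intercept included."""
        return len(self.coefficients) + 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "descriptor_names": list(self.descriptor_names),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "n_train": self.n_train,
            "y_train_mean": self.y_train_mean,
            "y_train_ss": self.y_train_ss,
            "r2": self.r2,
            "rmsec": self.rmsec,
            "standardized": (None if self.standardized is None
                             else np.asarray(self.standardized).tolist()),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "QSRRModel":
        d = json.loads(Path(path).read_text())
        std = d.get("standardized")
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            intercept=float(d["intercept"]),
            coefficients=np.array(d["coefficients"], dtype=float),
            n_train=int(d["n_train"]),
            y_train_mean=float(d["y_train_mean"]),
            y_train_ss=float(d["y_train_ss"]),
            r2=float(d["r2"]),
            rmsec=float(d["rmsec"]),
            standardized=None if std is None else np.array(std, dtype=float),
        )


@dataclass
class ValidationReport:
    """Collected cross-validation / randomization / external statistics."""

    crossval: dict[str, dict] = field(default_factory=dict)
    y_randomization: dict | None = None
    external: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"crossval": self.crossval,
             "y_randomization": self.y_randomization,
             "external": self.external}, indent=2))


# ---------------------------------------------------------------------------
# fitting and prediction


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def _ols_solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via QR; raises on rank deficiency."""
    A = _design(X)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify offending columns for the error message
        bad = []
        cols = [A[:, :1]]
        for j in range(1, A.shape[1]):
            trial = np.column_stack(cols + [A[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(A[:, j:j + 1])
            else:
                bad.append(j - 1)
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear descriptor columns "
            f"(0-based): {bad}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def fit_ols(X: np.ndarray, y: np.ndarray,
            descriptor_names: Sequence[str] | None = None) -> QSRRModel:
    """Fit an OLS model; R² = 1 − SS_res/SS_tot, RMSEC = sqrt(SS_res/n)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    beta = _ols_solve(X, y)
    resid = y - _design(X) @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    model = QSRRModel(
        descriptor_names=tuple(descriptor_names) if descriptor_names
        else tuple(f"x{j + 1}" for j in range(p)),
        intercept=float(beta[0]),
        coefficients=beta[1:],
        n_train=n,
        y_train_mean=float(y.mean()),
        y_train_ss=ss_tot,
        r2=r2,
        rmsec=float(np.sqrt(ss_res / n)),
    )
    model.standardized = standardized_coefficients(model, X, y)
    return model


def predict(model: QSRRModel, X, names: Sequence[str] | None = None
            ) -> np.ndarray:
    """Evaluate ``ŷ = b0 + Σ b_j x_j``.

    If ``X`` is a DataFrame (or ``names`` is given) columns are matched to
    the model's descriptors by name and reordered; a missing descriptor is
    an error.
    """
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :] if len(model.descriptor_names) > 1 else X[:, None]
    if names is not None:
        missing = [n for n in model.descriptor_names if n not in names]
        if missing:
            raise KeyError(f"input lacks model descriptors: {missing}")
        order = [names.index(n) for n in model.descriptor_names]
        X = X[:, order]
    if X.shape[1] != len(model.descriptor_names):
        raise ValueError(
            f"expected {len(model.descriptor_names)} descriptor columns, "
            f"got {X.shape[1]}"
        )
    return model.intercept + X @ model.coefficients


def standardized_coefficients(model: QSRRModel, X: np.ndarray,
                              y: np.ndarray) -> np.ndarray:
    """β_j = b_j · s_xj / s_y with sample standard deviations (ddof=1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    s_y = y.std(ddof=1)
    if s_y == 0:
        raise ValueError("response has zero variance")
    return model.coefficients * X.std(axis=0, ddof=1) / s_y


# ---------------------------------------------------------------------------
# cross-validation protocols

PROTOCOLS = ("LOO", "venetian5", "blocks5", "montecarlo", "bootstrap")


def _fold_indices(protocol: str, n: int, folds: int = 5) -> list[np.ndarray]:
    if protocol == "LOO":
        return [np.array([i]) for i in range(n)]
    if protocol == "venetian5":
        return [np.arange(k, n, folds) for k in range(folds)]
    if protocol == "blocks5":
        return [b for b in np.array_split(np.arange(n), folds) if len(b)]
    raise ValueError(f"unknown deterministic protocol {protocol!r}")


def crossvalidate(X: np.ndarray, y: np.ndarray, protocol: str = "LOO",
                  folds: int = 5, fraction: float = 0.2,
                  iterations: int = 1000, seed: int = 0
                  ) -> tuple[float, float]:
    """Cross-validated (R²cv, RMSECV) under one resampling protocol.

    Deterministic protocols (``LOO``, ``venetian5`` — every ``folds``-th row
    in stored order, ``blocks5`` — contiguous chunks) pool the held-out
    predictions: R²cv = 1 − PRESS/SS_tot.  ``montecarlo`` (random exclusion
    of ``fraction`` of the rows) and ``bootstrap`` (out-of-bag scoring)
    average the held-out R² and RMSE over ``iterations`` resamples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def _fit_predict(tr: np.ndarray, te: np.ndarray) -> np.ndarray:
        if len(tr) <= p + 1:
            raise ValueError(
                f"resample leaves {len(tr)} training rows for {p} "
                "descriptors"
            )
        beta = _ols_solve(X[tr], y[tr])
        return _design(X[te]) @ beta

    if protocol in ("LOO", "venetian5", "blocks5"):
        pred = np.empty(n)
        for k, held in enumerate(_fold_indices(protocol, n, folds)):
            tr = np.setdiff1d(np.arange(n), held)
            try:
                pred[held] = _fit_predict(tr, held)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design in fold {k}: {exc}") from exc
        press = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - press / ss_tot, float(np.sqrt(press / n))

    if protocol in ("montecarlo", "bootstrap"):
        rng = np.random.default_rng(seed)
        r2s, rmses = [], []
        for _ in range(iterations):
            if protocol == "montecarlo":
                held = rng.choice(n, size=max(1, int(round(fraction * n))),
                                  replace=False)
                tr = np.setdiff1d(np.arange(n), held)
            else:
                tr = rng.integers(0, n, size=n)
                held = np.setdiff1d(np.arange(n), np.unique(tr))
                if len(held) == 0:
                    continue
            pred = _fit_predict(tr, held)
            res = y[held] - pred
            sse = float(res @ res)
            ss = float(((y[held] - y[held].mean()) ** 2).sum())
            if ss > 0:
                r2s.append(1.0 - sse / ss)
            rmses.append(float(np.sqrt(sse / len(held))))
        return float(np.mean(r2s)), float(np.mean(rmses))

    raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")


def y_randomization(X: np.ndarray, y: np.ndarray, iterations: int = 1000,
                    seed: int = 0) -> tuple[float, float]:
    """Mean (R², RMSEC) over models refit to permuted responses.

    A real structure–retention relationship collapses under permutation:
    the mean permuted R² should sit near its null expectation k/(n−1).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    r2s = np.empty(iterations)
    rmses = np.empty(iterations)
    for it in range(iterations):
        yp = y[rng.permutation(n)]
        beta = _ols_solve(X, yp)
        resid = yp - _design(X) @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yp - yp.mean()) ** 2).sum())
        r2s[it] = 1.0 - ss_res / ss_tot
        rmses[it] = np.sqrt(ss_res / n)
    return float(r2s.mean()), float(rmses.mean())


def external_stats(model: QSRRModel, X_ext: np.ndarray, y_ext: np.ndarray
                   ) -> tuple[float, float]:
    """External predictivity: (Q²F3, RMSEP).

    ``Q²F3 = 1 − [Σ_ext (y−ŷ)²/n_ext] / [Σ_train (y−ȳ_train)²/n_train]``;
    the training-variance denominator makes the statistic insensitive to the
    external set's own spread.
    """
    X_ext = np.asarray(X_ext, dtype=float)
    y_ext = np.asarray(y_ext, dtype=float)
    if len(y_ext) == 0:
        raise ValueError("external set is empty")
    pred = predict(model, X_ext)
    mse_ext = float(((y_ext - pred) ** 2).mean())
    var_train = model.y_train_ss / model.n_train
    return 1.0 - mse_ext / var_train, float(np.sqrt(mse_ext))


def validate(X: np.ndarray, y: np.ndarray,
             descriptor_names: Sequence[str] | None = None,
             protocols: Sequence[str] = ("LOO", "venetian5", "blocks5",
                                         "montecarlo", "bootstrap"),
             iterations: int = 1000, seed: int = 0,
             X_ext: np.ndarray | None = None,
             y_ext: np.ndarray | None = None) -> ValidationReport:
    """Run the full battery and collect a :class:`ValidationReport`."""
    report = ValidationReport()
    for proto in protocols:
        r2cv, rmsecv = crossvalidate(X, y, proto, iterations=iterations,
                                     seed=seed)
        entry = {"r2cv": r2cv, "rmsecv": rmsecv}
        if proto in ("montecarlo", "bootstrap"):
            entry.update(iterations=iterations, seed=seed)
        report.crossval[proto] = entry
    mean_r2, mean_rmse = y_randomization(X, y, iterations=iterations,
                                         seed=seed)
    report.y_randomization = {"mean_r2": mean_r2, "mean_rmse": mean_rmse,
                              "iterations": iterations, "seed": seed}
    if X_ext is not None and y_ext is not None and len(y_ext):
        model = fit_ols(X, y, descriptor_names)
        q2f3, rmsep = external_stats(model, X_ext, y_ext)
        report.external = {"q2f3": q2f3, "rmsep": rmsep,
                           "n_external": int(len(y_ext))}
    return report


# ---------------------------------------------------------------------------
# frozen built-in model

def _hp5ms() -> QSRRModel:
    # Published three-descriptor calibration for GC retention indices of
    # flavour compounds on HP-5ms (186 training compounds).  Training SS is
    # not printed with the calibration, so external Q²F3 against this frozen
    # model uses the training RI variance implied by R² and RMSEC:
    # SS_tot/n = RMSEC² / (1 − R²).
    r2, rmsec, n = 0.945, 73.8, 186
    var = rmsec**2 / (1 - r2)
    model = QSRRModel(
        descriptor_names=("Eta_betaS", "MDEC-22", "MATS1p"),
        intercept=428.2,
        coefficients=np.array([126.7, 13.8, 627.1]),
        n_train=n,
        y_train_mean=float("nan"),
        y_train_ss=var * n,
        r2=r2,
        rmsec=rmsec,
        standardized=np.array([0.756, 0.251, 0.205]),
    )
    return model


BUILTIN_MODELS = {"hp5ms": _hp5ms}


def builtin(name: str) -> QSRRModel:
    """Load a frozen built-in model by name (currently ``"hp5ms"``)."""
    try:
        return BUILTIN_MODELS[name]()
    except KeyError:
        raise KeyError(
            f"unknown built-in model {name!r}; available: "
            f"{sorted(BUILTIN_MODELS)}"
        ) from None
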