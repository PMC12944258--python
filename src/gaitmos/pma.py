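"""Principal motion analysis: a PLS-derived deflation regression.

After centring the columns of X (n x d) and y (n,), the model extracts L
"principal motions".  With X_1 = X, y_1 = y and, for each component l:

    w_l = X_l^T y_l / |X_l^T y_l|          (unit weight vector)
    c_l = X w_l                            (scores; undeflated X)
    p_l = X_l^T c_l / (c_l^T c_l)          (loadings)
    b_l = c_l^T y_l / (c_l^T c_l)          (regression coefficient)
    X_{l+1} = X_l - c_l p_l^T,   y_{l+1} = y_l - b_l c_l

an unseen centred row x predicts as  y_hat = x^T sum_l b_l w_l + y_bar.

Two variants are provided.  ``as_printed`` (default) computes scores from
the *undeflated* X for every component, exactly as the defining equations
state; ``nipals`` uses the conventional PLS1 scores c_l = X_l w_l with the
standard coefficient reconstruction W (P^T W)^{-1} b.  The two coincide at
L = 1.

``pma_oracle`` is an independent brute-force transcription of the same
equations kept deliberately naive (explicit per-component lists, no shared
code with the estimator) for cross-checking.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import DataError

MODEL_FORMAT_VERSION = 1


class PMARegressor(RegressorMixin, BaseEstimator):
    """Principal-motion (PLS-derived deflation) regression.

    Parameters
    ----------
    n_components : int, default 6
        Number of principal motions L to extract.  Capped (with a warning)
        at min(n_samples - 1, n_features); extraction also stops early if a
        deflated cross-covariance vanishes.
    variant : {"as_printed", "nipals"}, default "as_printed"
        Score convention; see the module docstring.
    zero_tol : float, default 1e-12
        Threshold below which a cross-covariance norm counts as zero.

    Attributes
    ----------
    x_mean_, y_mean_ : training column means used for centring.
    weights_ : (L_eff, d) unit weight vectors w_l.
    loadings_ : (L_eff, d) loading vectors p_l.
    coefs_ : (L_eff,) per-component regression coefficients b_l.
    coef_ : (d,) combined coefficient vector mapping centred x to y_hat.
    n_components_ : effective number of components extracted.
    residual_norms_ : |y_l| for l = 1..L_eff + 1 (non-increasing).
    """

    def __init__(
        self,
        n_components: int = 6,
        variant: str = "as_printed",
        zero_tol: float = 1e-12,
    ):
        self.n_components = n_components
        self.variant = variant
        self.zero_tol = zero_tol

    def fit(self, X, y):
        if self.variant not in ("as_printed", "nipals"):
            raise ValueError(
                f"variant must be 'as_printed' or 'nipals', got "
                f"{self.variant!r}"
            )
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        X, y = check_X_y(X, y, y_numeric=True)
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 training samples")
        L = int(self.n_components)
        cap = min(n - 1, d)
        if L > cap:
            warnings.warn(
                f"n_components={L} exceeds min(n-1, d)={cap}; capped",
                stacklevel=2,
            )
            L = cap

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        if not np.any(np.ptp(Xc, axis=0) > 0):
            raise ValueError("X is constant in every column")

        Xl = Xc.copy()
        yl = yc.copy()
        weights, loadings, coefs = [], [], []
        residual_norms = [float(np.linalg.norm(yl))]
        for l in range(L):
            cov = Xl.T @ yl
            nrm = float(np.linalg.norm(cov))
            if nrm <= self.zero_tol:
                if l == 0:
                    raise ValueError(
                        "X and y are uncorrelated (zero cross-covariance)"
                    )
                warnings.warn(
                    f"cross-covariance vanished at component {l + 1}; "
                    f"stopping with {l} components",
                    stacklevel=2,
                )
                break
            w = cov / nrm
            c = Xc @ w if self.variant == "as_printed" else Xl @ w
            cc = float(c @ c)
            if cc <= self.zero_tol:
                if l == 0:
                    raise ValueError("first score vector has zero norm")
                warnings.warn(
                    f"score norm vanished at component {l + 1}; stopping",
                    stacklevel=2,
                )
                break
            p = (Xl.T @ c) / cc
            b = float(c @ yl) / cc
            weights.append(w)
            loadings.append(p)
            coefs.append(b)
            Xl = Xl - np.outer(c, p)
            yl = yl - b * c
            residual_norms.append(float(np.linalg.norm(yl)))

        self.weights_ = np.asarray(weights)
        self.loadings_ = np.asarray(loadings)
        self.coefs_ = np.asarray(coefs)
        self.n_components_ = len(coefs)
        self.residual_norms_ = np.asarray(residual_norms)
        self.coef_ = self._coef_upto(self.n_components_)
        self.n_features_in_ = d
        return self

    def _coef_upto(self, L: int) -> np.ndarray:
        """Combined coefficient vector using the first L components."""
        W = self.weights_[:L]
        b = self.coefs_[:L]
        if self.variant == "as_printed":
            return W.T @ b
        # standard PLS1 reconstruction: beta = W (P^T W)^{-1} b
        P = self.loadings_[:L]
        return W.T @ np.linalg.solve(P @ W.T, b)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.x_mean_.size:
            raise DataError(
                f"predict: expected {self.x_mean_.size} columns, "
                f"got {X.shape[1]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict_path(self, X) -> np.ndarray:
        """(m, L_eff) predictions using 1..L_eff components (for tuning)."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        Xc = X - self.x_mean_
        cols = [
            Xc @ self._coef_upto(L) + self.y_mean_
            for L in range(1, self.n_components_ + 1)
        ]
        return np.column_stack(cols)


def training_residual_curve(X, y, L_max: int, variant: str = "as_printed"):
    """Residual norms |y_l| for l = 1..L_max+1 (non-increasing by design)."""
    model = PMARegressor(n_components=L_max, variant=variant).fit(X, y)
    return model.residual_norms_


# ---------------------------------------------------------------------------
# independent brute-force oracle (testing aid; no code shared with the class)
# ---------------------------------------------------------------------------

def pma_oracle(X, y, X_new, L: int) -> np.ndarray:
    """Naive transcription of the deflation equations; returns predictions.

    Written independently of :class:`PMARegressor` (explicit lists and
    loops, per-row prediction) so the two paths can cross-check each other.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    xbar = X.mean(axis=0)
    ybar = y.mean()
    X1 = X - xbar
    y1 = y - ybar

    Xl_list = [X1]
    yl_list = [y1]
    b_list = []
    w_list = []
    for _ in range(L):
        Xl = Xl_list[-1]
        yl = yl_list[-1]
        v = Xl.T @ yl
        norm_v = np.sqrt(float(v @ v))
        if norm_v == 0.0:
            break
        w = v / norm_v
        c = X1 @ w
        p = (Xl.T @ c) / float(c @ c)
        b = float(c @ yl) / float(c @ c)
        w_list.append(w)
        b_list.append(b)
        Xl_list.append(Xl - np.outer(c, p))
        yl_list.append(yl - b * c)

    preds = []
    for i in range(X_new.shape[0]):
        xi = X_new[i] - xbar
        acc = 0.0
        for b, w in zip(b_list, w_list):
            acc += b * float(xi @ w)
        preds.append(acc + ybar)
    return np.asarray(preds)


# ---------------------------------------------------------------------------
# plain-text (JSON) model serialization
# ---------------------------------------------------------------------------

def save_model(model: PMARegressor, path: Path | str) -> None:
    """Serialize a fitted model to versioned JSON text."""
    check_is_fitted(model, "coef_")
    payload: Dict = {
        "format": "gaitmos-pma-model",
        "format_version": MODEL_FORMAT_VERSION,
        "variant": model.variant,
        "n_components": model.n_components_,
        "x_mean": model.x_mean_.tolist(),
        "y_mean": model.y_mean_,
        "weights": model.weights_.tolist(),
        "loadings": model.loadings_.tolist(),
        "coefs": model.coefs_.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: Path | str) -> PMARegressor:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "gaitmos-pma-model":
        raise DataError(f"{path}: not a gaitmos PMA model file")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise DataError(
            f"{path}: unsupported model format version "
            f"{payload.get('format_version')}"
        )
    model = PMARegressor(
        n_components=int(payload["n_components"]), variant=payload["variant"]
    )
    model.x_mean_ = np.asarray(payload["x_mean"], dtype=float)
    model.y_mean_ = float(payload["y_mean"])
    model.weights_ = np.asarray(payload["weights"], dtype=float)
    model.loadings_ = np.asarray(payload["loadings"], dtype=float)
    model.coefs_ = np.asarray(payload["coefs"], dtype=float)
    model.n_components_ = int(payload["n_components"])
    model.coef_ = model._coef_upto(model.n_components_)
    model.n_features_in_ = model.x_mean_.size
    model.residual_norms_ = np.asarray([])
    return model
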