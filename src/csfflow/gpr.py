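"""Dense velocity-field reconstruction by Gaussian-process regression (stage 3).

The two velocity components are modelled as independent scalar Gaussian
processes over 2D position with an isotropic squared-exponential kernel and
homoscedastic observation noise scaled per observation by the stage-2 fit
weights (effective noise variance ``sigma_n^2 / w_i``).  Hyperparameters are
either supplied or selected by maximizing the log marginal likelihood with a
seeded multi-start L-BFGS over log-parameters (analytic gradients).  The
posterior mean and standard deviation are evaluated at every masked pixel
centre, giving a spatially smooth dense field with a per-pixel uncertainty
map.

Exact GP inference is cubic in the number of observations, so two seeded
uniform subsamples bound the cost: hyperparameter search runs on at most
``opt_subset`` vectors and the final predictor conditions on at most
``max_train`` (default 2000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .errors import EmptyRegionError, InsufficientDataError, InvalidParameterError

__all__ = ["GPHyperparams", "GPPredictor", "fit_gpr_component", "predict_field", "DenseField"]

_JITTER = 1e-10


@dataclass
class GPHyperparams:
    """Squared-exponential kernel scales: length (µm), signal and noise variances."""

    length_scale: float
    signal_var: float
    noise_var: float

    def as_dict(self) -> dict:
        return {
            "length_scale_um": self.length_scale,
            "signal_var": self.signal_var,
            "noise_var": self.noise_var,
        }


def _kernel(Xa: np.ndarray, Xb: np.ndarray, ls: float, sf2: float) -> np.ndarray:
    d2 = cdist(Xa, Xb, metric="sqeuclidean")
    return sf2 * np.exp(-0.5 * d2 / ls**2)


class GPPredictor:
    """Fitted Gaussian-process posterior for one velocity component."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        weights: np.ndarray | None,
        hyper: GPHyperparams,
    ):
        self.X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.weights = (
            np.ones(len(y)) if weights is None else np.asarray(weights, float)
        )
        self.hyper = hyper
        sw = self.weights.sum()
        self.mean_ = float((self.weights * y).sum() / sw)
        resid = y - self.mean_
        K = _kernel(self.X, self.X, hyper.length_scale, hyper.signal_var)
        K[np.diag_indices_from(K)] += hyper.noise_var / self.weights + _JITTER * max(
            hyper.signal_var, 1.0
        )
        self.L_ = cholesky(K, lower=True)
        self.alpha_ = cho_solve((self.L_, True), resid)

    def predict(self, Xq: np.ndarray, chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation of the latent field at Xq."""
        Xq = np.atleast_2d(np.asarray(Xq, float))
        mean = np.empty(len(Xq))
        sd = np.empty(len(Xq))
        for a in range(0, len(Xq), chunk):
            b = min(a + chunk, len(Xq))
            ks = _kernel(self.X, Xq[a:b], self.hyper.length_scale, self.hyper.signal_var)
            mean[a:b] = ks.T @ self.alpha_ + self.mean_
            v = solve_triangular(self.L_, ks, lower=True)
            var = self.hyper.signal_var - np.einsum("ij,ij->j", v, v)
            sd[a:b] = np.sqrt(np.clip(var, 0.0, None))
        return mean, sd


def _neg_lml_and_grad(theta, X, resid, weights):
    ls, sf2, sn2 = np.exp(theta)
    n = len(resid)
    d2 = cdist(X, X, metric="sqeuclidean")
    E = np.exp(-0.5 * d2 / ls**2)
    K = sf2 * E
    noise_diag = sn2 / weights
    K[np.diag_indices_from(K)] += noise_diag + _JITTER * max(sf2, 1.0)
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    alpha = cho_solve((L, True), resid)
    lml = (
        -0.5 * resid @ alpha
        - np.log(np.diag(L)).sum()
        - 0.5 * n * np.log(2 * np.pi)
    )
    Kinv = cho_solve((L, True), np.eye(n))
    M = np.outer(alpha, alpha) - Kinv
    dK_dlogls = sf2 * E * (d2 / ls**2)
    dK_dlogsf = sf2 * E
    grad = np.array(
        [
            0.5 * np.sum(M * dK_dlogls),
            0.5 * np.sum(M * dK_dlogsf),
            0.5 * np.sum(np.diag(M) * noise_diag),
        ]
    )
    return -lml, -grad


def fit_gpr_component(
    vectors: pd.DataFrame,
    component: str,
    kernel_params: GPHyperparams | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    max_train: int = 2000,
    opt_subset: int = 400,
) -> GPPredictor:
    """Fit one velocity component (``"vx"`` or ``"vy"``) as a scalar GP.

    ``vectors`` is the stage-2 table (``x_um, y_um, vx_um_s, vy_um_s,
    weight``).  With ``kernel_params=None`` the hyperparameters maximize the
    log marginal likelihood from ``n_restarts + 1`` seeded starts.
    """
    if component not in ("vx", "vy"):
        raise InvalidParameterError("component must be 'vx' or 'vy'")
    col = f"{component}_um_s"
    X = vectors[["x_um", "y_um"]].to_numpy(dtype=float)
    y = vectors[col].to_numpy(dtype=float)
    w = (
        vectors["weight"].to_numpy(dtype=float)
        if "weight" in vectors.columns
        else np.ones(len(y))
    )
    if len(y) < 5:
        raise InsufficientDataError(f"GPR needs >= 5 vectors, got {len(y)}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(w))):
        raise InvalidParameterError("non-finite values in GPR inputs")
    if np.any(w <= 0):
        raise InvalidParameterError("GPR observation weights must be positive")

    rng = np.random.default_rng(seed)
    if len(y) > max_train:
        keep = rng.choice(len(y), size=max_train, replace=False)
        keep.sort()
        X, y, w = X[keep], y[keep], w[keep]

    if kernel_params is None:
        sub = np.arange(len(y))
        if len(y) > opt_subset:
            sub = rng.choice(len(y), size=opt_subset, replace=False)
            sub.sort()
        Xs, ys, ws = X[sub], y[sub], w[sub]
        mean0 = (ws * ys).sum() / ws.sum()
        resid = ys - mean0
        var_y = float(resid.var())
        if var_y <= 0:
            kernel_params = GPHyperparams(1.0, max(var_y, 1e-12), 1e-12)
        else:
            span = float(np.ptp(Xs, axis=0).max()) or 1.0
            samp = Xs[rng.choice(len(Xs), size=min(200, len(Xs)), replace=False)]
            pd2 = cdist(samp, samp)
            ls0 = float(np.median(pd2[pd2 > 0])) if np.any(pd2 > 0) else span / 4
            theta0 = np.log([ls0, var_y, 0.1 * var_y])
            bounds = [
                (np.log(span * 1e-3), np.log(span * 10.0)),
                (np.log(var_y * 1e-6), np.log(var_y * 1e4)),
                (np.log(var_y * 1e-8), np.log(var_y * 1e4)),
            ]
            best = None
            for k in range(n_restarts + 1):
                start = theta0 if k == 0 else theta0 + rng.normal(0.0, 0.7, size=3)
                start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
                res = minimize(
                    _neg_lml_and_grad,
                    start,
                    args=(Xs, resid, ws),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                )
                if best is None or res.fun < best.fun:
                    best = res
            ls, sf2, sn2 = np.exp(best.x)
            kernel_params = GPHyperparams(float(ls), float(sf2), float(sn2))

    return GPPredictor(X, y, w, kernel_params)


@dataclass
class DenseField:
    """Per-pixel velocity mean/sd grids restricted to an ROI mask.

    Grids are NaN outside the mask; units µm/s.  ``hyperparams`` records the
    fitted kernel scales per component.
    """

    roi_mask: np.ndarray
    vx_grid: np.ndarray
    vy_grid: np.ndarray
    sd_vx_grid: np.ndarray
    sd_vy_grid: np.ndarray
    pixel_size_um: float
    hyperparams: dict = field(default_factory=dict)

    @property
    def speed_grid(self) -> np.ndarray:
        return np.hypot(self.vx_grid, self.vy_grid)


def predict_field(
    predictor_vx: GPPredictor,
    predictor_vy: GPPredictor,
    roi_mask: np.ndarray,
    pixel_size_um: float,
) -> DenseField:
    """Evaluate both component posteriors at every masked pixel centre."""
    roi_mask = np.asarray(roi_mask, bool)
    rr, cc = np.nonzero(roi_mask)
    if len(rr) == 0:
        raise EmptyRegionError("ROI mask selects no pixels")
    Xq = np.column_stack([cc * pixel_size_um, rr * pixel_size_um]).astype(float)
    grids = {}
    for name, pred in (("vx", predictor_vx), ("vy", predictor_vy)):
        mean, sd = pred.predict(Xq)
        g = np.full(roi_mask.shape, np.nan)
        s = np.full(roi_mask.shape, np.nan)
        g[rr, cc] = mean
        s[rr, cc] = sd
        grids[name] = (g, s)
    return DenseField(
        roi_mask=roi_mask,
        vx_grid=grids["vx"][0],
        vy_grid=grids["vy"][0],
        sd_vx_grid=grids["vx"][1],
        sd_vy_grid=grids["vy"][1],
        pixel_size_um=pixel_size_um,
        hyperparams={
            "vx": predictor_vx.hyper.as_dict(),
            "vy": predictor_vy.hyper.as_dict(),
        },
    )
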