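"""Logistic generalized additive models with a bivariate spatial smooth.

Two backends fit ``logit p = beta0 + X_par @ gamma + s(x, y)``:

``spline``
    A penalized tensor-product cubic B-spline smooth (P-spline: uniform
    B-spline bases per margin, second-order difference penalties) fit by
    penalized IRLS.  The smoothing parameter is selected by minimizing AIC
    (deviance + 2 * effective degrees of freedom) over a log-spaced grid.
    Coordinates are affinely mapped to the unit square before the basis is
    built, so fits are invariant to translation and isotropic rescaling of
    the projected coordinates.  Pointwise standard errors come from the
    Bayesian posterior covariance of the penalized fit, the convention
    large GAM packages use for confidence bands.

``loess``
    Local scoring with a bivariate local-linear (tricube-weighted) smoother
    of the working response, backfit against the parametric terms.  The
    span is selected by AIC over a small grid.  Standard errors use the
    local-regression hat rows against the working-response variance; the
    parametric/smooth covariance cross-terms are ignored (a documented
    approximation — the spline backend is the default).

The smooth term is centered to mean zero over the training points, so the
fitted smooth is directly the log-odds contrast against the sample-average
log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

__all__ = ["SplineLogisticGAM", "LoessLogisticGAM"]

_EPS = 1e-9


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def _binom_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _uniform_bspline_knots(n_basis: int, degree: int = 3) -> np.ndarray:
    n_interior = n_basis - degree - 1
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _marginal_design(u: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    t = _uniform_bspline_knots(n_basis, degree)
    u = np.clip(u, 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(u, t, degree).toarray()


def _difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


class _TensorBasis:
    """Tensor-product B-spline basis over the unit square."""

    def __init__(self, x: np.ndarray, y: np.ndarray, n_basis: int = 8):
        self.n_basis = n_basis
        self.x0, self.x1 = float(x.min()), float(x.max())
        self.y0, self.y1 = float(y.min()), float(y.max())
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("degenerate spatial extent: coordinates constant in x or y")
        sx = _difference_penalty(n_basis)
        sy = _difference_penalty(n_basis)
        eye = np.eye(n_basis)
        self.penalty = np.kron(sx, eye) + np.kron(eye, sy)

    def design(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = (np.asarray(x, float) - self.x0) / (self.x1 - self.x0)
        v = (np.asarray(y, float) - self.y0) / (self.y1 - self.y0)
        bx = _marginal_design(u, self.n_basis)
        by = _marginal_design(v, self.n_basis)
        return (bx[:, :, None] * by[:, None, :]).reshape(len(u), -1)


@dataclass
class SplineLogisticGAM:
    """Penalized tensor-spline logistic GAM.

    Parameters
    ----------
    n_basis : int
        Marginal B-spline basis size (tensor has ``n_basis**2`` functions).
    lambdas : array-like
        Smoothing-parameter grid searched by AIC.
    max_iter, tol : IRLS controls.
    """

    n_basis: int = 8
    lambdas: np.ndarray = field(default_factory=lambda: np.logspace(-2.0, 6.0, 9))
    max_iter: int = 50
    tol: float = 1e-8

    def fit(self, coords: np.ndarray, X_par: np.ndarray | None, y: np.ndarray) -> "SplineLogisticGAM":
        coords = np.asarray(coords, float)
        y = np.asarray(y, float)
        n = y.shape[0]
        self.basis_ = _TensorBasis(coords[:, 0], coords[:, 1], self.n_basis)
        B = self.basis_.design(coords[:, 0], coords[:, 1])
        self.smooth_center_ = B.mean(axis=0)
        Bc = B - self.smooth_center_
        X_par = np.empty((n, 0)) if X_par is None else np.asarray(X_par, float)
        X = np.column_stack([np.ones(n), X_par, Bc])
        p_par = 1 + X_par.shape[1]
        p_sm = Bc.shape[1]
        S = np.zeros((X.shape[1], X.shape[1]))
        S[p_par:, p_par:] = self.basis_.penalty
        # tiny ridge on the smooth block: the centered basis still spans the
        # constant direction, which both the design and the difference
        # penalty annihilate
        ridge = np.zeros_like(S)
        ridge[p_par:, p_par:] = 1e-7 * np.eye(p_sm)

        best = None
        for lam in np.atleast_1d(self.lambdas):
            fitres = self._pirls(X, y, lam * S + ridge)
            if fitres is None:
                continue
            beta, mu, w, edf, edf_by_col = fitres
            dev = _binom_deviance(y, mu)
            aic = dev + 2.0 * edf
            if best is None or aic < best[0]:
                best = (aic, lam, beta, mu, w, edf, edf_by_col, dev)
        if best is None:
            raise RuntimeError("logistic GAM failed to converge for every smoothing parameter")
        self.aic_, self.lambda_, self.coef_, self.mu_, w, self.edf_, edf_by_col, self.deviance_ = best
        self.edf_smooth_ = float(edf_by_col[p_par:].sum())
        self.p_par_ = p_par
        # Bayesian posterior covariance of the selected penalized fit
        XtWX = X.T @ (w[:, None] * X)
        A = XtWX + self.lambda_ * S + ridge
        self.cov_ = np.linalg.solve(A, np.eye(A.shape[0]))
        self.X_ = X
        self.y_ = y
        self.coords_ = coords
        self.eta_ = X @ self.coef_
        self.null_deviance_ = self._null_deviance(X[:, :p_par], y)
        self.smooth_chi2_ = max(self.null_deviance_ - self.deviance_, 0.0)
        self.smooth_p_ = float(stats.chi2.sf(self.smooth_chi2_, max(self.edf_smooth_, 1.0)))
        return self

    def _pirls(self, X, y, P):
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
        dev_old = np.inf
        for _ in range(self.max_iter):
            eta = X @ beta
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            XtW = X.T * w
            A = XtW @ X + P
            try:
                beta = np.linalg.solve(A, XtW @ z)
            except np.linalg.LinAlgError:
                return None
            mu = _sigmoid(X @ beta)
            dev = _binom_deviance(y, mu)
            if abs(dev - dev_old) < self.tol * (abs(dev) + 0.1):
                break
            dev_old = dev
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = X.T @ (w[:, None] * X)
        F = np.linalg.solve(XtWX + P, XtWX)
        return beta, mu, w, float(np.trace(F)), np.diag(F)

    @staticmethod
    def _null_deviance(X_par, y):
        """Deviance of the parametric-only logistic fit (no smooth)."""
        gam = SplineLogisticGAM.__new__(SplineLogisticGAM)
        gam.max_iter, gam.tol = 50, 1e-8
        res = gam._pirls(X_par, y, np.zeros((X_par.shape[1],) * 2))
        if res is None:  # pragma: no cover - defensive
            return _binom_deviance(y, np.full_like(y, y.mean(), dtype=float))
        _, mu, *_ = res
        return _binom_deviance(y, mu)

    # -- prediction -----------------------------------------------------

    def smooth_at(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Centered smooth (log-odds contrast vs the sample average) and SE."""
        Bc = self.basis_.design(x, y) - self.smooth_center_
        C = np.zeros((len(Bc), self.coef_.shape[0]))
        C[:, self.p_par_:] = Bc
        s = C @ self.coef_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, self.cov_, C), 0.0))
        return s, se

    def parametric_table(self) -> np.ndarray:
        """(coef, se) rows for intercept + parametric columns."""
        se = np.sqrt(np.diag(self.cov_)[: self.p_par_])
        return np.column_stack([self.coef_[: self.p_par_], se])


class _Loess2D:
    """Bivariate local-linear smoother with tricube distance weights."""

    def __init__(self, coords: np.ndarray, span: float):
        self.coords = np.asarray(coords, float)
        sd = self.coords.std(axis=0)
        sd[sd == 0] = 1.0
        self.scaled = self.coords / sd
        self.sd = sd
        self.span = span
        self.q = max(int(np.ceil(span * len(self.coords))), 4)

    def hat_row(self, pt: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Equivalent-kernel row l such that s(pt) = l @ z."""
        d = np.linalg.norm(self.scaled - pt / self.sd, axis=1)
        idx = np.argpartition(d, self.q - 1)[: self.q]
        dmax = d[idx].max()
        tw = (1 - (d[idx] / max(dmax, 1e-12)) ** 3) ** 3
        ww = tw * w[idx]
        A = np.column_stack([
            np.ones(self.q),
            self.coords[idx, 0] - pt[0],
            self.coords[idx, 1] - pt[1],
        ])
        AtW = A.T * ww
        M = AtW @ A + 1e-10 * np.eye(3)
        coef_rows = np.linalg.solve(M, AtW)  # (3, q)
        row = np.zeros(len(self.coords))
        row[idx] = coef_rows[0]
        return row

    def smooth(self, z: np.ndarray, w: np.ndarray, eval_pts: np.ndarray | None = None):
        pts = self.coords if eval_pts is None else np.asarray(eval_pts, float)
        out = np.empty(len(pts))
        diag = np.empty(len(pts))
        rows = np.empty((len(pts), len(self.coords)))
        for i, pt in enumerate(pts):
            row = self.hat_row(pt, w)
            rows[i] = row
            out[i] = row @ z
            diag[i] = row[i] if eval_pts is None else 0.0
        return out, rows, diag


@dataclass
class LoessLogisticGAM:
    """Local-scoring logistic GAM with a bivariate loess smooth.

    ``span`` may be a single value or a grid; a grid is searched by AIC.
    """

    span: float | tuple = (0.2, 0.3, 0.5, 0.7)
    max_iter: int = 20
    backfit_iter: int = 3
    tol: float = 1e-6

    def fit(self, coords: np.ndarray, X_par: np.ndarray | None, y: np.ndarray) -> "LoessLogisticGAM":
        coords = np.asarray(coords, float)
        y = np.asarray(y, float)
        n = len(y)
        X_par = np.empty((n, 0)) if X_par is None else np.asarray(X_par, float)
        Xp = np.column_stack([np.ones(n), X_par])
        spans = np.atleast_1d(np.asarray(self.span, float))
        best = None
        for sp in spans:
            res = self._local_scoring(coords, Xp, y, float(sp))
            if res is None:
                continue
            aic = res["deviance"] + 2.0 * res["edf"]
            if best is None or aic < best["aic"]:
                best = {**res, "aic": aic, "span": float(sp)}
        if best is None:
            raise RuntimeError("loess logistic GAM failed to converge for every span")
        for k, v in best.items():
            setattr(self, f"{k}_", v)
        self.coords_, self.y_ = coords, y
        self.p_par_ = Xp.shape[1]
        self.null_deviance_ = SplineLogisticGAM._null_deviance(Xp, y)
        self.smooth_chi2_ = max(self.null_deviance_ - self.deviance_, 0.0)
        self.smooth_p_ = float(stats.chi2.sf(self.smooth_chi2_, max(self.edf_ - Xp.shape[1], 1.0)))
        return self

    def _local_scoring(self, coords, Xp, y, span):
        n = len(y)
        loess = _Loess2D(coords, span)
        s = np.zeros(n)
        gamma = np.zeros(Xp.shape[1])
        gamma[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
        dev_old = np.inf
        for _ in range(self.max_iter):
            eta = Xp @ gamma + s
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            for _ in range(self.backfit_iter):
                # parametric step on the partial residual
                r = z - s
                XtW = Xp.T * w
                gamma = np.linalg.solve(XtW @ Xp + 1e-10 * np.eye(Xp.shape[1]), XtW @ r)
                # smooth step on the other partial residual, centered
                r = z - Xp @ gamma
                s, _, diag = loess.smooth(r, w)
                s = s - np.average(s, weights=w)
            mu = _sigmoid(Xp @ gamma + s)
            dev = _binom_deviance(y, mu)
            if abs(dev - dev_old) < self.tol * (abs(dev) + 0.1):
                break
            dev_old = dev
        edf = float(diag.sum()) + Xp.shape[1]
        self._final = {"loess": loess, "w": w, "z": z, "gamma": gamma, "s": s, "Xp": Xp}
        return {
            "deviance": dev,
            "edf": edf,
            "mu": mu,
            "s": s,
            "gamma": gamma,
            "w": w,
            "z": z,
            "loess": loess,
        }

    def smooth_at(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Smooth contrast and approximate SE at arbitrary points.

        SEs use the loess equivalent-kernel rows against the working
        variances 1/w; cross-covariance with the parametric coefficients is
        neglected.
        """
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        loess, w = self.loess_, self.w_
        # partial residual the final smooth was fit to
        r = self.z_ - self._final["Xp"] @ self.gamma_
        s, rows, _ = loess.smooth(r, w, eval_pts=pts)
        s = s - np.average(loess.smooth(r, w)[0], weights=w)
        se = np.sqrt(np.maximum((rows**2 / w[None, :]).sum(axis=1), 0.0))
        return s, se

    def parametric_table(self) -> np.ndarray:
        """(coef, se) rows for intercept + parametric columns (approximate)."""
        Xp, w = self._final["Xp"], self.w_
        cov = np.linalg.inv(Xp.T @ (w[:, None] * Xp) + 1e-10 * np.eye(Xp.shape[1]))
        return np.column_stack([self.gamma_, np.sqrt(np.diag(cov))])
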