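"""GBLUP: mixed-model genomic prediction with REML variance components.

Model: y = 1*mu + Z u + e with u ~ N(0, U sigma_g^2) for a relationship
matrix U and e ~ N(0, I sigma_e^2).  The variance ratio
lambda = sigma_e^2 / sigma_g^2 is profiled out of the restricted likelihood
via a single eigendecomposition of the training-set relationship matrix, so
the REML fit reduces to a one-dimensional maximization over lambda
(log-grid bracketing followed by bounded refinement).  Genetic values of
unphenotyped individuals follow from relationship propagation,
u_hat = U[:, train] (U_tt + lambda I)^{-1} (y - 1 mu_hat).

When U is an inner-product kernel X X' / c of a marker dosage matrix, these
predictions coincide with ridge-regression marker BLUPs (RR-BLUP) — a
classical identity that serves as an independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .hapgrm import GRM

__all__ = ["GBLUP", "GBLUPFit", "reml_fit", "predict", "prediction_accuracy"]


class GBLUP(BaseEstimator, RegressorMixin):
    """GBLUP regressor over a precomputed relationship kernel.

    ``fit(K, y)`` takes the training-set block of the relationship matrix
    (n_train x n_train) and the training phenotypes; ``predict(K_cross)``
    takes the relationship of new individuals to the training set
    (n_new x n_train) and returns predicted phenotypic values
    ``mu_ + u_hat`` (the genetic deviations are ``predict(...) - mu_``).

    Parameters
    ----------
    lambda_bounds : bracket for the variance ratio sigma_e^2 / sigma_g^2.
    n_grid : points of the coarse log-spaced lambda grid.
    tol : relative tolerance of the bounded refinement in log-lambda.
    jitter : relative diagonal jitter applied when the kernel's smallest
        eigenvalue is barely negative (numerical PSD repair).
    """

    def __init__(
        self,
        lambda_bounds: tuple = (1e-6, 1e6),
        n_grid: int = 121,
        tol: float = 1e-8,
        jitter: float = 1e-8,
    ):
        self.lambda_bounds = lambda_bounds
        self.n_grid = n_grid
        self.tol = tol
        self.jitter = jitter

    # -- restricted log-likelihood profiled over mu and sigma_g^2 -------
    @staticmethod
    def _reml_ll(log_lam, d, o, t):
        lam = np.exp(log_lam)
        w = 1.0 / (d + lam)
        oo = np.sum(o * o * w)
        mu = np.sum(o * t * w) / oo
        r = t - mu * o
        n = len(d)
        sg2 = np.sum(r * r * w) / (n - 1)
        if sg2 <= 0:
            return -np.inf, mu, sg2
        ll = -0.5 * ((n - 1) * np.log(sg2) + np.sum(np.log(d + lam)) + np.log(oo) + (n - 1))
        return ll, mu, sg2

    def fit(self, K, y):
        K = np.asarray(K, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = len(y)
        if K.shape != (n, n):
            raise ValueError("K must be square and match y")
        if n < 10:
            raise ValueError("need at least 10 training individuals")
        if np.var(y) == 0:
            raise ValueError("degenerate phenotype vector (zero variance)")
        K = 0.5 * (K + K.T)
        d, Q = np.linalg.eigh(K)
        scale = np.trace(K) / n
        if d[0] < -self.jitter * max(scale, 1e-12):
            raise ValueError("relationship matrix is not PSD beyond jitter tolerance")
        if d[0] < 0:
            d = d - d[0] + self.jitter * scale
        t = Q.T @ y
        o = Q.T @ np.ones(n)

        lo, hi = np.log(self.lambda_bounds[0]), np.log(self.lambda_bounds[1])
        grid = np.linspace(lo, hi, self.n_grid)
        lls = np.array([self._reml_ll(g, d, o, t)[0] for g in grid])
        k = int(np.argmax(lls))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda g: -self._reml_ll(g, d, o, t)[0],
            bounds=(a, b),
            method="bounded",
            options={"xatol": self.tol},
        )
        log_lam = res.x if -res.fun >= lls[k] else grid[k]
        ll, mu, sg2 = self._reml_ll(log_lam, d, o, t)

        self.lambda_ = float(np.exp(log_lam))
        self.mu_ = float(mu)
        self.sigma_g2_ = float(sg2)
        self.sigma_e2_ = float(sg2 * self.lambda_)
        self.loglik_ = float(ll)
        w = 1.0 / (d + self.lambda_)
        self.alpha_ = Q @ (w * (t - mu * o))  # (K + lambda I)^{-1} (y - 1 mu)
        self.n_features_in_ = n
        return self

    def predict(self, K_cross):
        K_cross = np.atleast_2d(np.asarray(K_cross, dtype=np.float64))
        if K_cross.shape[1] != len(self.alpha_):
            raise ValueError("K_cross must have one column per training individual")
        return self.mu_ + K_cross @ self.alpha_

    def genetic_values(self, K_cross):
        """BLUPs of the genetic deviations u for rows of ``K_cross``."""
        return self.predict(K_cross) - self.mu_


@dataclass
class GBLUPFit:
    """REML fit summary plus BLUPs for every individual covered by U."""

    mu: float
    sigma_g2: float
    sigma_e2: float
    lam: float
    loglik: float
    u_hat: pd.Series  # indexed by individual id, all individuals in U
    train_ids: np.ndarray


def reml_fit(y_train, U: GRM, train_ids) -> GBLUPFit:
    """Fit GBLUP on the training subset of ``U`` and propagate BLUPs to all ids."""
    train_ids = np.asarray(train_ids)
    y_train = np.asarray(y_train, dtype=np.float64)
    if len(y_train) != len(train_ids):
        raise ValueError("one phenotype per training id required")
    pos = {ind: i for i, ind in enumerate(U.ids)}
    missing = [i for i in train_ids if i not in pos]
    if missing:
        raise ValueError(f"training ids not in U: {missing[:5]}")
    tr = np.array([pos[i] for i in train_ids])
    est = GBLUP().fit(U.values[np.ix_(tr, tr)], y_train)
    u_all = U.values[:, tr] @ est.alpha_
    return GBLUPFit(
        mu=est.mu_,
        sigma_g2=est.sigma_g2_,
        sigma_e2=est.sigma_e2_,
        lam=est.lambda_,
        loglik=est.loglik_,
        u_hat=pd.Series(u_all, index=U.ids),
        train_ids=train_ids,
    )


def predict(fit: GBLUPFit, predict_ids) -> pd.Series:
    """BLUP genetic values for unphenotyped individuals."""
    predict_ids = np.asarray(predict_ids)
    unknown = [i for i in predict_ids if i not in fit.u_hat.index]
    if unknown:
        raise ValueError(f"ids not covered by the fit: {unknown[:5]}")
    overlap = set(predict_ids) & set(fit.train_ids)
    if overlap:
        raise ValueError(f"prediction ids overlap the training set: {sorted(overlap)[:5]}")
    return fit.u_hat.loc[predict_ids]


def prediction_accuracy(predicted, observed, h2: float) -> float:
    """r(predicted, observed) / sqrt(h2) — correlation rescaled by heritability."""
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if len(predicted) != len(observed) or len(predicted) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        raise ValueError("accuracy undefined for a constant vector")
    r = stats.pearsonr(predicted, observed).statistic
    return float(r / np.sqrt(h2))
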