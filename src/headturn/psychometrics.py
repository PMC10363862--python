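"""Rationalized arcsine transform and the random-intercept logistic psychometric fit.

Word scores (counts correct out of 24 per cell) are variance-stabilized with
Studebaker's rationalized arcsine units (RAU).  The psychometric function
mapping model-predicted benefit (dB) to the probability of a correct word is a
logistic with a per-participant random intercept,

    logit p_ij = beta0 + beta1 * x_ij + u_j,    u_j ~ N(0, sigma_u^2),

fit by maximum likelihood with the random effect integrated out by
Gauss–Hermite quadrature.  The reported "slope per dB" is the maximum slope of
the psychometric function in proportion units, beta1 / 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "ScoreCell",
    "PsychFit",
    "PsychometricModel",
    "rau",
    "fit_glre",
    "predict_score",
    "rau_error_to_db",
]


def rau(n_correct, n_total) -> np.ndarray | float:
    """Studebaker's rationalized arcsine units from counts.

    theta = asin(sqrt(x/(n+1))) + asin(sqrt((x+1)/(n+1))); RAU = (146/pi) theta - 23.
    Midpoint counts give exactly 50; the scale is approximately percent in the
    midrange while remaining linear near the extremes.
    """
    x = np.asarray(n_correct, float)
    n = np.asarray(n_total, float)
    if np.any(x < 0) or np.any(x > n) or np.any(n < 1):
        raise ValueError("need 0 <= n_correct <= n_total, n_total >= 1")
    theta = np.arcsin(np.sqrt(x / (n + 1.0))) + np.arcsin(np.sqrt((x + 1.0) / (n + 1.0)))
    out = (146.0 / np.pi) * theta - 23.0
    return float(out) if np.isscalar(n_correct) and np.isscalar(n_total) else out


def rau_error_to_db(error_rau: float, slope_per_db: float) -> float:
    """Convert a RAU-scale error to dB via the psychometric slope.

    RAU is percent-like in midrange, so an error of e RAU corresponds to
    e / (100 * slope) dB for a maximum slope expressed in proportion per dB.
    """
    if slope_per_db <= 0:
        raise ValueError("slope must be positive")
    return error_rau / (100.0 * slope_per_db)


@dataclass
class ScoreCell:
    """One participant's score in one design cell (24 answers by default)."""

    participant: int | str
    condition: str
    target_deg: float
    word_position: int
    n_correct: int
    n_total: int = 24

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_total):
            raise ValueError("n_correct must be within [0, n_total]")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_correct / self.n_total

    @property
    def rau(self) -> float:
        return rau(self.n_correct, self.n_total)


@dataclass
class PsychFit:
    """Fitted random-intercept logistic psychometric function."""

    beta0: float
    beta1: float
    sigma_u: float
    ranef: dict = field(default_factory=dict)  # participant -> u_j (posterior mode)
    loglik: float = np.nan
    n_obs: int = 0

    @property
    def slope_per_db(self) -> float:
        """Maximum slope of the psychometric function, proportion per dB."""
        return self.beta1 / 4.0

    @property
    def midpoint_db(self) -> float:
        return -self.beta0 / self.beta1


class PsychometricModel:
    """sklearn-style estimator for the random-intercept logistic fit.

    Parameters
    ----------
    n_quad : number of Gauss–Hermite nodes for integrating the random intercept.
    """

    def __init__(self, n_quad: int = 40) -> None:
        self.n_quad = n_quad

    def get_params(self, deep: bool = True) -> dict:
        return {"n_quad": self.n_quad}

    def set_params(self, **params) -> "PsychometricModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _group_loglik(beta0, beta1, sigma, x, y, n, groups, nodes, weights):
        """Marginal log-likelihood, summed over participants."""
        total = 0.0
        for g in np.unique(groups):
            m = groups == g
            eta = beta0 + beta1 * x[m]  # (cells,)
            u = np.sqrt(2.0) * sigma * nodes  # (q,)
            lin = eta[None, :] + u[:, None]
            # binomial log-pmf without the constant binomial coefficient
            ll = y[m][None, :] * lin - n[m][None, :] * np.logaddexp(0.0, lin)
            per_node = ll.sum(axis=1)
            mx = per_node.max()
            total += mx + np.log(np.sum(weights * np.exp(per_node - mx)) / np.sqrt(np.pi))
        return total

    def fit(self, X, y, n, groups) -> "PsychometricModel":
        """Fit on per-cell binomial counts.

        X : predicted benefit in dB per cell; y : correct counts; n : totals;
        groups : participant label per cell.
        """
        x = np.asarray(X, float).ravel()
        y = np.asarray(y, float).ravel()
        n = np.asarray(n, float).ravel()
        groups = np.asarray(groups)
        if not (x.size == y.size == n.size == groups.size):
            raise ValueError("X, y, n, groups must have equal length")
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct predicted-dB values")
        if np.unique(groups).size < 2:
            raise ValueError("need at least 2 participants")
        if np.all(y == 0) or np.all(y == n):
            raise ValueError("complete separation: all responses identical")

        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)

        # moment start from pooled empirical logits
        p_emp = np.clip((y + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
        b1_0, b0_0 = np.polyfit(x, logit(p_emp), 1)
        theta0 = np.array([b0_0, max(b1_0, 1e-3), np.log(0.3)])

        def nll(theta):
            b0, b1, log_s = theta
            return -self._group_loglik(
                b0, b1, np.exp(log_s), x, y, n, groups, nodes, weights
            )

        # Nelder-Mead with a restart, plus a quasi-Newton polish; simplex
        # searches on this 3-parameter surface occasionally stall, so keep
        # the best of all attempts.
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        best = res
        for start in (res.x, theta0):
            for method in ("Nelder-Mead", "L-BFGS-B"):
                r = optimize.minimize(nll, start, method=method)
                if np.isfinite(r.fun) and r.fun < best.fun:
                    best = r
        if not np.isfinite(best.fun):
            raise RuntimeError("GLMM fit did not converge")
        b0, b1, log_s = best.x
        res = best
        sigma = float(np.exp(log_s))

        self.beta0_, self.beta1_, self.sigma_u_ = float(b0), float(b1), sigma
        self.loglik_ = -float(res.fun)
        self.ranef_ = {}
        for g in np.unique(groups):
            m = groups == g
            self.ranef_[g] = self._posterior_mode(b0, b1, sigma, x[m], y[m], n[m])
        self.n_obs_ = x.size
        return self

    @staticmethod
    def _posterior_mode(b0, b1, sigma, x, y, n, n_iter: int = 50) -> float:
        """Newton iteration for the mode of p(u | data) of one participant."""
        if sigma < 1e-8:
            return 0.0
        u = 0.0
        for _ in range(n_iter):
            p = expit(b0 + b1 * x + u)
            grad = np.sum(y - n * p) - u / sigma**2
            hess = -np.sum(n * p * (1 - p)) - 1.0 / sigma**2
            step = grad / hess
            u -= step
            if abs(step) < 1e-10:
                break
        return float(u)

    def predict(self, X, groups=None) -> np.ndarray:
        """Probability of a correct word at predicted benefit X (dB)."""
        x = np.asarray(X, float)
        u = np.zeros_like(x, dtype=float)
        if groups is not None:
            u = np.array([self.ranef_.get(g, 0.0) for g in np.asarray(groups).ravel()])
            u = u.reshape(x.shape)
        return expit(self.beta0_ + self.beta1_ * x + u)

    @property
    def fit_result_(self) -> PsychFit:
        return PsychFit(self.beta0_, self.beta1_, self.sigma_u_,
                        dict(self.ranef_), self.loglik_, self.n_obs_)


def fit_glre(cells: list[ScoreCell] | pd.DataFrame, predicted_db: dict) -> PsychFit:
    """Fit the psychometric GLMM on Static-condition score cells.

    ``predicted_db`` maps target azimuth (deg) to the model-predicted benefit
    for that location.  Returns the fitted fixed effects, random-intercept SD
    and per-participant intercepts.
    """
    if isinstance(cells, pd.DataFrame):
        df = cells
    else:
        df = pd.DataFrame(
            {
                "participant": [c.participant for c in cells],
                "target_deg": [c.target_deg for c in cells],
                "n_correct": [c.n_correct for c in cells],
                "n_total": [c.n_total for c in cells],
            }
        )
    x = df["target_deg"].map(lambda t: predicted_db[float(t)]).to_numpy(float)
    model = PsychometricModel().fit(
        x, df["n_correct"].to_numpy(float), df["n_total"].to_numpy(float),
        df["participant"].to_numpy(),
    )
    return model.fit_result_


def predict_score(
    fit: PsychFit, benefit_db, participant=None, n_total: int = 24
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Predicted proportion correct and RAU at a model benefit (dB).

    An unknown participant falls back to the population curve (u = 0).  The
    RAU value is that of the implied expected count on ``n_total`` answers.
    """
    u = 0.0
    if participant is not None:
        u = fit.ranef.get(participant, 0.0)
    p = expit(fit.beta0 + fit.beta1 * np.asarray(benefit_db, float) + u)
    r = rau(p * n_total, np.full_like(np.asarray(p, float), n_total))
    if np.isscalar(benefit_db):
        return float(p), float(r)
    return p, r
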