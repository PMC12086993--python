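"""Hyperbolic yield-density competition models fitted by log-scale NLS.

Two regression models, both fitted by nonlinear least squares on the
natural-log biomass scale:

* monoculture:  ln w = ln wm - b * ln(1 + a * N)
* biculture:    ln w = ln wm - b * ln(1 + beta * N_self + alpha * N_other)

with ``N`` the realized total density at harvest (the focal plant included).
In the biculture model the exponent ``b`` is *not* re-estimated: each focal
species carries the ``b`` from its own monoculture fit, so the biculture
stage estimates only (wm, beta, alpha).

Internally the free parameters are estimated on the log scale (ln wm, ln a,
ln b; respectively ln wm, ln beta, ln alpha), which enforces positivity
without bound constraints.  Estimates are reported on the natural scale with
delta-method standard errors; Wald t-statistics use a Student-t reference
with n - 3 degrees of freedom.

The estimators follow the scikit-learn API (``fit`` / ``predict`` /
``get_params``); :func:`fit_monoculture` and :func:`fit_biculture` wrap them
into frozen result records for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge or the design is degenerate."""


def predict_monoculture(wm: float, a: float, b: float, N) -> np.ndarray | float:
    """Mean per-plant biomass ``wm * (1 + a*N)**(-b)`` at density ``N``."""
    N = np.asarray(N, dtype=float)
    if wm <= 0:
        raise ValueError("wm must be > 0")
    if a < 0 or b < 0:
        raise ValueError("a and b must be >= 0")
    if np.any(N < 0):
        raise ValueError("density must be >= 0")
    out = wm * (1.0 + a * N) ** (-b)
    return out if out.ndim else float(out)


def predict_biculture(
    wm: float, beta: float, alpha: float, b: float, n_self, n_other
) -> np.ndarray | float:
    """Mean per-plant biomass ``wm * (1 + beta*N_self + alpha*N_other)**(-b)``."""
    n_self = np.asarray(n_self, dtype=float)
    n_other = np.asarray(n_other, dtype=float)
    if wm <= 0:
        raise ValueError("wm must be > 0")
    if beta < 0 or alpha < 0 or b < 0:
        raise ValueError("beta, alpha and b must be >= 0")
    if np.any(n_self < 0) or np.any(n_other < 0):
        raise ValueError("densities must be >= 0")
    out = wm * (1.0 + beta * n_self + alpha * n_other) ** (-b)
    return out if out.ndim else float(out)


def pseudo_r2(observed_log, fitted_log) -> float:
    """1 - SSE/SST on the natural-log scale; NaN when SST is zero."""
    obs = np.asarray(observed_log, dtype=float)
    fit = np.asarray(fitted_log, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        return float("nan")
    sse = float(np.sum((obs - fit) ** 2))
    return 1.0 - sse / sst


#: box bound on the internal log-scale parameters; e**30 ~ 1e13 covers any
#: biologically meaningful coefficient while keeping the optimizer finite
_THETA_BOUND = 30.0


def _nls_log_scale(residual, jacobian, theta0, rng, max_restarts, max_nfev, tol):
    """Least-squares polish with jittered restarts on the internal log scale."""
    theta = np.clip(np.asarray(theta0, dtype=float), -_THETA_BOUND, _THETA_BOUND)
    best = None
    for attempt in range(max_restarts + 1):
        start = theta if attempt == 0 else np.clip(
            theta + rng.normal(0.0, 0.5, theta.size), -_THETA_BOUND, _THETA_BOUND
        )
        res = optimize.least_squares(
            residual,
            start,
            jac=jacobian,
            method="trf",
            bounds=(-_THETA_BOUND, _THETA_BOUND),
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_nfev,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
            break
    if best is None:
        raise FitError("nonlinear least squares did not converge after restarts")
    return best


def _covariance(jac: np.ndarray, sse: float, n: int, p: int) -> np.ndarray:
    """Residual-variance-scaled covariance (J'J)^-1 * s2 at the optimum.

    A coefficient whose estimate collapses toward zero has a vanishing
    Jacobian column on the internal log scale; its variance then blows up,
    which is the honest answer (the data carry no information about it).
    Only an exactly singular Jacobian raises.
    """
    _, sv, vt = np.linalg.svd(jac, full_matrices=False)
    if sv[-1] == 0.0:
        raise FitError("singular Jacobian: parameters not identifiable")
    s2 = sse / max(n - p, 1)
    # (J'J)^-1 = V S^-2 V' — positive semidefinite by construction even when
    # the fit sits on a weakly identified ridge (huge variances, not garbage)
    return s2 * (vt.T * sv**-2.0) @ vt


class MonocultureYieldDensity(RegressorMixin, BaseEstimator):
    """Monoculture yield-density regressor ``w = wm * (1 + a*N)**(-b)``.

    Fitting minimises squared error on ln(w).  ``X`` is the realized density
    at harvest, shape ``(n, 1)`` or ``(n,)``; ``y`` is per-plant biomass in
    grams (strictly positive).

    Attributes (after ``fit``)
    --------------------------
    wm_, a_, b_ : float
        Natural-scale estimates.
    se_wm_, se_a_, se_b_ : float
        Delta-method standard errors.
    covariance_ : ndarray, shape (3, 3)
        Covariance of (ln wm, ln a, ln b) at the optimum.
    pseudo_r2_, sse_, n_ : float, float, int
        Log-scale goodness of fit.
    """

    _param_names = ("wm", "a", "b")

    def __init__(
        self,
        max_restarts: int = 10,
        tol: float = 1e-14,
        max_nfev: int = 10_000,
        random_state: int = 0,
    ):
        self.max_restarts = max_restarts
        self.tol = tol
        self.max_nfev = max_nfev
        self.random_state = random_state

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != self._n_density_cols:
                raise ValueError(f"X must have {self._n_density_cols} column(s)")
        elif X.ndim == 1 and self._n_density_cols == 1:
            X = X[:, None]
        else:
            raise ValueError("X has wrong shape")
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(y) != len(X):
            raise ValueError("y must be 1-d and match X")
        if np.any(y <= 0):
            raise ValueError("biomass must be > 0")
        if np.any(X < 0):
            raise ValueError("densities must be >= 0")
        return X, y

    _n_density_cols = 1

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        N = X[:, 0]
        if len(np.unique(N)) < 3:
            raise FitError("need >= 3 distinct density levels")
        if len(y) <= 3:
            raise FitError("need n > 3 observations")
        ly = np.log(y)

        def residual(t):
            return ly - (t[0] - np.exp(t[2]) * np.log1p(np.exp(t[1]) * N))

        def jacobian(t):
            a, b = np.exp(t[1]), np.exp(t[2])
            denom = 1.0 + a * N
            j = np.empty((len(N), 3))
            j[:, 0] = -1.0
            j[:, 1] = b * a * N / denom
            j[:, 2] = b * np.log1p(a * N)
            return j

        wm0 = float(np.mean(y[N == N.min()]))
        theta0 = np.log([wm0, 1.0, 1.0])
        rng = np.random.default_rng(self.random_state)
        res = _nls_log_scale(
            residual, jacobian, theta0, rng, self.max_restarts, self.max_nfev, self.tol
        )
        self._finalize(res, ly, n_params=3)
        self.wm_, self.a_, self.b_ = np.exp(res.x)
        se = np.sqrt(np.diag(self.covariance_))
        self.se_wm_, self.se_a_, self.se_b_ = np.exp(res.x) * se
        return self

    def _finalize(self, res, ly, n_params):
        self.theta_ = res.x
        self.n_ = len(ly)
        self.sse_ = float(2.0 * res.cost)
        self.covariance_ = _covariance(res.jac, self.sse_, self.n_, n_params)
        self.pseudo_r2_ = pseudo_r2(ly, ly - res.fun)
        self.df_resid_ = self.n_ - n_params
        self.n_features_in_ = self._n_density_cols

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return predict_monoculture(self.wm_, self.a_, self.b_, X[:, 0])

    def confint(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Log-scale Wald intervals, back-transformed to the natural scale."""
        check_is_fitted(self)
        crit = stats.t.ppf(0.5 + level / 2, self.df_resid_)
        se = np.sqrt(np.diag(self.covariance_))
        with np.errstate(over="ignore"):  # an unidentified parameter -> (0, inf)
            lo = np.exp(self.theta_ - crit * se)
            hi = np.exp(self.theta_ + crit * se)
        return {p: (lo[i], hi[i]) for i, p in enumerate(self._param_names)}


class BicultureCompetition(MonocultureYieldDensity):
    """Biculture competition regressor with the decay exponent held fixed.

    Model: ``w = wm * (1 + beta*N_self + alpha*N_other)**(-b)`` with ``b``
    supplied from the focal species' monoculture fit.  ``X`` has two columns,
    ``[N_self, N_other]`` (realized densities at harvest); ``y`` is biomass
    in grams.  Estimates (wm, beta, alpha) with Wald t and two-sided p for
    the two competition coefficients (df = n - 3).
    """

    _param_names = ("wm", "beta", "alpha")
    _n_density_cols = 2

    def __init__(
        self,
        b: float = 1.0,
        max_restarts: int = 10,
        tol: float = 1e-14,
        max_nfev: int = 10_000,
        random_state: int = 0,
    ):
        super().__init__(
            max_restarts=max_restarts,
            tol=tol,
            max_nfev=max_nfev,
            random_state=random_state,
        )
        self.b = b

    def fit(self, X, y):
        if self.b <= 0:
            raise ValueError("fixed exponent b must be > 0")
        X, y = self._validate_xy(X, y)
        ns, no = X[:, 0], X[:, 1]
        if np.all(no == 0):
            raise FitError(
                "all records have zero density of the other species: "
                "alpha is not identifiable"
            )
        if len(y) <= 3:
            raise FitError("need n > 3 observations")
        ly = np.log(y)
        b = self.b

        def residual(t):
            return ly - (t[0] - b * np.log1p(np.exp(t[1]) * ns + np.exp(t[2]) * no))

        def jacobian(t):
            beta, alpha = np.exp(t[1]), np.exp(t[2])
            denom = 1.0 + beta * ns + alpha * no
            j = np.empty((len(y), 3))
            j[:, 0] = -1.0
            j[:, 1] = b * beta * ns / denom
            j[:, 2] = b * alpha * no / denom
            return j

        low = ns + no
        wm0 = float(np.mean(y[low == low.min()]))
        theta0 = np.log([wm0, 1.0, 1.0])
        rng = np.random.default_rng(self.random_state)
        res = _nls_log_scale(
            residual, jacobian, theta0, rng, self.max_restarts, self.max_nfev, self.tol
        )
        self._finalize(res, ly, n_params=3)
        self.wm_, self.beta_, self.alpha_ = np.exp(res.x)
        se = np.sqrt(np.diag(self.covariance_))
        self.se_wm_, self.se_beta_, self.se_alpha_ = np.exp(res.x) * se
        # Wald statistics on the natural scale: t = estimate / SE
        # (a zero SE from an exact fit gives t = inf, p = 0)
        with np.errstate(divide="ignore"):
            self.t_beta_ = np.float64(self.beta_) / self.se_beta_
            self.t_alpha_ = np.float64(self.alpha_) / self.se_alpha_
        self.p_beta_ = 2.0 * stats.t.sf(abs(self.t_beta_), self.df_resid_)
        self.p_alpha_ = 2.0 * stats.t.sf(abs(self.t_alpha_), self.df_resid_)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return predict_biculture(
            self.wm_, self.beta_, self.alpha_, self.b, X[:, 0], X[:, 1]
        )


@dataclass(frozen=True)
class MonocultureFit:
    """Monoculture stage result for one species."""

    species: str
    wm: float
    a: float
    b: float
    se_wm: float
    se_a: float
    se_b: float
    covariance: np.ndarray  # internal (log) scale, 3x3
    theta: np.ndarray  # (ln wm, ln a, ln b)
    pseudo_r2: float
    sse: float
    n: int

    def predict(self, N):
        return predict_monoculture(self.wm, self.a, self.b, N)


@dataclass(frozen=True)
class BicultureFit:
    """Biculture stage result for one focal species (b carried from monoculture)."""

    focal_species: str
    wm: float
    beta: float
    alpha: float
    b_fixed: float
    se_wm: float
    se_beta: float
    se_alpha: float
    t_beta: float
    t_alpha: float
    p_beta: float
    p_alpha: float
    covariance: np.ndarray  # internal (log) scale, 3x3
    theta: np.ndarray  # (ln wm, ln beta, ln alpha)
    pseudo_r2: float
    sse: float
    n: int

    def predict(self, n_self, n_other):
        return predict_biculture(
            self.wm, self.beta, self.alpha, self.b_fixed, n_self, n_other
        )

    def confint(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        crit = stats.t.ppf(0.5 + level / 2, self.n - 3)
        se = np.sqrt(np.diag(self.covariance))
        with np.errstate(over="ignore"):
            lo = np.exp(self.theta - crit * se)
            hi = np.exp(self.theta + crit * se)
        return {p: (lo[i], hi[i]) for i, p in enumerate(("wm", "beta", "alpha"))}


def fit_monoculture(frame: pd.DataFrame, species: str | None = None, **kwargs) -> MonocultureFit:
    """Fit the monoculture model to a modelling frame (one species).

    ``frame`` comes from :func:`addseries.preprocess.prepare_log_response`;
    the covariate is the realized total density ``n_total``.
    """
    if species is not None:
        frame = frame[frame["species"] == species]
    else:
        sp = frame["species"].unique()
        if len(sp) != 1:
            raise ValueError("frame contains multiple species; pass species=")
        species = sp[0]
    est = MonocultureYieldDensity(**kwargs).fit(
        frame[["n_total"]].to_numpy(), np.exp(frame["log_biomass"].to_numpy())
    )
    return MonocultureFit(
        species=species,
        wm=est.wm_, a=est.a_, b=est.b_,
        se_wm=est.se_wm_, se_a=est.se_a_, se_b=est.se_b_,
        covariance=est.covariance_, theta=est.theta_,
        pseudo_r2=est.pseudo_r2_, sse=est.sse_, n=est.n_,
    )


def fit_biculture(
    frame: pd.DataFrame, b_fixed: float, species: str | None = None, **kwargs
) -> BicultureFit:
    """Fit the biculture model for one focal species with ``b`` held fixed.

    Covariates are the realized densities ``n_self`` and ``n_other``.
    """
    if species is not None:
        frame = frame[frame["species"] == species]
    else:
        sp = frame["species"].unique()
        if len(sp) != 1:
            raise ValueError("frame contains multiple species; pass species=")
        species = sp[0]
    est = BicultureCompetition(b=b_fixed, **kwargs).fit(
        frame[["n_self", "n_other"]].to_numpy(),
        np.exp(frame["log_biomass"].to_numpy()),
    )
    return BicultureFit(
        focal_species=species,
        wm=est.wm_, beta=est.beta_, alpha=est.alpha_, b_fixed=b_fixed,
        se_wm=est.se_wm_, se_beta=est.se_beta_, se_alpha=est.se_alpha_,
        t_beta=est.t_beta_, t_alpha=est.t_alpha_,
        p_beta=est.p_beta_, p_alpha=est.p_alpha_,
        covariance=est.covariance_, theta=est.theta_,
        pseudo_r2=est.pseudo_r2_, sse=est.sse_, n=est.n_,
    )


def coefficient_table(fits: list[BicultureFit]) -> pd.DataFrame:
    """Competition-coefficient report: estimate, SE, t, p per coefficient.

    One row per coefficient (beta then alpha) per fit, values rounded to 4
    decimal places as conventionally reported.
    """
    rows = []
    for f in fits:
        rows.append(
            ("beta_" + f.focal_species, f.beta, f.se_beta, f.t_beta, f.p_beta)
        )
        rows.append(
            ("alpha_" + f.focal_species, f.alpha, f.se_alpha, f.t_alpha, f.p_alpha)
        )
    out = pd.DataFrame(
        rows, columns=["parameter", "estimate", "standard_error", "t_value", "p"]
    )
    out[["estimate", "standard_error", "t_value", "p"]] = out[
        ["estimate", "standard_error", "t_value", "p"]
    ].round(4)
    return out
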