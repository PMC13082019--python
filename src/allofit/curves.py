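"""Single-ligand nonlinear models as scikit-learn-style estimators.

Three models, all with Hill slope fixed at 1 (three-parameter forms; a
free-slope logistic variant exists but is off by default):

* :class:`LogisticCurve` — E = Bottom + (Top − Bottom) / (1 + EC50/[A])
* :class:`SaturationBinding` — E = Bmax·[A] / (Kd + [A])
* :class:`CompetitionBinding` — E = Bottom + (Top − Bottom) / (1 + [C]/IC50),
  with the Cheng–Prusoff-type correction IC50 = Ki·(1 + [L]/Kd) relating the
  fitted IC50 to the competitor's inhibition constant via the radioligand
  concentration [L] and its dissociation constant Kd.

Concentration-scale parameters (EC50, Kd, Ki) are estimated on the log10
scale so their back-transforms are strictly positive. Fitting is unweighted
least squares (per-point SEM weights optional) with multi-start
initialization; standard errors come from the local curvature (Gauss–Newton
approximation) of the loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .assay_io import BindingIsotherm, DoseResponseSeries

__all__ = [
    "LogisticParams",
    "SaturationParams",
    "CompetitionParams",
    "FitResult",
    "LogisticCurve",
    "SaturationBinding",
    "CompetitionBinding",
    "logistic3_predict",
    "saturation_predict",
    "competition_predict",
    "fit_logistic3",
    "fit_saturation",
    "fit_competition",
    "NonIdentifiableWarning",
]


class NonIdentifiableWarning(UserWarning):
    """The data do not constrain one or more parameters."""


@dataclass(frozen=True)
class LogisticParams:
    bottom: float  # % units
    top: float  # % units
    log_ec50: float  # log10 molar

    @property
    def ec50(self) -> float:
        return 10.0**self.log_ec50

    @property
    def pec50(self) -> float:
        return -self.log_ec50


@dataclass(frozen=True)
class SaturationParams:
    bmax: float  # signal units
    kd: float  # molar

    @property
    def log_kd(self) -> float:
        return float(np.log10(self.kd))


@dataclass(frozen=True)
class CompetitionParams:
    log_ki: float  # log10 molar
    top: float
    bottom: float
    radioligand_conc: float  # molar
    radioligand_kd: float  # molar

    @property
    def ki(self) -> float:
        return 10.0**self.log_ki

    @property
    def ic50(self) -> float:
        """Cheng–Prusoff-corrected IC50 = Ki·(1 + [L]/Kd)."""
        return self.ki * (1.0 + self.radioligand_conc / self.radioligand_kd)


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``stderr`` carries entries only for free parameters; ``constraints``
    records any fixed ones. A ``converged=False`` result is flagged and
    must not be read as an estimate.
    """

    params: object
    stderr: dict[str, float]
    loss: float  # residual sum of squares
    converged: bool
    constraints: dict[str, float]
    n_points: int
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        p = self.params
        pdict = {k: getattr(p, k) for k in p.__dataclass_fields__} if hasattr(
            p, "__dataclass_fields__"
        ) else dict(p)
        return {
            "params": pdict,
            "stderr": self.stderr,
            "loss": self.loss,
            "converged": self.converged,
            "constraints": self.constraints,
            "n_points": self.n_points,
            "warnings": self.warnings,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def logistic3_predict(p: LogisticParams, conc) -> np.ndarray | float:
    """Three-parameter logistic effect at concentration ``conc`` (molar).

    E(0) = Bottom by continuity. E is strictly increasing in [A] when
    Top > Bottom, with half-maximal effect exactly at [A] = EC50.
    """
    a = np.asarray(conc, dtype=float)
    out = np.where(a > 0, p.bottom + (p.top - p.bottom) / (1.0 + p.ec50 / np.where(a > 0, a, 1.0)), p.bottom)
    return out if out.ndim else float(out)


def saturation_predict(p: SaturationParams, conc) -> np.ndarray | float:
    """One-site specific binding: E = Bmax·[A]/(Kd + [A])."""
    a = np.asarray(conc, dtype=float)
    out = p.bmax * a / (p.kd + a)
    return out if out.ndim else float(out)


def competition_predict(p: CompetitionParams, conc) -> np.ndarray | float:
    """One-site competition binding with the radioligand correction."""
    c = np.asarray(conc, dtype=float)
    ic50 = p.ic50
    out = np.where(
        c > 0,
        p.bottom + (p.top - p.bottom) / (1.0 + np.where(c > 0, c, 1.0) / ic50),
        p.top,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Shared least-squares machinery
# ---------------------------------------------------------------------------


def _multistart_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
    *,
    ftol: float = 1e-12,
    max_nfev: int = 2000,
):
    """Run bounded least squares from several starts; keep the best by loss.

    Ties are broken by the lower Jacobian condition number.
    """
    best = None
    best_key = (np.inf, np.inf)
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                residual, x0, bounds=bounds, ftol=ftol, xtol=1e-12, gtol=1e-12,
                max_nfev=max_nfev, method="trf",
            )
        except Exception:
            continue
        loss = float(2.0 * sol.cost)
        try:
            cond = float(np.linalg.cond(sol.jac))
        except Exception:
            cond = np.inf
        key = (loss, cond)
        if key < best_key:
            best, best_key = sol, key
    return best


def _stderr_from_jac(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    """Asymptotic standard errors from the Gauss–Newton curvature."""
    dof = max(n - p, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("expected a single concentration column")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if np.any(X < 0):
        raise ValueError("negative concentration")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite signal")
    return X, y


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class LogisticCurve(RegressorMixin, BaseEstimator):
    """Three-parameter logistic concentration–response fitter.

    Parameters
    ----------
    n_starts : int
        Multi-start count; starts are quantile-based heuristics over the
        observed response range.
    free_slope : bool
        Fit a Hill slope as a fourth parameter (off by default; the
        three-parameter form fixes it at 1).
    weights : array-like, optional
        Per-point weights (e.g. 1/SEM); default unweighted.
    ftol, max_iter : float, int
        Convergence controls: relative loss tolerance and iteration cap.
    seed : int
        Recorded in the fit report; start generation is deterministic.

    Attributes
    ----------
    bottom_, top_, log_ec50_ : float
        Point estimates; ``pec50_ = -log_ec50_``.
    result_ : FitResult
        Full report (estimates, stderr, loss, convergence, warnings).
    """

    def __init__(self, n_starts=8, free_slope=False, weights=None,
                 ftol=1e-10, max_iter=500, seed=0):
        self.n_starts = n_starts
        self.free_slope = free_slope
        self.weights = weights
        self.ftol = ftol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        a, y = _validate_xy(X, y)
        warn_list: list[str] = []
        nz = a > 0
        uniq = np.unique(a[nz])
        if uniq.size < 4:
            raise ValueError("need >= 4 distinct nonzero concentrations")
        span = np.log10(uniq.max() / uniq.min())
        if span < 2.0:
            warn_list.append(
                f"concentration span {span:.2f} log units is below 2; "
                "EC50 may be poorly constrained"
            )
        if np.ptp(y) == 0.0:
            warn_list.append("all signals identical; fit is non-identifiable")
            warnings.warn(warn_list[-1], NonIdentifiableWarning)
            self.bottom_, self.top_, self.log_ec50_ = float(y[0]), float(y[0]), float(
                np.log10(np.median(uniq))
            )
            self.result_ = FitResult(
                params=LogisticParams(self.bottom_, self.top_, self.log_ec50_),
                stderr={}, loss=0.0, converged=False,
                constraints={} if self.free_slope else {"hill_slope": 1.0},
                n_points=int(y.size), warnings=warn_list, seed=self.seed,
            )
            return self

        w = np.ones_like(y) if self.weights is None else np.asarray(self.weights, float)
        loga = np.where(nz, np.log10(np.where(nz, a, 1.0)), 0.0)

        lo, hi = float(y.min()), float(y.max())
        lg_lo, lg_hi = float(np.log10(uniq.min())), float(np.log10(uniq.max()))

        if self.free_slope:
            def model(theta):
                b, t, lec, h = theta
                e = np.where(nz, b + (t - b) / (1.0 + 10.0 ** (h * (lec - loga))), b)
                return e
            qs = np.linspace(0.15, 0.85, self.n_starts)
            starts = [
                np.array([lo, hi, lg_lo + q * (lg_hi - lg_lo), 1.0]) for q in qs
            ]
            lb = np.array([lo - 10 * (hi - lo) - 1, lo - 10 * (hi - lo) - 1, lg_lo - 6, 0.1])
            ub = np.array([hi + 10 * (hi - lo) + 1, hi + 10 * (hi - lo) + 1, lg_hi + 6, 10.0])
            names = ["bottom", "top", "log_ec50", "hill_slope"]
        else:
            def model(theta):
                b, t, lec = theta
                e = np.where(nz, b + (t - b) / (1.0 + 10.0 ** (lec - loga)), b)
                return e
            qs = np.linspace(0.15, 0.85, self.n_starts)
            starts = [np.array([lo, hi, lg_lo + q * (lg_hi - lg_lo)]) for q in qs]
            lb = np.array([lo - 10 * (hi - lo) - 1, lo - 10 * (hi - lo) - 1, lg_lo - 6])
            ub = np.array([hi + 10 * (hi - lo) + 1, hi + 10 * (hi - lo) + 1, lg_hi + 6])
            names = ["bottom", "top", "log_ec50"]

        sol = _multistart_least_squares(
            lambda th: w * (model(th) - y), starts, (lb, ub),
            ftol=self.ftol, max_nfev=self.max_iter * 4,
        )
        converged = sol is not None and sol.status > 0
        if sol is None:
            raise RuntimeError("all starts failed")
        rss = float(2.0 * sol.cost)
        se = _stderr_from_jac(sol.jac, rss, y.size, sol.x.size)
        self.bottom_, self.top_, self.log_ec50_ = (float(v) for v in sol.x[:3])
        if self.free_slope:
            self.hill_slope_ = float(sol.x[3])
        params = LogisticParams(self.bottom_, self.top_, self.log_ec50_)
        self.result_ = FitResult(
            params=params,
            stderr=dict(zip(names, se.tolist())),
            loss=rss,
            converged=converged,
            constraints={} if self.free_slope else {"hill_slope": 1.0},
            n_points=int(y.size),
            warnings=warn_list,
            seed=self.seed,
        )
        if not converged:
            warnings.warn("logistic fit did not converge", NonIdentifiableWarning)
        return self

    @property
    def pec50_(self) -> float:
        return -self.log_ec50_

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        a = X[:, 0] if X.ndim == 2 else X
        return np.asarray(
            logistic3_predict(
                LogisticParams(self.bottom_, self.top_, self.log_ec50_), a
            )
        )


class SaturationBinding(RegressorMixin, BaseEstimator):
    """One-site specific binding fitter: E = Bmax·[A]/(Kd + [A]).

    Kd is estimated as log10(Kd); fitted attributes are ``bmax_``, ``kd_``,
    ``log_kd_`` plus the full ``result_`` report.
    """

    def __init__(self, n_starts=8, weights=None, ftol=1e-10, max_iter=500, seed=0):
        self.n_starts = n_starts
        self.weights = weights
        self.ftol = ftol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        a, y = _validate_xy(X, y)
        if np.all(y == 0):
            raise ValueError("all-zero signals: degenerate saturation fit")
        uniq = np.unique(a[a > 0])
        if uniq.size < 5:
            raise ValueError("need >= 5 radioligand concentrations")
        w = np.ones_like(y) if self.weights is None else np.asarray(self.weights, float)
        lg_lo, lg_hi = float(np.log10(uniq.min())), float(np.log10(uniq.max()))
        ymax = float(y.max())

        def model(theta):
            bmax, lkd = theta
            kd = 10.0**lkd
            return bmax * a / (kd + a)

        qs = np.linspace(0.1, 0.9, self.n_starts)
        starts = [np.array([ymax, lg_lo + q * (lg_hi - lg_lo)]) for q in qs]
        lb = np.array([1e-12, lg_lo - 6])
        ub = np.array([10 * ymax + 1, lg_hi + 6])
        sol = _multistart_least_squares(
            lambda th: w * (model(th) - y), starts, (lb, ub),
            ftol=self.ftol, max_nfev=self.max_iter * 4,
        )
        if sol is None:
            raise RuntimeError("all starts failed")
        rss = float(2.0 * sol.cost)
        se = _stderr_from_jac(sol.jac, rss, y.size, 2)
        self.bmax_ = float(sol.x[0])
        self.log_kd_ = float(sol.x[1])
        self.kd_ = 10.0**self.log_kd_
        self.result_ = FitResult(
            params=SaturationParams(self.bmax_, self.kd_),
            stderr={"bmax": float(se[0]), "log_kd": float(se[1])},
            loss=rss,
            converged=bool(sol.status > 0),
            constraints={},
            n_points=int(y.size),
            seed=self.seed,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        a = X[:, 0] if X.ndim == 2 else X
        return np.asarray(saturation_predict(SaturationParams(self.bmax_, self.kd_), a))


class CompetitionBinding(RegressorMixin, BaseEstimator):
    """One-site competition binding fitter with the radioligand correction.

    The competitor's inhibition constant Ki is the fitted concentration-scale
    parameter; the observable IC50 follows from IC50 = Ki·(1 + [L]/Kd) using
    the measured radioligand concentration [L] and its dissociation constant
    Kd. Bottom can be floated (default) or fixed (e.g. to nonspecific
    binding) via ``fix_bottom``.
    """

    def __init__(self, radioligand_conc=None, radioligand_kd=None,
                 fix_bottom=None, n_starts=8, weights=None,
                 ftol=1e-10, max_iter=500, seed=0):
        self.radioligand_conc = radioligand_conc
        self.radioligand_kd = radioligand_kd
        self.fix_bottom = fix_bottom
        self.n_starts = n_starts
        self.weights = weights
        self.ftol = ftol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        if self.radioligand_conc is None or self.radioligand_kd is None:
            raise ValueError(
                "competition fitting requires radioligand_conc and radioligand_kd"
            )
        if self.radioligand_conc <= 0 or self.radioligand_kd <= 0:
            raise ValueError("radioligand_conc and radioligand_kd must be > 0")
        c, y = _validate_xy(X, y)
        nz = c > 0
        uniq = np.unique(c[nz])
        if uniq.size < 4:
            raise ValueError("need >= 4 distinct competitor concentrations")
        w = np.ones_like(y) if self.weights is None else np.asarray(self.weights, float)
        logc = np.where(nz, np.log10(np.where(nz, c, 1.0)), 0.0)
        corr = np.log10(1.0 + self.radioligand_conc / self.radioligand_kd)
        lo, hi = float(y.min()), float(y.max())
        lg_lo, lg_hi = float(np.log10(uniq.min())), float(np.log10(uniq.max()))

        fixed_bottom = self.fix_bottom

        def model(theta):
            if fixed_bottom is None:
                t, b, lki = theta
            else:
                t, lki = theta
                b = fixed_bottom
            lic50 = lki + corr
            return np.where(nz, b + (t - b) / (1.0 + 10.0 ** (logc - lic50)), t)

        qs = np.linspace(0.15, 0.85, self.n_starts)
        if fixed_bottom is None:
            starts = [np.array([hi, lo, lg_lo + q * (lg_hi - lg_lo) - corr]) for q in qs]
            lb = np.array([lo - 10 * (hi - lo) - 1, lo - 10 * (hi - lo) - 1, lg_lo - corr - 6])
            ub = np.array([hi + 10 * (hi - lo) + 1, hi + 10 * (hi - lo) + 1, lg_hi - corr + 6])
            names = ["top", "bottom", "log_ki"]
        else:
            starts = [np.array([hi, lg_lo + q * (lg_hi - lg_lo) - corr]) for q in qs]
            lb = np.array([lo - 10 * (hi - lo) - 1, lg_lo - corr - 6])
            ub = np.array([hi + 10 * (hi - lo) + 1, lg_hi - corr + 6])
            names = ["top", "log_ki"]

        sol = _multistart_least_squares(
            lambda th: w * (model(th) - y), starts, (lb, ub),
            ftol=self.ftol, max_nfev=self.max_iter * 4,
        )
        if sol is None:
            raise RuntimeError("all starts failed")
        rss = float(2.0 * sol.cost)
        se = _stderr_from_jac(sol.jac, rss, y.size, sol.x.size)
        if fixed_bottom is None:
            self.top_, self.bottom_, self.log_ki_ = (float(v) for v in sol.x)
            constraints = {}
        else:
            self.top_, self.log_ki_ = (float(v) for v in sol.x)
            self.bottom_ = float(fixed_bottom)
            constraints = {"bottom": self.bottom_}
        params = CompetitionParams(
            log_ki=self.log_ki_, top=self.top_, bottom=self.bottom_,
            radioligand_conc=float(self.radioligand_conc),
            radioligand_kd=float(self.radioligand_kd),
        )
        self.ic50_ = params.ic50
        self.result_ = FitResult(
            params=params,
            stderr=dict(zip(names, se.tolist())),
            loss=rss,
            converged=bool(sol.status > 0),
            constraints=constraints,
            n_points=int(y.size),
            seed=self.seed,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        c = X[:, 0] if X.ndim == 2 else X
        return np.asarray(competition_predict(self.result_.params, c))


# ---------------------------------------------------------------------------
# Container-level wrappers
# ---------------------------------------------------------------------------


def fit_logistic3(data: DoseResponseSeries, **kw) -> FitResult:
    """Fit the three-parameter logistic to a dose-response series.

    Vehicle rows enter the fit at Bottom via the continuity convention;
    estimation runs in log-concentration space. The report carries
    pEC50 = −logEC50 via ``result.params.pec50``.
    """
    est = LogisticCurve(**kw).fit(data.conc, data.signal)
    return est.result_


def fit_saturation(data: BindingIsotherm, **kw) -> FitResult:
    if data.mode != "saturation":
        raise ValueError("fit_saturation requires a saturation-mode isotherm")
    est = SaturationBinding(**kw).fit(np.asarray(data.radioligand_conc), data.signal)
    return est.result_


def fit_competition(
    data: BindingIsotherm, radioligand_kd: float | None = None, **kw
) -> FitResult:
    if data.mode != "competition":
        raise ValueError("fit_competition requires a competition-mode isotherm")
    kd = radioligand_kd if radioligand_kd is not None else data.radioligand_kd
    if kd is None:
        raise ValueError("radioligand_kd must be supplied")
    est = CompetitionBinding(
        radioligand_conc=float(data.radioligand_conc), radioligand_kd=float(kd), **kw
    ).fit(data.competitor_conc, data.signal)
    return est.result_
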