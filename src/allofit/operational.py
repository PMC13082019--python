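"""The operational model of allosteric modulation.

For an orthosteric agonist A and an allosteric ligand B the effect is

    E = Emax * N / (D + N)

    N = (tau_A*[A]/K_A + tau_B*[B]/K_B + alpha*beta*tau_A*[A][B]/(K_A*K_B))**n
    D = (1 + [A]/K_A + [B]/K_B + alpha*[A][B]/(K_A*K_B))**n

where K_A, K_B are the ligands' equilibrium dissociation constants, tau_A,
tau_B their operational efficacies, alpha the binding-cooperativity factor
(allosteric effect on orthosteric affinity), beta the activation-cooperativity
factor (allosteric effect on orthosteric efficacy), Emax the system maximum
and n the transducer slope. E(0,0) = 0 and E < Emax for finite
concentrations. With B = 0 and n = 1 the model reduces exactly to a
three-parameter logistic with EC50 = K_A/(1+tau_A) and
Top = Emax*tau_A/(1+tau_A).

Fitting follows the constraint convention used for such surfaces: Emax fixed
to the maximum measured response rounded up (to the next multiple of 10 on a
% scale, configurable), n fixed to 1; alpha and beta are estimated on the
log10 scale, tau on the natural scale bounded below by 0.

"Gain in potency" is the log10 drop of the observed agonist EC50 produced by
a fixed modulator concentration (default 1 uM): positive for a PAM. Because
only log(alpha) is usually tabulated while both alpha and beta enter the
surface, fit reports carry log_alpha, log_beta and their sum
(log_alphabeta) so either reading of "cooperativity" is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .assay_io import ResponseSurface
from .curves import (
    FitResult,
    NonIdentifiableWarning,
    _multistart_least_squares,
    _stderr_from_jac,
)

__all__ = [
    "OperationalParams",
    "OperationalFit",
    "operational_effect",
    "observed_ec50",
    "gain_in_potency",
    "predicted_affinity_shift",
    "round_up_emax",
    "OperationalModel",
    "fit_operational",
    "NoEC50Error",
]


class NoEC50Error(ValueError):
    """The effect profile is flat in [A]; no EC50 exists."""


@dataclass(frozen=True)
class OperationalParams:
    """Full parameter state of the allosteric operational model."""

    emax: float  # system maximum, % units
    log_ka: float  # log10 M, orthosteric dissociation constant
    log_kb: float  # log10 M, allosteric dissociation constant
    tau_a: float  # orthosteric operational efficacy, >= 0
    tau_b: float  # allosteric operational efficacy, >= 0
    log_alpha: float  # log10 binding cooperativity
    log_beta: float  # log10 activation cooperativity
    n: float = 1.0  # transducer slope

    def __post_init__(self):
        if self.emax <= 0:
            raise ValueError("emax must be > 0")
        if self.tau_a < 0 or self.tau_b < 0:
            raise ValueError("tau_a and tau_b must be >= 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        for name in ("log_ka", "log_kb", "log_alpha", "log_beta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def ka(self) -> float:
        return 10.0**self.log_ka

    @property
    def kb(self) -> float:
        return 10.0**self.log_kb

    @property
    def alpha(self) -> float:
        return 10.0**self.log_alpha

    @property
    def beta(self) -> float:
        return 10.0**self.log_beta

    @property
    def log_alphabeta(self) -> float:
        """Composite cooperativity log10(alpha*beta)."""
        return self.log_alpha + self.log_beta


@dataclass
class OperationalFit:
    """Fit report for the operational allosteric model."""

    params: OperationalParams
    fixed: dict[str, float]
    stderr: dict[str, float]
    gain_in_potency: float  # log10 units at the reference modulator conc
    gain_reference_b: float  # molar
    loss: float
    converged: bool
    n_points: int
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {k: getattr(p, k) for k in p.__dataclass_fields__},
            "log_alphabeta": p.log_alphabeta,
            "fixed": self.fixed,
            "stderr": self.stderr,
            "gain_in_potency": self.gain_in_potency,
            "gain_reference_b": self.gain_reference_b,
            "loss": self.loss,
            "converged": self.converged,
            "n_points": self.n_points,
            "warnings": self.warnings,
            "seed": self.seed,
        }


def operational_effect(p: OperationalParams, a, b) -> np.ndarray | float:
    """Effect E(a, b) of the operational allosteric model (vectorized)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("concentrations must be >= 0")
    ra = a / p.ka
    rb = b / p.kb
    num_base = p.tau_a * ra + p.tau_b * rb + p.alpha * p.beta * p.tau_a * ra * rb
    den_base = 1.0 + ra + rb + p.alpha * ra * rb
    N = num_base**p.n
    D = den_base**p.n
    out = p.emax * N / (D + N)
    return out if out.ndim else float(out)


def _asymptote_a_inf(p: OperationalParams, b: float) -> float:
    """Analytic limit of E(a, b) as a -> infinity."""
    rb = b / p.kb
    c_n = p.tau_a * (1.0 + p.alpha * p.beta * rb)  # leading coeff of num_base in a/KA
    c_d = 1.0 + p.alpha * rb  # leading coeff of den_base
    if c_n == 0.0:
        return float(operational_effect(p, 0.0, b))
    Nn, Dn = c_n**p.n, c_d**p.n
    return float(p.emax * Nn / (Dn + Nn))


def observed_ec50(p: OperationalParams, b: float, *, rtol: float = 1e-10) -> float:
    """Agonist concentration producing the half-way effect at fixed modulator.

    The EC50 is read from the curve E(a, b) at fixed b, as the a-value where
    E equals the midpoint between the basal effect E(0, b) and the analytic
    large-a asymptote — not half of Emax. Solved by bracketed monotone
    root-finding on log10(a).

    Raises
    ------
    NoEC50Error
        If the profile is flat in a (tau_a = 0 with no alpha*beta pathway).
    """
    b = float(b)
    if b < 0:
        raise ValueError("b must be >= 0")
    e0 = float(operational_effect(p, 0.0, b))
    einf = _asymptote_a_inf(p, b)
    if abs(einf - e0) <= 1e-15 * max(1.0, abs(einf)):
        raise NoEC50Error("effect profile is flat in [A]; EC50 undefined")
    target = 0.5 * (e0 + einf)

    def f(log_a: float) -> float:
        return float(operational_effect(p, 10.0**log_a, b)) - target

    lo = p.log_ka - 12.0
    hi = p.log_ka + 12.0
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 8:
        lo -= 6.0
        hi += 6.0
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo * fhi > 0:
        raise NoEC50Error("could not bracket the half-maximal concentration")
    root = brentq(f, lo, hi, xtol=1e-14, rtol=max(rtol, 4e-16))
    return float(10.0**root)


def gain_in_potency(p: OperationalParams, b_ref: float = 1e-6) -> float:
    """log10 EC50(b=0) − log10 EC50(b=b_ref); positive for a PAM."""
    ec0 = observed_ec50(p, 0.0)
    ecb = observed_ec50(p, b_ref)
    return float(np.log10(ec0) - np.log10(ecb))


def predicted_affinity_shift(log_kb: float, log_alpha: float, b: float) -> float:
    """Binding-only log10 shift in orthosteric affinity at modulator conc b.

    Returns log10[(1 + alpha*b/K_B)/(1 + b/K_B)]; saturates at log10(alpha)
    as b -> infinity and is 0 everywhere when alpha = 1.
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    kb = 10.0**log_kb
    alpha = 10.0**log_alpha
    return float(np.log10((1.0 + alpha * b / kb) / (1.0 + b / kb)))


def round_up_emax(max_mean: float, multiple: float | None = 10.0) -> float:
    """The Emax constraint: smallest multiple of ``multiple`` >= the maximum
    observed cell mean (plain ``math.ceil`` when multiple is None)."""
    if multiple is None:
        return float(math.ceil(max_mean))
    return float(multiple * math.ceil(max_mean / multiple))


_FREE_NAMES = ["log_ka", "log_kb", "tau_a", "tau_b", "log_alpha", "log_beta"]


class OperationalModel(RegressorMixin, BaseEstimator):
    """Constrained least-squares fitter for the operational allosteric model.

    ``X`` is an (n_points, 2) array of molar concentrations ``[a, b]`` and
    ``y`` the measured effect (typically on the normalized % scale). Emax is
    fixed (supply a value, or leave None to round the maximum observed
    response up to the next multiple of 10); the transducer slope n is fixed
    to 1 by default. The six free parameters (log_ka, log_kb, tau_a, tau_b,
    log_alpha, log_beta) are estimated by multi-start bounded least squares
    with bounds logK in [-14, -3] and log(alpha), log(beta) in [-4, 4].

    Structural non-identifiability (e.g. alpha/beta with a single modulator
    level) is detected from the curvature spectrum of the loss and reported
    as a :class:`~allofit.curves.NonIdentifiableWarning` naming the flat
    parameter combination.

    Attributes
    ----------
    params_ : OperationalParams
    gain_in_potency_ : float
        log10 potency gain at ``gain_reference_b`` computed from the fit.
    result_ : OperationalFit
    """

    def __init__(self, emax=None, n=1.0, emax_round_multiple=10.0,
                 gain_reference_b=1e-6, n_starts=8, bounds_logk=(-14.0, -3.0),
                 bounds_logcoop=(-4.0, 4.0), tau_max=1e4, ftol=1e-12,
                 max_iter=500, seed=0):
        self.emax = emax
        self.n = n
        self.emax_round_multiple = emax_round_multiple
        self.gain_reference_b = gain_reference_b
        self.n_starts = n_starts
        self.bounds_logk = bounds_logk
        self.bounds_logcoop = bounds_logcoop
        self.tau_max = tau_max
        self.ftol = ftol
        self.max_iter = max_iter
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _unpack(self, theta, emax):
        return OperationalParams(
            emax=emax, log_ka=theta[0], log_kb=theta[1],
            tau_a=theta[2], tau_b=theta[3],
            log_alpha=theta[4], log_beta=theta[5], n=self.n,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_points, 2): columns [a_molar, b_molar]")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        a, b = X[:, 0], X[:, 1]
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("concentrations must be >= 0")
        warn_list: list[str] = []

        n_a = np.unique(a[a > 0]).size
        n_b_levels = np.unique(b).size
        if n_a < 4 or n_b_levels < 2:
            raise ValueError(
                "need >= 4 orthosteric levels and >= 2 modulator levels (incl. 0)"
            )
        if not np.any(b == 0):
            raise ValueError("surface must include a modulator-free (b = 0) column")

        # cell means for the Emax constraint
        if self.emax is None:
            import pandas as pd

            means = pd.DataFrame({"a": a, "b": b, "y": y}).groupby(["a", "b"])["y"].mean()
            emax = round_up_emax(float(means.max()), self.emax_round_multiple)
        else:
            emax = float(self.emax)
            import pandas as pd

            means = pd.DataFrame({"a": a, "b": b, "y": y}).groupby(["a", "b"])["y"].mean()
            if emax < float(means.max()) - 1e-9:
                raise ValueError(
                    f"emax constraint {emax} below maximum observed cell mean "
                    f"{float(means.max()):.3f}"
                )

        ra_pos = a[a > 0]
        lga_mid = float(np.log10(np.median(ra_pos)))
        b_pos = b[b > 0]
        lgb_mid = float(np.log10(np.median(b_pos))) if b_pos.size else -6.0

        def residual(theta):
            p = self._unpack(theta, emax)
            return operational_effect(p, a, b) - y

        rng = np.random.default_rng(self.seed)
        lk_lo, lk_hi = self.bounds_logk
        lc_lo, lc_hi = self.bounds_logcoop
        lb = np.array([lk_lo, lk_lo, 0.0, 0.0, lc_lo, lc_lo])
        ub = np.array([lk_hi, lk_hi, self.tau_max, self.tau_max, lc_hi, lc_hi])
        starts = []
        base_taus = [0.5, 2.0, 5.0, 20.0]
        for i in range(self.n_starts):
            tau0 = base_taus[i % len(base_taus)]
            jit = rng.uniform(-0.75, 0.75, size=2) if i >= len(base_taus) else (0.0, 0.0)
            starts.append(
                np.array([
                    lga_mid + 1.0 + jit[0],  # KA above observed mid (tau shifts EC50 down)
                    lgb_mid + jit[1] if b_pos.size else -6.0,
                    tau0, 0.1, 0.5, 0.0,
                ])
            )
        sol = _multistart_least_squares(
            residual, starts, (lb, ub), ftol=self.ftol, max_nfev=self.max_iter * 6,
        )
        if sol is None:
            raise RuntimeError("all starts failed")
        converged = bool(sol.status > 0)
        rss = float(2.0 * sol.cost)
        params = self._unpack(sol.x, emax)

        # identifiability: curvature spectrum on scaled parameters
        jac = sol.jac
        scale = np.where(np.abs(sol.x) > 1.0, np.abs(sol.x), 1.0)
        jtj = (jac * scale).T @ (jac * scale)
        evals, evecs = np.linalg.eigh(jtj)
        if evals[-1] > 0 and evals[0] / evals[-1] < 1e-10:
            vec = evecs[:, 0]
            idx = np.argsort(-np.abs(vec))[:2]
            combo = " / ".join(_FREE_NAMES[i] for i in idx)
            msg = f"structurally non-identifiable direction involving {combo}"
            warn_list.append(msg)
            warnings.warn(msg, NonIdentifiableWarning)
        if n_b_levels <= 2:
            msg = "single nonzero modulator level: log_alpha / log_beta not separable"
            if msg not in warn_list:
                warn_list.append(msg)
                warnings.warn(msg, NonIdentifiableWarning)

        se = _stderr_from_jac(jac, rss, y.size, sol.x.size)
        try:
            gain = gain_in_potency(params, self.gain_reference_b)
        except NoEC50Error:
            gain = float("nan")
            warn_list.append("gain in potency undefined (flat agonist profile)")
        if not converged:
            warn_list.append("fit did not converge across starts")
            warnings.warn(warn_list[-1], NonIdentifiableWarning)

        self.params_ = params
        self.gain_in_potency_ = gain
        self.loss_ = rss
        self.converged_ = converged
        self.result_ = OperationalFit(
            params=params,
            fixed={"emax": emax, "n": self.n},
            stderr=dict(zip(_FREE_NAMES, se.tolist())),
            gain_in_potency=gain,
            gain_reference_b=float(self.gain_reference_b),
            loss=rss,
            converged=converged,
            n_points=int(y.size),
            warnings=warn_list,
            seed=self.seed,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.asarray(operational_effect(self.params_, X[:, 0], X[:, 1]))


def fit_operational(
    surface: ResponseSurface, constraints: dict | None = None, **kw
) -> OperationalFit:
    """Fit the operational allosteric model to a response surface.

    ``constraints`` may carry ``emax`` (a value, or "auto" to round the
    maximum observed cell mean up to the next multiple of 10) and ``n``
    (default 1). All other parameters are free.
    """
    constraints = dict(constraints or {})
    emax = constraints.pop("emax", None)
    if emax == "auto":
        emax = None
    n = constraints.pop("n", 1.0)
    if constraints:
        raise ValueError(f"unknown constraint(s): {sorted(constraints)}")
    X = np.column_stack([surface.conc_a, surface.conc_b])
    est = OperationalModel(emax=emax, n=n, **kw).fit(X, surface.signal)
    return est.result_
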