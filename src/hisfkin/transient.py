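"""Phenomenological stopped-flow analysis.

Transients are fitted to sums of decaying exponentials
``y = sum_i Amp_i * exp(-kobs_i * t) + c``; the number of phases is chosen by
AICc. Secondary plots (kobs vs ligand concentration) are fitted either to a
straight line (one-step binding, kobs = k1*[S] + k-1) or to the
rapid-equilibrium hyperbola of a binding-then-isomerization mechanism
(kobs = k-conf + kconf*[S]/(KD1+[S])), and the two are compared by AICc to
classify the binding mechanism. kobs-vs-concentration data alone cannot tell
induced fit from conformational selection - both produce nonlinear
concentration dependence - so the conformational verdict is deliberately
named "conformational-step".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .traces import Trace
from .util import (
    DegenerateDataError,
    FitError,
    IdentifiabilityWarning,
    aicc,
    weighted_linear_lstsq,
)

__all__ = [
    "ExponentialFit",
    "SecondaryPlotFit",
    "MechanismVerdict",
    "fit_exponential",
    "select_n_phases",
    "fit_secondary_plot",
    "classify_mechanism",
]


@dataclass(eq=False)
class ExponentialFit:
    """Multi-exponential fit result; amplitudes are referenced to the first
    recorded time point (the start of the observable window)."""

    n_phases: int
    amplitudes: list[float]  # fast phase first
    rates: list[float]  # kobs_i, s^-1, descending
    offset: float
    stderr: dict[str, float]
    ssr: float
    aicc: float
    n_points: int
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def noise_sigma(self) -> float:
        dof = max(self.n_points - (2 * self.n_phases + 1), 1)
        return math.sqrt(self.ssr / dof)

    def to_dict(self) -> dict:
        return {
            "n_phases": self.n_phases,
            "amplitudes": list(self.amplitudes),
            "kobs": list(self.rates),
            "offset": self.offset,
            "stderr": dict(self.stderr),
            "ssr": self.ssr,
            "aicc": self.aicc,
            "n_points": self.n_points,
        }


def _as_ty(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, Trace):
        return trace.time, trace.signal
    t, y = trace
    return np.asarray(t, float), np.asarray(y, float)


def _multiexp_design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    cols = [np.exp(-np.clip(k, 0, None) * t) for k in rates]
    cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _separable_ssr(t, y, rates, w=None):
    coefs, _, ssr = weighted_linear_lstsq(_multiexp_design(t, rates), y, w)
    return coefs, ssr


def fit_exponential(
    trace,
    n_phases: int = 1,
    init_strategy: str = "grid",
    n_starts: int = 5,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> ExponentialFit:
    """Least-squares multi-exponential fit of a transient.

    Rates are optimized in log space over a multistart grid spanning the
    observable window (amplitudes and offset solved exactly by linear least
    squares at each step), then all parameters are polished jointly to
    obtain the covariance-based standard errors.
    """
    t, y = _as_ty(trace)
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    n_par = 2 * n_phases + 1
    if t.size < 5 * n_par:
        raise DegenerateDataError(
            f"need >= {5 * n_par} points for a {n_phases}-phase fit, got {t.size}"
        )
    if np.ptp(y) == 0 or np.std(y) < 1e-12 * max(1.0, abs(np.mean(y))):
        raise DegenerateDataError("signal is constant; nothing to fit")

    t0 = t - t[0]  # decay referenced to the first recorded point
    span = t[-1] - t[0]
    dt = np.min(np.diff(t))
    lo, hi = math.log(0.1 / span), math.log(1.0 / dt)
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if init_strategy == "grid":
        base = np.linspace(lo, hi, n_starts)
        if n_phases == 1:
            starts = [np.array([b]) for b in base]
        else:
            gap = math.log(25.0)
            starts = [np.array([min(b + gap, hi + 1.0), b]) for b in base]
    else:  # random log-uniform
        for _ in range(n_starts):
            s = np.sort(rng.uniform(lo, hi, n_phases))[::-1]
            starts.append(s)

    def resid_logk(logk):
        design = _multiexp_design(t0, np.exp(logk))
        yy = y
        if weights is not None:
            design = design * weights[:, None]
            yy = y * weights
        coefs, *_ = np.linalg.lstsq(design, yy, rcond=None)
        return design @ coefs - yy

    best = None
    for s in starts:
        try:
            sol = least_squares(resid_logk, s, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        _, ssr = _separable_ssr(t0, y, np.exp(sol.x), weights)
        if best is None or ssr < best[1]:
            best = (np.exp(sol.x), ssr)
    if best is None:
        raise FitError("all multistart exponential fits failed")

    rates = np.sort(best[0])[::-1]
    coefs, ssr = _separable_ssr(t0, y, rates, weights)
    amps, c = coefs[:-1], coefs[-1]

    # joint polish for the covariance
    def resid_full(p):
        k = np.exp(p[:n_phases])
        model = _multiexp_design(t0, k) @ np.concatenate([p[n_phases:-1], p[-1:]])
        r = model - y
        return r if weights is None else r * weights

    p0 = np.concatenate([np.log(np.clip(rates, 1e-12, None)), amps, [c]])
    sol = least_squares(resid_full, p0, method="lm", xtol=1e-15, ftol=1e-15)
    k_fit = np.exp(sol.x[:n_phases])
    order = np.argsort(k_fit)[::-1]
    k_fit = k_fit[order]
    amps = sol.x[n_phases:-1][order]
    c = sol.x[-1]
    r = sol.fun
    ssr = float(r @ r)

    dof = max(t.size - n_par, 1)
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * ssr / dof
        se_raw = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_raw = np.full(sol.x.size, np.nan)
    se_k = se_raw[:n_phases][order] * k_fit  # log-space SE -> absolute
    se_amp = se_raw[n_phases:-1][order]
    stderr = {}
    for i in range(n_phases):
        stderr[f"kobs{i + 1}"] = float(se_k[i])
        stderr[f"Amp{i + 1}"] = float(se_amp[i])
    stderr["c"] = float(se_raw[-1])

    fitted = _multiexp_design(t0, k_fit) @ np.concatenate([amps, [c]])
    return ExponentialFit(
        n_phases=n_phases,
        amplitudes=[float(a) for a in amps],
        rates=[float(k) for k in k_fit],
        offset=float(c),
        stderr=stderr,
        ssr=ssr,
        aicc=aicc(ssr, t.size, n_par),
        n_points=int(t.size),
        residuals=y - fitted,
        fitted=fitted,
    )


def select_n_phases(
    trace,
    seed: int = 0,
    rate_ratio_floor: float = 1.1,
    amp_sigma_floor: float = 3.0,
) -> tuple[ExponentialFit, float]:
    """Choose between a 1- and 2-exponential description of a transient.

    Returns (best fit, delta_AICc) with delta_AICc = AICc(1) - AICc(2), so
    positive values favor the biphasic description. The 2-phase fit is
    discarded as degenerate when its two rates differ by < 10% or the minor
    amplitude is below ``amp_sigma_floor`` times the residual noise.
    """
    fit1 = fit_exponential(trace, 1, seed=seed)
    try:
        fit2 = fit_exponential(trace, 2, seed=seed)
    except (DegenerateDataError, FitError):
        return fit1, -math.inf
    delta = fit1.aicc - fit2.aicc
    sigma = fit2.noise_sigma
    degenerate = (
        fit2.rates[0] / max(fit2.rates[1], 1e-300) < rate_ratio_floor
        or min(abs(a) for a in fit2.amplitudes) < amp_sigma_floor * sigma
    )
    if degenerate or delta <= 0:
        return fit1, delta
    return fit2, delta


@dataclass
class SecondaryPlotFit:
    model: str  # "linear" | "hyperbolic"
    params: dict[str, float]
    stderr: dict[str, float]
    ssr: float
    aicc: float
    n_points: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "ssr": self.ssr,
            "aicc": self.aicc,
            "n_points": self.n_points,
            "warnings": list(self.warnings),
        }


def _check_design(conc: np.ndarray, n_min: int):
    if conc.size < n_min:
        raise DegenerateDataError(f"need >= {n_min} concentrations, got {conc.size}")
    if np.max(conc) / max(np.min(conc), 1e-300) < 4:
        raise DegenerateDataError("concentrations must span >= 4-fold range")


def fit_secondary_plot(points, model: str) -> SecondaryPlotFit:
    """Weighted fit of a kobs-vs-concentration plot.

    ``points`` is an iterable of (conc_uM, kobs_s, se) or (conc_uM, kobs_s);
    weights are 1/se^2 when SEs are given. The linear model returns the
    association/dissociation rate constants of one-step binding (slope k1,
    intercept k-1); the hyperbolic model returns KD1, kconf and k-conf of
    the rapid-equilibrium conformational-step expression.
    """
    pts = np.atleast_2d(np.asarray(list(points), float))
    conc, kobs = pts[:, 0], pts[:, 1]
    se = pts[:, 2] if pts.shape[1] > 2 else None
    w = 1.0 / se if se is not None and np.all(se > 0) else None
    warns: list[str] = []

    if model == "linear":
        _check_design(conc, 4)
        design = np.column_stack([conc, np.ones_like(conc)])
        coefs, _, ssr = weighted_linear_lstsq(design, kobs, w)
        if np.any(coefs < 0):  # bound-constrained refit via clipped profile
            slope = max(coefs[0], 0.0)
            intercept = max(coefs[1], 0.0)
            grid = {
                (slope, intercept),
                (0.0, float(np.average(kobs, weights=None if w is None else w**2))),
                (float(np.sum(conc * kobs) / np.sum(conc**2)), 0.0),
            }
            best = min(
                grid,
                key=lambda p: float(
                    np.sum(((design @ np.array(p) - kobs) * (1 if w is None else w)) ** 2)
                ),
            )
            coefs = np.array(best)
            r = (design @ coefs - kobs) * (1 if w is None else w)
            ssr = float(r @ r)
        dof = max(conc.size - 2, 1)
        Xw = design if w is None else design * w[:, None]
        cov = np.linalg.pinv(Xw.T @ Xw) * ssr / dof
        separ = np.sqrt(np.clip(np.diag(cov), 0, None))
        return SecondaryPlotFit(
            "linear",
            {"k1": float(coefs[0]), "k-1": float(coefs[1])},
            {"k1": float(separ[0]), "k-1": float(separ[1])},
            ssr,
            aicc(ssr, conc.size, 2),
            int(conc.size),
            warns,
        )

    if model != "hyperbolic":
        raise ValueError("model must be 'linear' or 'hyperbolic'")
    _check_design(conc, 5)

    def model_fn(p):
        kd, kc, kmc = p
        return kmc + kc * conc / (kd + conc)

    def resid(logp):
        r = model_fn(np.exp(np.clip(logp, -60, 60))) - kobs
        return r if w is None else r * w

    kmax = float(np.max(kobs))
    best = None
    for kd0 in np.geomspace(0.2 * np.min(conc), 50 * np.max(conc), 7):
        p0 = np.log([kd0, max(kmax - np.min(kobs), 1e-6), max(np.min(kobs), 1e-6)])
        try:
            sol = least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        ssr = float(sol.fun @ sol.fun)
        if best is None or ssr < best[1] * (1 - 1e-12):
            best = (sol, ssr)
    if best is None:
        raise FitError("hyperbolic secondary-plot fit failed")
    sol, ssr = best
    p = np.exp(np.clip(sol.x, -60, 60))
    dof = max(conc.size - 3, 1)
    cov = np.linalg.pinv(sol.jac.T @ sol.jac) * ssr / dof
    se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    separ = se_log * p
    params = {"KD1": float(p[0]), "kconf": float(p[1]), "k-conf": float(p[2])}
    stderr = {"KD1": float(separ[0]), "kconf": float(separ[1]), "k-conf": float(separ[2])}
    if params["KD1"] > 10 * np.max(conc) or se_log[0] > math.log(100.0):
        msg = (
            "KD1 is not constrained by the sampled concentration range; "
            "the hyperbolic fit is degenerate with a straight line"
        )
        warns.append(msg)
        warnings.warn(msg, IdentifiabilityWarning, stacklevel=2)
    return SecondaryPlotFit(
        "hyperbolic", params, stderr, ssr, aicc(ssr, conc.size, 3), int(conc.size), warns
    )


@dataclass
class MechanismVerdict:
    classification: str  # "two-state" | "conformational-step" | "ambiguous"
    delta_aicc: float  # AICc(linear) - AICc(hyperbolic); positive favors hyperbolic
    selected: SecondaryPlotFit
    linear: SecondaryPlotFit
    hyperbolic: SecondaryPlotFit | None
    threshold: float = 2.0

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "delta_aicc": self.delta_aicc,
            "threshold": self.threshold,
            "selected_model": self.selected.model,
            "linear": self.linear.to_dict(),
            "hyperbolic": self.hyperbolic.to_dict() if self.hyperbolic else None,
            "note": (
                "a nonlinear kobs([S]) identifies a conformational step but cannot "
                "distinguish induced fit from conformational selection"
            ),
        }


def classify_mechanism(points, threshold: float = 2.0) -> MechanismVerdict:
    """Compare one-step vs conformational-step binding on a secondary plot.

    Fits both candidate models and classifies by AICc: differences smaller
    than ``threshold`` (default 2) are reported as ambiguous.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IdentifiabilityWarning)
        lin = fit_secondary_plot(points, "linear")
        try:
            hyp = fit_secondary_plot(points, "hyperbolic")
        except DegenerateDataError:
            # too few concentrations for the 3-parameter model: only the
            # one-step description is supportable
            return MechanismVerdict(
                "two-state", -math.inf, lin, lin, None, threshold
            )
    delta = lin.aicc - hyp.aicc
    if abs(delta) < threshold:
        cls = "ambiguous"
        sel = lin if lin.aicc <= hyp.aicc else hyp
    elif delta > 0:
        cls, sel = "conformational-step", hyp
    else:
        cls, sel = "two-state", lin
    return MechanismVerdict(cls, float(delta), sel, lin, hyp, threshold)
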