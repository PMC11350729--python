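"""Steady-state and single-turnover analysis of enzyme progress curves.

Multiple-turnover A300 transients are reduced to initial velocities
(v = slope / (path * d_eps300)), fitted to the Michaelis-Menten equation
v = kcat*E_tot*[S]/(KM+[S]), and the specificity constant kcat/KM is derived
with Gaussian error propagation. Single-turnover decays (enzyme excess over
substrate, so product release does not contribute) give a chemistry-step
rate that is compared with kcat to diagnose the rate-limiting step: similar
rates mean the chemical step limits turnover, a much faster single-turnover
rate means a post-chemistry step (product release / conformational opening)
does.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .transient import fit_exponential
from .util import (
    DegenerateDataError,
    FitError,
    IdentifiabilityWarning,
    ValidationError,
    weighted_linear_lstsq,
)

__all__ = [
    "AssayConstants",
    "ProgressCurve",
    "MMResult",
    "STResult",
    "absorbance_to_velocity",
    "extract_steady_velocity",
    "fit_michaelis_menten",
    "propagate_kcat_over_km",
    "kcat_upper_limit",
    "fit_single_turnover",
    "diagnose_rate_limiting",
]


@dataclass(frozen=True)
class AssayConstants:
    """Photometric constants of the PrFAR cyclase assay at 300 nm."""

    d_eps300: float = 5637.0  # M^-1 cm^-1, PrFAR minus AICAR
    eps300_profar: float = 6069.0  # M^-1 cm^-1
    path_cm: float = 1.0

    def __post_init__(self):
        if self.d_eps300 <= 0 or self.eps300_profar <= 0 or self.path_cm <= 0:
            raise ValidationError("assay constants must be positive")

    @property
    def d_eps300_uM(self) -> float:
        """Difference extinction coefficient in A per uM per cm."""
        return self.d_eps300 * 1e-6


@dataclass(eq=False)
class ProgressCurve:
    """Continuous turnover record: absorbance (or concentration) vs time."""

    time: np.ndarray
    values: np.ndarray  # A300 if unit == "A300", else uM
    e_tot: float  # uM enzyme
    s0: float  # uM initial substrate
    mode: str  # "multiple_turnover" | "single_turnover" | "control"
    ammonia_present: bool = True
    unit: str = "A300"
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.values = np.asarray(self.values, float)
        if self.time.shape != self.values.shape or self.time.ndim != 1:
            raise ValidationError("time and values must match")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if self.mode not in ("multiple_turnover", "single_turnover", "control"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "control" and self.ammonia_present:
            raise ValidationError("a control curve is recorded without ammonia")


@dataclass(eq=False)
class MMResult:
    kcat: float
    kcat_se: float
    km: float  # uM
    km_se: float
    ssr: float
    n_points: int
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def kcat_over_km(self) -> tuple[float, float]:
        """(value, SE) of the specificity constant in M^-1 s^-1, recomputed."""
        return propagate_kcat_over_km(self.kcat, self.kcat_se, self.km, self.km_se)

    def to_dict(self) -> dict:
        v, se = self.kcat_over_km
        return {
            "kcat_s": self.kcat,
            "kcat_se": self.kcat_se,
            "KM_uM": self.km,
            "KM_se": self.km_se,
            "kcat_over_KM_M_s": v,
            "kcat_over_KM_se": se,
            "ssr": self.ssr,
            "n_points": self.n_points,
        }


@dataclass
class STResult:
    """Single-turnover rates per substrate concentration."""

    s0: list[float]
    kobs: list[float]
    kobs_se: list[float]

    def __post_init__(self):
        if any(k <= 0 for k in self.kobs):
            raise ValidationError("single-turnover kobs must be positive")

    @property
    def mean_kobs(self) -> float:
        return float(np.mean(self.kobs))

    @property
    def flatness(self) -> float:
        """Max relative deviation of kobs from its mean across [S]."""
        m = self.mean_kobs
        return float(np.max(np.abs(np.array(self.kobs) - m)) / m)

    def to_dict(self) -> dict:
        return {
            "S0_uM": list(self.s0),
            "kobs_s": list(self.kobs),
            "kobs_se": list(self.kobs_se),
            "mean_kobs_s": self.mean_kobs,
            "flatness": self.flatness,
        }


def absorbance_to_velocity(
    slope_A_per_s: float, constants: AssayConstants = AssayConstants()
) -> float:
    """Convert an A300 slope to a turnover velocity in uM/s."""
    return abs(slope_A_per_s) / (constants.path_cm * constants.d_eps300_uM)


def extract_steady_velocity(
    curve: ProgressCurve,
    constants: AssayConstants = AssayConstants(),
    burst_exclusion: bool = True,
    depletion_fraction: float = 0.2,
) -> tuple[float, float]:
    """Steady-state velocity (uM/s) from the linear phase of a progress curve.

    An initial mixing-artifact burst, when present, is located by fitting
    burst-exponential + line and excluded (the window starts where the burst
    has decayed to < 5% of its amplitude); the window ends once
    ``depletion_fraction`` of the substrate has been consumed. Returns
    (v, SE).
    """
    if curve.mode not in ("multiple_turnover", "control"):
        raise ValidationError("steady-state extraction needs a multiple-turnover or control curve")
    t, y = curve.time, curve.values
    scale = constants.path_cm * constants.d_eps300_uM if curve.unit == "A300" else 1.0

    t_start = t[0]
    y_use = y
    if burst_exclusion:
        # burst + line: y = a*exp(-k t) + b + c t. The burst rate is kept
        # above 20/span so that slow substrate depletion cannot masquerade
        # as the mixing artifact.
        amp0 = y[0] - y[-1]
        span = t[-1] - t[0]
        logk_min = math.log(20.0 / span)

        def resid(p):
            a, logk, b, c = p
            return a * np.exp(-np.exp(np.clip(logk, logk_min, 12)) * t) + b + c * t - y

        best = None
        for k0 in (3.0, 30.0, 300.0):
            if math.log(k0) < logk_min:
                continue
            try:
                sol = least_squares(
                    resid, [amp0, math.log(k0), y[-1], 0.0], method="lm",
                    xtol=1e-12, ftol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is not None:
            a, logk, _, _ = best.x
            kb = math.exp(min(max(logk, logk_min), 12))
            noise = np.std(np.diff(y)) / math.sqrt(2)
            if abs(a) > 3 * noise and kb > 1.05 * math.exp(logk_min):
                t_start = max(t_start, t[0] + math.log(20.0) / kb)
                # the fitted artifact is subtracted so that its tail cannot
                # bias the slope when the substrate signal is small
                y_use = y - a * np.exp(-kb * t)

    # end of window: 20% substrate depletion, judged on a smoothed signal so
    # that point noise cannot trigger the threshold
    n_sm = max(min(len(t) // 20, 25), 1)
    kernel = np.ones(n_sm) / n_sm
    y_smooth = np.convolve(np.pad(y_use, n_sm, mode="edge"), kernel, mode="same")[
        n_sm:-n_sm
    ]
    y0 = float(np.interp(t_start, t, y_smooth))
    depletion_cap = depletion_fraction * curve.s0 * scale
    mask = t >= t_start
    if curve.mode != "control" and depletion_cap > 0:
        consumed = np.abs(y_smooth - y0)
        over = mask & (consumed > depletion_cap)
        over[-n_sm:] = False  # smoothing edge artifact
        if over.any():
            t_end = t[over][0]
            mask &= t <= t_end
    if mask.sum() < 10:
        raise DegenerateDataError(
            f"steady-state window has only {int(mask.sum())} points (need >= 10)"
        )
    tt, yy = t[mask], y_use[mask]
    design = np.column_stack([tt, np.ones_like(tt)])
    coefs, _, ssr = weighted_linear_lstsq(design, yy)
    dof = max(tt.size - 2, 1)
    cov = np.linalg.pinv(design.T @ design) * ssr / dof
    slope_se = math.sqrt(max(cov[0, 0], 0.0))
    return abs(coefs[0]) / scale, slope_se / scale


def fit_michaelis_menten(points, e_tot: float, weighted: bool = True) -> MMResult:
    """Michaelis-Menten fit of (S0_uM, v_uM_per_s[, se]) initial-velocity data.

    Uses weighted least squares (1/se^2) when SEs are supplied and
    ``weighted`` is true. Warns when KM runs outside the sampled range.
    """
    pts = np.atleast_2d(np.asarray(list(points), float))
    S, v = pts[:, 0], pts[:, 1]
    se = pts[:, 2] if pts.shape[1] > 2 else None
    if S.size < 5:
        raise DegenerateDataError("need >= 5 substrate concentrations")
    if np.max(S) / max(np.min(S), 1e-300) < 8:
        raise DegenerateDataError("substrate range must span >= 8-fold")
    if np.all(v == 0):
        raise DegenerateDataError("all velocities are zero")
    if e_tot <= 0:
        raise ValidationError("e_tot must be positive")
    w = 1.0 / se if weighted and se is not None and np.all(se > 0) else None

    def resid(logp):
        kcat, km = np.exp(np.clip(logp, -40, 40))
        r = kcat * e_tot * S / (km + S) - v
        return r if w is None else r * w

    vmax0 = max(np.max(v), 1e-12)
    best = None
    for km0 in np.geomspace(0.2 * np.min(S), 5 * np.max(S), 5):
        try:
            sol = least_squares(
                resid, np.log([vmax0 / e_tot, km0]), method="lm",
                xtol=1e-14, ftol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("Michaelis-Menten fit failed")
    kcat, km = np.exp(best.x)
    ssr = float(2 * best.cost)
    dof = max(S.size - 2, 1)
    cov = np.linalg.pinv(best.jac.T @ best.jac) * ssr / dof
    se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    if km > 5 * np.max(S):
        warnings.warn(
            f"KM = {km:.3g} uM exceeds 5x the largest sampled concentration; "
            "kcat and KM are only jointly constrained",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    r = resid(best.x)
    return MMResult(
        kcat=float(kcat),
        kcat_se=float(se_log[0] * kcat),
        km=float(km),
        km_se=float(se_log[1] * km),
        ssr=ssr,
        n_points=int(S.size),
        residuals=np.asarray(r),
    )


def propagate_kcat_over_km(
    kcat: float, se_kcat: float, km_uM: float, se_km: float
) -> tuple[float, float]:
    """Specificity constant kcat/KM in M^-1 s^-1 with propagated SE.

    Gaussian propagation for a ratio: the relative SE is the quadrature sum
    of the relative SEs of kcat and KM.
    """
    if kcat <= 0 or km_uM <= 0:
        raise ValidationError("kcat and KM must be positive")
    value = kcat / (km_uM * 1e-6)
    rel = math.sqrt((se_kcat / kcat) ** 2 + (se_km / km_uM) ** 2)
    return value, value * rel


def kcat_upper_limit(v_detect: float, e_tot: float) -> float:
    """Upper bound on kcat from an assay with no detectable turnover.

    ``v_detect`` is the smallest velocity (uM/s) the assay could have seen;
    the bound is v_detect / E_tot, to be reported as 'kcat < bound'.
    """
    if v_detect < 0 or e_tot <= 0:
        raise ValidationError("need v_detect >= 0 and e_tot > 0")
    if v_detect == 0:
        warnings.warn(
            "v_detect = 0 gives a degenerate bound of 0", UserWarning, stacklevel=2
        )
    return v_detect / e_tot


def fit_single_turnover(curve: ProgressCurve, seed: int = 0) -> tuple[float, float]:
    """Single-exponential rate of a single-turnover decay; returns (kobs, SE).

    Requires enzyme excess (E_tot >= 2*S0) so that every substrate molecule
    is enzyme-bound and product release cannot contribute to the rate.
    """
    if curve.mode != "single_turnover":
        raise ValidationError("curve is not in single-turnover mode")
    if curve.e_tot < curve.s0:
        raise ValidationError(
            f"mode violation: E_tot = {curve.e_tot} uM < S0 = {curve.s0} uM "
            "is not a single-turnover design"
        )
    if curve.e_tot < 2 * curve.s0:
        warnings.warn(
            "E_tot < 2*S0: substrate may not be fully enzyme-saturated",
            UserWarning,
            stacklevel=2,
        )
    fit = fit_exponential((curve.time, curve.values), 1, seed=seed)
    return fit.rates[0], fit.stderr["kobs1"]


def diagnose_rate_limiting(
    mm: MMResult, st: STResult, low: float = 1.0 / 3.0, high: float = 3.0
) -> dict:
    """Compare single- and multiple-turnover rates to locate the slow step.

    ratio = mean single-turnover kobs / kcat. Within [low, high] ("same
    order of magnitude") the chemical step is rate-limiting; above ``high``
    a post-chemistry step (product release / loop opening) is; a ratio
    below ``low`` is physically unexpected (kcat cannot exceed the
    chemistry rate) and is reported as inconclusive.
    """
    ratio = st.mean_kobs / mm.kcat
    rel_se = math.sqrt(
        (mm.kcat_se / mm.kcat) ** 2
        + (np.std(st.kobs, ddof=1) / math.sqrt(len(st.kobs)) / st.mean_kobs) ** 2
        if len(st.kobs) > 1
        else (mm.kcat_se / mm.kcat) ** 2
    )
    if low <= ratio <= high:
        verdict = "chemistry rate-limiting"
    elif ratio > high:
        verdict = "product release (or post-chemistry step) rate-limiting"
    else:
        verdict = "inconclusive"
    return {
        "verdict": verdict,
        "ratio": float(ratio),
        "ratio_se": float(ratio * rel_se),
        "kcat_s": mm.kcat,
        "st_kobs_s": st.mean_kobs,
    }
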