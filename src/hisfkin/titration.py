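"""Equilibrium fluorescence titration analysis and ternary-complex synergy.

Fluorescence changes on stepwise ligand addition are corrected for dilution
and intrinsic ligand fluorescence, then fitted to the hyperbolic binding
isotherm dF = dF_max*[L]/(KD_app+[L]) + c. When the receptor concentration
is not negligible against KD (ligand depletion), the quadratic
tight-binding form replaces the free-ligand approximation. Apparent KD
values predicted from a ternary binding scheme let the measured synergy
(tighter apparent binding of one product in the presence of the other) be
compared against the loop-closure equilibrium K4: at saturating co-ligand
KD_app = KD_intrinsic / (1 + K4).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import dynamics
from .schemes import KineticScheme, RateParameterSet
from .util import (
    DegenerateDataError,
    FitError,
    IdentifiabilityWarning,
    ValidationError,
)

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "SynergyReport",
    "preprocess_titration",
    "fit_binding_isotherm",
    "predict_apparent_kd",
    "synergy",
]


@dataclass(eq=False)
class TitrationSeries:
    ligand: str
    conc: np.ndarray  # uM, nondecreasing
    fluorescence: np.ndarray
    protein_conc: float = 0.0  # uM receptor
    co_ligand: str | None = None
    co_ligand_conc: float = 0.0  # uM, fixed
    added_volume: np.ndarray | None = None  # uL cumulative
    corrections: list[str] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        self.conc = np.asarray(self.conc, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.conc.shape != self.fluorescence.shape:
            raise ValidationError("conc and fluorescence must match")
        if np.any(np.diff(self.conc) < 0):
            raise ValidationError("concentrations must be nondecreasing")
        if self.added_volume is not None:
            self.added_volume = np.asarray(self.added_volume, float)


@dataclass(eq=False)
class TitrationFit:
    kd_app: float  # uM
    kd_se: float
    amplitude: float  # dF_max; negative for quench
    baseline: float
    model: str  # "hyperbolic" | "quadratic"
    ssr: float
    n_points: int
    warnings: list[str] = field(default_factory=list)
    residuals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "KD_app_uM": self.kd_app,
            "KD_se": self.kd_se,
            "dF_max": self.amplitude,
            "baseline": self.baseline,
            "model": self.model,
            "ssr": self.ssr,
            "n_points": self.n_points,
            "warnings": list(self.warnings),
        }


def preprocess_titration(
    series: TitrationSeries,
    dilution: bool = True,
    initial_volume: float | None = None,
    ligand_background: float = 0.0,
) -> TitrationSeries:
    """Apply dilution and intrinsic-ligand-fluorescence corrections once.

    Dilution: readings are rescaled by (V0 + Vadded)/V0. Intrinsic ligand
    fluorescence: a linear background ``ligand_background * [L]`` is
    subtracted (as needed for ImGP). Raises if a correction is requested
    twice or dilution volumes are missing.
    """
    f = series.fluorescence.astype(float).copy()
    applied = list(series.corrections)
    if dilution:
        if "dilution" in applied:
            raise ValidationError("dilution correction already applied")
        if series.added_volume is None:
            raise ValidationError("dilution correction requested but added volumes missing")
        if initial_volume is None or initial_volume <= 0:
            raise ValidationError("dilution correction needs the initial volume")
        f = f * (initial_volume + series.added_volume) / initial_volume
        applied.append("dilution")
    if ligand_background != 0.0:
        if "ligand_background" in applied:
            raise ValidationError("ligand background correction already applied")
        f = f - ligand_background * series.conc
        applied.append("ligand_background")
    return TitrationSeries(
        ligand=series.ligand,
        conc=series.conc.copy(),
        fluorescence=f,
        protein_conc=series.protein_conc,
        co_ligand=series.co_ligand,
        co_ligand_conc=series.co_ligand_conc,
        added_volume=None if series.added_volume is None else series.added_volume.copy(),
        corrections=applied,
        label=series.label,
    )


def _bound_fraction_quadratic(L_tot, e_tot, kd):
    """[EL]/E_tot by the tight-binding quadratic root."""
    b = L_tot + e_tot + kd
    return (b - np.sqrt(b * b - 4 * L_tot * e_tot)) / (2 * e_tot)


def fit_binding_isotherm(
    series: TitrationSeries,
    model: str = "auto",
    depletion_threshold: float = 5.0,
) -> TitrationFit:
    """Fit a titration to the hyperbolic (or tight-binding quadratic) isotherm.

    ``model="auto"`` starts hyperbolic and switches to the quadratic
    (ligand-depletion) form when the receptor concentration exceeds
    KD_app / ``depletion_threshold``. Warns when the titration does not
    reach 2*KD (amplitude and KD then correlate strongly).
    """
    L, F = series.conc, series.fluorescence
    if L.size < 6:
        raise DegenerateDataError("need >= 6 titration points")
    warns: list[str] = []

    def _fit(use_quadratic: bool):
        def model_fn(p):
            kd = math.exp(min(p[0], 60))
            amp, base = p[1], p[2]
            if use_quadratic:
                frac = _bound_fraction_quadratic(L, series.protein_conc, kd)
            else:
                frac = L / (kd + L)
            return amp * frac + base

        def resid(p):
            return model_fn(p) - F

        span = F[-1] - F[0]
        best = None
        for kd0 in np.geomspace(max(np.min(L[L > 0], initial=0.1), 1e-3), 10 * np.max(L), 6):
            try:
                sol = least_squares(
                    resid, [math.log(kd0), span, F[0]], method="lm",
                    xtol=1e-14, ftol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("binding isotherm fit failed")
        return best

    use_quad = model == "quadratic"
    sol = _fit(use_quad)
    kd = math.exp(sol.x[0])
    if model == "auto" and series.protein_conc > kd / depletion_threshold:
        use_quad = True
        sol = _fit(True)
        kd = math.exp(sol.x[0])
        warns.append(
            "receptor concentration is significant against KD; "
            "ligand-depletion (quadratic) form used"
        )
    ssr = float(2 * sol.cost)
    dof = max(L.size - 3, 1)
    cov = np.linalg.pinv(sol.jac.T @ sol.jac) * ssr / dof
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    if np.max(L) < 2 * kd:
        msg = (
            f"titration reaches only {np.max(L) / kd:.2g}*KD; "
            "KD and amplitude are poorly separated"
        )
        warns.append(msg)
        warnings.warn(msg, IdentifiabilityWarning, stacklevel=2)
    return TitrationFit(
        kd_app=float(kd),
        kd_se=float(se[0] * kd),
        amplitude=float(sol.x[1]),
        baseline=float(sol.x[2]),
        model="quadratic" if use_quad else "hyperbolic",
        ssr=ssr,
        n_points=int(L.size),
        warnings=warns,
        residuals=np.asarray(sol.fun),
    )


def predict_apparent_kd(
    scheme: KineticScheme,
    params: RateParameterSet,
    ligand: str,
    co_ligand: str | None = None,
    co_ligand_conc: float = 0.0,
    enzyme_moiety: str = "E",
) -> float:
    """Model-predicted apparent KD (uM) of ``ligand`` at fixed free co-ligand.

    Scans the scheme's equilibrium over free ligand (the co-ligand is
    clamped as a bath) and returns the free-ligand concentration at
    half-maximal total ligand-bound enzyme. With no co-ligand this equals
    the intrinsic KD; at saturating co-ligand it equals
    KD_intrinsic/(1+K4) for the ternary loop-closure scheme.
    """
    if co_ligand_conc < 0:
        raise ValidationError("co_ligand_conc must be >= 0")
    lig_moiety = next(iter(scheme[ligand].moiety_counts))
    bound_species = [
        s.name
        for s in scheme.species
        if s.moiety_counts.get(lig_moiety, 0) and s.moiety_counts.get(enzyme_moiety, 0)
    ]
    e_tot = 1e-6  # trace enzyme: the scan probes the binding polynomial only

    def bound(free_L: float) -> float:
        clamp = {ligand: free_L}
        if co_ligand is not None:
            clamp[co_ligand] = co_ligand_conc
        eq = dynamics.equilibrium_state(
            scheme, params, {enzyme_moiety: e_tot}, clamped=clamp
        )
        return sum(eq[n] for n in bound_species)

    # saturation plateau: push free ligand far beyond any KD in the scheme
    kds = [
        params[r.kr_name] / params[r.kf_name]
        for r in scheme.reactions
        if params[r.kf_name] > 0 and len(r.reactants) == 2
    ]
    free_max = 1e4 * max(kds) if kds else 1e8
    return dynamics.halfsat_free_ligand(bound, free_max)


@dataclass
class SynergyReport:
    ligand: str
    kd_binary: float
    kd_ternary: float
    ratio_se: float
    amplitude_binary: float
    amplitude_ternary: float
    flag: str  # "synergistic" | "neutral" | "antagonistic"

    @property
    def ratio(self) -> float:
        """KD(binary)/KD(+co-ligand), recomputed; > 1 means synergy."""
        return self.kd_binary / self.kd_ternary

    def to_dict(self) -> dict:
        return {
            "ligand": self.ligand,
            "KD_binary_uM": self.kd_binary,
            "KD_ternary_uM": self.kd_ternary,
            "synergy_ratio": self.ratio,
            "ratio_se": self.ratio_se,
            "amplitude_binary": self.amplitude_binary,
            "amplitude_ternary": self.amplitude_ternary,
            "flag": self.flag,
        }


def synergy(
    fit_binary: TitrationFit,
    fit_ternary: TitrationFit,
    ligand: str,
    ligand_ternary: str | None = None,
) -> SynergyReport:
    """Compare apparent affinity with and without the co-ligand.

    Synergistic when the apparent KD drops (ratio > 1) beyond the
    propagated SE of the ratio; antagonistic when it rises beyond it.
    """
    if ligand_ternary is not None and ligand_ternary != ligand:
        raise ValidationError(
            f"titrations follow different ligands: {ligand!r} vs {ligand_ternary!r}"
        )
    ratio = fit_binary.kd_app / fit_ternary.kd_app
    rel = math.sqrt(
        (fit_binary.kd_se / fit_binary.kd_app) ** 2
        + (fit_ternary.kd_se / fit_ternary.kd_app) ** 2
    )
    se = ratio * rel
    if ratio - 1 > se:
        flag = "synergistic"
    elif 1 - ratio > se:
        flag = "antagonistic"
    else:
        flag = "neutral"
    return SynergyReport(
        ligand=ligand,
        kd_binary=fit_binary.kd_app,
        kd_ternary=fit_ternary.kd_app,
        ratio_se=se,
        amplitude_binary=fit_binary.amplitude,
        amplitude_ternary=fit_ternary.amplitude,
        flag=flag,
    )
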