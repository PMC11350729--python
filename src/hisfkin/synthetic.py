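"""Synthetic dataset generators with recorded ground truth.

Every generator emulates one of the reference experiment types at its
design - pseudo-first-order binding transients (0.5-40 uM ligand over 0.1 uM
enzyme), the 16-trace product-binding dataset, multiple/single-turnover
progress curves with a mixing-artifact burst, and equilibrium titrations -
adds i.i.d. Gaussian noise and the instrument dead time, and attaches a
``SyntheticTruth`` record so that every fitter can be validated by parameter
recovery. Averaging ``n_average`` shots (the instrument protocol) scales the
per-shot noise by 1/sqrt(n_average).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import dynamics
from .schemes import KineticScheme, RateParameterSet, Reaction, Species, build_scheme
from .titration import TitrationSeries
from .traces import ObservableModel, Trace, TraceSet
from .turnover import AssayConstants, ProgressCurve
from .util import ValidationError

__all__ = [
    "SyntheticTruth",
    "AmmoniaSpec",
    "free_ammonia",
    "default_induced_fit_params",
    "default_one_step_params",
    "default_ternary_params",
    "default_turnover_params",
    "turnover_scheme",
    "gen_transient_series",
    "gen_ternary_dataset",
    "gen_progress_curves",
    "gen_titration_series",
]

DEAD_TIME = 0.002  # s


@dataclass
class SyntheticTruth:
    """Provenance of a generated dataset: everything needed to regenerate it."""

    scheme_id: str
    params: RateParameterSet
    responses: dict[str, float]
    baseline: float
    sigma: float  # effective noise SD in signal units (after shot averaging)
    seed: int
    design: dict = field(default_factory=dict)
    artifact: dict | None = None
    dead_time: float = DEAD_TIME

    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "params": self.params.to_dict(),
            "responses": dict(self.responses),
            "baseline": self.baseline,
            "sigma": self.sigma,
            "seed": self.seed,
            "design": dict(self.design),
            "artifact": dict(self.artifact) if self.artifact else None,
            "dead_time": self.dead_time,
        }


@dataclass(frozen=True)
class AmmoniaSpec:
    """Total ammonium, pH and the ammonium pKa fixing the free-NH3 fraction."""

    total_mM: float = 100.0
    pH: float = 8.5
    pKa: float = 9.27  # 25 C

    def __post_init__(self):
        if not (0 < self.pH < 14 and 0 < self.pKa < 14):
            raise ValidationError("pH and pKa must lie in (0, 14)")
        if self.total_mM <= 0:
            raise ValidationError("total ammonium must be positive")


def free_ammonia(spec: AmmoniaSpec) -> float:
    """Free NH3 (mM) by Henderson-Hasselbalch: total/(1 + 10^(pKa - pH))."""
    return spec.total_mM / (1.0 + 10.0 ** (spec.pKa - spec.pH))


# ---------------------------------------------------------------------------
# Default "true" parameter sets (the experimental conditions being emulated)
# ---------------------------------------------------------------------------

def default_induced_fit_params() -> RateParameterSet:
    """Wild-type-like induced-fit binding: fast association (k1 = 10 uM^-1 s^-1,
    i.e. 1e7 M^-1 s^-1), KD1 = 10 uM, loop closing strongly favored
    (kconf = 40 s^-1 >> k-conf = 2 s^-1)."""
    return RateParameterSet({"k1": 10.0, "k-1": 100.0, "kconf": 40.0, "k-conf": 2.0})


def default_one_step_params() -> RateParameterSet:
    """Loop-variant-like one-step binding with kobs in the stopped-flow window
    (slope 0.05 uM^-1 s^-1 = 5e4 M^-1 s^-1, intercept 4 s^-1)."""
    return RateParameterSet({"k1": 0.05, "k-1": 4.0})


def default_ternary_params() -> RateParameterSet:
    """Product binding + loop closure: binary-complex formation within the
    dead time (k2*[I] and k3*[A] >> 500 s^-1 at the printed concentrations),
    loop closure near 50 s^-1. KD(ImGP) = 50 uM, KD(AICAR) = 200 uM,
    K4 = k4/k-4 ~ 4 (closed state favored)."""
    return RateParameterSet(
        {"k2": 100.0, "k-2": 5000.0, "k3": 100.0, "k-3": 20000.0, "k4": 50.0, "k-4": 12.0}
    )


def default_turnover_params() -> dict[str, float]:
    """Full catalytic cycle with chemistry 10x slower than every other step:
    kon = 10 uM^-1 s^-1, koff = 20 s^-1, kchem = 2.64 s^-1,
    krel = 26.4 s^-1, weak product rebinding 0.1 uM^-1 s^-1."""
    return {"kon": 10.0, "koff": 20.0, "kchem": 2.64, "krel": 26.4, "kpon": 0.1}


def turnover_scheme() -> KineticScheme:
    """Minimal turnover cycle E+S <=> ES -> EP <=> E+P.

    The S moiety tracks the substrate backbone through chemistry, so the
    chemical step is a moiety-conserving isomerization; the reverse chemical
    rate of 0 marks it irreversible.
    """
    return build_scheme(
        species=[
            Species("E", "enzyme-state", {"E": 1}),
            Species("S", "ligand", {"S": 1}),
            Species("ES", "complex", {"E": 1, "S": 1}),
            Species("EP", "complex", {"E": 1, "S": 1}),
            Species("P", "ligand", {"S": 1}),
        ],
        reactions=[
            Reaction(("E", "S"), ("ES",), "kon", "koff"),
            Reaction(("ES",), ("EP",), "kchem", "kchem_r"),
            Reaction(("EP",), ("E", "P"), "krel", "kpon"),
        ],
    )


# ---------------------------------------------------------------------------
# Transient series (PrFAR-binding-like)
# ---------------------------------------------------------------------------

def _noise(rng, sigma, shape):
    return rng.normal(0.0, sigma, shape) if sigma > 0 else np.zeros(shape)


def gen_transient_series(
    scheme_id: str = "INDUCED_FIT",
    params: RateParameterSet | None = None,
    concs: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0),
    enzyme_conc: float = 0.1,
    sigma: float = 0.0025,
    n_average: int = 5,
    seed: int = 0,
    n_points: int = 300,
    mode: str = "auto",
    dead_time: float = DEAD_TIME,
) -> tuple[TraceSet, SyntheticTruth]:
    """Pseudo-first-order binding transients over a ligand concentration series.

    One trace per ligand concentration (enzyme held constant); the signal is
    a CouA-like quench (complex species darker than free enzyme). ``sigma``
    is the per-shot noise SD; ``n_average`` recorded shots are averaged.
    """
    scheme = build_scheme(scheme_id)
    if params is None:
        params = (
            default_one_step_params()
            if scheme_id == "ONE_STEP"
            else default_induced_fit_params()
        )
    responses = {n: -1.0 for n in scheme.complex_species()}
    if "ES" in responses and "E*S" in responses:
        responses["ES"] = -0.3  # loop-open complex quenches less than closed
    baseline = 1.0
    sigma_eff = sigma / math.sqrt(max(n_average, 1))
    rng = np.random.default_rng(seed)

    traces = []
    for S in concs:
        rates = dynamics.relaxation_rates_pfo(
            scheme_id if scheme_id != "CONF_SELECTION" else scheme_id, params, S
        )
        slow = min(rates)
        t_end = max(8.0 / max(slow, 1e-6), 10 * dead_time)
        t_full = np.concatenate(
            [[0.0], np.geomspace(dead_time / 4, t_end, n_points)]
        )
        ratio = S / enzyme_conc
        use_pfo = mode == "pfo" or (mode == "auto" and ratio >= dynamics.PFO_EXCESS_RATIO)
        if use_pfo:
            states, A = dynamics.pfo_rate_matrix(scheme, params, {"S": S})
            x0 = np.zeros(len(states))
            x0[states.index("E")] = enzyme_conc
            X = dynamics.propagate_linear(A, x0, t_full)
            traj = {n: X[:, i] for i, n in enumerate(states)}
        else:
            traj = dynamics.integrate_scheme(
                scheme, params, {"E": enzyme_conc, "S": S}, t_full, method="BDF"
            )
        obs = ObservableModel(baseline, responses, dead_time)
        tr = dynamics.project_observable(
            t_full, traj, obs, totals={"E": enzyme_conc, "S": S},
            label=f"{scheme_id}:S={S:g}uM",
        )
        tr.signal = tr.signal + _noise(rng, sigma_eff, tr.signal.shape)
        tr.sigma = sigma_eff
        tr.mix = {"syringes": [{"E": 2 * enzyme_conc}, {"S": 2 * S}], "fractions": [0.5, 0.5]}
        traces.append(tr)

    truth = SyntheticTruth(
        scheme_id, params, responses, baseline, sigma_eff, seed,
        design={"concs_uM": list(concs), "enzyme_uM": enzyme_conc, "n_average": n_average},
        dead_time=dead_time,
    )
    return TraceSet(traces, name=f"transients:{scheme_id}"), truth


def gen_secondary_plot(
    scheme_id: str = "INDUCED_FIT",
    params: RateParameterSet | None = None,
    concs: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0),
    noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, RateParameterSet]:
    """kobs-vs-concentration points with multiplicative Gaussian noise.

    The noiseless kobs are the slow PFO relaxation rates of the generating
    scheme; reported SEs equal the noise SD (noise_frac * kobs).
    """
    if params is None:
        params = (
            default_one_step_params()
            if scheme_id == "ONE_STEP"
            else default_induced_fit_params()
        )
    rng = np.random.default_rng(seed)
    rows = []
    for S in concs:
        k = min(dynamics.relaxation_rates_pfo(scheme_id, params, S))
        se = noise_frac * k
        rows.append((S, k + rng.normal(0, se) if se > 0 else k, se))
    return np.array(rows), params


# ---------------------------------------------------------------------------
# 16-trace ternary product-binding dataset
# ---------------------------------------------------------------------------

TERNARY_RESPONSES = {"EI": -6.0, "EA": -4.0, "EIA": -8.0, "EIA*": -20.0}
TERNARY_BASELINE = 2.0


def ternary_trace_designs(enzyme_conc: float = 0.05) -> list[dict]:
    """The 16 mixing designs: free enzyme vs one ligand, vs both, and each
    preformed binary complex vs the second ligand (final concentrations, uM)."""
    e = enzyme_conc
    designs = []
    for I in (100.0, 250.0):
        designs.append({"label": f"E+I{I:g}", "syr1": {"E": 2 * e}, "syr2": {"I": 2 * I}})
    for A in (250.0, 1000.0):
        designs.append({"label": f"E+A{A:g}", "syr1": {"E": 2 * e}, "syr2": {"A": 2 * A}})
    for I in (100.0, 250.0):
        for A in (250.0, 1000.0):
            designs.append(
                {"label": f"E+I{I:g}+A{A:g}", "syr1": {"E": 2 * e}, "syr2": {"I": 2 * I, "A": 2 * A}}
            )
    for A in (250.0, 500.0, 750.0, 1000.0):
        designs.append(
            {"label": f"EI+A{A:g}", "syr1": {"E": 2 * e, "I": 2 * 400.0}, "syr2": {"A": 2 * A}}
        )
    for I in (100.0, 150.0, 200.0, 250.0):
        designs.append(
            {"label": f"EA+I{I:g}", "syr1": {"E": 2 * e, "A": 2 * 1250.0}, "syr2": {"I": 2 * I}}
        )
    return designs


def gen_ternary_dataset(
    params: RateParameterSet | None = None,
    enzyme_conc: float = 0.05,
    sigma_frac: float = 0.01,
    seed: int = 0,
    n_points: int = 1000,
    t_end: float = 0.15,
    dead_time: float = DEAD_TIME,
) -> tuple[TraceSet, SyntheticTruth]:
    """The 16-trace stopped-flow dataset probing product binding + loop closure.

    Binary-complex formation completes within the dead time at these ligand
    concentrations; the observable relaxation is dominated by the
    loop-closure step. ``sigma_frac`` scales a common absolute noise SD
    (sigma_frac * median trace amplitude), mimicking instrument-level noise
    that does not know each trace's amplitude.
    """
    params = params or default_ternary_params()
    scheme = build_scheme("TERNARY")
    rng = np.random.default_rng(seed)
    t_full = np.concatenate([[0.0], np.geomspace(dead_time / 4, t_end, n_points + 49)])

    clean = []
    for d in ternary_trace_designs(enzyme_conc):
        mix = {"syringes": [d["syr1"], d["syr2"]], "fractions": [0.5, 0.5]}
        totals = {m: 0.0 for m in scheme.moieties}
        for syr, f in zip(mix["syringes"], mix["fractions"]):
            for n, c in syr.items():
                for m, cnt in scheme[n].moiety_counts.items():
                    totals[m] += f * cnt * c
        totals = {m: v for m, v in totals.items() if v > 0}
        dummy = Trace(
            time=t_full, signal=np.zeros(t_full.size),
            totals=totals, mix=mix, dead_time=dead_time, label=d["label"],
        )
        from .globalfit import simulate_trace  # deferred: avoid import cycle

        X = simulate_trace(scheme, params, dummy, list(TERNARY_RESPONSES), mode="auto")
        sig_full = TERNARY_BASELINE + X @ np.array(
            [TERNARY_RESPONSES[n] for n in TERNARY_RESPONSES]
        )
        clean.append((d["label"], totals, mix, sig_full))

    amps = [np.ptp(sig[t_full >= dead_time]) for _, _, _, sig in clean]
    sigma = sigma_frac * float(np.median([a for a in amps if a > 0]))

    traces = []
    for label, totals, mix, sig_full in clean:
        mask = t_full >= dead_time
        t = t_full[mask]
        y = sig_full[mask] + _noise(rng, sigma, mask.sum())
        pre = abs(np.interp(dead_time, t_full, sig_full) - sig_full[0])
        tot = abs(sig_full[-1] - sig_full[0])
        traces.append(
            Trace(
                time=t, signal=y, totals=totals, mix=mix, dead_time=dead_time,
                sigma=sigma, label=label,
                dead_time_obscured=bool(tot > 0 and pre / tot >= 0.86),
            )
        )
    truth = SyntheticTruth(
        "TERNARY", params, dict(TERNARY_RESPONSES), TERNARY_BASELINE, sigma, seed,
        design={"enzyme_uM": enzyme_conc, "n_traces": len(traces), "t_end_s": t_end},
        dead_time=dead_time,
    )
    return TraceSet(traces, name="ternary16"), truth


# ---------------------------------------------------------------------------
# Progress curves (multiple/single turnover)
# ---------------------------------------------------------------------------

def gen_progress_curves(
    mode: str,
    s0_list: tuple[float, ...] | None = None,
    params: dict[str, float] | None = None,
    e_tot: float | None = None,
    sigma: float = 0.0005,
    burst: dict | None = None,
    seed: int = 0,
    n_points: int = 400,
    constants: AssayConstants = AssayConstants(),
) -> tuple[list[ProgressCurve], SyntheticTruth]:
    """Turnover progress curves from the minimal catalytic cycle.

    multiple_turnover: 0.1 uM enzyme vs excess substrate, A300 decrease,
    optional additive mixing-artifact burst (defaults amp 0.05 A at
    30 s^-1, chemistry-independent). single_turnover: 20 uM enzyme over
    2.5-10 uM substrate. control: chemistry switched off (no ammonia), so
    the only signal change is the artifact.
    """
    if mode not in ("multiple_turnover", "single_turnover", "control"):
        raise ValidationError(f"unknown mode {mode!r}")
    p = dict(default_turnover_params() if params is None else params)
    if mode == "control":
        p["kchem"] = 0.0
    p.setdefault("kchem_r", 0.0)
    if e_tot is None:
        e_tot = 20.0 if mode == "single_turnover" else 0.1
    if s0_list is None:
        s0_list = (2.5, 5.0, 10.0) if mode == "single_turnover" else (1.0, 2.0, 4.0, 8.0, 16.0, 40.0)
    if burst is None and mode in ("multiple_turnover", "control"):
        burst = {"amp": 0.05, "rate": 30.0}
    scheme = turnover_scheme()
    rp = RateParameterSet(p)
    rng = np.random.default_rng(seed)
    deps = constants.d_eps300_uM * constants.path_cm

    curves = []
    for s0 in s0_list:
        if mode == "single_turnover":
            kcat_eff = p["kchem"] if p["kchem"] > 0 else 1.0
            t_end = 8.0 / kcat_eff
        else:
            vmax = p["kchem"] * p["krel"] / (p["kchem"] + p["krel"]) * e_tot if p["kchem"] else 1.0
            t_end = 0.6 * s0 / max(vmax, 1e-9) if p["kchem"] else 10.0
        t = np.linspace(0.0, t_end, n_points)
        traj = dynamics.integrate_scheme(
            scheme, rp, {"E": e_tot, "S": s0}, t, method="BDF"
        )
        a300 = deps * (traj["S"] + traj["ES"]) + 0.05  # PrFAR-linked absorbance + offset
        if burst:
            a300 = a300 + burst["amp"] * np.exp(-burst["rate"] * t)
        a300 = a300 + _noise(rng, sigma, t.shape)
        curves.append(
            ProgressCurve(
                time=t, values=a300, e_tot=e_tot, s0=s0, mode=mode,
                ammonia_present=(mode != "control"), unit="A300",
                label=f"{mode}:S0={s0:g}uM",
            )
        )
    truth = SyntheticTruth(
        "TURNOVER", rp, {"S+ES": deps}, 0.05, sigma, seed,
        design={"mode": mode, "S0_uM": list(s0_list), "E_uM": e_tot},
        artifact=burst,
        dead_time=0.0,
    )
    return curves, truth


# ---------------------------------------------------------------------------
# Equilibrium titrations
# ---------------------------------------------------------------------------

def gen_titration_series(
    scheme: KineticScheme | None = None,
    params: RateParameterSet | None = None,
    ligand: str = "A",
    concs: tuple[float, ...] | None = None,
    protein_conc: float = 1.0,
    co_ligand: str | None = None,
    co_ligand_conc: float = 0.0,
    responses: dict[str, float] | None = None,
    baseline: float = TERNARY_BASELINE,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TitrationSeries, SyntheticTruth]:
    """Equilibrium titration: fluorescence vs total ligand at fixed protein.

    Signals come from the scheme's mass-action equilibrium at every point
    (ligand totals, not free concentrations, as in the experiment), so
    receptor depletion is faithfully present in the data.
    """
    scheme = scheme or build_scheme("TERNARY")
    params = params or default_ternary_params()
    responses = responses or TERNARY_RESPONSES
    lig_moiety = next(iter(scheme[ligand].moiety_counts))
    if concs is None:
        kd = min(
            params[r.kr_name] / params[r.kf_name]
            for r in scheme.reactions
            if ligand in r.reactants and params[r.kf_name] > 0
        )
        concs = tuple(np.concatenate([[0.0], np.geomspace(kd / 20, 20 * kd, 11)]))
    co_moiety = next(iter(scheme[co_ligand].moiety_counts)) if co_ligand else None

    rng = np.random.default_rng(seed)
    f = []
    for L in concs:
        totals = {"E": protein_conc, lig_moiety: L}
        if co_moiety:
            totals[co_moiety] = co_ligand_conc
        eq = dynamics.equilibrium_state(scheme, params, totals)
        sig = baseline + sum(
            r * eq.get(n, 0.0) for n, r in responses.items()
        )
        f.append(sig)
    f = np.array(f) + _noise(rng, sigma, len(concs))
    series = TitrationSeries(
        ligand=ligand,
        conc=np.array(concs),
        fluorescence=f,
        protein_conc=protein_conc,
        co_ligand=co_ligand,
        co_ligand_conc=co_ligand_conc,
        corrections=["dilution", "ligand_background"],  # generated post-correction
        label=f"titration:{ligand}" + (f"+{co_ligand}{co_ligand_conc:g}" if co_ligand else ""),
    )
    truth = SyntheticTruth(
        scheme.builtin_id, params, dict(responses), baseline, sigma, seed,
        design={
            "ligand": ligand, "concs_uM": list(concs), "protein_uM": protein_conc,
            "co_ligand": co_ligand, "co_ligand_uM": co_ligand_conc,
        },
        dead_time=0.0,
    )
    return series, truth
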