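"""Simultaneous (global) fitting of multi-trace datasets to a kinetic scheme.

The engine simulates every trace by direct numerical integration of the
scheme's mass-action equations (an exact linear propagator is used in the
ligand-excess regime), while per-trace response coefficients and offsets are
solved exactly by linear least squares at every iteration (variable
projection). Only the shared rate constants are optimized nonlinearly, in
log space, which enforces positivity and conditions the search.

Mixing experiments are described per trace by syringe compositions: each
syringe is pre-equilibrated under the candidate parameters, the contents are
mixed, and the relaxation to the new equilibrium is simulated - the same
treatment classic global-fitting programs (DynaFit, KinTek) apply to
stopped-flow data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import dynamics
from .schemes import KineticScheme, RateParameterSet
from .traces import Trace, TraceSet
from .util import FitError, IdentifiabilityWarning, ValidationError, aicc

__all__ = [
    "GlobalFitProblem",
    "GlobalFitResult",
    "global_fit",
    "bootstrap_ci",
    "compare_models",
    "simulate_trace",
]

SE_FLAG_RATIO = 10.0  # SE/value above this marks a structurally weak parameter


@dataclass
class GlobalFitProblem:
    traces: TraceSet
    scheme: KineticScheme
    params: dict[str, dict]  # name -> {"value", "vary", "min", "max"}
    observable_species: list[str] | None = None  # default: all complex species
    weighting: str = "uniform"  # "uniform" | "sigma" (per-trace 1/sigma)
    mode: str = "auto"  # "auto" | "pfo" | "ode"
    enzyme_moiety: str = "E"
    # "shared": one response coefficient per species for the whole dataset
    # (one fluorophore, one instrument gain) with per-trace offsets;
    # "per_trace": every trace gets its own coefficients.
    response_sharing: str = "shared"

    def __post_init__(self):
        if len(self.traces) < 1:
            raise ValidationError("need at least one trace")
        if self.observable_species is None:
            self.observable_species = self.scheme.complex_species()
        missing = set(self.scheme.rate_names()) - set(self.params)
        if missing:
            raise ValidationError(f"missing rate parameters: {sorted(missing)}")
        if not any(p.get("vary", True) for p in self.params.values()):
            raise ValidationError("at least one parameter must be free")
        for name, p in self.params.items():
            if p.get("min", 0.0) < 0:
                raise ValidationError(f"{name}: rate constants are bounded below by 0")
        for tr in self.traces:
            for m in tr.totals:
                if m not in self.scheme.moieties:
                    raise ValidationError(
                        f"trace {tr.label!r}: moiety {m!r} not in scheme"
                    )

    def free_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.get("vary", True)]

    def make_params(self, free_values: dict[str, float] | None = None) -> RateParameterSet:
        vals = {n: p["value"] for n, p in self.params.items()}
        if free_values:
            vals.update(free_values)
        return RateParameterSet(vals)


def _mix_initial_state(
    scheme: KineticScheme,
    params: RateParameterSet,
    trace: Trace,
    enzyme_moiety: str,
    pfo_ok: bool,
    g_cache: "np.ndarray | None" = None,
) -> dict[str, float]:
    """Post-mix per-species concentrations from syringe compositions.

    Each syringe is equilibrated before mixing; syringes without enzyme are
    taken as-is. In the ligand-excess regime the enzyme partition uses the
    closed-form fixed-free-ligand weights so that fitting stays fast.
    """
    if trace.mix is None:
        init = trace.initial_state
        if init is None:
            raise ValidationError(
                f"trace {trace.label!r} has neither mix nor initial_species"
            )
        return dict(init)
    syringes = trace.mix["syringes"]
    fracs = trace.mix.get("fractions") or [1.0 / len(syringes)] * len(syringes)
    state = {n: 0.0 for n in scheme.names}
    for syr, f in zip(syringes, fracs):
        has_enzyme = any(
            scheme[n].moiety_counts.get(enzyme_moiety, 0) for n in syr if syr[n] > 0
        )
        if not has_enzyme:
            eq = dict(syr)
        else:
            totals = {m: 0.0 for m in scheme.moieties}
            for n, c in syr.items():
                for m, cnt in scheme[n].moiety_counts.items():
                    totals[m] += cnt * c
            if pfo_ok:
                free_lig = {
                    s.name: totals.get(next(iter(s.moiety_counts)), 0.0)
                    for s in scheme.species
                    if s.role == "ligand"
                }
                wts = dynamics.pfo_equilibrium_weights(
                    scheme, params, free_lig, enzyme_moiety, G=g_cache
                )
                e_tot = totals[enzyme_moiety]
                eq = {k: v for k, v in free_lig.items()}
                for n, w in wts.items():
                    eq[n] = w * e_tot
            else:
                eq = dynamics.equilibrium_state(scheme, params, totals)
        for n, c in eq.items():
            state[n] = state.get(n, 0.0) + f * c
    return state


def simulate_trace(
    scheme: KineticScheme,
    params: RateParameterSet,
    trace: Trace,
    observable_species: list[str],
    enzyme_moiety: str = "E",
    mode: str = "auto",
    g_cache: "np.ndarray | None" = None,
) -> np.ndarray:
    """Concentrations of the observable species at the trace's time points.

    Returns an array of shape (n_times, n_observable_species). ``mode``
    selects full ODE integration ("ode"), the fixed-free-ligand linear
    propagator ("pfo"), or automatic choice by excess ratio ("auto").
    """
    ratio = dynamics.pfo_excess_ratio(trace.totals, enzyme_moiety)
    if mode == "auto":
        use_pfo = ratio >= dynamics.PFO_EXCESS_RATIO
    elif mode == "pfo":
        if ratio < dynamics.PFO_EXCESS_RATIO:
            warnings.warn(
                f"trace {trace.label!r}: excess ratio {ratio:.3g} < "
                f"{dynamics.PFO_EXCESS_RATIO:g}; pseudo-first-order treatment is "
                "unreliable - the full ODE is recommended",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        use_pfo = True
    else:
        use_pfo = False

    state = _mix_initial_state(scheme, params, trace, enzyme_moiety, use_pfo, g_cache)
    if use_pfo:
        free_lig = {
            s.name: state.get(s.name, 0.0)
            for s in scheme.species
            if s.role == "ligand"
        }
        states, A = dynamics.pfo_rate_matrix(scheme, params, free_lig, enzyme_moiety)
        x0 = np.array([state.get(n, 0.0) for n in states])
        X = dynamics.propagate_linear(A, x0, trace.time)
        idx = [states.index(n) for n in observable_species]
        return X[:, idx]
    traj = dynamics.integrate_scheme(
        scheme, params, state, trace.time, method="BDF"
    )
    return np.column_stack([traj[n] for n in observable_species])


@dataclass(eq=False)
class GlobalFitResult:
    params: dict[str, float]
    stderr: dict[str, float]
    free_names: list[str]
    fixed: dict[str, float]
    # linear coefficients: per-trace offsets first, then response
    # coefficients (shared per species, or per trace depending on the
    # problem's response_sharing)
    responses: np.ndarray
    unidentifiable: list[str]
    ssr: float
    aicc: float
    n_obs: int
    n_free_total: int
    residuals: list[np.ndarray] = field(repr=False, default=None)
    fitted: list[np.ndarray] = field(repr=False, default=None)
    covariance: np.ndarray | None = field(repr=False, default=None)
    convergence: dict = field(default_factory=dict)
    dataset_hash: str = ""
    observable_species: list[str] = field(default_factory=list)

    def kd(self, kf_name: str, kr_name: str) -> float:
        """Dissociation constant recomputed from the fitted rate constants."""
        return self.params[kr_name] / self.params[kf_name]

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "free": list(self.free_names),
            "unidentifiable": list(self.unidentifiable),
            "ssr": self.ssr,
            "aicc": self.aicc,
            "n_obs": self.n_obs,
            "n_free_total": self.n_free_total,
            "convergence": {
                k: v for k, v in self.convergence.items() if np.isscalar(v)
            },
            "dataset_hash": self.dataset_hash,
        }


def _trace_weights(problem: GlobalFitProblem) -> list[float]:
    if problem.weighting == "uniform":
        return [1.0] * len(problem.traces)
    if problem.weighting == "sigma":
        return [
            1.0 / tr.sigma if tr.sigma and tr.sigma > 0 else 1.0
            for tr in problem.traces
        ]
    raise ValidationError(f"unknown weighting {problem.weighting!r}")


def _all_pfo(problem) -> bool:
    if problem.mode == "ode":
        return False
    if problem.mode == "pfo":
        return True
    return all(
        dynamics.pfo_excess_ratio(tr.totals, problem.enzyme_moiety)
        >= dynamics.PFO_EXCESS_RATIO
        for tr in problem.traces
    )


def _batch_pfo_trajectories(problem, params, g_cache):
    """Observable-species trajectories for every trace, with one batched
    eigendecomposition over all traces (they share the scheme, so the
    enzyme-state subsystems have identical structure)."""
    scheme = problem.scheme
    mats, x0s = [], []
    states = None
    for tr in problem.traces:
        state = _mix_initial_state(
            scheme, params, tr, problem.enzyme_moiety, True, g_cache
        )
        free_lig = {
            s.name: state.get(s.name, 0.0) for s in scheme.species if s.role == "ligand"
        }
        states, A = dynamics.pfo_rate_matrix(
            scheme, params, free_lig, problem.enzyme_moiety
        )
        mats.append(A)
        x0s.append([state.get(n, 0.0) for n in states])
    idx = [states.index(n) for n in problem.observable_species]
    x0s = np.array(x0s)
    masks = [dynamics.reachable_states(A, x) for A, x in zip(mats, x0s)]
    full = [b for b, m in enumerate(masks) if m.all()]
    out: list = [None] * len(mats)
    if full:
        w, V = np.linalg.eig(np.array([mats[b] for b in full]))
        c = np.linalg.solve(V, x0s[full].astype(complex)[..., None])[..., 0]
        for i, b in enumerate(full):
            E = np.exp(np.outer(w[i], problem.traces[b].time))
            X = np.real((V[i] @ (c[i][:, None] * E)).T)
            out[b] = X[:, idx]
    for b, m in enumerate(masks):
        if out[b] is None:
            X = dynamics.propagate_linear(mats[b], x0s[b], problem.traces[b].time)
            out[b] = X[:, idx]
    return out


def _linear_design(problem, params):
    """Weighted stacked design matrix of the linear (response) subproblem.

    Columns: one offset per trace, then either one shared response per
    observable species (default) or per-trace responses.
    """
    n_tr = len(problem.traces)
    n_sp = len(problem.observable_species)
    tw = _trace_weights(problem)
    lens = [len(tr) for tr in problem.traces]
    n_obs = sum(lens)
    shared = problem.response_sharing == "shared"
    n_lin = n_tr + n_sp if shared else n_tr * (1 + n_sp)
    D = np.zeros((n_obs, n_lin))
    try:
        g_cache = dynamics._formation_potentials(problem.scheme, params)
    except Exception:
        g_cache = None
    Xs = None
    if _all_pfo(problem):
        Xs = _batch_pfo_trajectories(problem, params, g_cache)
    row = 0
    for j, (tr, w) in enumerate(zip(problem.traces, tw)):
        if Xs is not None:
            X = Xs[j]
        else:
            X = simulate_trace(
                problem.scheme, params, tr, problem.observable_species,
                problem.enzyme_moiety, problem.mode, g_cache=g_cache,
            )
        D[row : row + lens[j], j] = w
        if shared:
            D[row : row + lens[j], n_tr:] = X * w
        else:
            c0 = n_tr + j * n_sp
            D[row : row + lens[j], c0 : c0 + n_sp] = X * w
        row += lens[j]
    return D


def _eval_residuals(problem, theta_log, free, signals, tw):
    """Stacked weighted residuals + linear solution at the given log10 rates."""
    params = problem.make_params(
        {n: 10.0**v for n, v in zip(free, theta_log)}
    )
    D = _linear_design(problem, params)
    yw = np.concatenate([y * w for y, w in zip(signals, tw)])
    # normal equations are ~5x faster than lstsq here; fall back to the
    # minimum-norm solution when the design is (near-)singular
    try:
        beta = np.linalg.solve(D.T @ D, D.T @ yw)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(D, yw, rcond=None)
    fitw = D @ beta
    res = fitw - yw
    fits = []
    i = 0
    for tr, w in zip(problem.traces, tw):
        fits.append(fitw[i : i + len(tr)] / w)
        i += len(tr)
    return res, beta, fits


def global_fit(
    problem: GlobalFitProblem,
    n_starts: int = 5,
    seed: int = 0,
    multistart_span: float = 100.0,
    xtol: float = 1e-12,
    max_nfev: int | None = None,
) -> GlobalFitResult:
    """Fit shared rate constants to all traces simultaneously.

    Multistart (``n_starts`` log-uniform perturbations of the initial values
    within ``multistart_span``-fold, seeded) guards against local minima;
    the best-SSR solution is polished and reported with covariance-based
    standard errors. Parameters with SE/value > 10 are flagged as
    unidentifiable rather than reported as precise.
    """
    if len(problem.traces) < 2:
        warnings.warn(
            "fewer than 2 traces: most rate constants will not be identifiable",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    free = problem.free_names()
    signals = [tr.signal for tr in problem.traces]
    tw = _trace_weights(problem)
    lo = np.array(
        [math.log10(max(problem.params[n].get("min", 0.0), 1e-12)) for n in free]
    )
    hi = np.array(
        [math.log10(problem.params[n].get("max", math.inf)) for n in free]
    )
    x_init = np.array([math.log10(problem.params[n]["value"]) for n in free])

    rng = np.random.default_rng(seed)
    span = math.log10(multistart_span)
    starts = [x_init]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.clip(x_init + rng.uniform(-span, span, len(free)), lo, hi))

    def fun(theta):
        try:
            r, _, _ = _eval_residuals(problem, theta, free, signals, tw)
            return r
        except Exception:
            return np.full(sum(len(tr) for tr in problem.traces), 1e6)

    best = None
    history = []
    for x0 in starts:
        sol = least_squares(
            fun, x0, bounds=(lo, hi), xtol=xtol, ftol=xtol, gtol=1e-14,
            x_scale="jac", max_nfev=max_nfev,
        )
        history.append(2 * sol.cost)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("global fit did not converge from any start")

    theta = best.x
    r, beta, fits = _eval_residuals(problem, theta, free, signals, tw)
    ssr = float(r @ r)
    values = {n: 10.0**v for n, v in zip(free, theta)}
    params_all = problem.make_params(values)

    n_obs = sum(len(tr) for tr in problem.traces)
    D_opt = _linear_design(problem, params_all)
    n_lin = D_opt.shape[1]
    p_total = len(free) + n_lin

    # full covariance: numeric d(res)/d(log10 k) columns + analytic linear block
    J = np.zeros((n_obs, len(free) + n_lin))
    h = 1e-6
    for j in range(len(free)):
        tp = theta.copy()
        tp[j] += h
        rp, _, _ = _eval_residuals(problem, tp, free, signals, tw)
        tm = theta.copy()
        tm[j] -= h
        rm, _, _ = _eval_residuals(problem, tm, free, signals, tw)
        J[:, j] = (rp - rm) / (2 * h)
    J[:, len(free) :] = D_opt
    dof = max(n_obs - p_total, 1)
    cov = np.linalg.pinv(J.T @ J) * ssr / dof
    se_log = np.sqrt(np.clip(np.diag(cov)[: len(free)], 0, None))
    stderr = {
        n: float(math.log(10.0) * values[n] * s) for n, s in zip(free, se_log)
    }
    # structural unidentifiability: rate parameters with a large component in
    # the near-null space of the Jacobian (SEs from a pseudo-inverse are
    # silently small there, so the SE/value rule alone would miss them)
    _, sing, Vt = np.linalg.svd(J, full_matrices=False)
    null_rows = sing < 1e-8 * max(sing[0], 1e-300)
    null_frac = (Vt[null_rows, : len(free)] ** 2).sum(axis=0) if null_rows.any() else (
        np.zeros(len(free))
    )
    unident = [
        n
        for j, n in enumerate(free)
        if not math.isfinite(stderr[n])
        or stderr[n] > SE_FLAG_RATIO * values[n]
        or null_frac[j] > 0.3
    ]
    if unident:
        warnings.warn(
            f"parameters not constrained by the data: {unident}",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    residuals = []
    i = 0
    for tr in problem.traces:
        residuals.append(np.asarray(r[i : i + len(tr)]))
        i += len(tr)

    return GlobalFitResult(
        params=dict(params_all.values),
        stderr=stderr,
        free_names=free,
        fixed={n: p["value"] for n, p in problem.params.items() if n not in free},
        responses=beta,
        unidentifiable=unident,
        ssr=ssr,
        aicc=aicc(ssr, n_obs, p_total),
        n_obs=n_obs,
        n_free_total=p_total,
        residuals=residuals,
        fitted=fits,
        covariance=cov,
        convergence={
            "nfev": int(best.nfev),
            "status": int(best.status),
            "multistart_ssr": history,
        },
        dataset_hash=problem.traces.data_hash(),
        observable_species=list(problem.observable_species),
    )


def bootstrap_ci(
    problem: GlobalFitProblem,
    result: GlobalFitResult,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    max_nfev: int = 200,
) -> dict:
    """Residual-resampling bootstrap percentile intervals for the free rates.

    Residuals are resampled with replacement within each trace, added to the
    fitted curves, and the fit is repeated from the point estimate. Errors in
    more than 20% of the replicates abort the analysis.
    """
    if n_boot < 100:
        warnings.warn(
            "n_boot < 100: intervals are reported but poorly resolved",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    free = result.free_names
    tw = _trace_weights(problem)
    x_hat = np.array([math.log10(result.params[n]) for n in free])
    lo = np.array(
        [math.log10(max(problem.params[n].get("min", 0.0), 1e-12)) for n in free]
    )
    hi = np.array([math.log10(problem.params[n].get("max", math.inf)) for n in free])

    samples = {n: [] for n in free}
    n_fail = 0
    for _ in range(n_boot):
        y_boot = []
        for fit, res in zip(result.fitted, result.residuals):
            idx = rng.integers(0, len(res), len(res))
            y_boot.append(fit + res[idx])

        def fun(theta):
            try:
                r, _, _ = _eval_residuals(problem, theta, free, y_boot, tw)
                return r
            except Exception:
                return np.full(result.n_obs, 1e6)

        try:
            sol = least_squares(
                fun, np.clip(x_hat, lo, hi), bounds=(lo, hi),
                xtol=1e-10, ftol=1e-10, x_scale="jac", max_nfev=max_nfev,
            )
            if not np.all(np.isfinite(sol.x)):
                raise FitError("non-finite bootstrap solution")
            for n, v in zip(free, sol.x):
                samples[n].append(10.0**v)
        except Exception:
            n_fail += 1
    if n_fail > 0.2 * n_boot:
        raise FitError(f"bootstrap non-convergence in {n_fail}/{n_boot} replicates")

    intervals = {}
    for n in free:
        s = np.array(samples[n])
        intervals[n] = (
            float(np.percentile(s, 100 * alpha / 2)),
            float(np.percentile(s, 100 * (1 - alpha / 2))),
        )
    return {
        "intervals": intervals,
        "samples": {n: np.array(v) for n, v in samples.items()},
        "n_fail": n_fail,
        "n_boot": n_boot,
        "alpha": alpha,
    }


def compare_models(result_a: GlobalFitResult, result_b: GlobalFitResult) -> dict:
    """AICc-based discrimination between two global fits of the same dataset."""
    if result_a.dataset_hash != result_b.dataset_hash:
        raise ValidationError("results were fitted to different datasets")
    delta = result_a.aicc - result_b.aicc
    if abs(delta) < 2.0:
        preferred = "indistinguishable"
    else:
        preferred = "A" if delta < 0 else "B"
    return {
        "delta_aicc": float(delta),
        "preferred": preferred,
        "aicc_a": result_a.aicc,
        "aicc_b": result_b.aicc,
    }
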