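"""Mass-action dynamics: ODE integration, equilibria and relaxation rates.

The integrator is a stiff-capable implicit method (``scipy.integrate.solve_ivp``
with BDF/LSODA) with an analytic Jacobian assembled from the reaction list.
Defaults rtol=1e-8, atol=1e-12 uM keep conserved totals constant to better
than 1e-8 relative over the time spans used here.

Two pseudo-first-order (PFO) shortcuts are provided for the ligand-excess
regime (excess ratio >= PFO_EXCESS_RATIO = 10):

* ``integrate_scheme(..., clamped=...)`` holds selected species constant, so
  a one-step trace can be checked against the textbook closed form
  ``[ES](t) = E0*S0/(KD+S0)*(1-exp(-(k1*S0+k-1)*t))`` to solver precision;
* ``pfo_rate_matrix`` builds the linear rate matrix of the enzyme-state
  subsystem at fixed free-ligand concentrations, which ``propagate_linear``
  solves exactly by eigendecomposition. This is what makes global fitting of
  large ligand-excess datasets fast.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig as dense_eig
from scipy.optimize import brentq, root

from .schemes import KineticScheme, RateParameterSet
from .traces import ObservableModel, Trace
from .util import EquilibriumError, IntegrationError, ValidationError

PFO_EXCESS_RATIO = 10.0  # ligand/enzyme excess at which PFO shortcuts apply

__all__ = [
    "integrate_scheme",
    "equilibrium_state",
    "relaxation_rates_pfo",
    "kobs_hyperbolic",
    "project_observable",
    "pfo_rate_matrix",
    "propagate_linear",
    "pfo_excess_ratio",
    "PFO_EXCESS_RATIO",
]


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def _compiled_reactions(scheme: KineticScheme, params: RateParameterSet):
    """Per reaction: (reactant indices, product indices, kf, kr)."""
    out = []
    for rxn in scheme.reactions:
        ri = [scheme.index(n) for n in rxn.reactants]
        pi = [scheme.index(n) for n in rxn.products]
        out.append((ri, pi, params[rxn.kf_name], params[rxn.kr_name]))
    return out


def make_rhs(scheme: KineticScheme, params: RateParameterSet, clamped: set[str] = frozenset()):
    """Return (rhs, jac) callables for solve_ivp; clamped species stay fixed."""
    compiled = _compiled_reactions(scheme, params)
    n = len(scheme.species)
    clamp_idx = np.array([scheme.index(s) for s in clamped], dtype=int)

    def rhs(t, x):
        dx = np.zeros(n)
        for ri, pi, kf, kr in compiled:
            vf = kf
            for i in ri:
                vf *= x[i]
            vr = kr
            for i in pi:
                vr *= x[i]
            v = vf - vr
            for i in ri:
                dx[i] -= v
            for i in pi:
                dx[i] += v
        if clamp_idx.size:
            dx[clamp_idx] = 0.0
        return dx

    def jac(t, x):
        J = np.zeros((n, n))
        for ri, pi, kf, kr in compiled:
            # forward flux derivative w.r.t. each reactant
            for k, ik in enumerate(ri):
                d = kf
                for j, ij in enumerate(ri):
                    if j != k:
                        d *= x[ij]
                for i in ri:
                    J[i, ik] -= d
                for i in pi:
                    J[i, ik] += d
            for k, ik in enumerate(pi):
                d = kr
                for j, ij in enumerate(pi):
                    if j != k:
                        d *= x[ij]
                for i in ri:
                    J[i, ik] += d
                for i in pi:
                    J[i, ik] -= d
        if clamp_idx.size:
            J[clamp_idx, :] = 0.0
        return J

    return rhs, jac


def integrate_scheme(
    scheme: KineticScheme,
    params: RateParameterSet,
    initial: dict[str, float],
    time_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    clamped: set[str] | frozenset = frozenset(),
    method: str = "LSODA",
) -> dict[str, np.ndarray]:
    """Integrate the scheme from per-species initial concentrations (uM).

    Returns {species: concentration array} on ``time_grid`` (which may start
    at 0 or later; integration always starts at t=0). Raises
    ``IntegrationError`` on solver failure (carrying the last successful
    time) or if concentrations go negative beyond tolerance.
    """
    t = np.asarray(time_grid, float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("time_grid must be strictly increasing and nonempty")
    if rtol <= 0 or atol <= 0:
        raise ValidationError("tolerances must be positive")
    x0 = np.zeros(len(scheme.species))
    for name, c in initial.items():
        if c < 0:
            raise ValidationError(f"negative initial concentration for {name!r}")
        x0[scheme.index(name)] = c

    rhs, jac = make_rhs(scheme, params, set(clamped))
    t0 = 0.0 if t[0] > 0 else t[0]
    kwargs = dict(rtol=rtol, atol=atol, t_eval=t, dense_output=False)
    if method in ("BDF", "Radau", "LSODA"):
        kwargs["jac"] = jac
    sol = solve_ivp(rhs, (t0, t[-1]), x0, method=method, **kwargs)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t0
        raise IntegrationError(f"integrator failed: {sol.message}", last_time=last)

    y = sol.y
    floor = -100 * atol - 1e-9 * np.max(x0)
    if np.min(y) < floor:
        raise IntegrationError(
            f"negative concentration {np.min(y):.3g} beyond tolerance; "
            "the system may be stiff - try method='BDF' or tighter tolerances",
            last_time=float(sol.t[-1]),
        )
    y = np.clip(y, 0.0, None) if np.min(y) < 0 else y
    return {name: y[i] for i, name in enumerate(scheme.names)}


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

def _formation_potentials(scheme: KineticScheme, params: RateParameterSet):
    """Solve for species formation potentials G with [s] = exp(sum_m n_sm*lam_m - G_s).

    Each reversible reaction fixes sum_R G - sum_P G = ln(kf/kr). The system
    is solved in the least-squares sense; a residual above tolerance means
    the cycle equilibrium constants are inconsistent (no detailed balance).
    A kf of exactly 0 (irreversible association) is mapped to ln Keq -> -inf,
    i.e. the product complex concentration underflows to 0.
    """
    n = len(scheme.species)
    rows, rhs_vals = [], []
    for rxn in scheme.reactions:
        kf, kr = params[rxn.kf_name], params[rxn.kr_name]
        if kr == 0:
            raise EquilibriumError(
                f"reaction {rxn.label} irreversible (kr=0): no finite equilibrium"
            )
        row = np.zeros(n)
        for name in rxn.reactants:
            row[scheme.index(name)] += 1
        for name in rxn.products:
            row[scheme.index(name)] -= 1
        rows.append(row)
        rhs_vals.append(math.log(kf / kr) if kf > 0 else -1e4)
    # gauge fixing: pin one single-moiety reference species per moiety to G=0
    for m in scheme.moieties:
        for sp in scheme.species:
            if sp.moiety_counts.get(m, 0) == 1 and sp.total_moieties == 1:
                row = np.zeros(n)
                row[scheme.index(sp.name)] = 1.0
                rows.append(row)
                rhs_vals.append(0.0)
                break
    M = np.array(rows)
    b = np.array(rhs_vals)
    G, *_ = np.linalg.lstsq(M, b, rcond=None)
    n_rxn = len(scheme.reactions)
    resid = (M @ G - b)[:n_rxn]
    if np.max(np.abs(resid)) > 1e-9:
        raise EquilibriumError(
            "cycle equilibrium constants are inconsistent (detailed balance "
            f"violated by {np.max(np.abs(resid)):.3g} in log units)"
        )
    return G


def equilibrium_state(
    scheme: KineticScheme,
    params: RateParameterSet,
    totals: dict[str, float],
    clamped: dict[str, float] | None = None,
) -> dict[str, float]:
    """Mass-action equilibrium concentrations for given conserved totals (uM).

    ``clamped`` fixes the free concentration of single-moiety species (a
    ligand bath); the conservation equation of that moiety is dropped.
    """
    clamped = dict(clamped or {})
    for m, tval in totals.items():
        if tval < 0:
            raise ValidationError(f"negative total for moiety {m!r}")
    G = _formation_potentials(scheme, params)
    names = scheme.names
    counts = {m: v for m, v in scheme.conservation_vectors().items()}

    clamped_moieties: dict[str, float] = {}
    for sname, conc in clamped.items():
        sp = scheme[sname]
        mc = {m: c for m, c in sp.moiety_counts.items() if c}
        if len(mc) != 1 or list(mc.values())[0] != 1:
            raise ValidationError("only single-moiety species can be clamped")
        (m,) = mc
        # lam_m follows from ln c = lam_m - G_s
        clamped_moieties[m] = (math.log(conc) if conc > 0 else -745.0) + G[scheme.index(sname)]

    free_moieties = [
        m for m in scheme.moieties
        if m not in clamped_moieties and totals.get(m, 0.0) > 0
    ]
    zero_moieties = {
        m for m in scheme.moieties
        if m not in clamped_moieties and totals.get(m, 0.0) <= 0
    }

    nvec = np.array([[counts[m][i] for m in scheme.moieties] for i in range(len(names))])
    m_order = scheme.moieties

    def concentrations(lam_free: np.ndarray) -> np.ndarray:
        lam = {}
        for m, v in zip(free_moieties, lam_free):
            lam[m] = v
        lam.update(clamped_moieties)
        c = np.empty(len(names))
        for i in range(len(names)):
            if any(nvec[i, m_order.index(m)] > 0 for m in zero_moieties):
                c[i] = 0.0
                continue
            expo = -G[i]
            for j, m in enumerate(m_order):
                if nvec[i, j]:
                    expo += nvec[i, j] * lam[m]
            c[i] = math.exp(min(expo, 700.0))
        return c

    if not free_moieties:
        c = concentrations(np.empty(0))
        return dict(zip(names, c))

    def fun(lam_free):
        c = concentrations(lam_free)
        return np.array(
            [
                sum(nvec[i, m_order.index(m)] * c[i] for i in range(len(names)))
                - totals[m]
                for m in free_moieties
            ]
        )

    def jacf(lam_free):
        c = concentrations(lam_free)
        J = np.zeros((len(free_moieties), len(free_moieties)))
        for a, ma in enumerate(free_moieties):
            ja = m_order.index(ma)
            for b, mb in enumerate(free_moieties):
                jb = m_order.index(mb)
                J[a, b] = sum(nvec[i, ja] * nvec[i, jb] * c[i] for i in range(len(names)))
        return J

    x0 = np.array([math.log(max(totals[m], 1e-300)) for m in free_moieties])
    # damped fixed-point pre-iterations (lam_m <- lam_m + log(T_m/F_m)) bring
    # the start into the Newton basin even for strongly shifted equilibria
    for _ in range(60):
        c = concentrations(x0)
        shift = np.empty_like(x0)
        for a, m in enumerate(free_moieties):
            j = m_order.index(m)
            tot_m = sum(nvec[i, j] * c[i] for i in range(len(names)))
            shift[a] = math.log(totals[m] / tot_m) if tot_m > 0 else 0.0
        x0 = x0 + 0.5 * shift
        if np.max(np.abs(shift)) < 1e-6:
            break
    sol = root(fun, x0, jac=jacf, method="hybr", tol=1e-13)
    # judge convergence by the conservation residual, not the solver status
    # (hybr reports "no progress" when started at an already-converged point)
    best_x = sol.x if np.max(np.abs(sol.fun)) <= np.max(np.abs(fun(x0))) else x0
    resid = np.max(
        np.abs(fun(best_x))
        / np.array([max(totals[m], 1e-300) for m in free_moieties])
    )
    if resid > 1e-8:
        raise EquilibriumError(
            f"equilibrium solve failed (relative residual {resid:.3g}): {sol.message}"
        )
    c = concentrations(best_x)
    return dict(zip(names, c))


# ---------------------------------------------------------------------------
# Pseudo-first-order machinery
# ---------------------------------------------------------------------------

def pfo_excess_ratio(totals: dict[str, float], enzyme_moiety: str = "E") -> float:
    """Smallest ligand-to-enzyme total ratio; inf if no ligand moieties."""
    e = totals.get(enzyme_moiety, 0.0)
    ligs = [v for m, v in totals.items() if m != enzyme_moiety]
    if e <= 0 or not ligs:
        return math.inf
    return min(ligs) / e


def pfo_rate_matrix(
    scheme: KineticScheme,
    params: RateParameterSet,
    free_ligands: dict[str, float],
    enzyme_moiety: str = "E",
):
    """Linear rate matrix of the enzyme-state subsystem at fixed free ligand.

    Returns (state_names, A) with d x/dt = A x for x the concentrations of
    all enzyme-containing species. Only valid in ligand excess.
    """
    states = scheme.enzyme_species(enzyme_moiety)
    idx = {n: i for i, n in enumerate(states)}
    A = np.zeros((len(states), len(states)))
    for rxn in scheme.reactions:
        kf, kr = params[rxn.kf_name], params[rxn.kr_name]
        r_enz = [n for n in rxn.reactants if n in idx]
        r_lig = [n for n in rxn.reactants if n not in idx]
        p_enz = [n for n in rxn.products if n in idx]
        p_lig = [n for n in rxn.products if n not in idx]
        if len(r_enz) != 1 or len(p_enz) != 1:
            raise ValidationError(
                f"reaction {rxn.label} is not pseudo-first-order in the enzyme"
            )
        src, dst = idx[r_enz[0]], idx[p_enz[0]]
        kf_eff = kf
        for lig in r_lig:
            kf_eff *= free_ligands[lig]
        kr_eff = kr
        for lig in p_lig:
            kr_eff *= free_ligands[lig]
        A[dst, src] += kf_eff
        A[src, src] -= kf_eff
        A[src, dst] += kr_eff
        A[dst, dst] -= kr_eff
    return states, A


def reachable_states(A: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Boolean mask of states reachable (via nonzero rates) from the support
    of ``x0``. Unreachable states (e.g. complexes of an absent ligand) make
    the eigenvector matrix defective and must be pruned before propagation.
    """
    n = A.shape[0]
    mask = np.asarray(x0) > 0
    if not mask.any():
        mask = np.ones(n, bool)
        return mask
    changed = True
    while changed:
        changed = False
        for j in np.flatnonzero(mask):
            new = (np.abs(A[:, j]) > 0) & ~mask
            new[j] = False
            if new.any():
                mask |= new
                changed = True
    return mask


def propagate_linear(A: np.ndarray, x0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact solution x(t) = exp(A t) x0 via eigendecomposition.

    Returns an array of shape (len(t), len(x0)). Detailed-balanced rate
    matrices have real spectra; a tiny imaginary part from roundoff is
    discarded. States unreachable from the initial condition are held at
    zero (their inclusion would make the eigenproblem defective).
    """
    x0 = np.asarray(x0, float)
    mask = reachable_states(A, x0)
    out = np.zeros((len(t), x0.size))
    Ar = A[np.ix_(mask, mask)]
    w, V = dense_eig(Ar)
    c = np.linalg.solve(V, x0[mask].astype(complex))
    out[:, mask] = np.real((V @ (c[:, None] * np.exp(np.outer(w, t)))).T)
    return out


def pfo_equilibrium_weights(
    scheme: KineticScheme,
    params: RateParameterSet,
    free_ligands: dict[str, float],
    enzyme_moiety: str = "E",
    G: np.ndarray | None = None,
) -> dict[str, float]:
    """Fractional equilibrium populations of enzyme states at fixed free ligand."""
    if G is None:
        G = _formation_potentials(scheme, params)
    states = scheme.enzyme_species(enzyme_moiety)
    logw = []
    for name in states:
        sp = scheme[name]
        lw = -G[scheme.index(name)]
        for m, cnt in sp.moiety_counts.items():
            if m == enzyme_moiety or cnt == 0:
                continue
            lig_name = next(
                s.name for s in scheme.species
                if s.role == "ligand" and s.moiety_counts.get(m, 0)
            )
            conc = free_ligands[lig_name]
            lw += cnt * (math.log(conc) if conc > 0 else -745.0)
        logw.append(lw)
    logw = np.array(logw)
    w = np.exp(logw - np.max(logw))
    w /= w.sum()
    return dict(zip(states, w))


# ---------------------------------------------------------------------------
# Relaxation rates and the hyperbolic kobs law
# ---------------------------------------------------------------------------

def relaxation_rates_pfo(
    builtin_id: str, params: RateParameterSet, ligand_conc: float
) -> list[float]:
    """Relaxation rates (s^-1) of a binding scheme in the ligand-excess regime.

    ONE_STEP returns the single rate k1*L + k-1. INDUCED_FIT and
    CONF_SELECTION return the two eigenvalue magnitudes of the linearized
    2x2 enzyme-state system (free-enzyme pool eliminated through
    conservation), sorted fast-first.
    """
    if ligand_conc < 0:
        raise ValidationError("ligand concentration must be >= 0")
    L = float(ligand_conc)
    if builtin_id == "ONE_STEP":
        return [params["k1"] * L + params["k-1"]]
    k1, km1 = params["k1"], params["k-1"]
    kc, kmc = params["kconf"], params["k-conf"]
    if builtin_id == "INDUCED_FIT":
        # states (ES, E*S); E = Etot - ES - E*S
        A = np.array([[-(k1 * L + km1 + kc), -(k1 * L) + kmc], [kc, -kmc]])
    elif builtin_id == "CONF_SELECTION":
        # states (E*, E*S); E = Etot - E* - E*S
        A = np.array([[-(kc + kmc + k1 * L), -kc + km1], [k1 * L, -km1]])
    else:
        raise ValidationError(f"no PFO relaxation form for scheme {builtin_id!r}")
    rates = sorted(np.abs(np.linalg.eigvals(A)), reverse=True)
    return [float(r) for r in rates]


def kobs_hyperbolic(params: RateParameterSet, S: float) -> float:
    """Rapid-equilibrium induced-fit observed rate: k-conf + kconf*S/(KD1+S)."""
    if S < 0:
        raise ValidationError("S must be >= 0")
    KD1 = params.KD1
    if KD1 <= 0:
        raise ValidationError("KD1 must be positive")
    return params["k-conf"] + params["kconf"] * S / (KD1 + S)


# ---------------------------------------------------------------------------
# Observable projection
# ---------------------------------------------------------------------------

def project_observable(
    times: np.ndarray,
    trajectories: dict[str, np.ndarray],
    observable: ObservableModel,
    totals: dict[str, float] | None = None,
    label: str = "",
) -> Trace:
    """Project species trajectories onto the instrument signal.

    Samples only t >= dead_time and flags the trace as dead-time-obscured
    when the pre-dead-time signal change exceeds ``observable.obscured_fraction``
    of the total change.
    """
    times = np.asarray(times, float)
    unknown = set(observable.responses) - set(trajectories)
    if unknown:
        raise ValidationError(f"responses reference unknown species: {sorted(unknown)}")
    sig = np.full(times.shape, observable.baseline)
    for name, r in observable.responses.items():
        sig = sig + r * np.asarray(trajectories[name], float)

    td = observable.dead_time
    if td > 0 and times[-1] <= td:
        raise ValidationError("trajectory ends before the dead time")
    obscured = False
    if td > 0 and times[0] < td:
        s0 = sig[0]
        s_dead = float(np.interp(td, times, sig))
        total = sig[-1] - s0
        if total != 0:
            lost = abs(s_dead - s0) / abs(total)
            obscured = lost >= observable.obscured_fraction
    mask = times >= td
    return Trace(
        time=times[mask],
        signal=sig[mask],
        totals=dict(totals or {}),
        dead_time=td,
        dead_time_obscured=obscured,
        label=label,
    )


def halfsat_free_ligand(bound_of_free, free_max: float, tol: float = 1e-10) -> float:
    """Free-ligand concentration at half-maximal bound signal (log-space brentq)."""
    top = bound_of_free(free_max)
    target = 0.5 * top

    def f(loga):
        return bound_of_free(math.exp(loga)) - target

    lo, hi = math.log(free_max) - 40, math.log(free_max)
    return math.exp(brentq(f, lo, hi, xtol=tol))
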