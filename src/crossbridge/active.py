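"""Steady-state five-state model of active muscle contraction.

States (per myosin head, one actin site per 36 nm repeat):

    MDP/AMDP  detached (or weakly bound) with hydrolysis products; the
              weak-binding equilibrium K_w(x) is rapid, so MDP and AMDP are
              carried as one pool,
    AMD_L     strongly attached, pre-power-stroke (ADP, low force),
    AMD_H     post-power-stroke (ADP, high force),
    AM/AMD    post-second-step lumped AMD/AM/AMT state,
    MT        detached with ATP (rebuilds MDP by hydrolysis).

The strain coordinate x is the position of the actin site relative to the
head; each attached state j has its extension-free position x_j and its
own force-extension law (linear or nonlinear, see
:mod:`crossbridge.elasticity`).  Transition-rate functions follow
Kramers/Bell forms built from the elastic energies; every rate is clamped
to [r_min, r_max] for numerical stability, with r_max raised tenfold at
the fastest shortening velocities.

During steady shortening at velocity v the state densities obey

    da_j/dx = (sum_k k_kj(x) a_k - sum_k k_jk(x) a_j) / v,

integrated from x = +14 nm downward (attached states empty there, the
detached states at their equilibrium split).  The isometric limit solves
the per-x stationary distribution directly (states at different x decouple
when v = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .elasticity import ElasticityProfile, make_profile, KBT_PN_NM
from .params import load_active_defaults

__all__ = [
    "ActiveParameters",
    "ActiveDensity",
    "make_active_params",
    "rate_table",
    "clamp",
    "rate_matrix",
    "solve_steady",
    "solve_isometric",
    "solve_periodic",
    "STATE_NAMES",
]

STATE_NAMES = ("AMDL", "AMDH", "AMAMD", "MT", "MDP")
_ATTACHED = slice(0, 3)


@dataclass(frozen=True)
class ActiveParameters:
    """Parameter set of the active-contraction model.

    Kinetic and energetic defaults come from the versioned parameter file
    (``data/active_defaults.cfg``), which records the provenance of each
    entry; any field can be overridden per run.
    """

    profile_AMDL: ElasticityProfile
    profile_AMDH: ElasticityProfile
    profile_AMAMD: ElasticityProfile
    x1: float            # nm, AMD_L extension-free position
    x2: float            # nm, AMD_H extension-free position
    x3: float            # nm, AM/AMD extension-free position
    dG_w: float          # kBT, weak-binding free-energy drop
    ksw: float           # pN/nm, weak-binding (AMDP) stiffness
    x_w: float           # nm, weak-binding minimum position
    dG_AMDP_AMDL: float  # kBT, drop at the Pi-release/attachment step
    dG_AMDL_AMDH: float  # kBT, drop at the power stroke
    dG_AMDH_AM: float    # kBT, drop at the second (nucleotide-pocket) step
    kb0: float           # 1/s, attachment/Pi-step rate scale
    K_C: float           # mM, phosphate dissociation constant
    Pi: float            # mM, inorganic-phosphate concentration
    kLH_minus: float     # 1/s, power-stroke reversal rate
    k5_x2: float         # 1/s, scale of the AMD_H -> AM/AMD rate
    k2_0: float          # 1/s, ATP-induced detachment at zero force
    k6: float            # 1/s, ADP release
    K1: float            # 1/mM, MgATP binding equilibrium constant
    x_crit: float        # nm, Bell strain sensitivity of k2
    MgATP: float         # mM
    k_h: float           # 1/s, MT -> MDP hydrolysis
    K_H: float           # hydrolysis equilibrium constant
    attach_lo: float = -0.55   # nm, attachment window (half-open [lo, hi))
    attach_hi: float = 16.0
    x_hi: float = 14.0         # nm, integration start
    x_lo: float = -91.0        # nm, integration end
    denom_lo: float = -22.0    # nm, denominator span lower limit
    intersite: float = 36.0    # nm, actin repeat per site
    r_max_slow: float = 1.0e5  # 1/s, rate cap (isometric / slow)
    r_max_fast: float = 1.0e6  # 1/s, rate cap at the fastest velocities
    v_rmax_switch: float = 5000.0  # nm/s, velocity at which the cap switches
    r_min: float = 1.0e-6      # 1/s, rate floor
    kBT: float = KBT_PN_NM     # pN nm
    grid_step: float = 0.05    # nm

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.x_hi - self.x_lo) / self.grid_step)) + 1
        return np.linspace(self.x_lo, self.x_hi, n)

    def r_max(self, v: float | None) -> float:
        if v is not None and abs(v) > self.v_rmax_switch:
            return self.r_max_fast
        return self.r_max_slow


@dataclass
class ActiveDensity:
    """State densities over the strain axis at one sliding velocity."""

    x: np.ndarray          # (nx,) ascending strain grid, nm
    a: np.ndarray          # (5, nx) state probabilities, STATE_NAMES order
    v: float               # nm/s (0 for the isometric solution)
    residual: float = 0.0  # max |1 - sum_j a_j| over the grid
    periodic: bool = False
    tail_attached: float = 0.0  # per-repeat attached measure below denom_lo


Elasticity = Literal["linear", "nonlinear", "nonlinear_amamd", "nonlinear_amdl",
                     "nonlinear_amdh"]


def make_active_params(elasticity: Elasticity = "nonlinear",
                       c: float | None = None,
                       **overrides) -> ActiveParameters:
    """Build a parameter set for one of the standard elasticity variants.

    ``linear``: all states Hookean (2.8 pN/nm); defaults k2_0 = 1800 1/s
    with strain-dependent detachment (x_crit = 0.6 nm).

    ``nonlinear``: all attached states nonlinear; the AM/AMD drag-stroke
    stiffness is set by ``c`` (default 0.0255, i.e. S_low = 0.1 pN/nm);
    defaults k2_0 = 1600 1/s, x_crit = 0.

    ``nonlinear_amamd`` / ``nonlinear_amdl`` / ``nonlinear_amdh``: only the
    named state(s) nonlinear, otherwise as ``nonlinear``.
    """
    d = load_active_defaults()
    if c is None:
        c = d["c_standard"]
    lin = {"AMDL": "linear", "AMDH": "linear", "AM_AMD": "linear"}
    modes = dict(lin)
    if elasticity == "nonlinear":
        modes = {"AMDL": "nonlinear", "AMDH": "nonlinear", "AM_AMD": "nonlinear"}
    elif elasticity == "nonlinear_amamd":
        modes["AM_AMD"] = "nonlinear"
    elif elasticity == "nonlinear_amdl":
        modes["AMDL"] = "nonlinear"
    elif elasticity == "nonlinear_amdh":
        modes["AMDH"] = "nonlinear"
    elif elasticity != "linear":
        raise ValueError(f"unknown elasticity variant {elasticity!r}")

    linear_all = elasticity == "linear"
    kin = dict(
        x1=d["x1"], x2=d["x2"], x3=d["x3"], dG_w=d["dG_w"], ksw=d["ksw"],
        x_w=d["x_w"], dG_AMDP_AMDL=d["dG_AMDP_AMDL"],
        dG_AMDL_AMDH=d["dG_AMDL_AMDH"], dG_AMDH_AM=d["dG_AMDH_AM"],
        kb0=d["kb0"], K_C=d["K_C"], Pi=d["Pi"], kLH_minus=d["kLH_minus"],
        k5_x2=d["k5_x2"], k6=d["k6"], K1=d["K1"], MgATP=d["MgATP"],
        k_h=d["k_h"], K_H=d["K_H"],
        k2_0=d["k2_0_linear"] if linear_all else d["k2_0_nonlinear"],
        x_crit=d["x_crit_linear"] if linear_all else d["x_crit_nonlinear"],
    )
    kin.update(overrides)
    return ActiveParameters(
        profile_AMDL=make_profile("AMDL", modes["AMDL"], c=0.0),
        profile_AMDH=make_profile("AMDH", modes["AMDH"], c=0.0),
        profile_AMAMD=make_profile("AM_AMD", modes["AM_AMD"], c=c),
        **kin,
    )


# ----------------------------------------------------------------------
# rate functions

def clamp(rate, params: ActiveParameters, v: float | None = None):
    """Clamp a rate (1/s) to [r_min, r_max]; r_max depends on |v|."""
    return np.clip(rate, params.r_min, params.r_max(v))


def _energies(params: ActiveParameters, x):
    """Elastic-energy terms entering the rate exponents, pN nm.

    The rate formulas use the local-quadratic form (k_s(x)/2)(x - x_j)^2
    with the tangent stiffness at x, which coincides with the integrated
    elastic energy for every single-segment law and approximates it for
    the multi-segment nonlinear AM/AMD law.  (The exact integrated energy
    would make the strain gate of the nucleotide-pocket step, k5, lose its
    steep growth at negative strain, leaving drag-stroke AMD_H heads
    attached over the whole span - contrary to the model's distributions.)
    Forces and observables always use the true piecewise law.
    """
    x = np.asarray(x, dtype=float)
    Ew = 0.5 * params.ksw * (x - params.x_w) ** 2

    def quad(prof, xr):
        e = x - xr
        return 0.5 * prof.stiffness_at(e) * e * e

    E1 = quad(params.profile_AMDL, params.x1)
    E2 = quad(params.profile_AMDH, params.x2)
    E3 = quad(params.profile_AMAMD, params.x3)
    return Ew, E1, E2, E3


def rate_table(params: ActiveParameters, x, v: float | None = None) -> dict:
    """All transition-rate functions evaluated at strain ``x`` (vectorized).

    Returns K_w (0 outside the attachment window), k_plusP, k_minusP,
    kLH_plus, kLH_minus, k5, k2, k_off, k_h and the derived pool fractions,
    each rate clamped to [r_min, r_max].
    """
    x = np.asarray(x, dtype=float)
    kBT = params.kBT
    Ew, E1, E2, E3 = _energies(params, x)
    in_window = (x >= params.attach_lo) & (x < params.attach_hi)
    with np.errstate(over="ignore"):
        Kw = np.where(in_window, np.exp(params.dG_w - Ew / kBT), 0.0)
        Kw = np.minimum(Kw, params.r_max(v))
        k_plusP = clamp(
            params.kb0 * np.exp(params.dG_AMDP_AMDL - (E1 - Ew) / (2 * kBT)),
            params, v)
        k_b = params.kb0 * np.exp((E1 - Ew) / (2 * kBT))
        k_minusP = clamp(k_b * params.Pi / (params.K_C + params.Pi), params, v)
        kLH_plus = clamp(
            params.kLH_minus * np.exp(params.dG_AMDL_AMDH + (E1 - E2) / kBT),
            params, v)
        kLH_minus = clamp(np.full_like(x, params.kLH_minus), params, v)
        k5 = clamp(
            params.k5_x2 * np.exp(params.dG_AMDH_AM + (E2 - E3) / kBT),
            params, v)
        F3 = params.profile_AMAMD.force_at(x - params.x3)
        k2 = clamp(
            params.k2_0 * np.exp(np.abs(F3) * params.x_crit / kBT), params, v)
        T = params.MgATP
        k_off = clamp(
            k2 * params.k6 * T / (params.k6 / params.K1 + (k2 + params.k6) * T),
            params, v)
    f_w = Kw / (1.0 + Kw)          # AMDP fraction of the detached pool
    return {
        "K_w": Kw, "k_plusP": k_plusP, "k_minusP": k_minusP,
        "kLH_plus": kLH_plus, "kLH_minus": kLH_minus, "k5": k5,
        "k2": k2, "k_off": k_off, "k_h": params.k_h,
        "k_h_rev": params.k_h / params.K_H, "f_w": f_w,
        "attach_eff": k_plusP * f_w,
    }


def rate_matrix(params: ActiveParameters, x, v: float | None = None) -> np.ndarray:
    """Rate matrix A with A[j, k] the rate k -> j, shape (..., 5, 5).

    Column sums vanish, so d(sum_j a_j)/dt = 0 exactly.  The AM/AMD state
    detaches obligately (at r_max, into the pool) where its law forbids
    attachment (x - x3 < -90 nm).
    """
    x = np.asarray(x, dtype=float)
    r = rate_table(params, x, v)
    shape = x.shape + (5, 5)
    A = np.zeros(shape)
    i_L, i_H, i_A, i_T, i_P = range(5)

    def add(dst, src, rate):
        A[..., dst, src] += rate
        A[..., src, src] -= rate

    add(i_L, i_P, r["attach_eff"])
    add(i_P, i_L, r["k_minusP"])
    add(i_H, i_L, r["kLH_plus"])
    add(i_L, i_H, r["kLH_minus"])
    add(i_A, i_H, r["k5"])
    add(i_T, i_A, r["k_off"])
    add(i_P, i_T, np.full_like(x, r["k_h"]))
    # reverse hydrolysis acts on the MDP part of the pool only
    add(i_T, i_P, r["k_h_rev"] * (1.0 - r["f_w"]))
    # obligate detachment where the AM/AMD elastic law ends
    forbidden = (x - params.x3) < -90.0
    if np.any(forbidden):
        add(i_P, i_A, np.where(forbidden, params.r_max(v), 0.0))
    return A


def _detached_split(params: ActiveParameters, x: float) -> np.ndarray:
    """Equilibrium MT / pool split of a fully detached head at strain x."""
    r = rate_table(params, np.asarray([x]))
    Kw = float(r["K_w"][0])
    pool = params.K_H * (1.0 + Kw)
    out = np.zeros(5)
    out[3] = 1.0 / (1.0 + pool)
    out[4] = pool / (1.0 + pool)
    return out


# ----------------------------------------------------------------------
# solvers

def solve_steady(params: ActiveParameters, v: float,
                 rtol: float = 1.0e-8, atol: float = 1.0e-12,
                 _source=None, _a0=None, _redirect_below=None) -> ActiveDensity:
    """Steady-state densities during shortening at velocity ``v`` (nm/s).

    Integrates the master equations in the co-moving coordinate from
    x = +14 nm downward with a stiff (BDF) solver; the problem is linear,
    so the exact Jacobian is supplied.
    """
    if v <= 0:
        raise ValueError("solve_steady requires v > 0; use solve_isometric")
    grid = params.grid           # ascending
    x_of_tau = lambda tau: params.x_hi - v * tau
    tau_grid = (params.x_hi - grid[::-1]) / v   # increasing

    redirect = _redirect_below if _redirect_below is not None else -np.inf

    # the system is linear with piecewise-smooth coefficients: precompute
    # the rate matrix on the grid and interpolate linearly inside the rhs
    Agrid = rate_matrix(params, grid, v)        # (nx, 5, 5)
    if np.isfinite(redirect):
        # periodic variant: detachment products born below the re-entry
        # edge leave this repeat (they are re-injected 36 nm up)
        below = grid < redirect
        Agrid[below, 3, 2] = 0.0
        Agrid[below, 4, 2] = 0.0
    x0, dx = grid[0], grid[1] - grid[0]
    n_hi = grid.size - 1

    def matrix(x):
        f = np.clip((x - x0) / dx, 0.0, n_hi)
        i = min(int(f), n_hi - 1)
        w = f - i
        return (1.0 - w) * Agrid[i] + w * Agrid[i + 1]

    def rhs(tau, a):
        x = x_of_tau(tau)
        out = matrix(x) @ a
        if _source is not None:
            out = out + _source(x)
        return out

    def jac(tau, a):
        return matrix(x_of_tau(tau))

    a0 = _a0 if _a0 is not None else _detached_split(params, params.x_hi)
    sol = solve_ivp(rhs, (0.0, tau_grid[-1]), a0, method="BDF",
                    t_eval=tau_grid, jac=jac, rtol=rtol, atol=atol,
                    max_step=max(2.0 / v, tau_grid[-1] / 4000))
    if not sol.success:
        raise RuntimeError(f"steady-state integration failed: {sol.message}")
    a = sol.y[:, ::-1]           # back to ascending x
    a = np.clip(a, 0.0, None)
    residual = float(np.max(np.abs(1.0 - a.sum(axis=0)))) if _source is None else 0.0
    return ActiveDensity(x=grid.copy(), a=a, v=v, residual=residual)


def solve_isometric(params: ActiveParameters) -> ActiveDensity:
    """Isometric (v = 0) stationary distribution, solved per grid point.

    With no sliding the states at different strains decouple; the local
    rate matrix has a unique stationary distribution (the ATP-driven cycle
    keeps running), found by replacing one balance equation with the
    normalization constraint.
    """
    grid = params.grid
    A = rate_matrix(params, grid, v=None)
    M = A.copy()
    M[:, -1, :] = 1.0
    b = np.zeros((grid.size, 5))
    b[:, -1] = 1.0
    try:
        a = np.linalg.solve(M, b[:, :, None])[:, :, 0].T
    except np.linalg.LinAlgError as err:
        raise RuntimeError("singular local rate matrix in isometric solve") from err
    a = np.clip(a, 0.0, None)
    a /= a.sum(axis=0, keepdims=True)
    residual = float(np.max(np.abs(1.0 - a.sum(axis=0))))
    return ActiveDensity(x=grid.copy(), a=a, v=0.0, residual=residual)


def solve_periodic(params: ActiveParameters, v: float,
                   max_iter: int = 12, tol: float = 1.0e-6) -> ActiveDensity:
    """Periodic-boundary control variant of :func:`solve_steady`.

    The detached-state density exiting at the denominator edge (x = -22 nm)
    re-enters at x = +14 nm (one 36 nm actin repeat up), and detachment
    products born below that edge are re-injected one repeat up as an MT
    source, iterated to self-consistency.  Attached AM/AMD tails beyond one
    repeat are retained in the extended domain.
    """
    grid = params.grid
    edge = params.denom_lo
    base = solve_steady(params, v)
    dens = base
    prev = None
    for _ in range(max_iter):
        # detachment flux below the edge, mapped one (or two) repeats up
        r = rate_table(params, grid, v)
        flux = r["k_off"] * dens.a[2]            # AM/AMD -> MT, 1/s
        below = grid < edge
        src = np.zeros_like(grid)
        for shift in (params.intersite, 2 * params.intersite):
            xs = grid + shift
            sel = below & (xs <= params.x_hi)
            if np.any(sel):
                src += np.interp(grid, xs[sel], flux[sel], left=0.0, right=0.0)
        src_fn = lambda x: np.array([0, 0, 0, np.interp(x, grid, src), 0.0])
        # re-entry: detached state observed at the edge
        i_edge = int(np.argmin(np.abs(grid - edge)))
        a0 = np.zeros(5)
        a0[3:] = dens.a[3:, i_edge]
        tot0 = a0.sum()
        if tot0 <= 0:
            break
        new = solve_steady(params, v, _source=src_fn, _a0=a0,
                           _redirect_below=edge)
        new.periodic = True
        metric = float(np.abs(new.a[_ATTACHED]).sum())
        if prev is not None and abs(metric - prev) <= tol * max(prev, 1e-12):
            dens = new
            break
        prev = metric
        dens = new
    sel = grid < edge
    dens.tail_attached = float(np.trapezoid(dens.a[_ATTACHED][:, sel].sum(axis=0),
                                            grid[sel]))
    dens.periodic = True
    return dens
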