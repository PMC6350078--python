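"""Multi-site equilibrium cross-bridge model for rigor (nucleotide-free) muscle.

Each myosin head can form a rigor link to one of five neighbouring actin
sites (indices -2..2, spaced 5.5 nm).  Site occupancies evolve by
strain-dependent detachment

    k_d^i(x) = k_d(0) * exp(|F(x - 5.5 i)| * x_crit^R / kBT)

and attachment fixed by detailed balance against the free-energy difference
between the detached head and the rigor link,

    k_a^i(x) / k_d^i(x) = exp(-dG_AM^i(x)),
    dG_AM^i(x) = dG_min + E(x - 5.5 i)/kBT,

capped at ``ka_cap`` for numerical stability (results are insensitive while
k_a >> k_d).  The distributions m(x), a_i(x) live on a strain grid covering
one site spacing; filament sliding shifts every extension by the same
amount, tracked as a scalar offset, and a lumped linear series element
(myofilament compliance) splits imposed length changes according to

    dx = (k_se * x_se - <F>) / (k_se + <S>).          (force balance)

Because rigor detachment rates are of order 1e-3 s^-1, the head
distribution established when rigor develops (heads attaching in
proportion to k_a) is effectively frozen on experimental timescales; that
kinetically trapped state - not the fully relaxed Boltzmann distribution,
which carries almost no net force - is what bears the isometric rigor
tension when the elasticity is nonlinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elasticity import ElasticityProfile, make_profile, KBT_PN_NM

__all__ = [
    "RigorParameters",
    "RigorState",
    "LengthProtocol",
    "detach_rate",
    "attach_rate",
    "step",
    "equilibrate",
    "ensemble_force",
    "ensemble_stiffness",
    "to_tension",
    "partition_length_change",
    "run_protocol",
    "probe_sarcomere_stiffness",
]


@dataclass(frozen=True)
class RigorParameters:
    """Rigor-model parameters (defaults per the fast skeletal muscle set)."""

    profile: ElasticityProfile = field(
        default_factory=lambda: make_profile("rigor_AM", "nonlinear", c=0.0)
    )
    n_sites: int = 5
    site_spacing: float = 5.5          # nm between actin sites
    dG_min: float = -18.0              # kBT, rigor well depth below detached
    kd_ref: float = 0.0014             # 1/s, detachment at zero strain
    x_crit_R: float = 1.4              # nm, strain sensitivity of detachment
    k_se: float = 160.0                # pN/nm, series (myofilament) stiffness
    heads_per_halffilament: int = 294
    lattice_area: float = 2.0e-15      # m^2 per half thick filament
    grid_points: int = 1100
    grid_half: float = 2.75            # nm, grid spans [-grid_half, grid_half]
    kBT: float = KBT_PN_NM             # pN nm
    ka_cap: float = 1.0e6              # 1/s, attachment-rate cap

    @property
    def sites(self) -> np.ndarray:
        h = self.n_sites // 2
        return np.arange(-h, h + 1)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(-self.grid_half, self.grid_half, self.grid_points)


@dataclass
class RigorState:
    """Occupancies on the strain grid plus the mechanical offsets."""

    m: np.ndarray          # (nx,) detached probability
    a: np.ndarray          # (n_sites, nx) rigor-link probabilities
    shift: float = 0.0     # nm, cumulative cross-bridge strain offset
    x_se: float = 0.0      # nm, series-element strain
    t: float = 0.0         # s

    def total(self) -> np.ndarray:
        return self.m + self.a.sum(axis=0)


@dataclass(frozen=True)
class LengthProtocol:
    """Piecewise-constant-velocity half-sarcomere length schedule.

    ``segments`` is a sequence of ``(amplitude_nm, velocity_nm_s)`` ramps;
    zero-velocity entries are holds with ``amplitude_nm`` reinterpreted as
    the hold duration in seconds.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for amp, v in self.segments:
            if v != 0.0 and not 1.0 <= abs(v) <= 1000.0:
                raise ValueError(f"segment velocity {v} nm/s outside [1, 1000]")


# ----------------------------------------------------------------------
# rates

def _extensions(params: RigorParameters, x: np.ndarray, shift: float) -> np.ndarray:
    """(n_sites, nx) extensions of every site at every grid point."""
    return x[None, :] + shift - params.site_spacing * params.sites[:, None]


def _rates(params: RigorParameters, shift: float = 0.0):
    """Detachment / attachment rate tables on the grid, (n_sites, nx)."""
    e = _extensions(params, params.grid, shift)
    F = params.profile.force_at(e)
    E = params.profile.strain_energy(e, kBT=params.kBT)  # kBT units
    kd = params.kd_ref * np.exp(np.abs(F) * params.x_crit_R / params.kBT)
    with np.errstate(over="ignore"):
        ka = np.minimum(kd * np.exp(-(params.dG_min + E)), params.ka_cap)
    ka = np.where(np.isfinite(E), ka, 0.0)  # attachment forbidden beyond -90 nm
    return kd, ka


def detach_rate(params: RigorParameters, i: int, x, shift: float = 0.0):
    """Strain-dependent rigor detachment rate of site ``i`` at position x, 1/s."""
    if i not in params.sites:
        raise ValueError(f"site index {i} outside {params.sites}")
    e = np.asarray(x, dtype=float) + shift - params.site_spacing * i
    F = params.profile.force_at(e)
    out = params.kd_ref * np.exp(np.abs(F) * params.x_crit_R / params.kBT)
    return out if np.ndim(out) else float(out)


def attach_rate(params: RigorParameters, i: int, x, shift: float = 0.0):
    """Detailed-balance attachment rate of site ``i``, capped at ``ka_cap``, 1/s."""
    kd = detach_rate(params, i, x, shift)
    e = np.asarray(x, dtype=float) + shift - params.site_spacing * i
    E = params.profile.strain_energy(e, kBT=params.kBT)
    with np.errstate(over="ignore"):
        out = np.minimum(kd * np.exp(-(params.dG_min + E)), params.ka_cap)
    out = np.where(np.isfinite(np.asarray(E)), out, 0.0)
    return out if np.ndim(out) else float(out)


# ----------------------------------------------------------------------
# kinetics

def step(state: RigorState, params: RigorParameters, dt: float) -> RigorState:
    """Advance the six-state kinetics by ``dt`` (backward-Euler, per point).

    The implicit update ``(I - dt A) p_new = p_old`` is L-stable and
    conserves per-point probability exactly (columns of A sum to zero).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0.0:
        return replace_state(state)
    kd, ka = _rates(params, state.shift)
    n_s, nx = ka.shape
    n = n_s + 1
    A = np.zeros((nx, n, n))
    A[:, 0, 0] = -ka.sum(axis=0).T
    for j in range(n_s):
        A[:, j + 1, 0] = ka[j]
        A[:, 0, j + 1] = kd[j]
        A[:, j + 1, j + 1] = -kd[j]
    M = np.eye(n)[None, :, :] - dt * A
    p = np.concatenate([state.m[None, :], state.a], axis=0).T[:, :, None]
    p_new = np.linalg.solve(M, p)[:, :, 0].T
    return RigorState(m=p_new[0], a=p_new[1:], shift=state.shift,
                      x_se=state.x_se, t=state.t + dt)


def replace_state(state: RigorState) -> RigorState:
    return RigorState(m=state.m.copy(), a=state.a.copy(), shift=state.shift,
                      x_se=state.x_se, t=state.t)


def equilibrate(params: RigorParameters, kind: str = "induced") -> RigorState:
    """Pre-protocol rigor state.

    ``kind="induced"`` (default): rigor developed from detached heads -
    heads attach in proportion to k_a (completing within microseconds) and
    the series element is brought to force balance (compliance partition
    at fixed overall length).  Further redistribution is negligible on
    experimental timescales because rigor detachment takes hundreds of
    seconds; this trapped state carries the isometric rigor tension when
    the elasticity is nonlinear.

    ``kind="boltzmann"``: the fully relaxed stationary distribution of the
    per-point kinetics (detailed balance), which bears essentially no net
    force for any elasticity law.
    """
    kd, ka = _rates(params, 0.0)
    if kind == "boltzmann":
        K = np.where(kd > 0, ka / kd, 0.0)
        m = 1.0 / (1.0 + K.sum(axis=0))
        state = RigorState(m=m, a=K * m)
        # stationary reference state: series strain set to match the (tiny)
        # residual force without shifting the distribution
        state.x_se = ensemble_force(state, params) / params.k_se
        return state
    elif kind == "induced":
        tot = ka.sum(axis=0)
        w = ka / tot
        # quasi-steady detached fraction of the trapped distribution
        # (dm/dt = 0 with occupancies frozen at the attachment weights)
        q = (w * kd).sum(axis=0) / tot
        m = q / (1.0 + q)
        state = RigorState(m=m, a=w * (1.0 - m))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    # series-element force balance at fixed overall length
    state = _rebalance(state, params)
    return state


def ensemble_force(state: RigorState, params: RigorParameters) -> float:
    """Average cross-bridge force per half thick filament, pN."""
    e = _extensions(params, params.grid, state.shift)
    F = params.profile.force_at(e)
    num = np.trapezoid((state.a * F).sum(axis=0), params.grid)
    den = np.trapezoid(state.total(), params.grid)
    return params.heads_per_halffilament * num / den


def ensemble_stiffness(state: RigorState, params: RigorParameters) -> float:
    """Average cross-bridge stiffness per half thick filament, pN/nm."""
    e = _extensions(params, params.grid, state.shift)
    S = params.profile.stiffness_at(e)
    num = np.trapezoid((state.a * S).sum(axis=0), params.grid)
    den = np.trapezoid(state.total(), params.grid)
    return params.heads_per_halffilament * num / den


def to_tension(force_pn: float, params: RigorParameters | None = None) -> float:
    """Convert half-filament force (pN) to fibre tension (kPa)."""
    area = params.lattice_area if params is not None else 2.0e-15
    return force_pn * 1.0e-12 / area / 1.0e3


def partition_length_change(F: float, S: float, k_se: float, x_se: float) -> float:
    """Cross-bridge strain increment restoring series force balance (nm)."""
    den = k_se + S
    if den <= 0:
        raise ValueError("degenerate compliance: k_se + S must be positive")
    return (k_se * x_se - F) / den


def _rebalance(state: RigorState, params: RigorParameters,
               tol: float = 1.0e-10, max_iter: int = 200) -> RigorState:
    """Iterate the force-balance partition at fixed overall length."""
    shift, x_se = state.shift, state.x_se
    for _ in range(max_iter):
        tmp = RigorState(m=state.m, a=state.a, shift=shift, x_se=x_se, t=state.t)
        F = ensemble_force(tmp, params)
        S = ensemble_stiffness(tmp, params)
        dx = partition_length_change(F, S, params.k_se, x_se)
        shift += dx
        x_se -= dx
        if abs(dx) < tol:
            break
    return RigorState(m=state.m, a=state.a, shift=shift, x_se=x_se, t=state.t)


# ----------------------------------------------------------------------
# protocols

def run_protocol(params: RigorParameters, protocol: LengthProtocol,
                 state: RigorState | None = None,
                 dl_step: float = 0.01, record_every: int = 10) -> pd.DataFrame:
    """Impose a length-change schedule and record the mechanical time series.

    Each external length increment is split between cross-bridges and the
    series element by their compliances, the kinetics advanced, and the
    force balance restored.  Time step follows the imposed velocity
    (``dl_step`` nm per step) within 0.1-500 ms.
    """
    if state is None:
        state = equilibrate(params)
    else:
        state = replace_state(state)
    rows = []
    L = 0.0
    nstep = 0

    def record():
        F = ensemble_force(state, params)
        S = ensemble_stiffness(state, params)
        rows.append((state.t, L, state.shift, state.x_se, F, to_tension(F, params),
                     to_tension(S, params)))

    record()
    for amp, v in protocol.segments:
        if v == 0.0:  # hold: amp is a duration in seconds
            duration = amp
            if duration <= 0:
                raise ValueError("hold segment needs positive duration")
            dt = min(0.5, max(1.0e-4, duration / 50))
            t_end = state.t + duration
            while state.t < t_end - 1e-12:
                h = min(dt, t_end - state.t)
                state = step(state, params, h)
                state = _rebalance(state, params)
                nstep += 1
                if nstep % record_every == 0:
                    record()
            continue
        if amp == 0.0:
            raise ValueError("ramp segment needs nonzero amplitude")
        duration = abs(amp / v)
        n = max(1, int(round(abs(amp) / dl_step)))
        dl = amp / n
        dt = float(np.clip(duration / n, 1.0e-4, 0.5))
        for _ in range(n):
            S = ensemble_stiffness(state, params)
            d_cb = dl * params.k_se / (params.k_se + S)
            state = RigorState(m=state.m, a=state.a, shift=state.shift + d_cb,
                               x_se=state.x_se + (dl - d_cb), t=state.t)
            state = step(state, params, dt)
            state = _rebalance(state, params)
            L += dl
            nstep += 1
            if nstep % record_every == 0:
                record()
    record()
    return pd.DataFrame(
        rows, columns=["t_s", "L_nm", "xcb_nm", "xse_nm", "F_pN",
                       "tension_kPa", "stiffness_kPa_per_nm"]
    ).drop_duplicates(subset="t_s", keep="last").reset_index(drop=True)


def probe_sarcomere_stiffness(params: RigorParameters, state: RigorState,
                              amplitude: float = 0.1) -> float:
    """Chord stiffness of the half sarcomere, kPa/nm.

    Applies an instantaneous +/- ``amplitude`` length step with the
    occupancies frozen, restores the series force balance at the stepped
    length, and returns d(tension)/d(length).
    """
    tensions = []
    for sgn in (+1.0, -1.0):
        dl = sgn * amplitude
        shift, x_se = state.shift, state.x_se + dl
        for _ in range(100):
            tmp = RigorState(m=state.m, a=state.a, shift=shift, x_se=x_se)
            F = ensemble_force(tmp, params)
            S = ensemble_stiffness(tmp, params)
            dx = partition_length_change(F, S, params.k_se, x_se)
            shift += dx
            x_se -= dx
            if abs(dx) < 1.0e-12:
                break
        tensions.append(to_tension(params.k_se * x_se, params))
    return (tensions[0] - tensions[1]) / (2.0 * amplitude)
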