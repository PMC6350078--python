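"""Derived steady-state analyses over the active-contraction engine.

Observables are per-myosin-head averages over the actin repeat: attached-
state integrals run over the full strain span, the normalizing denominator
over one 36 nm repeat, following the master-equation averaging of the
underlying model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .active import (ActiveDensity, ActiveParameters, rate_table,
                     solve_isometric, solve_steady, _ATTACHED)

__all__ = [
    "SteadyObservables",
    "observables",
    "find_vmax",
    "force_velocity_scan",
    "atp_velocity_scan",
    "fit_km_v",
    "efficiency",
    "q10_scale",
    "q10_scale_params",
]

#: conversion from per-head force (pN) to fibre tension (kPa):
#: 294 heads per half filament over a 2e-15 m^2 lattice cross-section
PN_PER_HEAD_TO_KPA = 294 * 1.0e-12 / 2.0e-15 / 1.0e3


@dataclass(frozen=True)
class SteadyObservables:
    """Per-head steady-state observables at one sliding velocity."""

    v: float            # nm/s
    F: float            # pN per head
    S: float            # pN/nm per head
    Na: float           # attached fraction
    mean_strain: float  # nm, attached-weighted mean extension
    ATPase: float       # 1/s per head
    efficiency: float = np.nan

    @property
    def tension_kPa(self) -> float:
        return self.F * PN_PER_HEAD_TO_KPA


def observables(density: ActiveDensity, params: ActiveParameters) -> SteadyObservables:
    """Force, stiffness, attached fraction, mean strain and ATPase."""
    x = density.x
    a = density.a
    profs = (params.profile_AMDL, params.profile_AMDH, params.profile_AMAMD)
    refs = (params.x1, params.x2, params.x3)
    den_sel = (x >= params.denom_lo) & (x <= params.x_hi)
    denom = np.trapezoid(a[:, den_sel].sum(axis=0), x[den_sel])
    if density.periodic:
        # heads still attached below the repeat edge occupy no slot there
        below = x < params.denom_lo
        denom += np.trapezoid(a[_ATTACHED][:, below].sum(axis=0), x[below])
    if denom <= 0:
        raise ValueError("zero denominator: empty density")
    num_F = num_S = num_Na = num_strain = 0.0
    for j, (prof, xr) in enumerate(zip(profs, refs)):
        ext = x - xr
        num_F += np.trapezoid(a[j] * prof.force_at(ext), x)
        num_S += np.trapezoid(a[j] * prof.stiffness_at(ext), x)
        num_Na += np.trapezoid(a[j], x)
        num_strain += np.trapezoid(a[j] * ext, x)
    r = rate_table(params, x, density.v if density.v > 0 else None)
    num_atp = np.trapezoid(r["k_off"] * a[2], x)
    return SteadyObservables(
        v=density.v,
        F=num_F / denom,
        S=num_S / denom,
        Na=num_Na / denom,
        mean_strain=(num_strain / num_Na) if num_Na > 0 else 0.0,
        ATPase=num_atp / denom,
    )


def _force_at_v(params: ActiveParameters, v: float) -> float:
    return observables(solve_steady(params, v), params).F


def find_vmax(params: ActiveParameters, f_tol: float = 1.0e-3,
              v_start: float = 1000.0, v_cap: float = 2.0e5) -> float:
    """Unloaded shortening velocity: the zero crossing of <F>(v), nm/s.

    Brackets by doubling from ``v_start`` and bisects until the per-head
    force magnitude falls below ``f_tol`` (pN).
    """
    lo = v_start
    f_lo = _force_at_v(params, lo)
    if f_lo <= 0:
        lo, f_lo = v_start / 100, _force_at_v(params, v_start / 100)
        if f_lo <= 0:
            raise ValueError("force not positive at the lower bracket")
    hi = lo
    f_hi = f_lo
    while f_hi > 0:
        hi *= 2.0
        if hi > v_cap:
            raise ValueError("no force zero crossing below v_cap")
        f_hi = _force_at_v(params, hi)
    while True:
        mid = 0.5 * (lo + hi)
        f_mid = _force_at_v(params, mid)
        if abs(f_mid) < f_tol or (hi - lo) / mid < 1.0e-4:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid


def force_velocity_scan(params: ActiveParameters, velocities,
                        dG_ATP: float = 25.0) -> pd.DataFrame:
    """Steady observables over a velocity grid (isometric row for v = 0)."""
    rows = []
    for v in velocities:
        dens = solve_isometric(params) if v == 0 else solve_steady(params, float(v))
        obs = observables(dens, params)
        obs = replace(obs, efficiency=efficiency(obs, params, dG_ATP=dG_ATP))
        rows.append(obs.__dict__ | {"tension_kPa": obs.tension_kPa})
    df = pd.DataFrame(rows)
    f0 = df.loc[df["v"].idxmin(), "F"]
    vmax = df.loc[df["F"] > 0, "v"].max()
    df["F_norm"] = df["F"] / f0 if f0 > 0 else np.nan
    df["v_norm"] = df["v"] / vmax if np.isfinite(vmax) and vmax > 0 else np.nan
    return df


def atp_velocity_scan(params: ActiveParameters, mgatp_grid) -> pd.DataFrame:
    """Unloaded velocity as a function of [MgATP] (mM)."""
    mgatp_grid = np.asarray(list(mgatp_grid), dtype=float)
    if mgatp_grid.size < 5 or mgatp_grid.min() < 0.05 or mgatp_grid.max() > 5.0:
        raise ValueError("need >= 5 MgATP values spanning 0.05-5 mM")
    rows = []
    for T in mgatp_grid:
        p = replace(params, MgATP=float(T))
        rows.append({"MgATP_mM": float(T), "v_nm_s": find_vmax(p)})
    return pd.DataFrame(rows)


def fit_km_v(table: pd.DataFrame) -> dict:
    """Least-squares rectangular-hyperbola fit v = Vmax*T/(Km + T).

    Returns ``{"vmax_nm_s", "km_mM", "rss"}``.
    """
    T = np.asarray(table["MgATP_mM"], dtype=float)
    v = np.asarray(table["v_nm_s"], dtype=float)
    hyper = lambda t, vmax, km: vmax * t / (km + t)
    p0 = (float(v.max()), float(np.median(T)))
    popt, _ = curve_fit(hyper, T, v, p0=p0, maxfev=20000)
    rss = float(np.sum((v - hyper(T, *popt)) ** 2))
    return {"vmax_nm_s": float(popt[0]), "km_mM": float(popt[1]), "rss": rss}


def efficiency(obs: SteadyObservables, params: ActiveParameters,
               dG_ATP: float = 25.0) -> float:
    """Thermodynamic efficiency <F> v / (<ATPase> dG_ATP kBT).

    ``dG_ATP`` is the free energy of ATP hydrolysis in kBT (default 25,
    an assumption recorded in the configuration comments).
    """
    if obs.ATPase <= 0:
        return 0.0
    power = max(obs.F, 0.0) * obs.v          # pN nm / s
    return power / (obs.ATPase * dG_ATP * params.kBT)


def q10_scale(rate: float, T_from: float, T_to: float, Q10: float) -> float:
    """Scale a rate constant between temperatures (deg C) with a Q10."""
    if Q10 <= 0:
        raise ValueError("Q10 must be positive")
    return rate * Q10 ** ((T_to - T_from) / 10.0)


def q10_scale_params(params: ActiveParameters, T_from: float, T_to: float,
                     Q10: float) -> ActiveParameters:
    """Apply Q10 scaling to every kinetic rate prefactor of the model.

    Equilibrium constants and free energies are left unchanged.
    """
    f = Q10 ** ((T_to - T_from) / 10.0)
    return replace(params, kb0=params.kb0 * f, kLH_minus=params.kLH_minus * f,
                   k5_x2=params.k5_x2 * f, k2_0=params.k2_0 * f,
                   k6=params.k6 * f, k_h=params.k_h * f)
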