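"""Synthetic pseudo-experimental curves and printed reference constants.

The generators emulate the statistical structure of the experimental data
the analyses are compared against - rectangular-hyperbolic velocity vs
[MgATP] curves and piecewise-linear tension-vs-length ("T1") curves - with
known ground truth and multiplicative Gaussian noise, so that the fitting
and comparison routines are testable without any downloads.  All
generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticCurve", "gen_hyperbola", "gen_t1_curve",
           "reference_constants", "lookup_reference"]


@dataclass(frozen=True)
class SyntheticCurve:
    """One synthetic curve with its generating ground truth."""

    predictor: np.ndarray
    response: np.ndarray
    ground_truth: dict
    noise_sd: float
    seed: int
    predictor_name: str = "x"
    response_name: str = "y"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.predictor_name: self.predictor,
                             self.response_name: self.response})

    def write_csv(self, path) -> None:
        """CSV with the seed and ground truth recorded in header comments."""
        with open(path, "w") as fh:
            fh.write(f"# seed = {self.seed}\n# noise_sd = {self.noise_sd}\n")
            for k, v in self.ground_truth.items():
                fh.write(f"# {k} = {v}\n")
            self.to_frame().to_csv(fh, index=False)


def gen_hyperbola(Vmax: float, Km: float, atp_grid, noise_sd: float = 0.0,
                  seed: int = 0) -> SyntheticCurve:
    """Velocity vs [MgATP] hyperbola v = Vmax*T/(Km+T) with relative noise.

    Each point is multiplied by (1 + eps), eps ~ N(0, noise_sd).
    """
    if Vmax <= 0 or Km <= 0:
        raise ValueError("Vmax and Km must be positive")
    T = np.asarray(list(atp_grid), dtype=float)
    v = Vmax * T / (Km + T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, noise_sd, size=T.shape))
    return SyntheticCurve(T, v, {"Vmax": Vmax, "Km": Km}, noise_sd, seed,
                          "MgATP_mM", "v_nm_s")


def gen_t1_curve(stiffness_kPa_nm: float, offsets, noise_sd: float = 0.0,
                 seed: int = 0, tension0_kPa: float = 0.0) -> SyntheticCurve:
    """Tension-vs-length-step ("T1") curve with relative noise.

    Piecewise linear: tension0 + stiffness * step, clipped at zero tension
    (a fibre cannot push), mimicking the shape of rapid length-step
    experiments used to estimate instantaneous sarcomere stiffness.
    """
    if stiffness_kPa_nm <= 0:
        raise ValueError("stiffness must be positive")
    dl = np.asarray(list(offsets), dtype=float)
    t1 = np.clip(tension0_kPa + stiffness_kPa_nm * dl, 0.0, None)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        t1 = t1 * (1.0 + rng.normal(0.0, noise_sd, size=dl.shape))
    return SyntheticCurve(dl, t1,
                          {"stiffness_kPa_nm": stiffness_kPa_nm,
                           "tension0_kPa": tension0_kPa},
                          noise_sd, seed, "dL_nm", "T1_kPa")


#: printed experimental comparison values (value, units, context)
_REFERENCE = {
    "stiffness_range": ((30.0, 70.0), "kPa/nm",
                        "sarcomere stiffness of rigor fibres"),
    "rigor_tension": ((30.0, 4.0), "kPa (mean, sem)",
                      "isometric rigor tension, skinned fibres"),
    "vmax_range": ((13000.0, 18000.0), "nm/s",
                   "unloaded shortening velocity, fast mammalian muscle, ~30 C"),
    "km_v": (0.4, "mM", "[MgATP] at half-maximal sliding velocity"),
    "active_tension": (150.0, "kPa", "isometric active tension, lattice level"),
}


def reference_constants() -> pd.DataFrame:
    """Table of printed experimental reference constants."""
    rows = [{"key": k, "value": v, "units": u, "context": c}
            for k, (v, u, c) in _REFERENCE.items()]
    return pd.DataFrame(rows)


def lookup_reference(key: str):
    """Value of one reference constant; raises KeyError for unknown keys."""
    if key not in _REFERENCE:
        raise KeyError(f"unknown reference constant {key!r}; "
                       f"known: {sorted(_REFERENCE)}")
    return _REFERENCE[key][0]
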