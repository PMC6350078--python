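"""Force-extension laws of attached cross-bridge states.

Each attached biochemical state of the actomyosin cross-bridge carries an
elastic element.  With *linear* (Hookean) elasticity the element has one
stiffness at all extensions.  With *nonlinear* elasticity the stiffness for
negative extension (the "drag-stroke" side, where the myosin subfragment-2
rod can buckle) is much lower, described by a piecewise-linear force law.

Sign convention: ``ext = x - x_ref`` where ``x_ref`` is the extension-free
position of the state; positive extension produces positive
(shortening-directed) force.

The nonlinearity interpolant ``c`` in [0, 1] slides the drag-stroke segment
stiffnesses of the AM/AMD state between the extreme single-molecule law
(``c = 0``) and the fully linear law (``c = 1``)::

    S_low(c) = 0.0326 + c * (2.8 - 0.0326)   [pN/nm, middle segment]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElasticityProfile",
    "make_profile",
    "make_rigor_cubic",
    "force_at",
    "stiffness_at",
    "strain_energy",
    "KBT_PN_NM",
]

#: thermal energy unit used throughout, pN*nm (kBT ~ 4 pN nm near 30 C)
KBT_PN_NM = 4.0

# stiffness of positively strained cross-bridges, pN/nm
_K_POS_ACTIVE = 2.8
_K_POS_RIGOR = 2.5

# drag-stroke breakpoints of the AM/AMD law, nm (extension coordinates)
_AM_BREAKS = (-4.0, -75.0, -90.0)


def _am_amd_slopes(c: float) -> tuple[float, float, float]:
    """Drag-stroke segment stiffnesses of the AM/AMD state for interpolant c."""
    return (
        0.308 + c * (2.8 - 0.308),
        0.0326 + c * (2.8 - 0.0326),
        2.8,
    )


@dataclass(frozen=True)
class ElasticityProfile:
    """Piecewise-linear force-extension law of one attached state.

    Parameters
    ----------
    state_id:
        One of ``AMDL``, ``AMDH``, ``AM_AMD``, ``rigor_AM``.
    mode:
        ``"linear"`` or ``"nonlinear"``.
    k_pos:
        Stiffness for positive extension, pN/nm.
    breakpoints:
        Strictly decreasing negative extensions delimiting the drag-stroke
        segments (the first segment spans ``[breakpoints[0], 0)``).
    segment_stiffnesses:
        Stiffness of each drag-stroke segment, pN/nm (same length as
        ``breakpoints``; the i-th value applies above ``breakpoints[i]``).
    c:
        Nonlinearity interpolant actually used to build the law.
    detach_beyond:
        Extension below which attachment is forbidden (force and stiffness
        are zero, elastic energy infinite), or ``None``.
    cubic:
        Optional ``(a1, a2, a3)`` coefficients replacing the piecewise
        negative side with ``F = a1*e + a2*e**2 + a3*e**3``.
    """

    state_id: str
    mode: str
    k_pos: float
    breakpoints: tuple[float, ...] = ()
    segment_stiffnesses: tuple[float, ...] = ()
    c: float = 1.0
    detach_beyond: float | None = None
    cubic: tuple[float, float, float] | None = None

    # cached knot forces / energies for the piecewise negative side
    _knot_force: tuple[float, ...] = field(default=(), repr=False)
    _knot_energy: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"unknown elasticity mode {self.mode!r}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"nonlinearity interpolant c={self.c} outside [0, 1]")
        if len(self.breakpoints) != len(self.segment_stiffnesses):
            raise ValueError("breakpoints and segment_stiffnesses length mismatch")
        # cumulative force / energy at the knots (force continuity by
        # construction: each segment integrates from the previous knot)
        kf, ke = [], []
        f = 0.0
        e = 0.0
        prev = 0.0
        for b, k in zip(self.breakpoints, self.segment_stiffnesses):
            de = b - prev
            e += f * de + 0.5 * k * de * de
            f += k * de
            kf.append(f)
            ke.append(e)
            prev = b
        object.__setattr__(self, "_knot_force", tuple(kf))
        object.__setattr__(self, "_knot_energy", tuple(ke))

    # ------------------------------------------------------------------
    @property
    def s_low(self) -> float:
        """Stiffness of the wide low-stiffness drag-stroke segment, pN/nm."""
        return self.stiffness_at(-40.0)

    def force_at(self, ext):
        """Cross-bridge force at extension ``ext`` (nm), in pN.

        Zero at zero extension, continuous and piecewise linear; zero is
        returned below ``detach_beyond`` where the state cannot exist.
        """
        e = np.asarray(ext, dtype=float)
        out = np.where(e >= 0.0, self.k_pos * e, 0.0)
        if self.cubic is not None:
            a1, a2, a3 = self.cubic
            out = np.where(e < 0.0, a1 * e + a2 * e**2 + a3 * e**3, out)
        elif self.breakpoints:
            prev_b, prev_f = 0.0, 0.0
            for b, k, f in zip(self.breakpoints, self.segment_stiffnesses, self._knot_force):
                seg = (e < prev_b) & (e >= b)
                out = np.where(seg, prev_f + k * (e - prev_b), out)
                prev_b, prev_f = b, f
        else:  # uniform linear law
            out = np.where(e < 0.0, self.k_pos * e, out)
        if self.detach_beyond is not None:
            out = np.where(e < self.detach_beyond, 0.0, out)
        return out if out.ndim else float(out)

    def stiffness_at(self, ext):
        """Tangent stiffness at extension ``ext`` (nm), in pN/nm."""
        e = np.asarray(ext, dtype=float)
        out = np.where(e >= 0.0, self.k_pos, 0.0)
        if self.cubic is not None:
            a1, a2, a3 = self.cubic
            out = np.where(e < 0.0, a1 + 2 * a2 * e + 3 * a3 * e**2, out)
        elif self.breakpoints:
            prev_b = 0.0
            for b, k in zip(self.breakpoints, self.segment_stiffnesses):
                out = np.where((e < prev_b) & (e >= b), k, out)
                prev_b = b
        else:
            out = np.where(e < 0.0, self.k_pos, out)
        if self.detach_beyond is not None:
            out = np.where(e < self.detach_beyond, 0.0, out)
        return out if out.ndim else float(out)

    def strain_energy(self, ext, kBT: float = KBT_PN_NM):
        """Elastic energy stored at extension ``ext``, in units of kBT.

        Exact closed form per piecewise segment (``int_0^ext F de / kBT``);
        infinite below ``detach_beyond`` (state forbidden there).
        """
        e = np.asarray(ext, dtype=float)
        out = np.where(e >= 0.0, 0.5 * self.k_pos * e * e, 0.0)
        if self.cubic is not None:
            a1, a2, a3 = self.cubic
            out = np.where(
                e < 0.0, a1 * e**2 / 2 + a2 * e**3 / 3 + a3 * e**4 / 4, out
            )
        elif self.breakpoints:
            prev_b, prev_f, prev_e = 0.0, 0.0, 0.0
            for b, k, f, en in zip(
                self.breakpoints, self.segment_stiffnesses, self._knot_force, self._knot_energy
            ):
                seg = (e < prev_b) & (e >= b)
                d = e - prev_b
                out = np.where(seg, prev_e + prev_f * d + 0.5 * k * d * d, out)
                prev_b, prev_f, prev_e = b, f, en
        else:
            out = np.where(e < 0.0, 0.5 * self.k_pos * e * e, out)
        if self.detach_beyond is not None:
            out = np.where(e < self.detach_beyond, np.inf, out)
        out = out / kBT
        return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# constructors

#: default rescaling of the drag-stroke slopes for the rigor law, so the
#: piecewise AM/AMD shape is used with the rigor positive-side stiffness
_RIGOR_SCALE = _K_POS_RIGOR / _K_POS_ACTIVE


def make_profile(state_id: str, mode: str, c: float = 0.0) -> ElasticityProfile:
    """Build the force-extension law for one attached state.

    ``AMDL`` / ``AMDH``: 2.8 pN/nm everywhere when linear; 2.8 pN/nm for
    positive and 0.12 pN/nm for negative extension when nonlinear.

    ``AM_AMD``: 2.8 pN/nm when linear; when nonlinear the drag-stroke
    segments interpolated by ``c`` with obligate detachment below -90 nm.

    ``rigor_AM``: positive-side stiffness 2.5 pN/nm; the nonlinear
    drag-stroke side reuses the AM/AMD piecewise shape rescaled by 2.5/2.8.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"nonlinearity interpolant c={c} outside [0, 1]")
    if state_id in ("AMDL", "AMDH"):
        if mode == "linear":
            return ElasticityProfile(state_id, mode, _K_POS_ACTIVE, c=1.0)
        return ElasticityProfile(
            state_id, mode, _K_POS_ACTIVE,
            breakpoints=(-1.0e6,), segment_stiffnesses=(0.12,), c=c,
        )
    if state_id == "AM_AMD":
        if mode == "linear":
            return ElasticityProfile(state_id, mode, _K_POS_ACTIVE, c=1.0)
        return ElasticityProfile(
            state_id, mode, _K_POS_ACTIVE,
            breakpoints=_AM_BREAKS, segment_stiffnesses=_am_amd_slopes(c),
            c=c, detach_beyond=-90.0,
        )
    if state_id == "rigor_AM":
        if mode == "linear":
            return ElasticityProfile(state_id, mode, _K_POS_RIGOR, c=1.0)
        slopes = tuple(_RIGOR_SCALE * s for s in _am_amd_slopes(c))
        return ElasticityProfile(
            state_id, mode, _K_POS_RIGOR,
            breakpoints=_AM_BREAKS, segment_stiffnesses=slopes,
            c=c, detach_beyond=-90.0,
        )
    raise ValueError(f"unknown state_id {state_id!r}")


def make_rigor_cubic(coeffs: tuple[float, float, float]) -> ElasticityProfile:
    """Rigor law with a user-supplied cubic drag-stroke side.

    ``F(e) = a1*e + a2*e**2 + a3*e**3`` for e < 0; 2.5 pN/nm for e >= 0.
    """
    return ElasticityProfile(
        "rigor_AM", "nonlinear", _K_POS_RIGOR, c=0.0,
        detach_beyond=-90.0, cubic=tuple(float(a) for a in coeffs),
    )


# module-level functional aliases -------------------------------------

def force_at(profile: ElasticityProfile, ext):
    return profile.force_at(ext)


def stiffness_at(profile: ElasticityProfile, ext):
    return profile.stiffness_at(ext)


def strain_energy(profile: ElasticityProfile, ext, kBT: float = KBT_PN_NM):
    return profile.strain_energy(ext, kBT=kBT)
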