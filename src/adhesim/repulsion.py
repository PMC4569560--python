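"""Gated nonlinear-spring cell-cell repulsion.

Lumps microvilli pushing, electrostatic repulsion and steric stabilization
into a cubic spring acting between every pair of surface faces closer than a
critical distance eps (default 1.2 um, the combined microvilli length scale):

    F_raw(d) = a*d + b*d^3        for d < eps, else 0

with a = -110e-6 N/m and b = 600e6 N/m^3, calibrated to hold the surfaces
roughly 0.3 um apart. Taken literally along the repulsive direction, the raw
cubic is negative (attractive) below its root d* = sqrt(-a/b) ~ 0.43 um and
positive beyond — the opposite of contact repulsion. The default "clamped"
convention therefore applies push = max(0, -F_raw): monotone repulsive below
d*, zero at and beyond it, continuous everywhere. The "signed" convention
applies the raw value as printed, for fidelity experiments.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .geometry import FacePairs, FaceSet, GeometryError, Load


@dataclasses.dataclass(frozen=True)
class RepulsionParams:
    """Cubic-spring constants and gating distance.

    ``mode`` selects the sign convention: "clamped" (default, purely
    repulsive) or "signed" (the cubic applied literally).
    """

    a: float = -110.0e-6  # [N/m]
    b: float = 600.0e6  # [N/m^3]
    eps: float = 1.2e-6  # critical (gating) distance [m]
    mode: str = "clamped"

    def __post_init__(self):
        if not self.b > 0.0:
            raise ValueError("repulsion constant b must be positive")
        if not self.eps > 0.0:
            raise ValueError("repulsion critical distance must be positive")
        if self.mode not in ("clamped", "signed"):
            raise ValueError("repulsion mode must be 'clamped' or 'signed'")

    @property
    def zero_force_root(self) -> float:
        """Separation d* = sqrt(-a/b) where the cubic crosses zero [m]."""
        if self.a >= 0.0:
            return 0.0
        return math.sqrt(-self.a / self.b)


def repulsion_magnitude(d: float, p: RepulsionParams) -> float:
    """Scalar force coefficient along the repulsive direction (from the PMN
    face toward the TC face) for one face pair at separation ``d``.

    Positive pushes the bodies apart. In clamped mode the result is
    ``max(0, -(a*d + b*d^3))``; in signed mode the raw cubic is returned, so
    short-range values are negative (attractive) — the printed formulation's
    pathology, preserved on purpose.
    """
    if not d > 0.0:
        raise GeometryError("face separation must be positive (bodies interpenetrating)")
    if d >= p.eps:
        return 0.0
    raw = p.a * d + p.b * d ** 3
    if p.mode == "clamped":
        return max(0.0, -raw)
    return raw


def repulsion_loads(
    pairs: FacePairs, tc_faces: FaceSet, pmn_faces: FaceSet, p: RepulsionParams
) -> tuple[Load, Load]:
    """Aggregate repulsion force and torque from all gated face pairs.

    Per pair the force on the TC face acts along the unit vector from the PMN
    face toward the TC face; the PMN receives the equal and opposite share
    (computed for completeness even though the PMN is fixed). Returns
    (load on TC, load on PMN).
    """
    F_tc = np.zeros(3)
    T_tc = np.zeros(3)
    F_pmn = np.zeros(3)
    T_pmn = np.zeros(3)
    tc_lever = {int(fid): tc_faces.lever_arms[k] for k, fid in enumerate(tc_faces.face_ids)}
    pmn_lever = {int(fid): pmn_faces.lever_arms[k] for k, fid in enumerate(pmn_faces.face_ids)}
    for k in range(len(pairs)):
        d = float(pairs.distance[k])
        if d >= p.eps:
            continue
        scalar = repulsion_magnitude(d, p)
        if scalar == 0.0:
            continue
        # pairs.e_hat points TC -> PMN; repulsion pushes the TC the other way
        f_tc = -scalar * pairs.e_hat[k]
        F_tc += f_tc
        T_tc += np.cross(tc_lever[int(pairs.tc_ids[k])], f_tc)
        F_pmn += -f_tc
        T_pmn += np.cross(pmn_lever[int(pairs.pmn_ids[k])], -f_tc)
    return Load(F_tc, T_tc), Load(F_pmn, T_pmn)
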