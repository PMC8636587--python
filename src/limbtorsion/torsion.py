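"""Signed torsion angles from pairs of axial reference lines.

Torsion is the projected angle, in the axial plane, between a bone's proximal
and distal reference lines.  Sign conventions follow clinical usage:

* **femoral torsion** is positive for antetorsion — the femoral neck axis
  rotated anteriorly relative to the posterior condylar line (internal
  rotation of the distal segment relative to the proximal one);
* **tibial torsion** is positive for external torsion — the distal
  tibio-fibular line externally rotated relative to the posterior tibial
  condylar line.

Reference lines are undirected up to the orientation rules fixed upstream, so
angles are reduced to (-90 deg, 90 deg]; clinical torsion magnitudes stay far
from the wrap boundary.  For left limbs the x-axis is mirrored before the
angle is taken, so both sides report on the same scale (positive =
antetorsion / external tibial torsion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .landmarks import LandmarkSet, MissingBoneError, ReferenceLine, Side
from .volume import LabelMask

__all__ = [
    "TorsionMeasurement", "projected_axial_angle", "femoral_torsion",
    "tibial_torsion", "measure_limb",
]


def _reduce_halfturn(angle_deg: float) -> float:
    """Map an angle to the half-turn interval (-90, 90]."""
    r = (angle_deg + 90.0) % 180.0 - 90.0
    if r <= -90.0:
        r += 180.0
    return r


def projected_axial_angle(u, v) -> float:
    """Signed angle (degrees) from ``v`` to ``u`` in the axial plane.

    Counterclockwise in canonical (x, y) array coordinates is positive; the
    result is reduced to (-90, 90] because reference lines are undirected.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValueError("projected angle undefined for a zero vector")
    cross = v[0] * u[1] - v[1] * u[0]
    dot = float(u @ v)
    return _reduce_halfturn(float(np.degrees(np.arctan2(cross, dot))))


def _mirror_if_left(direction: np.ndarray, side: Side) -> np.ndarray:
    if side == "left":
        return np.array([-direction[0], direction[1]])
    if side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return direction


def femoral_torsion(proximal: ReferenceLine, distal: ReferenceLine,
                    side: Side = "right") -> float:
    """Femoral torsion in degrees; positive = antetorsion."""
    if proximal.kind != "proximal_femoral" or distal.kind != "distal_femoral":
        raise ValueError(
            f"expected proximal_femoral/distal_femoral lines, got "
            f"{proximal.kind}/{distal.kind}")
    u = _mirror_if_left(distal.direction, side)
    v = _mirror_if_left(proximal.direction, side)
    return projected_axial_angle(u, v)


def tibial_torsion(proximal: ReferenceLine, distal: ReferenceLine,
                   side: Side = "right") -> float:
    """Tibial torsion in degrees; positive = external torsion."""
    if proximal.kind != "proximal_tibial" or distal.kind != "distal_tibial":
        raise ValueError(
            f"expected proximal_tibial/distal_tibial lines, got "
            f"{proximal.kind}/{distal.kind}")
    u = _mirror_if_left(proximal.direction, side)
    v = _mirror_if_left(distal.direction, side)
    return projected_axial_angle(u, v)


@dataclass
class TorsionMeasurement:
    femoral_torsion: float
    tibial_torsion: float
    side: Side
    landmarks: LandmarkSet
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "femoral_torsion_deg": float(self.femoral_torsion),
            "tibial_torsion_deg": float(self.tibial_torsion),
            "side": self.side,
            "warnings": list(self.warnings),
            "provenance": self.landmarks.to_dict(),
        }


def measure_limb(hip: LabelMask, knee: LabelMask, ankle: LabelMask,
                 side: Side = "right") -> TorsionMeasurement:
    """Full per-limb measurement from three single-limb label masks.

    Runs every landmark operation, assembles the four reference lines, and
    returns both torsion angles with full provenance.  Missing-bone errors
    propagate with the offending joint named; landmark warnings (fallback
    slice selections, degenerate moments) are collected on the measurement.
    """
    for joint, mask in (("hip", hip), ("knee", knee), ("ankle", ankle)):
        if mask is None:
            raise MissingBoneError(f"{joint}: mask is missing")

    def named(joint, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MissingBoneError as err:
            raise MissingBoneError(f"{joint}: {err}") from err

    from .landmarks import (distal_tibial_line, femoral_head_center,
                            posterior_condylar_line, proximal_femoral_line)
    from .volume import FEMUR, TIBIA

    head = named("hip", femoral_head_center, hip, side)
    lms = LandmarkSet(femoral_head_center_mm=head, lines={
        "proximal_femoral": named("hip", proximal_femoral_line, hip, head, side),
        "distal_femoral": named("knee", posterior_condylar_line, knee, FEMUR, side=side),
        "proximal_tibial": named("knee", posterior_condylar_line, knee, TIBIA, side=side),
        "distal_tibial": named("ankle", distal_tibial_line, ankle, side),
    })
    ft = femoral_torsion(lms.lines["proximal_femoral"], lms.lines["distal_femoral"], side)
    tt = tibial_torsion(lms.lines["proximal_tibial"], lms.lines["distal_tibial"], side)
    warnings = [f"{name}: {w}" for name, line in lms.lines.items()
                for w in line.warnings]
    return TorsionMeasurement(femoral_torsion=ft, tibial_torsion=tt, side=side,
                              landmarks=lms, warnings=warnings)
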