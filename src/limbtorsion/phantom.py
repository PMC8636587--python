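"""Parametric lower-limb phantoms with analytically known torsion.

Each phantom is one limb imaged as three axial stacks (hip, knee, ankle) in
the canonical frame, mimicking the acquisition geometry of clinical torsion
MRI: anisotropic voxels (default 0.6 x 0.6 x 6.5 mm), 29 slices per stack,
bright bone on dark background.  The construction encodes the requested
torsion angles exactly:

* the **femoral neck** (head ball + neck capsule + trochanter ball, all
  centred on one axial line) is rotated anteriorly by ``femoral_torsion``
  relative to the femoral condylar axis;
* the **condyles** of femur and tibia are equal-radius ball pairs, so the
  line through their posterior poles is exactly parallel to the line through
  their centres (the condylar axis);
* the **fibula** is a thin cylinder placed so the tibio-fibular centroid line
  realizes ``tibial_torsion`` (external-positive) against the tibial condylar
  axis.

Left-sided phantoms are exact mirrors of the right-sided construction.  The
intensity model is binary bone (1.0) on background (0.0) with optional
additive Gaussian noise and one optional acquisition artifact per stack; it
keeps the segmentation task learnable at desk scale while exercising the full
measurement pipeline.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import ndimage

from .artifacts import ARTIFACT_FAMILIES, apply_artifact
from .torsion import projected_axial_angle
from .volume import FEMUR, FIBULA, TIBIA, LabelMask, Volume

__all__ = ["PhantomSpec", "GroundTruth", "LimbPhantom", "generate_phantom",
           "phantom_batch", "segment_stack_by_threshold"]

Side = Literal["left", "right"]


@dataclass
class PhantomSpec:
    """Ground-truth parameters of one synthetic limb (lengths in mm)."""

    femoral_torsion: float = 15.0
    tibial_torsion: float = 30.0
    side: Side = "right"
    # proximal femur
    head_radius: float = 14.0
    neck_length: float = 32.0
    neck_radius: float = 6.0
    trochanter_radius: float = 10.0
    shaft_radius: float = 9.0
    # knee
    condyle_radius: float = 11.0
    condyle_sep: float = 40.0
    tibial_condyle_radius: float = 10.0
    tibial_condyle_sep: float = 34.0
    # ankle
    tibia_radius: float = 9.0
    fibula_radius: float = 4.5
    fibula_offset: float = 22.0
    tibia_anterior_offset: float = 10.0
    # grid
    spacing: tuple[float, float, float] = (0.6, 0.6, 6.5)
    shape: tuple[int, int, int] = (144, 144, 29)
    # pose perturbations (degrees, in the axial plane)
    axis_rotation: float = 0.0
    ankle_rotation: float = 0.0
    # imaging
    noise_sd: float = 0.0
    artifact: str | None = None
    epiphyseal_gap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        geometric = (self.head_radius, self.neck_length, self.neck_radius,
                     self.trochanter_radius, self.shaft_radius,
                     self.condyle_radius, self.condyle_sep,
                     self.tibial_condyle_radius, self.tibial_condyle_sep,
                     self.tibia_radius, self.fibula_radius, self.fibula_offset)
        if any(g <= 0 for g in geometric):
            raise ValueError("all geometric parameters must be positive")
        for name in ("femoral_torsion", "tibial_torsion"):
            v = getattr(self, name)
            if not -90.0 < v < 90.0:
                raise ValueError(f"{name} must lie in (-90, 90) degrees, got {v}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.artifact is not None and self.artifact not in ARTIFACT_FAMILIES:
            raise ValueError(f"unknown artifact family {self.artifact!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Analytic construction record; all directions are axial-plane unit
    vectors for the limb as generated (already mirrored for left sides)."""

    head_center_mm: tuple[float, float, float]
    neck_axis: tuple[float, float]
    condylar_axis: tuple[float, float]
    tibial_condylar_axis: tuple[float, float]
    tibiofibular_axis: tuple[float, float]
    femoral_torsion: float
    tibial_torsion: float

    def to_dict(self) -> dict:
        return {
            "head_center_mm": [float(v) for v in self.head_center_mm],
            "neck_axis": [float(v) for v in self.neck_axis],
            "condylar_axis": [float(v) for v in self.condylar_axis],
            "tibial_condylar_axis": [float(v) for v in self.tibial_condylar_axis],
            "tibiofibular_axis": [float(v) for v in self.tibiofibular_axis],
            "femoral_torsion": float(self.femoral_torsion),
            "tibial_torsion": float(self.tibial_torsion),
        }


@dataclass
class LimbPhantom:
    spec: PhantomSpec
    hip: tuple[Volume, LabelMask]
    knee: tuple[Volume, LabelMask]
    ankle: tuple[Volume, LabelMask]
    truth: GroundTruth

    @property
    def stacks(self) -> dict[str, tuple[Volume, LabelMask]]:
        return {"hip": self.hip, "knee": self.knee, "ankle": self.ankle}

    def masks(self) -> dict[str, LabelMask]:
        return {region: pair[1] for region, pair in self.stacks.items()}


# ---------------------------------------------------------------------------
# rasterization helpers (operate on 2D in-plane mm grids, slice by slice)


def _rot(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


class _StackBuilder:
    def __init__(self, shape, spacing):
        self.shape = shape
        self.spacing = spacing
        X, Y, Z = shape
        sx, sy, sz = spacing
        self.labels = np.zeros(shape, dtype=np.uint8)
        xc = (np.arange(X) + 0.5) * sx
        yc = (np.arange(Y) + 0.5) * sy
        self.XX, self.YY = np.meshgrid(xc, yc, indexing="ij")
        self.zc = (np.arange(Z) + 0.5) * sz

    def _paint(self, sel2d: np.ndarray, k: int, cls: int) -> None:
        self.labels[:, :, k][sel2d] = cls

    def _disk(self, center, r) -> np.ndarray:
        return (self.XX - center[0]) ** 2 + (self.YY - center[1]) ** 2 <= r * r

    def ball(self, center_xy, z_mm: float, r: float, cls: int) -> None:
        for k, zk in enumerate(self.zc):
            dz = zk - z_mm
            if abs(dz) < r:
                self._paint(self._disk(center_xy, np.sqrt(r * r - dz * dz)), k, cls)

    def cylinder(self, center_xy, r: float, k0: int, k1: int, cls: int) -> None:
        sel = self._disk(center_xy, r)
        for k in range(max(k0, 0), min(k1, self.shape[2] - 1) + 1):
            self._paint(sel, k, cls)

    def capsule_slice(self, p0, p1, r: float, k: int, cls: int) -> None:
        p0 = np.asarray(p0, float)
        d = np.asarray(p1, float) - p0
        L2 = float(d @ d)
        px, py = self.XX - p0[0], self.YY - p0[1]
        t = np.clip((px * d[0] + py * d[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
        dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
        self._paint(dist2 <= r * r, k, cls)

    def check_inside(self, center_xy, r: float, what: str) -> None:
        X, Y = self.shape[0] * self.spacing[0], self.shape[1] * self.spacing[1]
        if (center_xy[0] - r < 0 or center_xy[0] + r > X
                or center_xy[1] - r < 0 or center_xy[1] + r > Y):
            raise ValueError(
                f"invalid phantom spec: {what} leaves the stack grid "
                f"(centre {tuple(np.round(center_xy, 1))}, radius {r})")


# ---------------------------------------------------------------------------
# generation


def generate_phantom(spec: PhantomSpec) -> LimbPhantom:
    """Generate hip/knee/ankle stacks plus the analytic ground truth."""
    X, Y, Z = spec.shape
    sx, sy, sz = spec.spacing
    centre = np.array([X * sx / 2.0, Y * sy / 2.0])
    R = _rot(spec.axis_rotation)
    ft, tt = spec.femoral_torsion, spec.tibial_torsion

    # ---- hip: head + neck + trochanter on one slice, shaft below
    hip = _StackBuilder(spec.shape, spec.spacing)
    kh = int(round(0.30 * (Z - 1)))
    zh = hip.zc[kh]
    u_n = R @ np.array([np.cos(np.deg2rad(ft)), -np.sin(np.deg2rad(ft))])
    head = centre + (spec.neck_length / 2.0) * u_n
    troch = centre - (spec.neck_length / 2.0) * u_n
    hip.check_inside(head, spec.head_radius, "femoral head")
    hip.check_inside(troch, spec.trochanter_radius, "greater trochanter")
    hip.ball(head, zh, spec.head_radius, FEMUR)
    hip.capsule_slice(head, troch, spec.neck_radius, kh, FEMUR)
    hip.ball(troch, zh, spec.trochanter_radius, FEMUR)
    hip.cylinder(troch, spec.shaft_radius, kh + 1, Z - 1, FEMUR)

    # ---- knee: condylar ball pairs with an anterior bridge, shafts
    knee = _StackBuilder(spec.shape, spec.spacing)
    u_c = R @ np.array([1.0, 0.0])
    kf = int(round(0.35 * (Z - 1)))
    kt = int(round(0.65 * (Z - 1)))
    if kt - kf < 2:
        raise ValueError("invalid phantom spec: too few slices to separate "
                         "femoral and tibial condyles")
    for (bone, k, r_c, sep, shaft_r, bridge_r) in (
            (FEMUR, kf, spec.condyle_radius, spec.condyle_sep,
             spec.shaft_radius, 5.0),
            (TIBIA, kt, spec.tibial_condyle_radius, spec.tibial_condyle_sep,
             spec.tibia_radius, 4.0)):
        zc = knee.zc[k]
        c_med = centre + (sep / 2.0) * u_c
        c_lat = centre - (sep / 2.0) * u_c
        knee.check_inside(c_med, r_c, "condyle")
        knee.check_inside(c_lat, r_c, "condyle")
        knee.ball(c_med, zc, r_c, bone)
        knee.ball(c_lat, zc, r_c, bone)
        # metaphyseal bridge: anterior of the condylar axis so the posterior
        # poles of the balls stay the most posterior points of each half
        anterior = R @ np.array([0.0, -6.0])
        knee.capsule_slice(c_med + anterior, c_lat + anterior, bridge_r, k, bone)
        if bone == FEMUR:
            knee.cylinder(centre + anterior, shaft_r, 0, kf - 1, bone)
        else:
            knee.cylinder(centre + anterior, shaft_r, kt + 1, Z - 1, bone)

    # ---- ankle: tibia and fibula cylinders
    ankle = _StackBuilder(spec.shape, spec.spacing)
    # ankle_rotation is an additional *external* rotation of the distal
    # segment, which for the right-sided construction is clockwise in (x, y)
    Ra = _rot(spec.axis_rotation - spec.ankle_rotation)
    u_ct = Ra @ np.array([1.0, 0.0])  # tibial condylar axis as seen distally
    u_tf = Ra @ np.array([-np.cos(np.deg2rad(tt)), np.sin(np.deg2rad(tt))])
    p_t = centre + Ra @ np.array([0.0, -spec.tibia_anterior_offset])
    p_f = p_t + spec.fibula_offset * u_tf
    ankle.check_inside(p_t, spec.tibia_radius, "distal tibia")
    ankle.check_inside(p_f, spec.fibula_radius, "fibula")
    ka = int(round(0.8 * (Z - 1)))
    ankle.cylinder(p_t, spec.tibia_radius, 0, ka, TIBIA)
    ankle.cylinder(p_f, spec.fibula_radius, 0, ka, FIBULA)

    head_mm = (float(head[0]), float(head[1]), float(zh))
    truth_dirs = {
        "neck": u_n, "cond": R @ np.array([1.0, 0.0]),
        "cond_t": R @ np.array([1.0, 0.0]), "tf": u_tf,
    }

    stacks = {}
    rng = np.random.default_rng(spec.seed)
    for region, builder in (("hip", hip), ("knee", knee), ("ankle", ankle)):
        labels = builder.labels
        if spec.side == "left":
            labels = np.flip(labels, axis=0).copy()
        intensities = (labels > 0).astype(np.float32)
        if spec.epiphyseal_gap and region == "knee":
            for bone, k in ((FEMUR, kf - 1), (TIBIA, kt + 1)):
                sel = labels[:, :, k] == bone
                intensities[:, :, k][sel] *= 0.2
        if spec.noise_sd > 0:
            intensities = intensities + rng.normal(
                0.0, spec.noise_sd, size=intensities.shape).astype(np.float32)
        if spec.artifact is not None:
            extra = {"spacing": spec.spacing} if spec.artifact == "motion" else {}
            intensities = apply_artifact(
                intensities, spec.artifact, seed=int(rng.integers(0, 2 ** 31)),
                **extra)
        stacks[region] = (
            Volume(data=intensities, spacing=spec.spacing, region=region),
            LabelMask(data=labels, spacing=spec.spacing, region=region),
        )

    if spec.side == "left":
        mirror_x = X * sx
        head_mm = (mirror_x - head_mm[0], head_mm[1], head_mm[2])
        truth_dirs = {k: np.array([-v[0], v[1]]) for k, v in truth_dirs.items()}

    def mirrored(d):
        return np.array([-d[0], d[1]]) if spec.side == "left" else d

    truth = GroundTruth(
        head_center_mm=head_mm,
        neck_axis=tuple(truth_dirs["neck"]),
        condylar_axis=tuple(truth_dirs["cond"]),
        tibial_condylar_axis=tuple(truth_dirs["cond_t"]),
        tibiofibular_axis=tuple(truth_dirs["tf"]),
        # closed-form angles recomputed from the recorded directions with the
        # same sign conventions as the measurement
        femoral_torsion=projected_axial_angle(
            mirrored(truth_dirs["cond"]), mirrored(truth_dirs["neck"])),
        tibial_torsion=projected_axial_angle(
            mirrored(truth_dirs["cond_t"]), mirrored(truth_dirs["tf"])),
    )
    return LimbPhantom(spec=spec, hip=stacks["hip"], knee=stacks["knee"],
                       ankle=stacks["ankle"], truth=truth)


def phantom_batch(n: int, ranges: Mapping[str, tuple[float, float]] | None = None,
                  seed: int = 0, **fixed) -> list[LimbPhantom]:
    """Draw ``n`` phantom specs uniformly from per-parameter ranges.

    ``ranges`` maps PhantomSpec field names to ``(low, high)`` intervals
    (degenerate ``low == high`` intervals pin the value); ``fixed`` passes
    constant spec fields through.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(ranges or {"femoral_torsion": (-20.0, 45.0),
                             "tibial_torsion": (0.0, 45.0)})
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        kwargs = dict(fixed)
        for name, (lo, hi) in ranges.items():
            kwargs[name] = float(rng.uniform(lo, hi))
        kwargs.setdefault("side", "right" if rng.random() < 0.5 else "left")
        kwargs["seed"] = int(rng.integers(0, 2 ** 31))
        out.append(generate_phantom(PhantomSpec(**kwargs)))
    return out


# ---------------------------------------------------------------------------
# rule-based reference segmentation of phantom stacks


def segment_stack_by_threshold(volume: Volume, region: str | None = None,
                               threshold: float = 0.5, min_voxels: int = 30,
                               smooth_sigma: float = 0.7) -> LabelMask:
    """Segment a phantom stack by intensity thresholding plus region rules.

    Intensities are smoothed in-plane (Gaussian, ``smooth_sigma`` voxels) so
    additive noise cannot punch through the threshold, then binarized.
    Connected bright components below ``min_voxels`` are discarded as noise.
    Class assignment uses the stack's body region: hip voxels are femur; in
    the knee, components superior of the stack midplane are femur and the
    rest tibia; in the ankle, the largest component is tibia and the others
    fibula.  Intended for noiseless or mildly corrupted phantom stacks, e.g.
    to validate the geometry pipeline independently of the network.
    """
    region = region or volume.region
    if region not in ("hip", "knee", "ankle"):
        raise ValueError(f"region must be hip/knee/ankle, got {region!r}")
    data = volume.data
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=(smooth_sigma, smooth_sigma, 0))
    fg = data >= threshold
    comps, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    labels = np.zeros(volume.shape, dtype=np.uint8)
    if n:
        counts = np.bincount(comps.ravel())
        keep = [i for i in range(1, n + 1) if counts[i] >= min_voxels]
        if region == "ankle" and keep:
            largest = max(keep, key=lambda i: counts[i])
        for i in keep:
            if region == "hip":
                cls = FEMUR
            elif region == "knee":
                cz = ndimage.center_of_mass(comps == i)[2]
                cls = FEMUR if cz < volume.shape[2] / 2.0 else TIBIA
            else:
                cls = TIBIA if i == largest else FIBULA
            labels[comps == i] = cls
    # noise at marginal intensities punches interior holes, which would cap
    # the inscribed-sphere landmark; fill them per class
    for cls in (FEMUR, TIBIA, FIBULA):
        sel = labels == cls
        if sel.any():
            labels[ndimage.binary_fill_holes(sel)] = cls
    return LabelMask(data=labels, spacing=volume.spacing, region=region)
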