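"""Anatomic landmark extraction and reference lines from single-limb masks.

All operations are deterministic, closed-form geometry on label masks in the
canonical frame (x right->left, y anterior->posterior, z superior->inferior).
Four axial reference lines are produced per limb:

* **proximal femoral** — the femoral neck axis at the hip.  The femoral head
  centre is located as the centre of the largest inscribed sphere of the
  proximal femur (argmax of the anisotropic Euclidean distance transform over
  the proximal third of the bone); the neck slice is the most proximal axial
  slice, at or distal to the head centre, on which the femur cross-section is
  wide enough to contain head, neck and greater trochanter; the axis is the
  major principal axis of that cross-section's second moments.
* **distal femoral / proximal tibial** — the posterior condylar lines: on the
  axial slice with the largest convex cross-sectional area, the most
  posterior point of the medial and of the lateral half are connected.
* **distal tibial** — the line connecting the tibial and fibular centroids on
  the most distal slice where both bones present a sufficient cross-section.

Positions are reported both as voxel indices and in millimetres (voxel-centre
convention: mm = (index + 0.5) * spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .volume import FEMUR, FIBULA, TIBIA, CLASS_NAMES, LabelMask

__all__ = [
    "MissingBoneError", "DegenerateAnatomyError", "ReferenceLine", "LandmarkSet",
    "femoral_head_center", "proximal_femoral_line", "select_condylar_slice",
    "posterior_condylar_line", "distal_tibial_line", "extract_reference_lines",
]

Side = Literal["left", "right"]

#: the neck slice must show an in-plane extent at least this multiple of the
#: femoral head diameter (head + neck + trochanter visible); calibrated default
NECK_SLICE_DIAMETER_RATIO = 1.6
#: minimum cross-sectional area (mm^2) for tibia and fibula on the distal slice
MIN_DISTAL_AREA_MM2 = 25.0


class MissingBoneError(ValueError):
    """A required bone class is absent from the mask."""


class DegenerateAnatomyError(ValueError):
    """The mask geometry does not admit the requested landmark."""


def _medial_sign(side: Side) -> int:
    # canonical x increases right->left: for a right limb the body midline
    # (medial direction) lies at larger x, for a left limb at smaller x
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return 1 if side == "right" else -1


@dataclass
class ReferenceLine:
    kind: Literal["proximal_femoral", "distal_femoral", "proximal_tibial", "distal_tibial"]
    slice_index: int
    direction: np.ndarray  # 2D unit vector, axial (x, y) plane
    anchors_vox: list[tuple[float, float, float]]
    anchors_mm: list[tuple[float, float, float]]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("reference line direction must be a nonzero vector")
        self.direction = d / n

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "slice_index": int(self.slice_index),
            "direction": [float(v) for v in self.direction],
            "anchors_vox": [[float(v) for v in a] for a in self.anchors_vox],
            "anchors_mm": [[float(v) for v in a] for a in self.anchors_mm],
            "warnings": list(self.warnings),
        }


@dataclass
class LandmarkSet:
    femoral_head_center_mm: tuple[float, float, float] | None
    lines: dict[str, ReferenceLine]

    def to_dict(self) -> dict:
        return {
            "femoral_head_center_mm": (
                None if self.femoral_head_center_mm is None
                else [float(v) for v in self.femoral_head_center_mm]),
            "lines": {k: v.to_dict() for k, v in self.lines.items()},
        }


# ---------------------------------------------------------------------------
# helpers


def _largest_component(mask: LabelMask, cls: int) -> np.ndarray:
    """Boolean grid of the largest 26-connected component of one class.

    Smaller fragments (typically segmentation noise) are ignored.
    """
    sel = mask.data == cls
    if not sel.any():
        raise MissingBoneError(f"no {CLASS_NAMES[cls]} voxels in mask")
    labels, n = ndimage.label(sel, structure=np.ones((3, 3, 3), bool))
    if n == 1:
        return sel
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def _vox_to_mm(idx, spacing) -> tuple[float, ...]:
    return tuple((float(i) + 0.5) * s for i, s in zip(idx, spacing))


def _mm_to_slice(z_mm: float, sz: float) -> int:
    return int(np.floor(z_mm / sz))


def _slice_points_mm(comp: np.ndarray, k: int, spacing) -> np.ndarray:
    """(n, 2) array of in-plane voxel-centre coordinates on slice k (mm)."""
    xs, ys = np.nonzero(comp[:, :, k])
    return np.column_stack([(xs + 0.5) * spacing[0], (ys + 0.5) * spacing[1]])


def _max_diameter(points: np.ndarray) -> float:
    """Maximum pairwise distance of a 2D point set (via its convex hull)."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 16:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # collinear sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def hull_area_mm2(points: np.ndarray) -> float:
    """Area of the 2D convex hull of voxel-centre points (0 for degenerate sets)."""
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2D "volume" is the area
    except QhullError:
        return 0.0


# ---------------------------------------------------------------------------
# proximal femur


def _head_center_and_radius(mask: LabelMask, side: Side = "right"):
    femur = _largest_component(mask, FEMUR)
    ks = np.nonzero(femur.any(axis=(0, 1)))[0]
    zmin, zmax = int(ks[0]), int(ks[-1])
    kcut = zmin + max(1, int(np.ceil((zmax - zmin + 1) / 3.0)))
    # distance transform of the full bone (restricting first would introduce
    # an artificial boundary at the cut); the argmax search is restricted to
    # the proximal third of the z-range
    dist = ndimage.distance_transform_edt(femur, sampling=mask.spacing)
    restricted = dist[:, :, :kcut]
    rmax = float(restricted.max())
    if rmax <= 0:
        raise DegenerateAnatomyError("femur has no interior voxel in its proximal third")
    cand = np.argwhere(restricted >= rmax - 1e-9)
    # ties: most proximal (smallest z), then most medial
    s = _medial_sign(side)
    order = np.lexsort((-s * cand[:, 0], cand[:, 2]))
    best = tuple(int(v) for v in cand[order[0]])
    # if the inscribed sphere is clipped by the cut, ascend the distance field
    # to its local maximum (exact for a spherical head)
    best = _ascend_distance_field(dist, best)
    return best, float(dist[best]), femur


def _ascend_distance_field(dist: np.ndarray, start: tuple[int, int, int]):
    shape = dist.shape
    current = start
    while True:
        i, j, k = current
        window = dist[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2,
                      max(k - 1, 0):k + 2]
        rel = np.unravel_index(int(np.argmax(window)), window.shape)
        nxt = (max(i - 1, 0) + rel[0], max(j - 1, 0) + rel[1],
               max(k - 1, 0) + rel[2])
        if dist[nxt] <= dist[current]:
            return current
        current = nxt


def femoral_head_center(mask: LabelMask, side: Side = "right") -> tuple[float, float, float]:
    """Femoral head centre (mm): centre of the largest sphere inscribed in the
    proximal third of the femur."""
    best, _, _ = _head_center_and_radius(mask, side)
    return _vox_to_mm(best, mask.spacing)


def proximal_femoral_line(mask: LabelMask,
                          head_center: tuple[float, float, float] | None = None,
                          side: Side = "right") -> ReferenceLine:
    """Femoral neck axis on the most proximal sufficiently wide femur slice."""
    best_vox, radius, femur = _head_center_and_radius(mask, side)
    if head_center is None:
        head_center = _vox_to_mm(best_vox, mask.spacing)
    head_xy = np.array(head_center[:2])
    head_diameter = 2.0 * radius
    kh = _mm_to_slice(head_center[2], mask.spacing[2])
    warnings: list[str] = []

    def component_with_head(k: int) -> np.ndarray | None:
        sl = femur[:, :, k]
        if not sl.any():
            return None
        labels, n = ndimage.label(sl, structure=np.ones((3, 3), bool))
        hi = int(round(head_center[0] / mask.spacing[0] - 0.5))
        hj = int(round(head_center[1] / mask.spacing[1] - 0.5))
        if 0 <= hi < sl.shape[0] and 0 <= hj < sl.shape[1] and labels[hi, hj] > 0:
            comp_id = labels[hi, hj]
        else:
            # head projection outside the slice: take the nearest component
            xs, ys = np.nonzero(sl)
            pts = np.column_stack([(xs + 0.5) * mask.spacing[0],
                                   (ys + 0.5) * mask.spacing[1]])
            nearest = np.argmin(((pts - head_xy) ** 2).sum(1))
            comp_id = labels[xs[nearest], ys[nearest]]
        out = np.zeros_like(sl)
        out[labels == comp_id] = True
        return out

    chosen = None
    diam_by_k = {}
    for k in range(max(kh, 0), mask.shape[2]):
        comp = component_with_head(k)
        if comp is None:
            continue
        pts = np.column_stack(np.nonzero(comp)).astype(float)
        pts = (pts + 0.5) * np.array(mask.spacing[:2])
        diam = _max_diameter(pts)
        diam_by_k[k] = (diam, comp, pts)
        if diam >= NECK_SLICE_DIAMETER_RATIO * head_diameter:
            chosen = k
            break
    if chosen is None:
        if not diam_by_k:
            raise DegenerateAnatomyError("no femur cross-section at or distal to the head")
        chosen = max(diam_by_k, key=lambda k: diam_by_k[k][0])
        warnings.append(
            "no slice reached the neck-slice diameter criterion; "
            "fell back to the widest cross-section")
    _, comp, pts = diam_by_k[chosen]
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0 or (evals[1] - evals[0]) / evals[1] < 1e-3:
        warnings.append("nearly isotropic cross-section; neck axis defaulted to the x-axis")
        direction = np.array([1.0, 0.0])
    else:
        direction = evecs[:, 1]  # eigenvector of the larger second moment
    # orient from the lateral end towards the femoral head
    if float(np.dot(direction, head_xy - centroid)) < 0:
        direction = -direction
    anchors_mm = [(*head_xy, (chosen + 0.5) * mask.spacing[2]),
                  (*centroid, (chosen + 0.5) * mask.spacing[2])]
    anchors_vox = [tuple(np.array(a) / np.array(mask.spacing) - 0.5) for a in anchors_mm]
    return ReferenceLine(kind="proximal_femoral", slice_index=chosen,
                         direction=direction, anchors_vox=anchors_vox,
                         anchors_mm=anchors_mm, warnings=warnings)


# ---------------------------------------------------------------------------
# knee


def select_condylar_slice(mask: LabelMask, bone: int) -> int:
    """Axial slice with the largest convex cross-sectional area of ``bone``.

    Ties resolve to the more distal slice for the femur and the more proximal
    slice for the tibia.
    """
    if bone not in (FEMUR, TIBIA):
        raise ValueError("bone must be FEMUR or TIBIA")
    comp = _largest_component(mask, bone)
    areas = {}
    for k in range(mask.shape[2]):
        pts = _slice_points_mm(comp, k, mask.spacing)
        if len(pts):
            areas[k] = hull_area_mm2(pts)
    if not areas:
        raise MissingBoneError(f"no {CLASS_NAMES[bone]} voxels in mask")
    best = max(areas.values())
    tol = 1e-9 * max(1.0, best)  # hull areas from different routes round differently
    tied = [k for k, a in areas.items() if a >= best - tol]
    return max(tied) if bone == FEMUR else min(tied)


def posterior_condylar_line(mask: LabelMask, bone: int,
                            slice_index: int | None = None,
                            side: Side = "right") -> ReferenceLine:
    """Line joining the most posterior points of the medial and lateral condyles.

    The cross-section is split into medial and lateral halves at the vertical
    line through its centroid; in each half the posterior-most voxel row is
    found and its mean x used as the condylar point (sub-voxel in x, exact in
    y).  The direction is oriented medial -> lateral.
    """
    s = _medial_sign(side)
    if slice_index is None:
        slice_index = select_condylar_slice(mask, bone)
    comp = _largest_component(mask, bone)
    pts = _slice_points_mm(comp, slice_index, mask.spacing)
    if not len(pts):
        raise MissingBoneError(
            f"no {CLASS_NAMES[bone]} voxels on slice {slice_index}")
    cx = pts[:, 0].mean()
    halves = {}
    for name, sel in (("medial", s * (pts[:, 0] - cx) > 0),
                      ("lateral", s * (pts[:, 0] - cx) < 0)):
        sub = pts[sel]
        if not len(sub):
            raise DegenerateAnatomyError(
                f"{name} half of the {CLASS_NAMES[bone]} cross-section is empty "
                f"on slice {slice_index}")
        ymax = sub[:, 1].max()
        run = sub[sub[:, 1] == ymax]
        halves[name] = np.array([run[:, 0].mean(), ymax])
    med, lat = halves["medial"], halves["lateral"]
    direction = lat - med
    if np.linalg.norm(direction) == 0:
        raise DegenerateAnatomyError("condylar points coincide")
    z_mm = (slice_index + 0.5) * mask.spacing[2]
    anchors_mm = [(*med, z_mm), (*lat, z_mm)]
    anchors_vox = [tuple(np.array(a) / np.array(mask.spacing) - 0.5) for a in anchors_mm]
    kind = "distal_femoral" if bone == FEMUR else "proximal_tibial"
    return ReferenceLine(kind=kind, slice_index=slice_index, direction=direction,
                         anchors_vox=anchors_vox, anchors_mm=anchors_mm)


# ---------------------------------------------------------------------------
# ankle


def distal_tibial_line(mask: LabelMask, side: Side = "right") -> ReferenceLine:
    """Tibio-fibular centroid line on the most distal slice where both the
    tibia and the fibula show at least ``MIN_DISTAL_AREA_MM2`` of cross-section."""
    tibia = _largest_component(mask, TIBIA)
    try:
        fibula = _largest_component(mask, FIBULA)
    except MissingBoneError:
        raise MissingBoneError("fibula absent from ankle mask") from None
    pixel_area = mask.spacing[0] * mask.spacing[1]
    warnings: list[str] = []
    chosen = None
    fallback_k, fallback_score = None, -1.0
    for k in range(mask.shape[2] - 1, -1, -1):
        at = tibia[:, :, k].sum() * pixel_area
        af = fibula[:, :, k].sum() * pixel_area
        score = min(at, af)
        if score > fallback_score:
            fallback_score, fallback_k = score, k
        if at >= MIN_DISTAL_AREA_MM2 and af >= MIN_DISTAL_AREA_MM2:
            chosen = k
            break
    if chosen is None:
        if fallback_score <= 0:
            raise MissingBoneError(
                "tibia and fibula never co-occur on an axial slice")
        chosen = fallback_k
        warnings.append(
            "no slice met the minimum cross-sectional area; fell back to the "
            "slice with the largest joint cross-section")
    pts_t = _slice_points_mm(tibia, chosen, mask.spacing)
    pts_f = _slice_points_mm(fibula, chosen, mask.spacing)
    ct, cf = pts_t.mean(axis=0), pts_f.mean(axis=0)
    direction = cf - ct
    if np.linalg.norm(direction) == 0:
        raise DegenerateAnatomyError("tibial and fibular centroids coincide")
    z_mm = (chosen + 0.5) * mask.spacing[2]
    anchors_mm = [(*ct, z_mm), (*cf, z_mm)]
    anchors_vox = [tuple(np.array(a) / np.array(mask.spacing) - 0.5) for a in anchors_mm]
    return ReferenceLine(kind="distal_tibial", slice_index=chosen,
                         direction=direction, anchors_vox=anchors_vox,
                         anchors_mm=anchors_mm, warnings=warnings)


# ---------------------------------------------------------------------------
# orchestration


def extract_reference_lines(hip: LabelMask, knee: LabelMask, ankle: LabelMask,
                            side: Side = "right") -> LandmarkSet:
    """All four reference lines for one limb from its three stacks."""
    head = femoral_head_center(hip, side)
    lines = {
        "proximal_femoral": proximal_femoral_line(hip, head, side),
        "distal_femoral": posterior_condylar_line(knee, FEMUR, side=side),
        "proximal_tibial": posterior_condylar_line(knee, TIBIA, side=side),
        "distal_tibial": distal_tibial_line(ankle, side),
    }
    return LandmarkSet(femoral_head_center_mm=head, lines=lines)
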