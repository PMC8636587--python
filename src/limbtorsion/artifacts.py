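"""MRI acquisition artifact models for training-time augmentation.

Four artifact families are modelled, mirroring the corruptions that degrade
axial turbo-spin-echo stacks in practice:

``motion``
    A weighted average of the volume with copies under small rigid
    transforms, emulating patient movement between echo trains.
``ghosting``
    Modulation of periodic k-space planes along one axis, producing the
    classic displaced low-intensity copies along the phase-encode direction.
``spiking``
    Isolated spurious k-space spikes (herring-bone artifact).
``bias_field``
    Multiplication by a smooth exp-polynomial field with mean one, emulating
    coil-sensitivity inhomogeneity.

All transforms are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["ARTIFACT_FAMILIES", "apply_artifact"]

ARTIFACT_FAMILIES = ("motion", "ghosting", "spiking", "bias_field")


def _motion(data: np.ndarray, rng: np.random.Generator, *,
            max_rotation_deg: float = 5.0, max_shift_mm: float = 3.0,
            n_transforms: int = 2,
            spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Weighted sum of the volume with small rigid-transformed copies.

    Shifts are drawn in millimetres and converted to (possibly anisotropic)
    voxel units via ``spacing``.
    """
    # mild motion: the resting position dominates, moved copies smear edges
    w0 = rng.uniform(0.55, 0.75)
    rest = rng.uniform(0.5, 1.0, size=n_transforms)
    weights = np.concatenate([[w0], (1.0 - w0) * rest / rest.sum()])
    out = weights[0] * data
    centre = (np.array(data.shape) - 1) / 2.0
    for w in weights[1:]:
        theta = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
        shift = rng.uniform(-max_shift_mm, max_shift_mm, size=3) / np.asarray(
            spacing, dtype=float)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        offset = centre - rot @ (centre + shift)
        moved = ndimage.affine_transform(data, rot, offset=offset, order=1,
                                         mode="nearest")
        out = out + w * moved
    return out.astype(np.float32)


def _ghosting(data: np.ndarray, rng: np.random.Generator, *,
              intensity: float = 0.3, n_ghosts: int = 4,
              axis: int | None = None) -> np.ndarray:
    """Attenuate every ``n_ghosts``-th k-space plane along one axis (not DC)."""
    if axis is None:
        axis = int(rng.integers(0, 2))  # phase encoding is in-plane
    strength = rng.uniform(0.5, 1.0) * intensity
    k = np.fft.fft(data, axis=axis)
    idx = np.arange(data.shape[axis])
    sel = (idx % n_ghosts == 0) & (idx != 0)
    sl = [slice(None)] * 3
    sl[axis] = sel
    k[tuple(sl)] *= 1.0 - strength
    return np.real(np.fft.ifft(k, axis=axis)).astype(np.float32)


def _spiking(data: np.ndarray, rng: np.random.Generator, *,
             n_spikes: int = 3, intensity: float = 0.2) -> np.ndarray:
    """Add isolated k-space spikes (conjugate-symmetric, output stays real)."""
    k = np.fft.fftn(data)
    amp = intensity * np.abs(k).max()
    shape = np.array(data.shape)
    n = int(rng.integers(1, n_spikes + 1))
    for _ in range(n):
        pos = tuple(int(rng.integers(1, s)) for s in shape)
        phase = rng.uniform(0, 2 * np.pi)
        k[pos] += amp * np.exp(1j * phase)
        mirror = tuple((-p) % s for p, s in zip(pos, shape))
        k[mirror] += amp * np.exp(-1j * phase)
    return np.real(np.fft.ifftn(k)).astype(np.float32)


def _bias_field(data: np.ndarray, rng: np.random.Generator, *,
                order: int = 3, amplitude: float = 0.3) -> np.ndarray:
    """Multiply by exp of a random low-order polynomial, normalized to mean 1."""
    coords = [np.linspace(-1.0, 1.0, s, dtype=np.float32) for s in data.shape]
    xg, yg, zg = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(data.shape, dtype=np.float32)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                coeff = amplitude * rng.uniform(-1.0, 1.0)
                poly += coeff * (xg ** i) * (yg ** j) * (zg ** k)
    field = np.exp(poly)
    field /= field.mean()
    return (data * field).astype(np.float32)


_DISPATCH = {
    "motion": _motion,
    "ghosting": _ghosting,
    "spiking": _spiking,
    "bias_field": _bias_field,
}


def apply_artifact(volume: Volume | np.ndarray, family: str, seed: int, **params):
    """Apply one artifact family to a volume, deterministically given ``seed``."""
    if family not in _DISPATCH:
        raise ValueError(
            f"unknown artifact family {family!r}; expected one of {ARTIFACT_FAMILIES}")
    rng = np.random.default_rng(seed)
    if isinstance(volume, Volume):
        if family == "motion":
            params.setdefault("spacing", volume.spacing)
        return replace(volume, data=_DISPATCH[family](volume.data, rng, **params))
    return _DISPATCH[family](np.asarray(volume, dtype=np.float32), rng, **params)
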