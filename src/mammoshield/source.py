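"""Photon emission models.

Two monoenergetic source kinds:

* ``isotropic_point`` -- directions uniform on the unit sphere (used by the
  transmission-factor pilot);
* ``collimated_pyramid`` -- directions uniform over the solid angle
  subtended by a rectangular footprint below the source (the mammography
  exposure: the beam covers the top face of the examined breast).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidSourceError

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle: plane ``axis = coord``, bounded on the two
    remaining axes (in axis order)."""

    axis: str
    coord: float
    lo1: float
    hi1: float
    lo2: float
    hi2: float

    def __post_init__(self) -> None:
        if self.axis not in _AXIS:
            raise ValueError(f"axis must be x, y or z, got {self.axis!r}")

    @property
    def area(self) -> float:
        return (self.hi1 - self.lo1) * (self.hi2 - self.lo2)

    def other_axes(self):
        return tuple(i for i in range(3) if i != _AXIS[self.axis])

    def corners(self) -> np.ndarray:
        a = _AXIS[self.axis]
        o1, o2 = self.other_axes()
        out = np.empty((4, 3))
        for k, (c1, c2) in enumerate(
            [(self.lo1, self.lo2), (self.lo1, self.hi2), (self.hi1, self.lo2), (self.hi1, self.hi2)]
        ):
            out[k, a] = self.coord
            out[k, o1] = c1
            out[k, o2] = c2
        return out

    def contains_point(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        o1, o2 = self.other_axes()
        return (
            (p[:, o1] >= self.lo1) & (p[:, o1] <= self.hi1)
            & (p[:, o2] >= self.lo2) & (p[:, o2] <= self.hi2)
        )


@dataclass(frozen=True)
class SourceSpec:
    kind: str  # "isotropic_point" | "collimated_pyramid"
    position: tuple
    energy_keV: float
    n_histories: int = 1
    footprint: Optional[Rectangle] = None

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic_point", "collimated_pyramid"):
            raise InvalidSourceError(f"unknown source kind {self.kind!r}")
        if not (self.energy_keV > 0):
            raise InvalidSourceError("energy must be positive")
        if self.n_histories < 1:
            raise InvalidSourceError("n_histories must be >= 1")
        if self.kind == "collimated_pyramid":
            fp = self.footprint
            if fp is None or fp.area <= 0:
                raise InvalidSourceError("collimated source needs a footprint of nonzero area")
            a = _AXIS[fp.axis]
            if self.position[a] <= fp.coord:
                raise InvalidSourceError("footprint must lie below the source along the beam axis")


def _isotropic_dirs(rng: np.random.Generator, n: int) -> np.ndarray:
    w = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(np.maximum(1.0 - w * w, 0.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


def _cap_dirs(rng, n, axis_dir, cos_min):
    """Directions uniform in the spherical cap around ``axis_dir``."""
    mu = cos_min + (1.0 - cos_min) * rng.random(n)
    phi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(np.maximum(1.0 - mu * mu, 0.0))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
    # Orthonormal frame with e3 = axis_dir.
    e3 = axis_dir / np.linalg.norm(axis_dir)
    helper = np.array([1.0, 0.0, 0.0]) if abs(e3[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(e3, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return local[:, 0:1] * e1 + local[:, 1:2] * e2 + local[:, 2:3] * e3


def emit_batch(spec: SourceSpec, rng: np.random.Generator, n: int):
    """Sample ``n`` emissions: (positions (n,3), unit directions (n,3),
    energies (n,), weights (n,) all equal to 1 in analog mode)."""
    pos = np.broadcast_to(np.asarray(spec.position, float), (n, 3)).copy()
    if spec.kind == "isotropic_point":
        dirs = _isotropic_dirs(rng, n)
    else:
        fp = spec.footprint
        src = np.asarray(spec.position, float)
        center = fp.corners().mean(axis=0)
        axis_dir = center - src
        dist = np.linalg.norm(axis_dir)
        axis_dir = axis_dir / dist
        rel = fp.corners() - src
        cos_min = min(
            float(np.dot(rel[k] / np.linalg.norm(rel[k]), axis_dir)) for k in range(4)
        )
        a = _AXIS[fp.axis]
        dirs = np.empty((n, 3))
        filled = 0
        # Rejection from the bounding cap: keep directions whose ray pierces
        # the footprint rectangle.
        while filled < n:
            cand = _cap_dirs(rng, max(n - filled, 1024), axis_dir, cos_min)
            t = (fp.coord - src[a]) / cand[:, a]
            hit = t > 0
            pts = src[None, :] + t[:, None] * cand
            hit &= fp.contains_point(pts)
            take = cand[hit][: n - filled]
            dirs[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
    energies = np.full(n, float(spec.energy_keV))
    weights = np.ones(n)
    return pos, dirs, energies, weights


def emit(spec: SourceSpec, rng: np.random.Generator):
    """Single emission: (position, unit direction, energy keV, weight=1)."""
    pos, dirs, e, w = emit_batch(spec, rng, 1)
    return pos[0], dirs[0], float(e[0]), float(w[0])
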