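"""Axis-aligned box constructive geometry with priority overlap resolution.

A :class:`Scene` is a world box plus a list of :class:`BoxRegion` entries.
Boxes may overlap; the resolved region at a point is the contained box with
the highest priority (this is how 2-mm skin slabs sit on top of the breast
block without boolean subtraction).  Two queries drive the transport loop:

* :func:`locate` -- which region owns a point;
* :func:`distance_to_boundary` -- distance along a ray to the nearest
  surface crossing that changes the resolved region.

Convention: right-handed axes, z is the source-to-detector axis (source
above, image plane below), x spans right -> left breast.  A point exactly on
a face belongs to the region in the +direction of travel (half-open on the
entry side), which avoids double counting at shared faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSceneError, PointOutsideWorldError

#: push distance (cm) used to step across a face; far below any geometric
#: feature size (minimum feature here is the 0.2 cm skin slab)
EPS_PUSH = 1e-7

WORLD_ID = 0


@dataclass(frozen=True)
class BoxRegion:
    region_id: int
    label: str
    bounds: tuple  # (xmin, xmax, ymin, ymax, zmin, zmax), cm
    material: str
    priority: int = 0

    def __post_init__(self) -> None:
        b = self.bounds
        if len(b) != 6 or not all(b[2 * i] < b[2 * i + 1] for i in range(3)):
            raise InvalidSceneError(
                f"region {self.region_id} ({self.label}): min < max required on "
                f"every axis, got {b}"
            )

    @property
    def volume_cm3(self) -> float:
        b = self.bounds
        return (b[1] - b[0]) * (b[3] - b[2]) * (b[5] - b[4])

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        b = self.bounds
        return bool(
            (b[0] <= p[0] <= b[1]) and (b[2] <= p[1] <= b[3]) and (b[4] <= p[2] <= b[5])
        )


@dataclass
class BoundaryHit:
    distance: float
    next_region_id: int
    escaped: bool = False


class Scene:
    """World box plus prioritized regions, with vectorized point/ray queries."""

    def __init__(self, regions, world: BoxRegion):
        if world.region_id != WORLD_ID:
            raise InvalidSceneError("world region must carry id 0")
        ids = [r.region_id for r in regions]
        if len(set(ids)) != len(ids) or WORLD_ID in ids:
            raise InvalidSceneError("region ids must be unique and nonzero")
        wb = world.bounds
        for r in regions:
            b = r.bounds
            inside = all(
                wb[2 * a] <= b[2 * a] and b[2 * a + 1] <= wb[2 * a + 1] for a in range(3)
            )
            if not inside:
                raise InvalidSceneError(
                    f"region {r.region_id} ({r.label}) extends outside the world"
                )
        self.regions = list(regions)
        self.world = world
        self._ids = np.array(ids, dtype=np.int64)
        self._lo = np.array([[r.bounds[0], r.bounds[2], r.bounds[4]] for r in regions],
                            dtype=float).reshape(len(regions), 3)
        self._hi = np.array([[r.bounds[1], r.bounds[3], r.bounds[5]] for r in regions],
                            dtype=float).reshape(len(regions), 3)
        self._prio = np.array([r.priority for r in regions], dtype=np.int64)
        self._wlo = np.array([wb[0], wb[2], wb[4]])
        self._whi = np.array([wb[1], wb[3], wb[5]])
        # All face planes (regions + world) as (axis, coordinate) pairs.
        axes, coords = [], []
        for r in list(regions) + [world]:
            for a in range(3):
                axes += [a, a]
                coords += [r.bounds[2 * a], r.bounds[2 * a + 1]]
        self._plane_axis = np.array(axes, dtype=np.int64)
        self._plane_coord = np.array(coords, dtype=float)
        self._by_id = {r.region_id: r for r in regions}
        self._by_id[WORLD_ID] = world

    def region(self, region_id: int) -> BoxRegion:
        return self._by_id[region_id]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    # -- point location ----------------------------------------------------

    def locate_batch(self, points: np.ndarray) -> np.ndarray:
        """Region ids for an (n, 3) array of points; -1 marks points outside
        the world."""
        p = np.atleast_2d(points)
        in_world = np.all((p >= self._wlo) & (p <= self._whi), axis=1)
        if self.n_regions:
            inside = np.all(
                (p[:, None, :] >= self._lo) & (p[:, None, :] <= self._hi), axis=2
            )
            score = np.where(inside, self._prio, np.iinfo(np.int64).min)
            best = np.argmax(score, axis=1)
            any_inside = inside[np.arange(p.shape[0]), best]
            ids = np.where(any_inside, self._ids[best], WORLD_ID)
        else:
            ids = np.full(p.shape[0], WORLD_ID, dtype=np.int64)
        return np.where(in_world, ids, -1)

    # -- ray queries -------------------------------------------------------

    def plane_crossings(self, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Distance to the nearest face-plane crossing for each ray (inf if
        none ahead).  Crossing any face plane is a sufficient stopping set:
        containment in every box is constant between consecutive crossings."""
        p = np.atleast_2d(points)
        d = np.atleast_2d(dirs)
        pa = p[:, self._plane_axis]
        da = d[:, self._plane_axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self._plane_coord[None, :] - pa) / da
        t = np.where((da != 0) & (t > 1e-12), t, np.inf)
        return t.min(axis=1)


def locate(scene: Scene, point, direction=None) -> int:
    """Resolved region id at ``point`` (world id 0 if in no box).

    With ``direction`` given, a point exactly on a face is attributed to the
    region just ahead of travel (half-open entry-side convention).  Points
    outside the world raise :class:`PointOutsideWorldError`.
    """
    p = np.asarray(point, dtype=float)
    if direction is not None:
        p = p + EPS_PUSH * np.asarray(direction, dtype=float)
    rid = int(scene.locate_batch(p[None, :])[0])
    if rid < 0:
        raise PointOutsideWorldError(f"point {point} outside world")
    return rid


def distance_to_boundary(scene: Scene, point, direction) -> BoundaryHit:
    """Distance to the nearest surface crossing that changes the resolved
    region, and the region id just beyond.

    If the ray leaves the world without any region change, the distance to
    the world boundary is returned with ``escaped=True``.
    """
    p = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if abs(n - 1.0) > 1e-9:
        raise ValueError("direction must be normalized within 1e-9")
    current = locate(scene, p, d)
    travelled = 0.0
    pos = p.copy()
    for _ in range(10000):
        t = float(scene.plane_crossings(pos[None, :], d[None, :])[0])
        if not np.isfinite(t):  # cannot happen inside a closed world box
            return BoundaryHit(travelled, WORLD_ID, escaped=True)
        travelled += t
        pos = p + travelled * d
        probe = scene.locate_batch((pos + EPS_PUSH * d)[None, :])[0]
        if probe < 0:
            return BoundaryHit(travelled, WORLD_ID, escaped=True)
        if int(probe) != current:
            return BoundaryHit(travelled, int(probe), escaped=False)
    raise InvalidSceneError("no region change found after 10000 plane crossings")
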