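"""Analog photon-history random walk through a scene.

The engine tracks photons surface-to-surface: in each step a photon either
reaches the nearest face-plane crossing (and re-resolves its region) or
interacts after an exponentially sampled free path.  Interactions are chosen
proportionally to the partial mass-attenuation components:

* photoelectric -- the full remaining energy is deposited locally and the
  history ends;
* incoherent (Compton) -- the polar angle is drawn from the free-electron
  Klein-Nishina distribution (Kahn's rejection method); the electron recoil
  energy ``E - E'`` is deposited locally (kerma approximation: sub-50 keV
  electron ranges in tissue are tens of micrometres, far below the 2-mm
  skin-voxel scale);
* coherent -- elastic, Thomson angular law ``(1 + cos^2 theta)``.

Histories end on absorption, energy cutoff (remainder deposited locally),
escape through the world boundary, or the interaction cap (remainder
deposited locally, history counted as truncated).  Energy is conserved
per history to machine precision: emitted = deposited + escaped.

Transport is analog (weight fixed at 1; the weight field is carried for
forward compatibility).  Reproducibility contract: one RNG stream per
history batch, seeded deterministically from (master seed, batch index),
so identical seed + config give bit-identical tallies.

Characteristic X-ray fluorescence after photoelectric absorption is ignored
(energy deposited locally), including for high-Z screen elements; this is a
documented physics limitation (Cd/Te/Pb K and L fluorescence can escape
thin regions in reality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import materials as mat
from .errors import InvalidMediumError, InvalidSceneError
from .geometry import EPS_PUSH, Scene, WORLD_ID
from .source import SourceSpec, emit_batch
from .xsdata import MEC2_KEV

__all__ = [
    "PhotonState",
    "TransportConfig",
    "MaterialTables",
    "RunResult",
    "sample_free_path",
    "sample_interaction",
    "sample_interaction_batch",
    "sample_compton",
    "sample_coherent",
    "compton_scattered_energy",
    "klein_nishina_pdf",
    "rotate_direction",
    "run_simulation",
    "run_history",
]


@dataclass
class PhotonState:
    """One history in flight (analog mode: weight = 1)."""

    position: np.ndarray
    direction: np.ndarray
    energy_keV: float
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (within 1e-9)")
        if self.alive and not (self.energy_keV > 0):
            raise ValueError("energy must be positive while alive")


@dataclass(frozen=True)
class TransportConfig:
    cutoff_keV: float = 1.0
    coherent_enabled: bool = True
    max_interactions: int = 1000
    seed: int = 0
    batch_size: int = 100_000

    def __post_init__(self) -> None:
        if self.cutoff_keV < 1.0:
            raise ValueError("cutoff below 1 keV is outside the tabulated range")
        if self.max_interactions < 1:
            raise ValueError("max_interactions must be >= 1")


# ---------------------------------------------------------------------------
# sampling kernels


def sample_free_path(mu_total, rng: np.random.Generator, n: int | None = None):
    """Exponential free path: ``-ln(xi)/mu`` with xi uniform in (0, 1]."""
    mu = np.asarray(mu_total, dtype=float)
    if np.any(mu <= 0):
        raise InvalidMediumError("mu_total must be positive (vacuum is streamed, not sampled)")
    size = n if n is not None else (mu.shape if mu.shape else None)
    xi = rng.random(size)
    out = -np.log1p(-xi) / mu  # 1 - U is uniform on (0, 1]
    return out if np.ndim(out) else float(out)


def sample_interaction(material, energy_keV: float, rng: np.random.Generator,
                       coherent_enabled: bool = True) -> str:
    """Pick an interaction channel proportional to the partial components."""
    parts = {
        "photoelectric": mat.mu_rho(material, energy_keV, "photoelectric"),
        "incoherent": mat.mu_rho(material, energy_keV, "incoherent"),
        "coherent": mat.mu_rho(material, energy_keV, "coherent") if coherent_enabled else 0.0,
    }
    total = sum(parts.values())
    if total <= 0:
        raise InvalidMediumError("all partial cross-sections are zero")
    u = rng.random() * total
    acc = 0.0
    for name, p in parts.items():
        acc += p
        if u < acc:
            return name
    return "coherent" if coherent_enabled else "incoherent"


def _select_channels(pp: np.ndarray, rng: np.random.Generator):
    """Channel masks (photoelectric, incoherent, coherent) for partials
    ``pp`` of shape (3, k); probability proportional to each partial."""
    tot = pp.sum(axis=0)
    if np.any(tot <= 0):
        raise InvalidMediumError("all partial cross-sections are zero")
    u = rng.random(pp.shape[1]) * tot
    is_pe = u < pp[0]
    is_coh = u >= pp[0] + pp[1]
    is_inc = ~is_pe & ~is_coh
    return is_pe, is_inc, is_coh


def sample_interaction_batch(material, energy_keV: float, rng: np.random.Generator,
                             n: int, coherent_enabled: bool = True) -> np.ndarray:
    """Vectorized channel sampling; returns an array of channel names."""
    pp = np.array([
        [mat.mu_rho(material, energy_keV, "photoelectric")],
        [mat.mu_rho(material, energy_keV, "incoherent")],
        [mat.mu_rho(material, energy_keV, "coherent") if coherent_enabled else 0.0],
    ]).repeat(n, axis=1)
    is_pe, is_inc, is_coh = _select_channels(pp, rng)
    out = np.empty(n, dtype=object)
    out[is_pe] = "photoelectric"
    out[is_inc] = "incoherent"
    out[is_coh] = "coherent"
    return out


def compton_scattered_energy(energy_keV, cos_theta):
    """Compton kinematics: ``E' = E / (1 + (E/mec^2)(1 - cos theta))``."""
    e = np.asarray(energy_keV, dtype=float)
    return e / (1.0 + (e / MEC2_KEV) * (1.0 - np.asarray(cos_theta, dtype=float)))


def klein_nishina_pdf(energy_keV: float, cos_theta) -> np.ndarray:
    """Unnormalized Klein-Nishina angular density in cos(theta)."""
    ct = np.asarray(cos_theta, dtype=float)
    a = energy_keV / MEC2_KEV
    r = 1.0 / (1.0 + a * (1.0 - ct))  # E'/E
    return r**2 * (r + 1.0 / r - (1.0 - ct**2))


def sample_compton(energy_keV, rng: np.random.Generator):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns (scattered energy keV, cos(polar angle)); the azimuth is
    sampled separately, uniform on [0, 2*pi).
    """
    e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
    a = e / MEC2_KEV
    x = np.empty_like(e)
    pending = np.arange(e.size)
    while pending.size:
        ap = a[pending]
        r1, r2, r3 = rng.random((3, pending.size))
        branch1 = r1 <= (1.0 + 2.0 * ap) / (9.0 + 2.0 * ap)
        xa = 1.0 + 2.0 * ap * r2
        xb = (1.0 + 2.0 * ap) / (1.0 + 2.0 * ap * r2)
        cand = np.where(branch1, xa, xb)
        ct = 1.0 - (cand - 1.0) / ap
        acc_a = r3 <= 4.0 * (1.0 / cand - 1.0 / cand**2)
        acc_b = r3 <= 0.5 * (ct**2 + 1.0 / cand)
        accept = np.where(branch1, acc_a, acc_b)
        x[pending[accept]] = cand[accept]
        pending = pending[~accept]
    cos_theta = np.clip(1.0 - (x - 1.0) / a, -1.0, 1.0)
    e_out = e / x
    if np.ndim(energy_keV) == 0:
        return float(e_out[0]), float(cos_theta[0])
    return e_out, cos_theta


def sample_coherent(rng: np.random.Generator, n: int | None = None):
    """Thomson angular law, density proportional to ``1 + cos^2 theta``."""
    size = n if n is not None else 1
    out = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        ct = 2.0 * rng.random(pending.size) - 1.0
        u = rng.random(pending.size)
        accept = u <= 0.5 * (1.0 + ct * ct)
        out[pending[accept]] = ct[accept]
        pending = pending[~accept]
    return out if n is not None else float(out[0])


def rotate_direction(dirs: np.ndarray, cos_theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle theta (about a local frame) and
    azimuth phi.

    Pole convention: when the propagation axis is within 1e-10 of +-z, the
    local frame degenerates and the scattered direction is taken directly as
    ``(sin theta cos phi, sin theta sin phi, sign(w) cos theta)``.
    """
    d = np.atleast_2d(dirs)
    ct = np.atleast_1d(cos_theta)
    ph = np.atleast_1d(phi)
    st = np.sqrt(np.maximum(1.0 - ct * ct, 0.0))
    u, v, w = d[:, 0], d[:, 1], d[:, 2]
    s = np.sqrt(np.maximum(1.0 - w * w, 0.0))
    polar = s < 1e-10
    sgn = np.where(w >= 0.0, 1.0, -1.0)
    s_safe = np.where(polar, 1.0, s)
    cp, sp = np.cos(ph), np.sin(ph)
    u2 = u * ct + st * (u * w * cp - v * sp) / s_safe
    v2 = v * ct + st * (v * w * cp + u * sp) / s_safe
    w2 = w * ct - s * st * cp
    u2 = np.where(polar, st * cp, u2)
    v2 = np.where(polar, sgn * st * sp, v2)
    w2 = np.where(polar, sgn * ct, w2)
    out = np.column_stack([u2, v2, w2])
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out if np.ndim(dirs) == 2 else out[0]


# ---------------------------------------------------------------------------
# per-material lookup tables for the batched engine


class MaterialTables:
    """Per-material log-log channel tables on the union of element grids."""

    def __init__(self, library: mat.MaterialLibrary, names):
        self.names = list(names)
        self._loge = []
        self._logparts = []  # (3, npts): pe, incoherent, coherent (mass coeff)
        self.density = np.empty(len(self.names))
        from . import xsdata

        for i, name in enumerate(self.names):
            m = library.get(name)
            self.density[i] = m.density
            if m.is_vacuum:
                self._loge.append(None)
                self._logparts.append(None)
                continue
            grids = [xsdata.build_element(sym).energy for sym, _ in m.composition]
            lo = max(g[0] for g in grids)
            hi = min(g[-1] for g in grids)
            grid = np.unique(np.concatenate(grids))
            grid = grid[(grid >= lo) & (grid <= hi)]
            parts = np.vstack([
                np.maximum(mat.mu_rho(m, grid, ch), 1e-300)
                for ch in ("photoelectric", "incoherent", "coherent")
            ])
            self._loge.append(np.log(grid))
            self._logparts.append(np.log(parts))

    def index(self, name: str) -> int:
        return self.names.index(name)

    def _interp(self, mi: int, e: np.ndarray) -> np.ndarray:
        """(3, k) mass-attenuation partials for one material."""
        if self._loge[mi] is None:
            return np.zeros((3, e.size))
        loge = np.log(e)
        lg = self._loge[mi]
        lp = self._logparts[mi]
        return np.exp(np.vstack([np.interp(loge, lg, lp[c]) for c in range(3)]))

    def partials_linear(self, mi_arr: np.ndarray, e: np.ndarray) -> np.ndarray:
        """(3, k) linear attenuation partials (1/cm) for mixed materials."""
        out = np.zeros((3, e.size))
        for m in np.unique(mi_arr):
            sel = mi_arr == m
            out[:, sel] = self._interp(int(m), e[sel]) * self.density[int(m)]
        return out

    def mu_linear(self, mi_arr: np.ndarray, e: np.ndarray,
                  coherent_enabled: bool = True) -> np.ndarray:
        p = self.partials_linear(mi_arr, e)
        return p[0] + p[1] + (p[2] if coherent_enabled else 0.0)


# ---------------------------------------------------------------------------
# batched history loop


@dataclass
class RunResult:
    """Aggregated outcome of a transport run.

    Region order follows ``scene.regions`` with the world appended last;
    energies in eV.
    """

    region_ids: np.ndarray
    n_histories: int
    dep_sum_eV: np.ndarray
    dep_sumsq_eV2: np.ndarray
    emitted_eV: float
    escaped_eV: float
    truncated_histories: int
    energy_keV: float

    def merge(self, other: "RunResult") -> "RunResult":
        if not np.array_equal(self.region_ids, other.region_ids):
            raise ValueError("cannot merge runs over different scenes")
        return RunResult(
            self.region_ids,
            self.n_histories + other.n_histories,
            self.dep_sum_eV + other.dep_sum_eV,
            self.dep_sumsq_eV2 + other.dep_sumsq_eV2,
            self.emitted_eV + other.emitted_eV,
            self.escaped_eV + other.escaped_eV,
            self.truncated_histories + other.truncated_histories,
            self.energy_keV,
        )


def _run_batch(scene, tables, row_material, spec, config, planes, rng, n):
    R = scene.n_regions
    id_rows = {int(r.region_id): i for i, r in enumerate(scene.regions)}
    id_rows[WORLD_ID] = R

    pos, dirn, E, wt = emit_batch(spec, rng, n)
    edep = np.zeros((n, R + 1))
    escaped = np.zeros(n)
    n_int = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    truncated = 0

    wlo = scene._wlo
    whi = scene._whi
    max_row = np.max(scene._ids) if R else 0
    id_to_row = np.full(int(max_row) + 1, R, dtype=np.int64)
    for rid, row in id_rows.items():
        id_to_row[rid] = row

    guard = 0
    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        guard += 1
        if guard > 100000:
            raise InvalidSceneError("transport loop failed to terminate")
        p = pos[idx]
        d = dirn[idx]
        e = E[idx]
        rid = scene.locate_batch(p)
        oob = rid < 0  # emitted outside or numerical push-out: treat as escape
        if oob.any():
            escaped[idx[oob]] += e[oob]
            alive[idx[oob]] = False
            keep = ~oob
            idx, p, d, e, rid = idx[keep], p[keep], d[keep], e[keep], rid[keep]
            if idx.size == 0:
                continue
        row = id_to_row[rid]
        mi = row_material[row]
        parts = tables.partials_linear(mi, e)
        mu = parts[0] + parts[1] + (parts[2] if config.coherent_enabled else 0.0)
        db = scene.plane_crossings(p, d)
        bad = ~np.isfinite(db) | (db <= 0)
        if bad.any():
            # corrupt-scene guard: abort these histories, keep energy books
            escaped[idx[bad]] += e[bad]
            alive[idx[bad]] = False
            truncated += int(bad.sum())
            keep = ~bad
            idx, p, d, e, row, mi, mu, db = (a[keep] for a in (idx, p, d, e, row, mi, mu, db))
            parts = parts[:, keep]
            if idx.size == 0:
                continue
        xi = rng.random(idx.size)
        with np.errstate(divide="ignore"):
            df = np.where(mu > 0, -np.log1p(-xi) / np.where(mu > 0, mu, 1.0), np.inf)
        step = np.minimum(df, db)
        for plane in planes:
            plane.score_segments(p, d, step, n_int[idx], e, wt[idx])
        newp = p + step[:, None] * d
        interact = df < db

        # boundary crossers: push across the face, escape if out of world
        cross = ~interact
        if cross.any():
            pushed = newp[cross] + EPS_PUSH * d[cross]
            out = np.any((pushed < wlo) | (pushed > whi), axis=1)
            ci = idx[cross]
            pos[ci] = pushed
            esc = ci[out]
            escaped[esc] += E[esc]
            alive[esc] = False

        if interact.any():
            ii = idx[interact]
            pos[ii] = newp[interact]
            rows_i = row[interact]
            e_i = E[ii]
            pp = parts[:, interact]
            if not config.coherent_enabled:
                pp = pp.copy()
                pp[2] = 0.0
            is_pe, is_inc, is_coh = _select_channels(pp, rng)

            if is_pe.any():
                t = ii[is_pe]
                edep[t, rows_i[is_pe]] += e_i[is_pe]
                alive[t] = False

            if is_inc.any():
                t = ii[is_inc]
                e_in = E[t]
                e_out, ct = sample_compton(e_in, rng)
                phi = 2.0 * np.pi * rng.random(t.size)
                edep[t, rows_i[is_inc]] += e_in - e_out
                E[t] = e_out
                dirn[t] = rotate_direction(dirn[t], ct, phi)
                n_int[t] += 1
                dead = e_out < config.cutoff_keV
                if dead.any():
                    td = t[dead]
                    edep[td, rows_i[is_inc][dead]] += E[td]
                    alive[td] = False

            if is_coh.any():
                t = ii[is_coh]
                ct = sample_coherent(rng, t.size)
                phi = 2.0 * np.pi * rng.random(t.size)
                dirn[t] = rotate_direction(dirn[t], ct, phi)
                n_int[t] += 1

            # interaction cap: deposit the remainder locally
            capped = alive[ii] & (n_int[ii] >= config.max_interactions)
            if capped.any():
                t = ii[capped]
                edep[t, rows_i[capped]] += E[t]
                alive[t] = False
                truncated += int(capped.sum())

    emitted = float(spec.energy_keV) * n
    return edep * 1e3, escaped * 1e3, emitted * 1e3, truncated


def run_simulation(scene: Scene, library: mat.MaterialLibrary, spec: SourceSpec,
                   config: TransportConfig, planes=(), tables: MaterialTables | None = None,
                   per_history=False):
    """Run ``spec.n_histories`` analog histories through ``scene``.

    Returns a :class:`RunResult`; planar tallies in ``planes`` are scored in
    place.  With ``per_history=True`` the raw per-history deposition matrix
    (n, n_regions + 1) in eV is attached as ``result.per_history_eV``
    (small runs only).
    """
    material_names = sorted({r.material for r in scene.regions} | {scene.world.material})
    if tables is None:
        tables = MaterialTables(library, material_names)
    row_material = np.array(
        [tables.index(r.material) for r in scene.regions] + [tables.index(scene.world.material)],
        dtype=np.int64,
    )
    n_left = spec.n_histories
    R = scene.n_regions
    region_ids = np.array([r.region_id for r in scene.regions] + [WORLD_ID], dtype=np.int64)
    total = RunResult(region_ids, 0, np.zeros(R + 1), np.zeros(R + 1), 0.0, 0.0, 0,
                      float(spec.energy_keV))
    batches = []
    batch_index = 0
    while n_left > 0:
        n = min(n_left, config.batch_size)
        rng = np.random.default_rng([config.seed, batch_index])
        edep, escaped, emitted, truncated = _run_batch(
            scene, tables, row_material, spec, config, planes, rng, n
        )
        part = RunResult(region_ids, n, edep.sum(axis=0), (edep**2).sum(axis=0),
                         emitted, float(escaped.sum()), truncated, float(spec.energy_keV))
        total = total.merge(part)
        if per_history:
            batches.append((edep, escaped))
        n_left -= n
        batch_index += 1
    if per_history:
        total.per_history_eV = np.vstack([b[0] for b in batches])
        total.escaped_per_history_eV = np.concatenate([b[1] for b in batches])
    return total


def run_history(scene: Scene, library: mat.MaterialLibrary, spec: SourceSpec,
                config: TransportConfig, planes=()):
    """Track a single history; returns (deposits-by-region-id dict in eV,
    escaped energy eV)."""
    one = SourceSpec(spec.kind, spec.position, spec.energy_keV, 1, spec.footprint)
    res = run_simulation(scene, library, one, config, planes=planes, per_history=True)
    dep = {int(rid): float(v) for rid, v in zip(res.region_ids, res.per_history_eV[0]) if v > 0}
    return dep, float(res.escaped_per_history_eV[0])
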