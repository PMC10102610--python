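"""Energy-deposition tallies, planar crossing counters and derived quantities.

Doses are scored per region as deposited energy per source photon (eV) with
the standard Monte Carlo uncertainty estimator: per-history scores x_i give
mean m = sum(x)/n and relative error s_m / m with s_m the standard error of
the mean.  Mass-normalized doses (eV/g per photon) divide by region volume
times material density.

The transmission factor of an absorber is the ratio of the photon intensity
recorded behind it to the intensity incident on it; intensity is a weighted
crossing count on a bounded detection rectangle (an energy-fluence variant
is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import TallyError, UndefinedTransmissionError
from .source import Rectangle, _AXIS

__all__ = [
    "RegionDoseTally",
    "PlanarCountTally",
    "TallyReport",
    "transmission_factor",
    "total_skin_dose",
    "relative_error",
]


@dataclass
class RegionDoseTally:
    """Per-region accumulator of per-history deposited energy (eV)."""

    region_id: int
    n_histories: int = 0
    sum_eV: float = 0.0
    sumsq_eV2: float = 0.0
    _pending: float = 0.0

    def score_deposit(self, energy_eV: float) -> None:
        """Add a deposit to the current (open) history."""
        if energy_eV < 0:
            raise TallyError("deposit must be non-negative")
        self._pending += energy_eV

    def end_history(self) -> None:
        """Close the current history and fold its total into the moments."""
        self.n_histories += 1
        self.sum_eV += self._pending
        self.sumsq_eV2 += self._pending**2
        self._pending = 0.0

    def add_batch(self, per_history_eV: np.ndarray) -> None:
        x = np.asarray(per_history_eV, dtype=float)
        self.n_histories += x.size
        self.sum_eV += float(x.sum())
        self.sumsq_eV2 += float((x**2).sum())

    @property
    def accumulated_eV(self) -> float:
        return self.sum_eV

    @property
    def mean_eV(self) -> float:
        return self.sum_eV / self.n_histories if self.n_histories else 0.0


def relative_error(tally: RegionDoseTally):
    """Relative MC error of the mean; (1.0, degenerate=True) on zero mean."""
    n = tally.n_histories
    if n < 2:
        raise TallyError("relative error needs at least 2 histories")
    mean = tally.sum_eV / n
    var = max(tally.sumsq_eV2 / n - mean**2, 0.0)
    if mean == 0.0:
        return 1.0, True
    return float(np.sqrt(var / n) / mean), False


class TallySet:
    """Dict of :class:`RegionDoseTally` built from a transport run."""

    def __init__(self, region_ids):
        self.tallies = {int(r): RegionDoseTally(int(r)) for r in region_ids}

    def score_deposit(self, region_id: int, energy_eV: float) -> None:
        if region_id not in self.tallies:
            raise TallyError(f"unknown region {region_id}")
        self.tallies[region_id].score_deposit(energy_eV)

    def end_history(self) -> None:
        for t in self.tallies.values():
            t.end_history()

    @classmethod
    def from_run(cls, result) -> "TallySet":
        ts = cls(result.region_ids)
        for i, rid in enumerate(result.region_ids):
            t = ts.tallies[int(rid)]
            t.n_histories = result.n_histories
            t.sum_eV = float(result.dep_sum_eV[i])
            t.sumsq_eV2 = float(result.dep_sumsq_eV2[i])
        return ts


@dataclass
class PlanarCountTally:
    """Weighted count of photons crossing a bounded detection rectangle.

    ``direction_sign`` restricts scoring to crossings travelling in the
    positive (+1) or negative (-1) axis direction; 0 counts both.  With
    ``primary_only`` set, only photons with no prior interactions score
    (narrow-beam mode for the analytic attenuation oracle).  With
    ``weight_by_energy`` the tally becomes an energy-fluence counter (keV).
    """

    plane: Rectangle
    direction_sign: int = 0
    primary_only: bool = False
    weight_by_energy: bool = False
    count: float = 0.0

    def score_segments(self, p0, dirs, step, n_prior, energies, weights) -> None:
        a = _AXIS[self.plane.axis]
        da = dirs[:, a]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.plane.coord - p0[:, a]) / da
        hit = (da != 0) & (t > 0) & (t <= step)
        if self.direction_sign:
            hit &= np.sign(da) == self.direction_sign
        if self.primary_only:
            hit &= n_prior == 0
        if not hit.any():
            return
        pts = p0[hit] + t[hit, None] * dirs[hit]
        inside = self.plane.contains_point(pts)
        w = weights[hit][inside]
        if self.weight_by_energy:
            w = w * energies[hit][inside]
        self.count += float(w.sum())


def transmission_factor(primary_count: float, secondary_count: float) -> float:
    """TF = secondary / primary intensity; in [0, 1] for pure attenuation."""
    if primary_count <= 0:
        raise UndefinedTransmissionError("primary intensity must be positive")
    return secondary_count / primary_count


@dataclass
class TallyReport:
    """Per-region dose table for one run, plus planar counts."""

    table: pd.DataFrame  # region_id, label, material, volume_cm3, mass_g,
    #                      mean_eV, rel_error, eV_per_g, n_histories
    n_histories: int
    emitted_eV: float
    escaped_eV: float
    plane_counts: dict = field(default_factory=dict)

    @classmethod
    def from_run(cls, result, scene, library, planes: Optional[dict] = None) -> "TallyReport":
        rows = []
        regions = {r.region_id: r for r in scene.regions}
        regions[scene.world.region_id] = scene.world
        n = result.n_histories
        for i, rid in enumerate(result.region_ids):
            reg = regions[int(rid)]
            m = library.get(reg.material)
            mean = result.dep_sum_eV[i] / n
            var = max(result.dep_sumsq_eV2[i] / n - mean**2, 0.0)
            re_ = float(np.sqrt(var / n) / mean) if mean > 0 else 1.0
            mass = reg.volume_cm3 * m.density
            rows.append(
                dict(region_id=int(rid), label=reg.label, material=reg.material,
                     volume_cm3=reg.volume_cm3, mass_g=mass,
                     mean_eV=float(mean), rel_error=re_,
                     eV_per_g=float(mean / mass) if mass > 0 else np.nan,
                     n_histories=n)
            )
        return cls(pd.DataFrame(rows), n, result.emitted_eV, result.escaped_eV,
                   dict(planes or {}))

    def mean_eV(self, region_id: int) -> float:
        sel = self.table[self.table.region_id == region_id]
        if sel.empty:
            raise TallyError(f"region {region_id} not in report")
        return float(sel.mean_eV.iloc[0])

    def rel_error(self, region_id: int) -> float:
        sel = self.table[self.table.region_id == region_id]
        if sel.empty:
            raise TallyError(f"region {region_id} not in report")
        return float(sel.rel_error.iloc[0])


def total_skin_dose(report: TallyReport, skin_ids) -> tuple:
    """Sum of mean deposited energies over the listed skin cells (eV/photon)
    with the uncertainty combined in quadrature."""
    ids = list(skin_ids)
    if not ids:
        return 0.0, 0.0
    total = 0.0
    var = 0.0
    for rid in ids:
        m = report.mean_eV(rid)
        total += m
        var += (report.rel_error(rid) * m) ** 2
    return total, float(np.sqrt(var))
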