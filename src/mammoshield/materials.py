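"""Material compositions and mixture-rule attenuation coefficients.

A :class:`Material` is a density plus normalized elemental weight fractions;
the mass attenuation coefficient of a mixture is the weight-fraction-weighted
sum of the element coefficients (mixture rule).  The default
:class:`MaterialLibrary` ships the layered breast-tissue compositions used by
the phantom (glandular fractions 25/50/75% and skin), standard soft tissue
for the body block, PMMA and lead for the lead-acrylic screen, a CdO-rich
quaternary tellurite glass (C40), air, water and vacuum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import xsdata
from .errors import InvalidCompositionError, UnknownMaterialError

__all__ = [
    "Material",
    "MaterialLibrary",
    "normalize_composition",
    "mu_rho",
    "linear_mu",
    "default_library",
    "oxide_composition",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def normalize_composition(raw_fractions):
    """Rescale raw (symbol, percent) pairs to weight fractions summing to 1.

    Published composition tables are often truncated (rows summing to
    99.3-99.8%); renormalization preserves the printed ratios.
    """
    raw = list(raw_fractions)
    if not raw:
        raise InvalidCompositionError("empty composition")
    total = 0.0
    for sym, pct in raw:
        if not (pct > 0):
            raise InvalidCompositionError(f"non-positive fraction for {sym}: {pct}")
        total += float(pct)
    return tuple((sym, float(pct) / total) for sym, pct in raw)


def oxide_composition(oxide_mol_percents: dict) -> tuple:
    """Convert oxide mol% (e.g. ``{"CdO": 40, "TeO2": 45}``) to elemental
    weight fractions."""
    import gemmi

    grams: dict[str, float] = {}
    for formula, mol_pct in oxide_mol_percents.items():
        if not (mol_pct > 0):
            raise InvalidCompositionError(f"non-positive mol% for {formula}")
        for sym, count in _FORMULA_RE.findall(formula):
            if not sym:
                continue
            el = gemmi.Element(sym)
            if el.atomic_number == 0:
                raise InvalidCompositionError(f"unknown element {sym!r} in {formula}")
            n = int(count) if count else 1
            grams[sym] = grams.get(sym, 0.0) + mol_pct * n * float(el.weight)
    return normalize_composition(sorted(grams.items()))


@dataclass(frozen=True)
class Material:
    """Named material: density (g/cm^3) and normalized weight fractions."""

    name: str
    density: float
    composition: tuple  # ((symbol, weight_fraction), ...)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.is_vacuum:
            return
        if not (self.density > 0):
            raise InvalidCompositionError(f"{self.name}: density must be > 0")
        if not self.composition:
            raise InvalidCompositionError(f"{self.name}: empty composition")
        s = sum(w for _, w in self.composition)
        if abs(s - 1.0) > 1e-9:
            raise InvalidCompositionError(
                f"{self.name}: weight fractions sum to {s}, expected 1"
            )
        if any(w <= 0 for _, w in self.composition):
            raise InvalidCompositionError(f"{self.name}: non-positive weight fraction")

    @property
    def is_vacuum(self) -> bool:
        return self.density == 0.0 and not self.composition

    @classmethod
    def from_percents(cls, name, density, pairs, provenance=""):
        return cls(name, float(density), normalize_composition(pairs), provenance)

    @classmethod
    def from_oxides(cls, name, density, oxide_mol_percents, provenance=""):
        return cls(name, float(density), oxide_composition(oxide_mol_percents), provenance)

    @classmethod
    def vacuum(cls):
        return cls("vacuum", 0.0, (), "non-attenuating filler")


def mu_rho(material: Material, energy_keV, channel: str = "total"):
    """Mass attenuation coefficient of a material (cm^2/g), mixture rule.

    ``channel`` selects ``total`` (default), ``photoelectric``,
    ``incoherent`` or ``coherent``.  Log-log interpolation on the element
    grids; energies outside the tabulated range raise
    :class:`~mammoshield.errors.EnergyOutOfRangeError`.
    """
    e = np.asarray(energy_keV, dtype=float)
    if material.is_vacuum:
        out = np.zeros_like(e)
        return out if out.shape else 0.0
    acc = np.zeros_like(e, dtype=float)
    for sym, w in material.composition:
        acc = acc + w * np.asarray(xsdata.build_element(sym).interp(e, channel))
    return acc if acc.shape else float(acc)


def linear_mu(material: Material, energy_keV, channel: str = "total"):
    """Linear attenuation coefficient (1/cm): mu_rho times density."""
    return mu_rho(material, energy_keV, channel) * material.density


class MaterialLibrary:
    """Registry of named materials with provenance notes."""

    def __init__(self) -> None:
        self._registry: dict[str, Material] = {}

    def register(self, material: Material) -> Material:
        self._registry[material.name] = material
        return material

    def get(self, name: str) -> Material:
        try:
            return self._registry[name]
        except KeyError:
            raise UnknownMaterialError(f"material {name!r} not in library") from None

    def __contains__(self, name: str) -> bool:
        return name in self._registry

    def __iter__(self):
        return iter(self._registry.values())

    def names(self):
        return list(self._registry)


# Layered breast tissue rows: weight % H/C/N/O and density, as printed in the
# three-layer heterogeneous phantom literature (rows are truncated to one
# decimal and renormalized here, see normalize_composition).
_TISSUE_ROWS = {
    "GF25": (0.955, [("H", 11.0), ("C", 51.0), ("N", 2.1), ("O", 35.7)]),
    "GF50": (0.982, [("H", 10.7), ("C", 40.1), ("N", 2.5), ("O", 46.4)]),
    "GF75": (1.010, [("H", 10.5), ("C", 29.3), ("N", 2.9), ("O", 57.0)]),
    "skin": (1.090, [("H", 9.8), ("C", 17.8), ("N", 5.0), ("O", 66.7)]),
}

DEFAULT_LEAD_ACRYLIC_PB_FRACTION = 0.30
DEFAULT_LEAD_ACRYLIC_DENSITY = 1.6

# Synthetic stand-in for the CdO-rich quaternary tellurite shielding glass
# (the source study prints neither oxide fractions nor density; this default
# is a realistic CdO-rich tellurite composition and is config-overridable).
DEFAULT_C40_OXIDES = {"CdO": 40.0, "TeO2": 45.0, "ZnO": 10.0, "B2O3": 5.0}
DEFAULT_C40_DENSITY = 5.7


def lead_acrylic_material(pb_weight_fraction: float = DEFAULT_LEAD_ACRYLIC_PB_FRACTION,
                          density: float = DEFAULT_LEAD_ACRYLIC_DENSITY) -> Material:
    """PMMA loaded with lead: the transparent lead-acrylic screen material."""
    if not (0.0 < pb_weight_fraction < 1.0):
        raise InvalidCompositionError("Pb weight fraction must be in (0, 1)")
    pmma = dict(_pmma_fractions())
    comp = [(s, w * (1.0 - pb_weight_fraction)) for s, w in pmma.items()]
    comp.append(("Pb", pb_weight_fraction))
    return Material(
        "lead_acrylic",
        density,
        normalize_composition(comp),
        f"PMMA + {100 * pb_weight_fraction:.1f} wt% Pb (composition assumed; "
        "narrow-beam equivalent ~0.5 mm Pb at 12 mm, 30 keV)",
    )


def _pmma_fractions():
    # C5H8O2
    import gemmi

    masses = {"C": 5 * gemmi.Element("C").weight,
              "H": 8 * gemmi.Element("H").weight,
              "O": 2 * gemmi.Element("O").weight}
    tot = sum(masses.values())
    return tuple((s, m / tot) for s, m in masses.items())


def default_library() -> MaterialLibrary:
    """Build the library of materials used by the default study."""
    lib = MaterialLibrary()
    for name, (rho, row) in _TISSUE_ROWS.items():
        lib.register(Material.from_percents(
            name, rho, row,
            "layered breast phantom table row (renormalized from printed %)"))
    lib.register(Material.from_percents(
        "soft_tissue", 1.00,
        [("H", 10.1), ("C", 11.1), ("N", 2.6), ("O", 76.2)],
        "ICRU four-component soft tissue; stands in for the body block"))
    lib.register(Material.from_percents(
        "water", 1.00, [("H", 11.19), ("O", 88.81)], "reference material"))
    lib.register(Material("PMMA", 1.19, _pmma_fractions(), "acrylic, C5H8O2"))
    lib.register(Material("lead", 11.35, (("Pb", 1.0),), "pure lead"))
    lib.register(lead_acrylic_material())
    lib.register(Material.from_oxides(
        "C40", DEFAULT_C40_DENSITY, DEFAULT_C40_OXIDES,
        "synthetic stand-in for the CdO-rich quaternary tellurite glass; "
        "override via config with measured oxide fractions and density"))
    lib.register(Material.from_percents(
        "air", 1.205e-3,
        [("N", 75.5), ("O", 23.2), ("Ar", 1.3)], "dry air near sea level"))
    lib.register(Material.vacuum())
    return lib
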