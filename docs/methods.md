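# Methods

This note documents the physical model, the data it rests on, the default
parameters, and the known limitations of `mammoshield`.

## Transport model

Photon histories are tracked analytically (analog Monte Carlo, weight = 1)
through an axis-aligned box geometry. In each step a photon either reaches
the nearest face-plane crossing of any region (and re-resolves which region
it is in) or interacts after an exponential free path d = −ln ξ / μ(E).
Interaction channels are selected with probability proportional to the
partial linear attenuation coefficients:

* **Photoelectric** — the full photon energy is deposited at the
  interaction point and the history ends.
* **Incoherent (Compton)** — the polar angle is sampled from the
  free-electron Klein–Nishina distribution using Kahn's two-branch
  rejection method; the scattered energy follows the Compton relation
  E′ = E / (1 + (E/mₑc²)(1 − cos θ)) and the recoil energy E − E′ is
  deposited locally. The azimuth is uniform.
* **Coherent (Rayleigh)** — elastic; the deflection follows the Thomson
  law ∝ (1 + cos²θ). It can be disabled in the transport configuration,
  in which case the remaining channels are renormalized.

Histories end on absorption, escape through the world boundary, the energy
cutoff (default 1 keV, the lower edge of the tabulated range; the residual
energy is deposited locally), or an interaction cap (default 1000; the
remainder is deposited locally and the history is counted as truncated).
Emitted energy equals deposited plus escaped energy per history to
floating-point precision; this is asserted in the tests.

**Kerma approximation.** Secondary electrons deposit all their energy at
the interaction site. Below 50 keV the CSDA range of electrons in soft
tissue is tens of micrometres, far below the 2-mm skin-cell scale, so
collision kerma and absorbed dose coincide for every scored region.

**Direction rotation.** Scattering rotates the direction in a local
orthonormal frame. When the propagation axis is within 10⁻¹⁰ of ±z the
frame degenerates and the new direction is taken directly as
(sin θ cos φ, sign(w) sin θ sin φ, sign(w) cos θ).

**Reproducibility.** One RNG stream (numpy PCG64) per history batch,
seeded deterministically from (master seed, batch index); identical seed
and configuration give bit-identical tallies regardless of batch size
scheduling. Scenario runs derive per-(screen, energy) seeds from the master
seed through `SeedSequence`.

## Cross-section data

Each element carries a log-spaced 1–150 keV grid, refined adaptively where
the photoelectric coefficient jumps (absorption edges), with three
mass-attenuation components:

* **Photoelectric** from the Cromer–Liberman anomalous-scattering factor
  f″(E) (via `gemmi`), converted through the optical theorem
  σ_pe = 2 r_e λ f″. This resolves the K/L edge structure, which matters
  here: the Cd (26.71 keV) and Te (31.81 keV) K edges fall inside the
  mammographic band and drive the tellurite glass's absorption advantage.
  Hydrogen lies below the tabulation range (Z ≥ 3) and uses the
  nonrelativistic Born K-shell formula; its photoelectric share in any
  shipped material is far below 0.1%.
* **Incoherent** as the closed-form Klein–Nishina total cross-section per
  free electron times Z/A·N_A. Electron binding (the incoherent scattering
  function) is neglected, which overestimates low-angle incoherent
  scattering at the low end of the band by ~10–15% of that channel.
* **Coherent** as the Thomson cross-section modulated by a Molière-fit
  Thomas–Fermi atomic form factor, integrated by Gauss–Legendre quadrature
  over angle (accuracy of order tens of percent for this minor channel).
  Note the *sampled* coherent deflection uses the bare Thomson law, not
  the form-factor-weighted one; coherent scattering contributes a few
  percent of tissue attenuation in this band.

Totals land close to standard compilations — e.g. water at 30 keV gives
0.384 cm²/g against the ~0.376 compilation value, lead 29.9 vs ~30.3 —
and the test suite pins these anchors with coarse bands. Interpolation is
log–log (power-law behavior of photoelectric cross-sections); energies
outside the grid raise an error rather than extrapolate. Tables can be
exported/imported through a documented CSV schema
(`symbol, energy_keV, photoelectric, incoherent, coherent`).

## Materials

Tissue rows (density, weight-% H/C/N/O) for the three glandular-fraction
layers and skin are taken from the layered-breast-phantom literature; the
printed rows sum to 99.3–99.8% (one-decimal truncation) and are
renormalized to 1 exactly, preserving the printed ratios; the raw row is
kept in the provenance note. The body block is ICRU four-component soft
tissue.

* **Lead-acrylic**: the composition is not specified by the reference
  setup, so the default is PMMA loaded with 30 wt% Pb at 1.6 g/cm³. At the
  reference 12-mm thickness this gives a narrow-beam lead equivalence of
  0.52 mm at 30 keV, consistent with the quoted ~0.5 mm;
  `calibrate_lead_acrylic_pb_fraction()` solves the fraction (≈28.8 wt%)
  that makes the equivalence exactly 0.5 mm if wanted.
* **C40 glass**: the published description is only "CdO-rich quaternary
  tellurite glass"; neither oxide fractions nor density are printed. The
  shipped default is a clearly-flagged *synthetic stand-in*:
  mol% 40 CdO / 45 TeO₂ / 10 ZnO / 5 B₂O₃ at 5.7 g/cm³, a realistic
  CdO-rich tellurite composition. Both screens are fully overridable in
  the config (oxide mol% or elemental weight %).

## Phantom and study defaults

| Parameter | Default | Note |
| --- | --- | --- |
| Breast core block | 10 × 10 × 6 cm per breast | three 2-cm layers, GF 25/50/75% top→bottom |
| Skin | 2 mm on five faces | not on the chest-wall face; tiled without overlap |
| Inter-breast gap | 4 cm | between inner skin faces |
| Body block | 30 × 15 × 20 cm soft tissue | behind both breasts |
| Screen | 20 × 20 cm², 12 mm | centered at the breasts' geometric center; overlaps the body block over part of its depth and wins by priority |
| Source | collimated pyramid, 65 cm above the image plane | footprint = right-breast top face; uniform in solid angle |
| Energy grid | 20, 25, 30, 35, 40 keV monoenergetic | spectra can be composed as weighted energy lists |
| Histories | 10⁶ per (screen, energy) | scenario default |
| World | air | room scatter above the phantom is a real dose path to the shielded breast |

Lateral breast size, gap and body dimensions are not fixed by the study
description (they appear only in sketches); every headline comparison is
ratio-based (reductions, orderings) and robust to these choices. Region
ids are deterministic; the three tallied skin cells of the unexposed left
breast (top, nipple-side, bottom) carry ids 9/10/11.

Skin is represented by five exact slabs per breast (corners attributed to
the medial/lateral slabs); the priority mechanism exists for genuinely
overlapping volumes (screen vs body). Where the screen overlaps the body,
the screen material wins; the body's nominal mass is not corrected for
this overlap, which only affects the (non-headline) body dose
normalization.

## Tallies and uncertainty

Per-region deposited energy is scored per history; the report carries the
mean (eV/photon), the mass-normalized mean (eV/g/photon), and the standard
MC relative error (standard error of the per-history mean over the mean;
a zero mean reports 1.0 with a degenerate flag). Relative error scales as
1/√n, asserted on nested runs. Scenario rows whose left- or right-breast
totals exceed 10% relative error are flagged unreliable. Planar tallies
count weighted crossings of bounded rectangles with optional direction
sign, primaries-only mode (for narrow-beam oracles) and an energy-fluence
variant.

**Transmission-factor pilot.** An isotropic point source faces the 12-mm
slab; detection zones sit immediately in front of and behind it. The
zones are half the slab's face size and the rear zone is scaled to subtend
the same solid angle from the source as the front zone, so a void absorber
gives TF = 1 exactly and no ray can reach the rear zone without traversing
the slab. Both shipped screens are optically thick in the mammographic
band (μt ≈ 18 for lead-acrylic and ≈ 97 for C40 at 30 keV), so their
analog secondary counts are statistical zeros; the pilot table therefore
also carries the deterministic narrow-beam transmission e^(−μt), which is
the column on which the materials are compared.

## What the scenario generator does and does not emulate

The generator produces the complete study scene, so every stage is
testable without external data. It emulates: depth-dependent attenuation
in a layered heterogeneous breast, skin capture of low-energy photons,
scatter transport between breasts, screen absorption with realistic
edge-resolved high-Z cross-sections, and room-air scatter. It does not
emulate: polychromatic tube spectra (Mo/Mo, W/Rh), breast compression and
paddle scatter, anatomically shaped breasts, characteristic fluorescence
re-emission (see below), or electron transport. Passing tests therefore
demonstrate correctness of the transport/tally machinery and the relative
physics of the screen comparison — not clinical dose accuracy for any
individual patient.

## Numerical choices

* Face-crossing push: 10⁻⁷ cm (far below the 0.2-cm minimum feature);
  a point exactly on a face belongs to the region ahead of travel.
* Planar tallies must sit ≥ the push distance away from region faces to
  see the crossing; the built-in experiments place them 10⁻³–10⁻⁴ cm off.
* Stopping set for ray stepping: all face planes of all boxes (containment
  is constant between consecutive plane crossings), which trades a few
  extra no-op stops for exactness.
* Log–log interpolation on per-material union grids; adaptive edge
  refinement caps at ~4000 points per element.
* Degenerate inputs raise typed errors (empty compositions, energies off
  the grid, zero-area footprints, unnormalized directions, zero primary
  counts, overlapping screen/breast volumes).

## Findings and limitations

* **The screened contralateral dose is bypass-dominated.** Because both
  12-mm screens transmit < 10⁻⁸ of a narrow beam anywhere in the band,
  the dose reaching the shielded left breast travels *around* the screen —
  multiple scatter through the body block and single/double scatter via
  the room air above. That pathway is independent of the screen material,
  so the measured C40 vs lead-acrylic left-breast reduction is
  statistically consistent with zero (e.g. −31% ± 40 at 30 keV with
  4 × 10⁵ histories; −41% ± 24 at 20 keV with 10⁶). A 35–38% material
  effect would require the through-screen component to dominate, which is
  excluded by the measured opacity; the corresponding acceptance check is
  left failing by design rather than relaxed.
* **Exposed-breast dose vs energy.** The absorbed *fraction* of emitted
  energy falls monotonically with energy (the breast becomes more
  transparent), so the per-photon deposit peaks near 30 keV rather than
  increasing across the whole grid.
* **No fluorescence.** K/L fluorescence after photoelectric absorption is
  deposited locally. For tissue (H/C/N/O) this is exact to well below a
  percent; for the high-Z screens, escaping Cd/Te/Pb K–L X-rays from the
  first ~0.2 mm of the entry face are neglected, which slightly
  overestimates the screen's self-absorption and neglects a small
  re-emission source term.
* **Free-electron Compton and Thomson-sampled coherent angles** bias
  low-energy scatter mildly forward-deficient; slab-transmission oracles
  are unaffected (they test self-consistency), but absolute scatter dose
  in the few-percent range inherits this model error.
* **Problem sizes.** The study-scale checks run 10⁶ histories per
  (screen, energy) for the scenario matrix and 10⁵ per case for the
  attenuation oracles and distribution tests; left-breast totals behind a
  screen then carry ~20–30% relative error, which is the dominant
  uncertainty in the reduction estimates above.
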