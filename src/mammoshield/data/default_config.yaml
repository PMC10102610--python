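# Default study configuration: two-breast phantom with an optional
# protective screen between the breasts, collimated exposure of the right
# breast on a monoenergetic grid.  All lengths in cm, energies in keV.

materials:
  # Entries here are registered on top of the built-in library.  The C40
  # default below restates the shipped synthetic stand-in composition of the
  # CdO-rich quaternary tellurite glass; replace it with measured oxide
  # fractions and density when available.
  overrides:
    - name: C40
      density: 5.7
      oxides: {CdO: 40.0, TeO2: 45.0, ZnO: 10.0, B2O3: 5.0}
      provenance: synthetic stand-in composition (config default)

phantom:
  breast_size_cm: [10.0, 10.0, 6.0]   # glandular core per breast (x, y, z)
  skin_thickness_cm: 0.2
  gap_cm: 4.0                         # between the inner skin faces
  layer_materials: [GF25, GF50, GF75] # top -> bottom glandular fractions
  body_size_cm: [30.0, 15.0, 20.0]
  body_material: soft_tissue
  source_image_distance_cm: 65.0
  world_material: air

screen:
  face_cm: [20.0, 20.0]
  thickness_cm: 1.2
  options: [none, lead_acrylic, C40]

source:
  kind: collimated_pyramid
  energies_keV: [20.0, 25.0, 30.0, 35.0, 40.0]
  n_histories: 1000000
  seed: 1234

transport:
  cutoff_keV: 1.0
  coherent_enabled: true
  max_interactions: 1000

tally:
  skin_cell_ids: [9, 10, 11]   # left-breast top / nipple-side / bottom skin

# Optional external validation case (80/20 adipose/glandular block).  The
# reference report's parameters are not shipped; fill this block to enable
# `mammoshield validate-tg195`.
tg195: null
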