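# Built-in component catalog.
#
# Schema: each top-level key is a component label mapping to a record
# with a `kind` ({catheter, syringe, mixing_point, tubing}) plus the
# fields of that kind:
#   catheter:     french_size, length_m, inner_diameter_mm
#   syringe:      nominal_volume_ml, compliance_ml_per_mbar
#   mixing_point: dead_volume_ml
#   tubing:       length_m, inner_diameter_mm
#
# Inner diameters and the syringe compliance are engineering ESTIMATES:
# manufacturers publish French size (outer diameter) and length but not
# lumen bore or plunger compliance.  Only the qualitative contrast
# between a wide low-resistance catheter and a very thin high-resistance
# one is load-bearing for the shipped scenarios; override any value by
# loading a user catalog file with infusim.components.load_catalog.

"Careflow 7Fr":
  kind: catheter
  french_size: 7
  length_m: 0.16          # 16 cm central venous catheter
  inner_diameter_mm: 1.6  # estimate for a 7 Fr single-lumen CVC

"Premicath 1Fr":
  kind: catheter
  french_size: 1
  length_m: 0.30          # 30 cm neonatal PICC
  inner_diameter_mm: 0.3  # estimate for a 1 Fr neonatal PICC

"Omnifix 50mL":
  kind: syringe
  nominal_volume_ml: 50.0
  compliance_ml_per_mbar: 2.0e-3  # ~2 uL/mbar, rubber plunger tip estimate

"Rigid 50mL":
  kind: syringe
  nominal_volume_ml: 50.0
  compliance_ml_per_mbar: 0.0     # idealized incompressible syringe

"Discofix C 3-gang":
  kind: mixing_point
  dead_volume_ml: 0.5             # manifold + connector shared volume

"Standard line 1m":
  kind: tubing
  length_m: 1.0
  inner_diameter_mm: 1.0
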