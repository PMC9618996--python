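# Default exposure constants and toxicological reference values (adult consumers).
# Units: concentrations mg/kg dw; intake rates g/person/day; RfD mg/kg/day;
# CSF (mg/kg/day)^-1; MTDI mg/day; MDL mg/kg.
body_weight_kg: 60.0
exposure_frequency_days_per_year: 365.0
exposure_duration_years: 70.0
averaging_time_days: 25550.0
food_intake_g_per_day:
  vegetable: 170.04
  fish: 59.91
rfd_mg_per_kg_day:
  As: 0.0003
  Mn: 0.14
  Cu: 0.04
  Ni: 0.02
  Pb: 0.004
  Cr: 1.5
csf_per_mg_kg_day:
  As: 1.5
  Pb: 0.0085
mac_mg_per_kg:
  vegetable:
    As: 0.1
    Cu: 40.0
    Ni: 10.0
    Pb: 0.1
    Cr: 2.3
  fish:
    As: 1.0
    Mn: 1.0
    Cu: 4.5
    Ni: 0.8
    Pb: 0.5
    Cr: 1.0
mtdi_mg_per_day:
  vegetable:
    As: 0.13
    Mn: 2.0
    Cu: 30.0
    Ni: 0.3
    Pb: 0.21
    Cr: 0.2
  fish:
    As: 1.0
    Cu: 4.5
    Ni: 0.9
    Pb: 0.3
    Cr: 1.0
# Instrumental detection limits; As is element-specific, the others fall in the
# instrument's 0.013-0.070 mg/kg window.
mdl_mg_per_kg:
  As: 0.0003
  Mn: 0.013
  Cu: 0.013
  Ni: 0.07
  Pb: 0.028
  Cr: 0.05
# Metals entering the average pollution load index, per food class. Mn is
# excluded for both classes: it carries no vegetable MAC, and including the
# fish Mn MAC is numerically inconsistent with the published index values.
apli_metals:
  vegetable: [As, Cu, Ni, Pb, Cr]
  fish: [As, Cu, Ni, Pb, Cr]
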