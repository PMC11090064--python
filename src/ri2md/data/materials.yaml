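# Bundled material constants (single-wavelength effective values, ~589 nm, room
# temperature).  These are literature stand-in values with per-entry citations;
# every value can be overridden by a user table.  Units: n dimensionless,
# rho g/mL, alpha/theta mL/g.  Entries given as (n, rho) are converted to
# (R, theta) via the Lorentz-Lorenz relation; entries given as (alpha, theta)
# are Biot RI increments referenced to water (n1 = 1.3330).
water:
  n: 1.3330
  rho: 0.997
  provenance: >-
    Distilled water at 23 degC; density from standard tables, RI at the
    sodium-D line.
trunk_protein:
  alpha: 0.1971
  dalpha: 0.0033
  theta: 0.734
  dtheta: 0.009
  n1: 1.3330
  provenance: >-
    Mean Biot RI increment and PSV of the larval zebrafish (96 hpf) trunk-tissue
    protein set, computed from amino-acid sequences (mass-averaged residue
    refractivities, consensus residue volumes).
human_protein:
  alpha: 0.197
  dalpha: 0.004
  theta: 0.735
  dtheta: 0.010
  n1: 1.3330
  provenance: >-
    Mean Biot RI increment and PSV of the human proteome computed from
    amino-acid sequences; normal fits to the univariate histograms.
triolein:
  n: 1.4676
  rho: 0.9078
  provenance: >-
    Neutral lipid triolein (glyceryl trioleate), liquid at room temperature;
    literature refractive index and density.
lactose:
  n: 1.5330
  rho: 1.5450
  provenance: >-
    Alpha-lactose, solid; literature stand-in for the milk sugar fraction of
    skim-milk powder.
casein:
  alpha: 0.1860
  theta: 0.7310
  n1: 1.3330
  provenance: >-
    Casein micellar protein; RI increment and PSV literature stand-ins for the
    dominant skim-milk protein fraction.
whey_protein:
  alpha: 0.1870
  theta: 0.7510
  n1: 1.3330
  provenance: >-
    Beta-lactoglobulin-dominated whey fraction; literature stand-in values.
soybean_oil:
  n: 1.4728
  rho: 0.9175
  provenance: >-
    Soybean oil (main solute of 20% intralipid emulsion); literature
    refractive index and density.
plfa_palmitic:
  n: 1.4273
  rho: 0.8530
  provenance: >-
    Palmitic acid (16:0); literature stand-in for the saturated phospholipid
    fatty-acid fraction of zebrafish larvae.
plfa_oleic:
  n: 1.4582
  rho: 0.8950
  provenance: Oleic acid (18:1); literature stand-in.
plfa_linoleic:
  n: 1.4699
  rho: 0.9020
  provenance: Linoleic acid (18:2); literature stand-in.
plfa_dha:
  n: 1.4835
  rho: 0.9430
  provenance: Docosahexaenoic acid (22:6); literature stand-in.
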