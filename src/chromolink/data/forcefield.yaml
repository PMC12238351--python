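schema: chromolink-forcefield-1
units:
  length: angstrom
  energy: kcal/mol
  angle: degree
  salt: mM
rbp:
  phi0:
  - 0.0
  - 0.0
  - 16.45
  - 0.0
  - 0.0
  - 172.0
  K_diag:
  - 0.301
  - 0.235
  - 1.56
  - 0.00614
  - 0.00515
  - 0.00724
masses:
  dna_bead: 3250.0
  core_bead: 108000.0
pair_table:
  50.0:
    dna-dna:
      epsilon: 0.5
      sigma: 25.9202
      r_cut: 29.094440784588613
    dna-core:
      epsilon: 0.5584700000000001
      sigma: 29.7038
      r_cut: 120.0
    core-core:
      epsilon: 1.8730250000000002
      sigma: 54.6844
      r_cut: 140.0
  100.0:
    dna-dna:
      epsilon: 0.5
      sigma: 25.9202
      r_cut: 29.094440784588613
    dna-core:
      epsilon: 0.8123200000000002
      sigma: 29.7038
      r_cut: 120.0
    core-core:
      epsilon: 2.7244
      sigma: 54.6844
      r_cut: 140.0
  150.0:
    dna-dna:
      epsilon: 0.5
      sigma: 25.9202
      r_cut: 29.094440784588613
    dna-core:
      epsilon: 1.0154
      sigma: 29.7038
      r_cut: 120.0
    core-core:
      epsilon: 3.4055
      sigma: 54.6844
      r_cut: 140.0
  200.0:
    dna-dna:
      epsilon: 0.5
      sigma: 25.9202
      r_cut: 29.094440784588613
    dna-core:
      epsilon: 1.16771
      sigma: 29.7038
      r_cut: 120.0
    core-core:
      epsilon: 3.9163249999999996
      sigma: 54.6844
      r_cut: 140.0
  250.0:
    dna-dna:
      epsilon: 0.5
      sigma: 25.9202
      r_cut: 29.094440784588613
    dna-core:
      epsilon: 1.2997120000000002
      sigma: 29.7038
      r_cut: 120.0
    core-core:
      epsilon: 4.35904
      sigma: 54.6844
      r_cut: 140.0
provenance:
  calibration: '150 mM well depths tuned by Nelder-Mead against idealized nucleosome-pair
    scans: face-to-face minimum ~60 A at ~-4.8 kcal/mol, face-to-side ~75 A at ~-4.2
    kcal/mol, side-to-side ~110 A at ~-0.8 kcal/mol (depth targets weighted against
    minimum locations; the side-to-side depth is the compromised residual, ~-0.5 kcal/mol,
    a geometric limit of the three-class bead representation). Other salts scale the
    attractive depths by a monotone multiplier: higher monovalent salt screens DNA-DNA
    repulsion, deepening net attraction.'
  procedure: chromolink.forcefield.calibrate_pair_table
  salt_multipliers: relative to the 150 mM anchor
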