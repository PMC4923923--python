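# Default kinetic parameter set for the canalized-transfer Min model.
#
# Values transcribed from the published in-vivo parameterization of the
# cooperative-recruitment (canalized transfer) MinD/MinE reaction scheme
# (Cell Rep 1:741-752, 2012), with the mean copy-number densities
# calibrated once so that the quasi-2D reduction reproduces the canonical
# phenomenology (pole-to-pole oscillations in narrow cells of length
# 2-6 um, stripe onset in long cells). Every value is overridable.
#
# Units are 3D: diffusion um^2/s, k_D um/s, recruitment constants um^3/s,
# first-order rates 1/s, densities 1/um^3. The quasi-2D mode divides the
# recruitment constants by the cell height (see model_core.quasi_2d_parameters).

provenance: >
  Rate constants adapted from the published canalized-transfer Min model
  literature (Cell Rep 1:741, 2012); recruitment, membrane diffusion and
  copy-number densities recalibrated once for the quasi-2D cross-section
  reduction so that narrow cells (width ~2 um, length 4-9 um) sustain
  large-amplitude longitudinal pole-to-pole oscillations.

kinetics:
  D_D: 16.0              # cytosolic MinD diffusion (um^2/s)
  D_E: 10.0              # cytosolic MinE diffusion (um^2/s)
  D_m: 0.06              # membrane diffusion (um^2/s)
  lambda_exchange: 6.0   # ADP->ATP nucleotide exchange (1/s)
  k_D: 0.1               # MinD attachment (um/s)
  k_dD: 0.04             # MinD recruitment (um^3/s); swept in basin studies
  k_dE: 0.12             # MinE recruitment (um^3/s)
  k_de: 0.4              # MinDE complex detachment (1/s)

densities:
  rho_D: 800.0           # mean total MinD density (1/um^3)
  rho_E: 500.0           # mean total MinE density (1/um^3)

height: 1.1              # chamber/cell height H (um)
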