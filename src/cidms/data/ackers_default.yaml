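# Default thermodynamic parameters for the CI / P_R repression model.
#
# Configuration free energies follow the classic Ackers/Johnson/Shea
# 8-state lysogen parameter set (intrinsic operator binding -11.7 kcal/mol
# for OR1 and -10.1 kcal/mol for OR2 and OR3; -2.0 kcal/mol pairwise
# cooperativity between adjacently bound dimers).  This file is a synthetic
# stand-in assembled from those published constants; edit it to supply a
# different parameterization.
#
# State ordering (N_CS = number of bound dimers):
#   CS1 empty | CS2 OR3 only (the single non-repressing bound state)
#   CS3 OR2 | CS4 OR1 | CS5 OR1+OR2 | CS6 OR1+OR3 | CS7 OR2+OR3 | CS8 all
dG_CS: [0.0, -10.1, -10.1, -11.7, -23.8, -21.8, -22.2, -33.9]
N_CS: [0, 1, 1, 1, 2, 2, 2, 3]
Ka: 7.0e+7          # M^-1, CI monomer-dimer association constant
OR_total: 2.0e-9    # M, operator concentration (single locus per cell)
R: 1.98e-3          # kcal/(mol*K)
T: 310.15           # K
log2_gfp_max: 11.76   # log2 AU, unrepressed reporter ceiling
log2_gfp_auto: 4.54   # log2 AU, cellular auto-fluorescence floor
K_fold_wt: 114.0      # wild-type folding equilibrium constant
expression_ratio: 15.0  # CI_E_high / CI_E_low
CI_E_low: 5.5e-8    # M, total expressed CI, low-expression condition
CI_E_high: 8.25e-7  # M, total expressed CI, high-expression condition
log2_gfp_wt_low: 7.23  # log2 AU, wild-type reporter level, low expression
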