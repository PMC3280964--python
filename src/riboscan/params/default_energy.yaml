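# Reduced nearest-neighbor RNA energy parameters.
#
# Units: all energies kcal/mol, enthalpies kcal/mol, temperatures Kelvin.
#
# Stacks are keyed "XY,ZW": the outer base pair 5'X...Y3' stacked on the
# inner pair 5'Z...W3' (i.e. pairs (i,j) and (i+1,j-1)).  Each value is
# [dG37, dH]; the entropy is derived as dS = (dH - dG37) / 310.15 so that
# dG(T) = dH - T*dS reproduces dG37 at 37 C.  Only one representative per
# symmetry orbit is listed: the stack read in the opposite direction,
# ("WZ,YX"), is physically identical and is filled in by the loader.
#
# Loop penalties are temperature-independent free-energy costs (kcal/mol)
# tabulated by loop size (unpaired nucleotides); sizes beyond the table are
# extrapolated as P(n) = P(n_max) + 1.75 * R * 310.15 * ln(n / n_max)
# (Jacobson-Stockmayer form).
#
# Multiloops carry a flat penalty; there is no dangle, coaxial-stacking or
# per-branch term.  Pseudoknot-layer pairs contribute a flat per-pair bonus
# (default 0).  These values are of plausible magnitude for RNA but are a
# deliberately reduced parameterization; they are not a Turner set.

gas_constant: 0.0019872
min_hairpin: 3
max_interior_loop: 30
multiloop_penalty: 3.4
pk_bonus_per_pair: 0.0
loop_extrapolation_coeff: 1.75

stacks:
  AU,AU: [-0.93, -6.82]
  AU,UA: [-1.10, -9.38]
  UA,AU: [-1.33, -7.69]
  AU,CG: [-2.24, -11.40]
  AU,GC: [-2.08, -10.48]
  UA,CG: [-2.35, -10.44]
  UA,GC: [-2.11, -12.44]
  CG,CG: [-3.26, -10.64]
  CG,GC: [-2.36, -13.39]
  GC,CG: [-3.42, -14.88]
  AU,GU: [-0.55, -3.21]
  AU,UG: [-1.36, -8.81]
  UA,GU: [-1.27, -6.99]
  UA,UG: [-1.00, -7.50]
  CG,GU: [-1.41, -5.61]
  CG,UG: [-2.11, -12.11]
  GC,GU: [-1.53, -8.33]
  GC,UG: [-2.51, -12.59]
  GU,GU: [-0.50, -13.47]
  GU,UG: [-0.60, -9.26]
  UG,GU: [-0.40, -5.00]

hairpin_loop:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.4
  7: 6.0
  8: 5.5
  9: 6.4

bulge_loop:
  1: 3.8
  2: 2.8
  3: 3.2
  4: 3.6
  5: 4.0
  6: 4.4

internal_loop:
  2: 1.5
  3: 1.6
  4: 1.7
  5: 2.0
  6: 2.1
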