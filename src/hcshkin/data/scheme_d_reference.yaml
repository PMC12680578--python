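# Reference kinetic parameter set for mechanism "d" (molecular, non-competitive
# H2 adsorption, no surface intermediates), as regressed for batch selective
# hydrogenation of canola oil over Lindlar catalyst at 120-180 degC and
# 0.4-1.2 MPa H2, centred at Tmean = 433.15 K.
#
# Units: rate pre-exponentials in mol mol^-1 min^-1; K1 pre-exponential in
# bar^-1; other equilibrium pre-exponentials dimensionless (mole-fraction
# basis); energies in kJ/mol (activation energy for k*, adsorption/desorption
# enthalpy for K*).
mechanism: d
constants:
  k4: {preexponential: 0.122, energy: 57.3, kind: rate}
  k5: {preexponential: 0.0141, energy: 55.2, kind: rate}
  k6: {preexponential: 0.0128, energy: 64.3, kind: rate}
  K1: {preexponential: 0.116, energy: -101.0, kind: equilibrium}
  K2: {preexponential: 11.2, energy: -0.761, kind: equilibrium}
  K3: {preexponential: 71.3, energy: -0.287, kind: equilibrium}
  K7: {preexponential: 3.27, energy: 26.0, kind: equilibrium}
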