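# Paci2017 hiPSC-CM single-cell model: the 2013 ventricular-like formulation
# with the late sodium current (INaL) added.  SI units throughout: potentials
# in V, time in s, concentrations in mM, conductances in S/F (permeability for
# gCaL in m^3/(F*s)), volumes in um^3, capacitance in F.
variant: paci2017
parameters:
  F: 96485.3415        # C/mol
  R: 8.314472          # J/(mol*K)
  T: 310.0             # K
  Cm: 9.87109e-11      # F
  Vc: 8800.0           # um^3, cytosol
  V_SR: 583.73         # um^3, sarcoplasmic reticulum
  Nao: 151.0
  Ko: 5.4
  Cao: 1.8
  Ki: 150.0            # fixed; the model has no K+ dynamics
  gNa: 3671.2302
  gNaL: 17.25          # 2.3 * 7.5, late sodium maximal conductance
  gCaL: 8.635702e-5
  gto: 29.9038
  gKr: 29.8667
  gKs: 2.041
  gK1: 28.1492
  gf: 30.10312
  gPCa: 0.4125         # A/F
  gbNa: 0.9
  gbCa: 0.69264
  kNaCa: 4872.9675     # A/F
  KmCa: 1.38
  KmNai: 87.5
  Ksat: 0.1
  gamma: 0.35
  alphaNaCa: 2.8571432
  PNaK: 1.841424       # A/F
  KmK: 1.0
  KmNa: 40.0
  KPCa: 0.0005
  E_f: -0.017          # V, funny-current reversal (native formulation)
  fNaIf: 0.37          # Na fraction for split If formulations (unused natively)
  VmaxUp: 0.56064      # mM/s
  Kup: 0.00025
  V_leak: 4.4444e-4    # 1/s
  a_rel: 16.464        # mM/s
  b_rel: 0.25
  c_rel: 8.232
  g_irel_max: 0.0      # RyR release model not used in this variant
  RyRa1: 0.0
  RyRa2: 0.0
  RyRahalf: 0.0
  RyRohalf: 0.0
  RyRchalf: 0.0
  Buf_C: 0.25
  Kbuf_C: 0.001
  Buf_SR: 10.0
  Kbuf_SR: 0.3
  L0: 0.025
  Q: 2.3
  PkNa: 0.03
  Vh_hLate: 87.61
  tau_hLate: 0.2       # s
initial_state:
  Vm: -0.0743340057623841
  Ca_SR: 0.302192
  Cai: 3.72347e-5
  g: 0.0
  d: 8.21e-5
  f1: 0.9999
  f2: 0.999
  fCa: 0.9987
  Xr1: 0.00779
  Xr2: 0.432162
  Xs: 0.0327
  h: 0.75
  j: 0.75
  m: 0.103
  Xf: 0.1132
  q: 0.839295925
  r: 0.00573289893
  Nai: 10.9248496212
  mL: 0.00297
  hL: 0.64
  RyRa: 0.05    # frozen, unused in this variant
  RyRo: 0.0
  RyRc: 1.0
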