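# Paci2018 hiPSC-CM single-cell model: recalibrated conductances and a
# RyR-gated sarcoplasmic-reticulum release replacing the 2013 release gate.
# SI units as in paci2017.yaml.
variant: paci2018
parameters:
  F: 96485.3415
  R: 8.314472
  T: 310.0
  Cm: 9.87109e-11
  Vc: 8800.0
  V_SR: 583.73
  Nao: 151.0
  Ko: 5.4
  Cao: 1.8
  Ki: 150.0
  gNa: 3671.2302
  gNaL: 17.25
  gCaL: 8.635702e-5
  gto: 29.9038
  gKr: 29.8667
  gKs: 2.041
  gK1: 28.1492
  gf: 30.10312
  gPCa: 0.4125
  gbNa: 0.95
  gbCa: 0.727272
  kNaCa: 3917.0463
  KmCa: 1.38
  KmNai: 87.5
  Ksat: 0.1
  gamma: 0.35
  alphaNaCa: 2.16659
  PNaK: 2.6351
  KmK: 1.0
  KmNa: 40.0
  KPCa: 0.0005
  E_f: -0.017
  fNaIf: 0.37
  VmaxUp: 0.5113
  Kup: 3.1928e-4
  V_leak: 4.7279e-4
  a_rel: 0.0           # 2013-style release not used in this variant
  b_rel: 1.0
  c_rel: 0.0
  g_irel_max: 62.5434
  RyRa1: 0.05354
  RyRa2: 0.0488
  RyRahalf: 0.02427
  RyRohalf: 0.01042
  RyRchalf: 0.00144
  Buf_C: 0.25
  Kbuf_C: 0.001
  Buf_SR: 10.0
  Kbuf_SR: 0.3
  L0: 0.025
  Q: 2.3
  PkNa: 0.03
  Vh_hLate: 87.61
  tau_hLate: 0.2
initial_state:
  Vm: -0.0749228904740065
  Ca_SR: 0.0936532528714175
  Cai: 3.79675694306440e-5
  g: 0.0     # frozen, unused in this variant
  d: 8.25220533963093e-5
  f1: 0.741143500777858
  f2: 0.999983958619179
  fCa: 0.997742015033076
  Xr1: 0.266113517200784
  Xr2: 0.434907203275640
  Xs: 0.0314334976383401
  h: 0.745356534740988
  j: 0.0760523580322096
  m: 0.0995891726023512
  Xf: 0.0249102482276486
  q: 0.841714924246004
  r: 0.00558005376429710
  Nai: 8.64821066193476
  mL: 0.00225383437957339
  hL: 0.0811507312565017
  RyRa: 0.0387066722172937
  RyRo: 0.0260449185736275
  RyRc: 0.0785849084330126
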