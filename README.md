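# hipsc-ap

In-silico pharmacology experiments on spontaneously beating human
iPSC-derived cardiomyocyte (hiPSC-CM) models: how do interventions that
primarily set the beating rate (funny-current modulation) or primarily set
repolarization (IKr / ICaL block) move the **inter-beat interval (rr)** and
the **action-potential duration at 90 % repolarization (APD90)** — and do the
models move them the way iCell monolayers do in vitro?

The package is aimed at safety-pharmacology and cardiac-modelling groups who
need a tested, scriptable version of this pipeline: two single-cell model
variants (Paci2017, Paci2018), four exchangeable formulations of the funny
current I_f, Hill-equation channel block, limit-cycle and acute perturbation
protocols, and per-beat biomarker extraction.

## The pieces

* **Cell models** (`hipsc_ap.model`, `hipsc_ap.parameters`) — stiff ODE
  systems (23 states: Vm, gates, Na⁺/Ca²⁺ handling) integrated with LSODA at
  rtol ≤ 1e-7. No stimulus current exists anywhere; the models beat
  spontaneously. dVm/dt is evaluated from the right-hand side at output
  samples, so upstroke detection is grid-independent.
* **Pharmacology** (`hipsc_ap.pharmacology`) — a compound is a set of
  (target, IC50, Hill slope) triples; the fraction of conductance remaining
  at concentration C is `s = 1 / (1 + (C/IC50)^h)`. Three shipped profiles
  (Diltiazem and two alternative Moxifloxacin selectivity profiles, each
  with off-targets) plus the g_f sweep {0, 50, 90, 99, 101, 110, 150, 200,
  300, 400} %.
* **Funny-current library** (`hipsc_ap.ifcurrent`) — native Paci gating plus
  Severi2012 (rabbit sinoatrial), Fabbri2017 (human sinoatrial) and an
  hESC-CM-calibrated formulation, all driven with the host's g_f and ionic
  concentrations ("same virtual channel density"), plus the simulated
  voltage clamp that characterizes them (hold −40 mV, steps −50…−100 mV).
* **Protocols** (`hipsc_ap.protocols`) — run to the limit cycle, apply a
  conductance scaling, analyze the final window (reference durations
  5000 s + 5000 s / 1000 s; documented scaled-down 800 s + 800 s / 400 s
  config flagged in every output); or apply the scaling exactly at the
  diastolic minimum and read the first two beats (acute protocol).
* **Biomarkers** (`hipsc_ap.biomarkers`) — peaks (20 mV prominence), rr as
  successive peak differences, APD90 from the maximum-upstroke-velocity
  instant to the interpolated 90 %-repolarization crossing, per-beat series
  averaged over the window.
* **Synthetic ground truth** (`hipsc_ap.synthetic`) — AP-train generators
  with exactly known period/APD90 for testing the biomarker pipeline, and
  clearly labelled *surrogate* repolarization-vs-rr reference curves for
  band plots (the experimental fit coefficients are not publicly printed).
* **Reporting** (`hipsc_ap.reporting`) — up/down/flat verdicts per
  intervention against a transcribed table of experimental directions,
  CSV/JSON/SVG export.

## Worked example

```bash
python analysis/01_pharmacology_tables.py
python analysis/02_voltage_clamp.py
python analysis/03_baseline_limit_cycles.py
```

The first script rebuilds the compound tables from IC50/Hill data; e.g. the
Diltiazem rows print

```
     profile  compound  concentration_uM  scale_gCaL  scale_gKr  scale_gNa
 diltiazem_I Diltiazem           10.0584      0.0500     0.5782     0.7375
 diltiazem_I Diltiazem            5.2224      0.1000     0.7457     0.8674
 diltiazem_I Diltiazem            0.7600      0.5000     0.9648     0.9874
 diltiazem_I Diltiazem            0.1106      0.9000     0.9961     0.9989
```

i.e. at the concentration that halves gCaL (0.76 µM, the IC50), the
off-target block leaves 96 % of gKr and 99 % of gNa. The third script runs
every model to its limit cycle and prints the baseline biomarkers:

```
              paci2017: rr=1.612 s  APD90=0.478 s  CV=0.0012  (beating)
              paci2018: rr=1.604 s  APD90=0.371 s  CV=0.0002  (beating)
   paci2018+severi2012: rr=1.740 s  APD90=0.364 s  CV=0.0003  (beating)
   paci2018+fabbri2017: rr=1.746 s  APD90=0.398 s  CV=0.0005  (beating)
paci2018+koivumaki2018: rr=1.711 s  APD90=0.417 s  CV=0.0008  (beating)
```

— spontaneous rates near 0.6 Hz with an rr coefficient of variation well
below the 1 % limit-cycle criterion. `analysis/04_intervention_sweep.py` and
`analysis/05_acute_effects.py` then produce the rr-vs-APD90 result tables
(including the sign disagreements with experiment: g_f augmentation prolongs
rr at the limit cycle but shortens it acutely under the sinoatrial-style
formulations), and `analysis/06_report.py` turns a sweep table into
direction verdicts and scatter figures with the surrogate bands.

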