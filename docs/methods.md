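# Methods

## Cell models

Two variants of the published hiPSC-CM single-cell model family are
implemented from their equation listings:

* **Paci2017** — the 2013 ventricular-like formulation (Hodgkin–Huxley
  currents INa, ICaL, Ito, IKr, IKs, IK1, If, background Na/Ca, NCX, NaK and
  sarcolemmal Ca pumps; ten-Tusscher-style SR release with a Ca-dependent
  inactivation gate) plus the late sodium current INaL added in the 2017
  revision (m³h gating, 200 ms inactivation).
* **Paci2018** — recalibrated conductances and Ca-handling parameters, a
  three-state RyR-gated SR release replacing the 2013 release gate, and the
  funny current split into Na⁺ and K⁺ components (fNa = 0.37) so that I_f
  feeds the intracellular Na⁺ balance. The Na⁺-carrying I_f matters: it is
  the slow adaptation pathway by which sustained I_f augmentation loads the
  cell with Na⁺ (raising the outward NaK-pump current) and ends up
  *prolonging* the inter-beat interval at the limit cycle even though the
  acute effect is a speed-up.

Both variants share one 23-slot state vector; slots a variant does not use
are frozen with zero derivative. Units are SI throughout (V, s, mM;
conductances in S/F; the reporting layer converts to mV/ms). All parameter
sets and initial states ship as per-variant YAML files
(`src/hipsc_ap/data/`). No stimulus current exists; the models are
spontaneously active.

Because the source publications' code is not redistributable here, the
equations were transcribed twice, independently: once in the packaged
(numba-compiled) right-hand side and once in a deliberately differently
organized plain-numpy coding (`tests/_oracle.py`). The test suite requires
the two transcriptions to agree to 1e-9 relative on derivative vectors at
random physiological states; this catches transcription slips, though it
cannot certify fidelity to the original sources beyond the published
equation listings they were both taken from.

## Funny-current formulations

Four single-gate formulations are exchangeable in the ``Xf`` state slot.
Substitution changes only the gating functions and current equation; the
host's g_f, capacitance and ionic concentrations are kept, so the virtual
channel density is the same across variants.

| formulation | V½ (mV) | slope (mV) | kinetics | current |
|---|---|---|---|---|
| paci (native) | −77.85 | 5 | sigmoid τ, max ≈1.9 s | 2017: lumped E=−17 mV; 2018: Na/K split, fNa 0.37 |
| severi2012 | −52.5 | 9 | rate-sum, fast | equal Na/K split × Ko/(Ko+45 mM) |
| fabbri2017 | piecewise (≈−97/8.2 below −80 mV) | — | rate-sum − 0.054 s | Na/K split, reversal ≈ −22 mV |
| koivumaki2018 | −96.9 | 8.8 | bell-shaped, peak ≈1.4 s near −90 mV | Na/K split, fNa 0.37 |

The Severi and Fabbri gating functions are transcribed from their published
models. The exact coefficients of the hESC-CM-calibrated formulation were
not available when this package was written; `koivumaki2018` is a documented
reconstruction (activation midpoint and slope from hESC-CM voltage-clamp
characterization, a bell-shaped time constant, HCN-style Na:K split) and its
docstring says so. The qualitative comparisons made with it (activation in
the diastolic range, acute chronotropic response) are insensitive to these
coefficient details. The Fabbri steady-state expression asymptotes slightly
above 1 (1.0125) below −133 mV; it is clipped to the unit interval there,
outside the operating range.

The simulated voltage clamp (hold −40 mV, 5 s steps to −50…−100 mV in 10 mV
increments, 5 s tail) runs in a "blank" host: fixed Paci2018 ionic
concentrations, no membrane ODE. With Vm piecewise constant the single
activation gate relaxes exactly exponentially, so the gate trajectory is
evaluated in closed form rather than by numerical integration.

## Pharmacological block

Channel block is pure conductance scaling through the inhibitory Hill
equation `s(C) = 1/(1 + (C/IC50)^h)`; no state- or voltage-dependent binding
(Markov drug kinetics are out of scope). Compound profiles are data, not
code (`data/compounds.json`): Diltiazem (primary gCaL, off-targets gKr and
gNa) and two alternative Moxifloxacin selectivity profiles (primary gKr;
off-targets gCaL+gNa or gNaL+gKs; the two profiles disagree between sources
and are kept as alternatives, never merged). Ivabradine and Forskolin are
represented as direct g_f scaling only — the underlying experiments used
incremental incubation or an indirect activator, so no concentration–effect
relation exists for them.

Scale factors are always recomputed at full precision from IC50 and slope;
the rounded printed tables serve only as golden tests (validated with
half-away-from-zero rounding at each cell's printed decimal count). For the
Diltiazem and first Moxifloxacin profiles the primary-target fractions are
the set points and concentrations are derived by the inverse Hill equation;
the alternative Moxifloxacin profile is driven by the shared concentration
series, because its printed primary column is itself a rounded forward
evaluation (inverting it would compound rounding).

## Protocols and biomarkers

Reference protocol: integrate the unperturbed model for 5000 s, apply the
scaling, integrate a further 5000 s, analyze the last 1000 s. Routine runs
use a documented scaled-down configuration — 800 s + 800 s with a 400 s
window — that carries an explicit `scaled_down` flag in every output; at
these durations the baseline rr coefficient of variation is ≈2×10⁻⁴, far
below the 1 % limit-cycle criterion, and all direction-of-effect results in
the test suite are obtained under this configuration. "Limit cycle reached"
is operationalized as rr CV < 1 % over the analysis window; non-converged
runs are reported, not discarded. A run with no detected peak for 30 s is
flagged quiescent; rr standard deviation above 5 % of the mean flags an
irregular rhythm (the per-beat series is always retained so alternans is
not masked by averaging).

The acute protocol locates the diastolic minimum between the first two
beats (grid minimum refined by a three-point parabolic fit — the numerical
operationalization is ours), advances the unperturbed model exactly to that
time, applies the scaling, and reports the APD90 of the first
post-perturbation AP and the rr between the first and second
post-perturbation peaks.

Biomarkers: beats are local maxima with ≥20 mV prominence (a declared
default; it cleanly separates APs from diastolic depolarization wiggle).
rr is the successive difference of peak times. APD90 runs from the
maximum-upstroke-velocity instant (dVm/dt evaluated from the right-hand
side at output samples, not finite differences) to the first downward
crossing of the per-beat level `Vpeak − 0.9 (Vpeak − Vdia)`, located by
linear interpolation; `Vdia` is the minimum between the previous and current
peaks, so the first beat of a window carries no APD90. rr and APD90
sequences are averaged over the window to suppress round-off scatter.

## Numerics

LSODA (variable-step, stiff) at rtol 1e-7, atol 1e-9; tightening tolerances
tenfold moves the baseline mean rr by < 0.1 % (asserted in tests). Output
grid 0.5 ms (the upstroke lasts ~1–2 ms). Long runs integrate in 50 s
chunks, retaining only t, Vm, dVm/dt (and optionally currents) plus the
final state, so memory stays flat. The L-type Ca current's GHK-style
driving term uses a series expansion of z/(e^z − 1) near z = 0. Gating
variables are never clipped inside the integrator; sampled states straying
more than 1e-6 outside [0, 1] truncate and flag the run (clipping happens
only at reporting). The membrane equation is assembled from the same current
values the API exposes, so dVm/dt ≡ −Σ I holds at machine precision.

One deliberate relaxation: the 2013-style SR release contains a
load-independent term, so under strong Ca-entry block (the Diltiazem grid)
the SR Ca²⁺ content drains monotonically through zero while the membrane
dynamics remain physiological — the formulation simply does not conserve SR
positivity in that regime, and an unconstrained stiff integrator (as used in
the original studies) integrates through it. Runs therefore *flag* SR
depletion (`sr_depleted` in solver stats) rather than aborting; strict
positivity is enforced for Cai and Nai, which enter Nernst logarithms.

## Synthetic ground truth

The AP-train generator exists so the biomarker definitions are testable
independently of the ODE models. The triangular family has closed-form
markers and is exact under linear interpolation; the default smooth family
(product-of-logistics beats, continuous derivative, repolarization midpoint
calibrated by root finding so the true APD90 equals the requested value)
provides a well-defined maximum-upstroke instant. Ground truth is computed
from the analytic waveform at high precision, independent of any sampled
trace. Generated trains emulate period, APD90, amplitude and additive
Gaussian noise; they do not emulate AP-shape pathologies (early
afterdepolarizations, alternans) or baseline drift, so biomarker tests
passing on them demonstrate correctness of the marker definitions, not
robustness to every real-trace pathology.

The repolarization-vs-rr reference curves shipped for band plots are
**surrogates** (second-order polynomial plus constant-half-width 90 % band
over a stated rr range): the experimental fit coefficients are not publicly
printed, so plausible stand-ins are shipped with a loud provenance tag and
are used only for plotting and inside/outside-band classification — never in
any assertion about experimental agreement.

## Known limitations

* Model fidelity is bounded by the double-transcription procedure described
  above; the original Matlab sources were not available for bit-level
  comparison, and the `koivumaki2018` I_f coefficients are reconstructions.
* Single-cell only: field-potential readouts (qtmax) from monolayers are
  treated as interchangeable with APD90 at the direction level; no
  multicellular coupling or cell-to-cell heterogeneity.
* Forskolin's signalling cascade is represented only as g_f scaling; no
  cAMP/second-messenger modulation of I_f.
* No parameter fitting to experimental curves and no population-of-models
  variability analysis: the package reproduces and interrogates the given
  model variants, it does not recalibrate them.
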