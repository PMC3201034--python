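# Methods

## Model structure

The clock is a 19-species autonomous ODE system (hours / nM throughout; no
unit conversions anywhere). Two interlocked negative feedback loops generate
the rhythm: nuclear BMAL1–CLOCK (*I_N*) represses Bmal1 transcription, and
nuclear CLOCK (*P_N*) represses Clock transcription; *I_N* simultaneously
activates Myod1 transcription, MYOD1 drives miR-206 synthesis, and miR-206
removes Clock mRNA by forming the silencing complex *R_ISC* at rate
`C3·miR·M_P` — a post-transcriptional negative limb closing the
Clock→MYOD1→miR-206→Clock loop. Transcription terms are Hill-type with
cooperativity 4, protein (de)phosphorylation and saturable degradation are
Michaelis–Menten, transport and complex formation are mass action.

Three gene bookkeeping variables (*G_B*, *G_C*, *G_M*) carry the printed
production/decay/transcription terms of the gene loci but feed into no other
equation; deleting them leaves the remaining 16-variable dynamics unchanged
(asserted structurally in the tests). Their transcription Hill term enters
with a negative sign on the gene variable, as defined; since the variables
are terminal this is a bookkeeping convention without dynamical effect.

Two readings of the model definition are ambiguous and resolved as follows:

* the nonspecific Bmal1-mRNA decay constant is `k_dmb` (the only constant
  defined for that role);
* the P0-phosphorylation flux uses `K_1` in both equations it touches
  (`K_1` is defined as the P0-phosphorylation Michaelis constant); reading
  its second occurrence with `K_2` instead would make the flux leaving P0
  differ from the flux entering P1. This choice matters: the consistent
  `K_1` reading yields a 22.98 h basal period, the two `K_2` readings
  24.6–25.3 h.

## Parameters

78 named constants, of which two (`k_stot`, `v_stot`) are pure scale
factors absorbed into `k_sB`, `k_sC`, `V_sB`, `V_sC` on load; the 76
resolved constants are the sensitivity-analysis targets. The four packaged
sets differ only in the coupling rate `C3` ∈ {0, 0.5, 1.0, 1.5} nM⁻¹·h⁻¹;
`Set3` (C3 = 1.0) is the package default for the coupled condition because
results are insensitive to the choice among the coupled sets (basal period
22.80/22.98/23.04 h for C3 = 0.5/1.0/1.5), and `Set1` (C3 = 0) is "no
miR-206 regulation". Constants users most often vary:

| constant | meaning | basal | unit |
|---|---|---|---|
| `C1` | constitutive miR-206 production | 0.01 | nM·h⁻¹ |
| `C2` | miR-206 degradation | 0.01 | h⁻¹ |
| `C3` | silencing-complex formation | 1.0 | nM⁻¹·h⁻¹ |
| `C4` | silencing-complex degradation | 0.6 | h⁻¹ |
| `V_sB` | max Bmal1 mRNA synthesis | 0.28 | nM·h⁻¹ |

## Numerics

* **Integration**: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  rtol 1e-8 / atol 1e-10, output resampled at 0.05 h (~480 samples per
  cycle). Halving the tolerances moves the post-transient trajectory by
  < 1e-5 relative (tested). The system preserves non-negativity
  analytically; solver round-off below zero is clamped on evaluation and
  counted in the trajectory diagnostics.
* **Initial condition**: all species at 0.1 nM by default (overridable).
  The basal attractor is a limit cycle, so post-transient metrics are
  initial-condition independent (periods from random starts agree to
  < 0.02 h); only transient-sensitive quantities (the local-period drift
  table) depend on it, and those are defined with this fixed default.
* **Transient discard**: 200 h before any limit-cycle metric; the
  local-period drift analysis deliberately uses no discard since the drift
  *is* the transient.
* **Peaks**: strict local maxima of the raw signal (no smoothing) with
  prominence ≥ 1e-6 nM, peak times refined by a three-point parabola.
  Period = mean inter-peak interval; amplitude = peak-to-trough excursion
  over complete cycles (half-range differs by the factor 2 and gives
  identical ratios; a peak-level convention is available where an absolute
  level is wanted). Regime: *steady* if the excursion is < 1e-4 of the mean
  level (amplitude then reported as 0), *damped* if cycle ranges shrink
  > 5% per cycle persistently (median successive ratio < 0.95), else
  *sustained*. A finite window necessarily classifies very slowly decaying
  oscillations as sustained; the damped-regime runner therefore uses a
  short (30 h) discard so the decaying cycles fall inside the window.
* **Phase**: circular cross-correlation of the mean-removed signals over an
  integer number of cycles, FFT-evaluated, parabolically refined, wrapped
  into (−T/2, T/2]; positive lag means the second species trails the first.
  In-phase / antiphase bands are ±T/6 around 0 and T/2.
* **Steady states**: 1500 h probe integration; if the trailing 20% of the
  span is flat (relative excursion < 1e-4 for every species) the endpoint is
  polished by a Newton root solve and accepted only if max |dy/dt| < 1e-9
  nM·h⁻¹. An oscillatory trajectory returns "none" — individual species may
  still be steady in a rhythmic system (e.g. at V_sB = 0.14 the Bmal1/MYOD1
  arms flatline while the CLOCK arm keeps cycling), which the per-species
  regime classification captures.
* **Sensitivity**: Y = flux averaged over all complete post-transient
  cycles (first-to-last Bmal1-mRNA peak within a 200–300 h window); an
  integer-cycle average is phase-invariant, and using several cycles
  shrinks the window-endpoint error of the finite difference. Central
  differences at X(1 ± 0.01); Hill exponents are perturbed continuously
  like any other constant. Halving the perturbation moves the reported S by
  < 1% in the median and < 3% at the most nonlinear entries. Entries ruled
  out by the parameter→flux dependency graph (computed from the symbolic
  term registry) are fixed at exactly 0; the unmasked finite differences at
  those entries measure below 1e-5 (tested). If a perturbation kills the
  oscillation the steady-state flux is used and the constant is flagged.
* **Oscillation-death boundaries**: per-species regime classification on a
  grid, with the largest all-steady value refined by bisection to 0.005
  (sweeps record per-point failures and continue).

## What the basal model does

Computed by the tests and the acceptance script, not asserted a priori:
the coupled basal sets sustain a ~23 h limit cycle in every species;
removing the coupling (C3 = 0) lengthens the period to ~23.4 h and changes
amplitudes by only a few percent, because at basal C1 = 0.01 nM·h⁻¹ the
silencing flux is small against Clock-mRNA turnover. Raising C1 damps the
rhythm at 0.23 nM·h⁻¹ and extinguishes it at 1.0 nM·h⁻¹; lowering V_sB
below ≈ 0.21 nM·h⁻¹ silences the Bmal1/MYOD1 arms while the CLOCK arm
stays rhythmic across V_sB ∈ [0.1, 3.0]. The flux-sensitivity ranking is
headed by the Bmal1 mRNA synthesis/degradation constants
(V_sB ≥ V_mB ≥ k_sB), with the miR-206 production rate C1 significant for
a handful of fluxes — the BMAL1 arm dominates the oscillator's
sensitivity, the microRNA limb tunes it weakly.

## Limitations

* No light–dark entrainment forcing, no stochastic (Gillespie)
  counterpart, no delay equations, no parameter fitting to expression
  data, and no global (Sobol/Morris) or period-sensitivity analysis.
* Quasi-periodic/mixed-mode regimes (e.g. V_sB = 0.56 develops a slow
  large-amplitude Bmal1 envelope) are reported through the same peak
  statistics, where "period" means the mean inter-peak interval and can be
  much longer than the circadian scale; per-cycle range variance is
  available from the metrics but no single-number descriptor is attached.
* Regime classification is window-based and cannot distinguish a true
  limit cycle from an oscillation decaying slower than ~0.1% per cycle.
* The model's phase structure (Bmal1 mRNA roughly in phase with Clock
  mRNA and ~8 h offset from Myod1 mRNA) follows from the printed rate
  laws; experimentally reported clock-gene phasing in muscle differs, so
  phase predictions should be treated as model properties, not tissue
  predictions.
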