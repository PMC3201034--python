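# mirclock

Deterministic model of the **miR-206-mediated mammalian circadian clock** in
skeletal muscle: a 19-variable ODE system coupling the core BMAL1/CLOCK
transcription–translation feedback loops to the muscle-specific microRNA
miR-206, together with the analyses that characterise it — limit-cycle
period/amplitude/phase metrics, with/without-miRNA comparisons, scaled local
sensitivity of every reaction flux to every rate constant, and
oscillation-death parameter sweeps.

The package is aimed at systems biologists studying post-transcriptional
(miRNA-level) regulation of peripheral circadian oscillators, and at anyone
who needs a compact, fully reproducible Hill/Michaelis–Menten clock model to
experiment with.

## The model

Nineteen concentrations (nM; time in hours) evolve under mass-action,
Michaelis–Menten and Hill-type kinetics:

* **BMAL1 arm** — Bmal1 mRNA *M_B* and the cytosolic/nuclear,
  un-/phosphorylated proteins *B_c*, *B_cp*, *B_n*, *B_np*. Transcription is
  repressed by the nuclear BMAL1–CLOCK complex *I_N*:
  `V_sB·K_IB^m1 / (K_IB^m1 + I_N^m1)` (negative feedback loop 1).
* **CLOCK arm** — Clock mRNA *M_P*, the cytosolic phosphoforms *P0 → P1 →
  P2*, and nuclear CLOCK *P_N*, which represses its own transcription
  (negative feedback loop 2). *B_n* and *P_N* associate into *I_N*
  (`k3·P_N·B_n`).
* **MYOD1 / miR-206 arm** — Myod1 mRNA *M_my* (transcription activated by
  *I_N*), cytosolic MYOD1 *MY_C*/*MY_cp*, the microRNA *miR* driven by MYOD1
  (`V_sM·MY_C^n2/(K_AM^n2+MY_C^n2) + C1`), and the silencing complex *R_ISC*
  formed at rate `C3·miR·M_P`, which removes Clock mRNA — the
  post-transcriptional coupling under study.
* three gene bookkeeping variables *G_B*, *G_C*, *G_M* that receive input
  from the nuclear regulators but feed back into nothing.

Every kinetic term is registered exactly once in a canonical 49-reaction
flux table (`mirclock flux-table`), and the signed flux sums reproduce the
right-hand side to round-off — a bookkeeping contract the test-suite
enforces. Four basal constant sets ship with the package; they differ only
in the silencing-coupling rate `C3` (0, 0.5, 1.0, 1.5 nM⁻¹·h⁻¹), `Set3`
(C3 = 1.0) being the default coupled condition and `Set1` the uncoupled
clock. The scaled local sensitivity of flux *Y* to constant *X* is
`S = (X/Y)·∂Y/∂X`, estimated by central finite differences with a 1%
perturbation on cycle-averaged fluxes (49 × 76 = 3724 entries).

## Worked example

```python
from mirclock import load_parameters, integrate, measure, phase
from mirclock.simulate import SimulationSettings

params = load_parameters("Set3")                 # coupled basal clock
traj = integrate(params, SimulationSettings(t_end=500))  # stiff solver, 500 h
for sp in ("M_B", "M_my", "M_P"):
    m = measure(traj, sp)                        # peak-based metrics
    print(f"{sp:5s} period {m.period:6.2f} h  amplitude {m.amplitude:.3f} nM"
          f"  regime {m.regime}")
print(phase(traj, "M_B", "M_P").classification)
```

prints

```
M_B   period  22.97 h  amplitude 0.220 nM  regime sustained
M_my  period  23.00 h  amplitude 0.441 nM  regime sustained
M_P   period  22.99 h  amplitude 1.789 nM  regime sustained
in-phase
```

i.e. the basal constants sustain a circadian-scale (~23 h) limit cycle in
which Clock mRNA swings an order of magnitude harder than Bmal1 mRNA, and
the two mRNAs peak within a couple of hours of each other. Raising the
constitutive miR-206 production rate `C1` from its basal 0.01 nM·h⁻¹
progressively damps (C1 = 0.23) and then kills (C1 = 1.0) the oscillation —
`find_steady_state` returns the surviving fixed point — while lowering the
Bmal1 transcription rate `V_sB` below ≈0.21 nM·h⁻¹ silences the
Bmal1/MYOD1 arms but leaves the CLOCK arm rhythmic.

The same experiments are scriptable from the shell:

```bash
mirclock simulate --set Set3 --t-end 500 --out traj.csv
mirclock analyze traj.csv --species M_B
mirclock compare --set Set3 --out comparison.csv     # coupling on vs off
mirclock sweep --parameter V_sB --grid 0.14,0.28,0.56 --out sweep.csv
mirclock sensitivity --out smat.csv --summary counts.csv
mirclock reproduce --figure 8 --out-dir out/
```

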