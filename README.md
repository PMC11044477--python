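# calsa — computer-aided lung sound analysis

`calsa` quantifies digital-stethoscope chest recordings the way a
research pipeline for computer-aided lung sound analysis (CALSA) does:
it denoises the signal, separates the continuous breath sound from
discontinuous adventitious transients with iterative wavelet-packet
thresholding, extracts respiratory cycles from the breath-sound
envelope, and computes per-recording endpoints —

* **E/I power ratios** `E_b/I_b` for the bands 100–200, 200–400,
  400–800 and 800–1600 Hz, where `E_b` and `I_b` are the mean squared
  band-limited amplitudes pooled over all expiratory and inspiratory
  samples (the ratio is invariant to the automatic gain of the
  stethoscope, which makes absolute levels uninterpretable);
* **crackle counts** per respiratory phase (mean events/cycle), from
  rectified-envelope peak picking on the transient component;
* **wheeze parameters** — per tonal segment the power-weighted mean
  frequency, the quartiles `f25 ≤ f50 ≤ f75` of the normalized segment
  spectrum, and the occupation rate (% of the phase type's duration).

A statistical layer relates these endpoints to lobar imaging scores and
spirometry with linear mixed-effects models
`y_ij = β₀ + β₁ x_ij + u_i + v_j + ε_ij` (random intercepts `u_i` per
subject and `v_j` per lung zone, REML, Wald test on `β₁`; subject-only
for assessment-level spirometry), plus interobserver agreement tools
(two-way absolute-agreement average-measures ICC, Bland–Altman limits),
Spearman interdependency of imaging subscores, and per-family
Bonferroni-adjusted significance levels.

Because no public auscultation dataset with known phase timings,
crackle positions and band-power ratios exists, the package ships a
**synthetic generator** (`calsa.synthetic`) that renders
auscultation-like audio with exhaustive ground truth; every detector is
validated against it. It is intended for researchers in respiratory
acoustics and anyone building or evaluating lung-sound pipelines.

## Worked example

```python
from calsa import SimulationSpec, simulate_recording, analyze_recording

spec = SimulationSpec(seed=7, crackles_per_insp=3.0, crackles_per_exp=1.0)
rec, truth = simulate_recording(spec)
row = analyze_recording(rec)

print("n_cycles:", row.n_cycles)
print("E/I ratios:", [round(v, 3) for v in row.ei.as_tuple()])
print("true E/I:  ", [round(v, 3) for v in truth.true_ei_ratios])
print(f"crackles per cycle: {row.crackles.full_cycle:.2f}")
```

prints

```
n_cycles: 7
E/I ratios: [0.256, 0.177, 0.241, 0.347]
true E/I:   [0.25, 0.168, 0.24, 0.36]
crackles per cycle: 4.29
```

The seven simulated breathing cycles are found automatically; the four
measured band-power ratios match the generator's ground truth (the
squared ratio of expiratory to inspiratory band gains) within a few
percent; the mean crackle count per cycle, 4.29, equals the injected
rate for this seed. An `AssociationResult` from the statistical layer
prints a compact `summary()` with slope, standard error, 95% CI,
p-value and the direction glyph used in lobar association tables.

The same pipeline runs from the shell:

```bash
calsa simulate --n 20 --seed 12345 --out suite/   # WAV + ground truth
calsa analyze recordings/ --out features.csv      # feature table
calsa validate --n 20 --seed 12345                # score vs ground truth
calsa associate features.csv --cfct cfct.csv --out results/
```

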