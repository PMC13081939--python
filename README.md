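# omnquant

Quantification pipeline for studying how the developmental origin of
zebrafish extraocular motor neurons (cranial nuclei nIII and nIV) maps
onto torsional eye-movement behavior.  It implements, as tested Python
with synthetic-data generators for every input:

- **Stimulus kinematics** — the tilt-step protocol: ±15° steps with a
  trapezoidal velocity profile (peak 35 °/s, peak acceleration 150 °/s²),
  50 cycles of four steps at 200 Hz, plus segmentation of recorded
  platform traces back into steps.
- **Torsion tracking** — per-frame torsional eye angle from a 100×100 px
  eye video by rotational registration (normalized cross-correlation over
  a circular mask, sub-grid parabolic refinement).
- **VOR gain** — the behavioral statistic
  `gain = peak eye velocity / peak platform velocity (35 °/s)`, with the
  peak taken over the first second after each step onset and averaged
  across retained steps per direction, and automated exclusion of steps
  contaminated by saccades or tracking failures.
- **Genotype statistics** — one-way ANOVA + Tukey HSD on per-fish gains;
  Welch t-tests on per-region soma counts.
- **Birthdating** — born-before classification from photoconverted red
  fluorescence thresholded on non-converted controls, cumulative
  birthdate curves over 18–54 hpf conversion timepoints, and topographic
  counting in dorsal nIII / ventral nIII / nIV.
- **Candidate selection** — the transcriptomic filters: differential
  expression (fold change > 2 and adjusted p < 0.01), one-sided binomial
  GO over-representation with Bonferroni correction, the single-cell QC
  gate (exclude <1,100 genes, >15,000 genes, >4% mitochondrial counts),
  and Venn-style expression-pattern summaries.

Intended users: systems/developmental neuroscientists who want the full
quantification chain of a tilt-VOR + birthdating + transcriptomics study
as inspectable, rerunnable code, with ground-truthed synthetic data in
place of raw recordings.

## Worked example

Simulate one fish with direction-specific gains and recover them:

```python
from omnquant.stimulus import StimulusParams
from omnquant.synthetic import EyePlantParams, generate_session
from omnquant.gain import fish_gain

stim = StimulusParams(n_cycles=2, hold_duration=1.5)
plant = EyePlantParams(gain_up=0.5, gain_down=0.9, noise_sd=0.1, seed=7)
sess = generate_session(stim, plant)
fr, audit = fish_gain(sess.platform_trace, sess.eye_trace, fish_id="fish1")
print(f"gain_up={fr.gain_up:.3f}  gain_down={fr.gain_down:.3f}  "
      f"retained={fr.n_retained_up}+{fr.n_retained_down}")
```

```
gain_up=0.512  gain_down=0.909  retained=2+2
```

The estimates match the injected plant gains (0.5 nose-up, 0.9
nose-down) to within the noise floor; `audit` lists each step's peak
velocity and retention decision.

The `analysis/` scripts run the same machinery as a narrative pipeline —
`01_simulate_behavior.py` (genotype cohorts → per-fish gains),
`02_track_torsion.py` (synthetic video → tracking error),
`03_compare_gains.py` (ANOVA + Tukey), `04_birthdating.py` (conversion
series, curves, count comparisons), `05_transcriptomics.py` (DE/GO/QC/
pattern outputs) — writing small tables under `results/`.  Running
`03_compare_gains.py` on the simulated cohorts prints, for example:

```
direction comparison  mean_difference    q  p_tukey   F  p_anova
       up Het vs Mut            0.643 30.4 2.88e-14 290 5.84e-15
       up  Het vs WT          -0.0258 1.27    0.647 290 5.84e-15
       up  Mut vs WT           -0.668 29.9 3.67e-14 290 5.84e-15
```

i.e. the simulated mutant deficit is detected against both control
groups while wildtype and heterozygote remain indistinguishable —
the qualitative pattern a motor-neuron fate mutant shows in this assay.

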