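# padrom

Quantifying how ice hockey shoulder/elbow pads restrict upper-body mobility,
and how that restriction relates to subjective comfort.

Protective pads keep hockey players safe but also bind the shoulder and
elbow. `padrom` implements the full analysis chain used to measure that
trade-off from inertial (IMU) motion capture: players perform nine static
single-degree-of-freedom tasks (shoulder flexion/extension,
adduction/abduction, internal/external rotation, elbow flexion, forearm
pronation/supination) and two shooting tasks (wrist shot, slap shot) under
six conditions — no pads plus five commercial pad models — and the package
turns the recorded segment orientations into range-of-motion (ROM)
statistics and a comfort evaluation.

## What it computes

**Kinematics.** Segment orientations are unit quaternions (scalar-first,
Hamilton convention) sampled at 96 Hz. After a zero-phase 4th-order
Butterworth low-pass (6 Hz) on the quaternion components, the joint rotation
is

```
q_joint = q_proximal^-1 ⊗ q_distal
```

decomposed with the intrinsic Y–X′–Z″ Euler sequence: Y =
flexion/extension, X = abduction/adduction, Z = axial rotation
(internal/external rotation, pronation/supination).

**ROM extraction.** Static ROM is the excursion from the initial anatomical
angle (mean over the first 0.25 s) to the task-direction extremum, averaged
over left and right sides. Shots are segmented by events — shot initiation
(SI) and shot release (SR), plus swing top (ST) for the slap shot — detected
from hand angular speed and shoulder backswing; phase ROM is the max − min
of each joint-plane angle inside the SI–SR, SI–ST and ST–SR windows.
Right-handed shooters are mirrored to left-handed form before pooling.

**Statistics.** Per joint plane, a one-way repeated-measures ANOVA across
the six conditions with Greenhouse–Geisser correction and partial η²
(bands 0.01/0.06/0.14), gated LSD post-hoc paired t-tests, Shapiro–Wilk
normality checks; Friedman and Wilcoxon signed-rank tests for the 1–5
Likert survey; Spearman correlation (exact permutation p at small n)
between per-pad comfort and total ROM, banded 0.1/0.3/0.5.

**Synthetic studies.** A generator reproduces the 9-participant × 11-task ×
6-condition × 5-repetition design with known per-condition ROM restriction
factors (seeded from the published pad/control ratios), ground-truth shot
events, and survey scores coupled to the injected restriction — so the
whole pipeline is testable without the original recordings.

## Worked example

```python
from padrom import RunConfig, run_pipeline
from padrom.synth import GeneratorConfig

cfg = RunConfig(
    output_dir="demo_run",
    seed=1,
    generator=GeneratorConfig(n_participants=4, repetitions=2, n_left_handed=3, seed=1),
)
result = run_pipeline(cfg)
row = result.stats_static.loc["sho_flex"]
print(f"shoulder flexion: no pads {row['no_pads_mean']:.1f} ± {row['no_pads_sd']:.1f} deg, "
      f"Vik-Max {row['vik_max_mean']:.1f} ± {row['vik_max_sd']:.1f} deg")
print(f"RM-ANOVA: F = {row['F']:.2f}, p(GG) = {row['p']:.2e}, eta_p^2 = {row['eta_sq']:.3f} ({row['effect_band']})")
print(result.correlations.round(3))
```

prints

```
shoulder flexion: no pads 164.3 ± 8.7 deg, Vik-Max 148.9 ± 7.7 deg
RM-ANOVA: F = 130.28, p(GG) = 3.46e-06, eta_p^2 = 0.977 (large)
          rho      p  band
tasks
static    0.9  0.083  high
dynamic   0.6  0.350  high
combined  0.9  0.083  high
```

The four synthetic participants lose ~15° of shoulder flexion under the most
restrictive pad (the generator injected exactly that restriction), the
condition effect is significant with a large effect size, and the per-pad
comfort scores track total ROM with a high Spearman correlation — the same
qualitative picture as the reference study. `demo_run/` receives the ROM
table, the per-plane statistics CSVs (publication-style formatted copies in
`table_*.csv`), normalised ROM, comfort summary, correlation report, run
log and a copy of the config.

A command-line interface covers the same steps:

```
padrom generate study_dir --seed 1      # write a synthetic study to disk
padrom rom study_dir --out rom.csv      # extract the ROM table
padrom run -o run_dir --seed 1          # full pipeline
padrom tables run_dir/stats_static.csv  # formatted condition tables
```

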