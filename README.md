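# trisync

Synchronization-pattern analysis for a ring of three coupled oscillators,
aimed at small-group coordination data: three agents (for example three
attackers in a 3-vs-1 ball possession drill) whose interaction is summarized
by the three interior angles θ₁, θ₂, θ₃ of the triangle they form.

## The science

Because θ₁ + θ₂ + θ₃ = π at every instant, an angle triple lives on a
2-simplex and can be drawn inside an equilateral triangle (the *phase
plane*): vertex *i* is the degenerate state θᵢ = π and the centre is the
symmetric state θᵢ = π/3. Treating the three agents as a symmetric ring of
coupled oscillators (dihedral D₃ symmetry), equivariant Hopf bifurcation
theory predicts five generic pattern classes — independent of the
oscillators' internal dynamics:

| class | phase relation | phase-plane attractor |
|---|---|---|
| all in-phase | three identical waveforms | the centre point (forced constant by the sum-π constraint) |
| rotation (R) | one waveform with cyclic 2π/3 shifts | circle about the centre, radius (√3/2)·A/π |
| partial anti-phase (PA) | one pair anti-phase, third channel dead (constant c); PA1: c < π/3, PA2: c > π/3 | line parallel to the edge opposite the dead vertex |
| partial in-phase (PI) | one pair identical in phase, third anti-phase at twice the amplitude | segment of a median line |
| asymmetric | three unrelated waveforms | no attractor |

`trisync` provides the full analysis chain:

- **synthetic** — closed-form generators for all five classes (plus
  pattern-switching trials and a track realization with seeded position
  noise), so every stage is testable without recordings;
- **preprocess** — 2-D DLT (projective) calibration from control points,
  zero-phase Butterworth track smoothing, interior-angle extraction, and
  exclusion-gap handling;
- **phase_plane** — simplex embedding, ideal template trajectories, and
  min–max-normalized occupancy densities;
- **classify** — peak-based relative-phase estimation, pairwise labels
  (in-phase / anti-phase / ±2π/3 shift / oscillator death), and triple
  pattern labels with per-trial occurrence frequencies;
- **stats** — two-group permutation tests on frequency vectors over
  {R, PA, PI} (trial-level and subgroup-level), exact for small designs;
- a `trisync` CLI (`simulate`, `preprocess`, `classify`, `density`,
  `permtest`, `run`) orchestrating seeded, reproducible runs.

## Worked example

Simulate a noise-free rotation trial, classify it, and compare a
rotation-dominant group with an anti-phase-dominant group:

```sh
trisync simulate --pattern R --amplitude 0.3 --frequency 0.5 \
    --duration 90 --seed 1 --out r_angles.csv
trisync classify --angles r_angles.csv --out labels.csv,freq.csv
head -4 freq.csv
```

```
trial,label,percent
0,R,98.888889
0,PA1,0.000000
0,PA2,0.000000
```

98.9% of the trial's valid time is labelled rotation (the remainder is the
trial's edges, before the first and after the last detected oscillation
peak). A two-group comparison from a YAML config (`trisync run --config
compare.yaml`, 8 trials per group, position noise 0.03 m, 999 permutations)
prints:

```
"group_means": {
  "a": {"R": 97.7, "PA": 0.0,  "PI": 0.0},
  "b": {"R": 0.0,  "PA": 97.1, "PI": 0.0}},
"perm_test_trials":    {"method": "exhaustive", "p_value": 0.000155},
"perm_test_subgroups": {"method": "exhaustive", "p_value": 0.0286}
```

Group a's trials are almost entirely rotation, group b's almost entirely
partial anti-phase; both permutation tests (trial-level over C(16,8)
re-assignments, subgroup-level over C(8,4)) reject exchangeability.

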