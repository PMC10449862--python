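# dynexpect

Tools for studying **sub-second dynamics of reward expectations** in
slot-machine tasks, for cognitive/behavioral neuroscientists working with
EEG and live-betting behavior.

While a slot-machine reel decelerates, a player's expectation of a match
changes moment to moment: far misses are given up early, an overshoot
(`NEAR_AFTER` — the chosen item crosses the payline and keeps going)
produces a rise-then-collapse, and matches and `NEAR_BEFORE` outcomes keep
uncertainty, and expectation, high until the standstill. `dynexpect`
provides a tested pipeline for the two readouts of this process and the
statistic linking them:

- **Behavior** — "Slot or Not" live-betting logs (switching between a sure
  amount and the machine at will) are converted to binary 50-ms bet-state
  timeseries; per-outcome expectation curves, six 500-ms deceleration-window
  means, and slope contrasts follow.
- **EEG** — stop-locked epochs are baseline-corrected to the 200 ms before
  spin onset, averaged by outcome, summarized as CNV-window means at Cz, and
  post-outcome FRN/P3 amplitudes are extracted by a peak-anchored 80-ms
  rule.
- **Inference** — per-window repeated-measures ANOVA with Greenhouse–Geisser
  correction at the Šidák threshold α′ = 1 − (1 − α)^(1/k) (0.05, k = 6 →
  0.008), Tukey pairwise comparisons, paired t-tests.
- **Coupling (the core algorithm)** — a data-driven window search: for each
  candidate window [t, 0], t ∈ [−3, −0.5] s, the four per-outcome curves of
  both sides are resampled to 100 points, concatenated into 400-point
  vectors, and Pearson-correlated per subject against the group behavioral
  curves; the window maximizing |mean over subjects of r| is selected, and
  significance comes from outcome-label permutations that **re-run the full
  search** each time, so the selection optimism is built into the null.
- **Simulation** — a seeded generator for complete cohorts (trial schedules
  with linear-deceleration reel kinematics, latent expectation trajectories,
  hazard-model betting logs, CNV-ramp EEG epochs), so every stage is
  testable without any data download.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a paired EEG + behavioral study in the gain framing and run the
coupling analysis with 199 permutations:

```sh
dynexpect couple --pair 1+2 --n-subjects-eeg 8 --n-subjects-beh 12 \
    --n-perm 199 --seed 7 --out out/
```

prints

```
window [-1.57, 0] s  |mean r| = 0.743  p = 0.005 (199 permutations)
```

meaning: across the 8 simulated EEG subjects, the absolute subject-averaged
correlation between per-outcome Cz averages and the group betting curves is
maximized (at 0.743) on the final 1.57 s of deceleration, and none of the
199 label-shuffled searches reached that value (p = (1+0)/(1+199) = 0.005).
`out/coupling.json` carries the per-subject and per-outcome correlations —
here match −0.93, near-before −0.93, near-after +0.20, full-away −0.54:
negative where the negative-going CNV ramp tracks the rising bet tendency —
and `out/coupling_null.csv` the permutation null.

The same stages are available as a library:

```python
from dynexpect import pipeline, coupling

eeg = pipeline.run_eeg_study(study=1, n_subjects=8, seed=7)
beh = pipeline.run_behavioral_study(study=2, n_subjects=12, seed=8)
res = pipeline.run_coupling(eeg, beh, coupling.CouplingConfig(n_permutations=199, seed=9))
print(res.t_star, res.mean_abs_r, res.p_value)
```

Other subcommands: `dynexpect simulate` writes a session bundle
(schedule/events/epoch files with JSON sidecars), `dynexpect behavior` and
`dynexpect erp` run a single study end to end, `dynexpect run-study` runs a
full pair including coupling.

## Acceptance script

`scripts/acceptance.py` recomputes the package's acceptance quantities from
scratch by running the library (currently the per-window Šidák threshold
for six windows at family-wise α = 0.05, truncated to three decimals) and
writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Reproducing the original studies' empirical numbers (window-mean μV values,
F statistics, the |r| = 0.44 at −0.97 s and |r| = 0.39 at −1.26 s coupling
results) requires the publicly deposited recordings; point the behavior/ERP
readers at data converted to the documented CSV/epoch formats and run the
same pipeline functions.
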