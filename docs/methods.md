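# Methods

`dynexpect` analyzes sub-second reward-expectation dynamics in a two-reel
slot-machine task. A trial ends with the right reel decelerating to a
standstill; the outcome is classified by the stop distance from the item the
player chose: a match (`MATCH`), one item before a match (`NEAR_BEFORE`), one
item after (`NEAR_AFTER`), or two-to-three items away (`FULL_AWAY`). All
times in the package are stop-locked seconds: 0 is the standstill, negative
values precede it. Everything below is deterministic under one master seed;
per-subject and per-trial random substreams are spawned from it with
`numpy.random.SeedSequence`.

## Task simulation

**Kinematics.** The fast spin duration is uniform on [0.850, 1.950] s and
the deceleration duration D uniform on [2.533, 4.050] s — only the mean and
range of these phases are known, so the uniform is the maximum-entropy
choice; its deceleration mean (3.2915 s) differs from the reported mean
(3.307 s) by under 0.5%, which we accept. Deceleration is linear: speed
decays from the fast-spin speed v0 (items/s) to zero, so the item j
positions before the stop item crosses the payline at
t_j = −sqrt(2 j D / v0). v0 is calibrated in closed form so that the mean
entry time of the one-before-last item equals −0.685 s over the duration
distribution (v0 ≈ 13.97 items/s); per trial the entry time varies with D,
so the −0.685 s figure holds on average, not per trial.

**Latent expectation trajectories.** Each outcome class carries a latent
unsigned match-expectation p(t) ∈ [0, 1] on the deceleration epoch. The
pre-evidence level is the objective match base rate of every study design,
p0 = 1/6 (25/150 = 6/36). `MATCH` and `NEAR_BEFORE` rise sigmoidally toward
0.95 / 0.90 (half-rise at −1.00 / −0.85 s, time constant 0.25 s) — the match
rises slightly earlier and higher because the approaching alignment is
visible. `NEAR_AFTER` follows the `NEAR_BEFORE` rise until the penultimate
item enters the payline (that item *is* the selected one), then collapses
exponentially (τ = 0.15 s) toward a floor of 0.03. `FULL_AWAY` decays from
p0 to the floor around the moment the selected item crosses the payline, and
is constrained monotone non-increasing. These shapes encode the qualitative
hypotheses of the task (early decay for far misses; a rise-then-collapse for
overshoots; monotone rises when uncertainty persists to the stop); the
numerical constants are choices, not measurements.

**Betting behavior.** The live-betting readout is a discrete-time hazard
process on a 50-ms grid from spin onset to +0.750 s. At each step the lagged
expectation e = p(t − lag) (held at p0 before deceleration and at the
realized outcome after the stop) determines the favored option — the machine
iff e exceeds the sure amount divided by the 100-point jackpot — and a
disagreeing state switches with probability 1 − exp(−h·|e − s/100|·Δt).
Defaults: lag 0.20 s (motor/decision latency; the behavioral drop should not
trail the EEG drop by more than a reaction time, as the empirical behavioral
collapse actually *precedes* the electrophysiological one), hazard
h = 10 s⁻¹ per unit gap. The initial state is an unbiased coin flip. No
behavioral generative model is claimed by the underlying studies; this one
is the documented default and reproduces the qualitative orderings of the
group curves (at −0.25 s: MATCH > NEAR_BEFORE > NEAR_AFTER > FULL_AWAY).

**EEG epochs.** Epochs span [−6.2, +1.0] s at 256 Hz by default (down from
512 Hz for desk-scale memory; configurable) on the seven midline electrodes
the analyses touch (Fz, FCz, Cz, CPz, Pz, POz, Oz). The pre-stop signal is a
CNV-like ramp: −gain · (p(t) − p0) scaled by a fronto-central scalp profile
maximal at Cz (gain default 10 μV per unit expectation, giving match-trial
window means near −7 μV). Because the ramp tracks the *unsigned* match
expectation, the gain and loss framings produce identical pre-stop EEG while
their behavioral values invert — the asymmetry of interest. Post-stop, each
epoch carries outcome-dependent FRN (negative, ~250 ms, fronto-central) and
P3 (positive, ~373 ms, centro-parietal) Gaussian components, both largest
for a match and the P3 next-largest for `NEAR_BEFORE`. White Gaussian sensor
noise (default sd 10 μV per sample) is added to all channels.

What the generator does **not** emulate: 1/f background spectra and
autocorrelated EEG noise, artifacts, channel covariance, per-subject
amplitude/latency heterogeneity beyond the noise, probability weighting or
risk attitudes in choice, or payline-visual confounds. A green test on this
world therefore establishes that the pipeline computes what it claims on
data with the assumed structure, not that the scientific effects replicate.

## Analyses

**Behavior (betting studies).** Event logs are converted by sample-and-hold:
the series value at grid time τ is the state set by the latest event at or
before τ, with the last event winning on exact ties. Participants who make
zero switches in ≥ 90% of their trials (the whole trial, including the
750 ms after the stop) are excluded. Curves aggregate trials → participant
means → unweighted group mean, matching the repeated-measures unit of
analysis. The six 500-ms deceleration windows from −3.0 s are half-open
[a, b) except the final [−0.5, 0], closed so the standstill sample counts
exactly once (the same convention is used for EEG window means). The slope
analysis fits per-participant OLS slopes of the curve on time within
[−0.5, 0] and contrasts `NEAR_BEFORE` vs `NEAR_AFTER` with a paired t-test.

**ERP.** Epochs are baseline-corrected to the 200 ms preceding each trial's
spin onset (earlier than the conventional pre-outcome baseline, which would
subtract away exactly the condition differences of interest). Condition
averages are computed per subject after baseline correction; an optional
zero-phase 4th-order Butterworth low-pass at 30 Hz is applied to averages
only, never to single trials. Deceleration-window means are taken at Cz.
FRN/P3 amplitudes use a peak-anchored rule: the peak is located on the
class-collapsed, cluster-averaged group grand average (FRN: most negative
point in 200–350 ms over Fz/FCz/Cz; P3: most positive in 300–500 ms over
Cz/CPz/Pz/POz/Oz; earliest sample on ties), and the fixed 80-ms window
(peak ± 40 ms, edges rounded to the nearest 10 ms) is then applied to every
subject and condition, avoiding per-condition peak bias.

**Inference.** The per-window threshold is α′ = 1 − (1 − α)^(1/k) — the
Šidák form, quoted truncated to three decimals (α = 0.05, k = 6 → 0.008).
The one-way repeated-measures ANOVA is computed from definitional sums of
squares with the subject-by-condition interaction as error term,
df (k−1, (k−1)(n−1)); the Greenhouse–Geisser ε comes from the
double-centered sample covariance of the condition scores, clipped to
[1/(k−1), 1], and both the uncorrected and ε-corrected p are reported, the
corrected one being primary whenever ε < 1 and k > 2. Tukey pairwise
comparisons use the omnibus within-subject mean-square error with the
studentized-range distribution at df (k−1)(n−1) — one of several defensible
repeated-measures conventions, chosen for its direct tie to the omnibus
test.

**EEG–behavior coupling.** For a candidate window [t, 0] with
t ∈ [−3, −0.5] (the upper bound enforces the 500-ms minimum window), the
four per-outcome curves on each side are linearly interpolated at 100 points
spanning the window, concatenated in the fixed order (MATCH, NEAR_BEFORE,
NEAR_AFTER, FULL_AWAY) into 400-point vectors, and Pearson-correlated — one
r per subject against the single group behavioral curve set. The statistic
is |mean over subjects of r| (signs may cancel; this is *not* the mean of
absolute values). The reference search is a deterministic 10-ms lattice over
window starts (reproducible, immune to local optima); `grid+refine` polishes
the observed optimum with a bounded scalar minimizer and never returns less
than the lattice value. Exact ties resolve to the later window start.
Significance: each of N permutations independently shuffles the four outcome
labels within every subject's EEG curves (a shared-shuffle variant is
available), re-runs the full lattice search, and records the maximized
statistic; p = (1 + #{null ≥ observed}) / (1 + N), never exactly zero.
Re-running the maximization inside the null is what absorbs the selection
optimism of the data-driven window choice. An optional lag parameter shifts
the EEG time axis before the search (default 0). Internally, relabeled
correlations reuse one interpolation pass per lattice point via block
cross-products, making 10⁴ permutations tractable on one CPU.

## Numerical choices and degenerate inputs

- Window-membership and baseline masks use a 1-ns tolerance against float
  grid dust; event-log times are written rounded to 0.1 ms (exact on the
  50-ms grid).
- Zero-variance concatenations raise (undefined correlation); zero-variance
  single conditions yield NaN per-condition r and are dropped from
  per-outcome means.
- A flat signal in a component search window warns and takes the earliest
  sample; a paired t-test on constant nonzero differences raises.
- ε denominators ≤ 0 (e.g., rank-deficient covariance) fall back to ε = 1.

## The recovery fixture and identifiability

Window-start recovery is only a well-posed estimation problem when the
condition-discriminative variance of the coupled content is concentrated
inside the injected window rather than piled up at its end: for an
exact-copy injection (EEG = −behavior on [−1, 0]), the search objective at
window [t, 0] tracks the per-point pattern variance of the behavioral
curves over that window, so monotone saturating trajectories make every
sub-window of the injection as good as the whole and the "true" start
unidentifiable (with exact ties, the tie rule then returns −0.5). The
dedicated recovery fixture (`simulate_coupled_curves`) therefore injects
coupling using curves with the crossing geometry of the final deceleration
second — a `NEAR_AFTER` hump and `NEAR_BEFORE` dip centered near −0.85 s
with partial reconvergence at the stop — which peaks the pattern variance at
the injected boundary. Its default in-window noise (sd 0.05 on curves
spanning [0, 1]) is a moderate 5%-of-range distortion. The fixture is a
validation instrument for the search, labelled synthetic; it is not the
cohort generator.

## Known limitations

- The synthetic EEG noise is white; real EEG autocorrelation would widen the
  sampling variability of window means and correlations.
- The hazard choice model saturates near certainty, so simulated group
  curves separate more strongly at the stop than empirical ones.
- The Tukey error-term convention and the per-subject (vs shared) label
  shuffle are documented choices among defensible alternatives; both
  variants of the shuffle are implemented, only the error-term convention is
  fixed.
- Printed FRN/P3 measurement windows in the source literature are not all
  consistent with a single rounding rule; the peak ± 40 ms / round-to-10-ms
  rule reproduces the canonical 251 ms → 210–290 ms case and is applied
  uniformly.
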