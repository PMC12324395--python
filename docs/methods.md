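# Methods

This note documents the models and procedures implemented in `gridshift`,
the choices made where the design was genuinely open, and what the synthetic
generators and the scaled circuit model do and do not establish.

## Coordinates and containers

All track coordinates are centimetres from the track start.  Spatial bins
are half-open `[k·b, (k+1)·b)` and centres of mass (COMs) are reported at
bin centres — the activity-weighted mean `Σ v_i x_i / Σ v_i` over a field's
bins.  The universal input is a runs × bins matrix of non-negative
ΔF/F-like values per cell with per-run day labels; bins without data carry a
coverage mask (values stored as 0 but distinguishable from true zeros).
The default track is 1000 cm with eight landmark front edges at
100/220/340/460/580/700/800/863 cm and a reward span at 863–909 cm; the
track start and end count as landmarks ("anchors") throughout.

Every stochastic stage draws a named stream from one master seed
(`RngPolicy`), so a full re-run with the same seed reproduces every output
byte-for-byte.

## Run-by-run field tracking

**Stage 1 (detection).**  Per run, each bin's amplitude is compared against
1000 circular rotations of that run's trace, with offsets drawn uniformly
(with replacement) from [0.05 N, 0.95 N] samples.  A field is a maximal
block of ≥ 3 contiguous bins (≥ 2 at the track ends) with 1 − p ≥ 0.85.
Fields wider than the dataset's width cap (95 cm / 150 cm / unlimited for
the two recorded-data presets and the simulated preset) are dropped; runs
with fewer than 20 covered bins yield nothing.

**Stage 2 (consecutive runs).**  Each field links to the nearest next-run
field within d (28 / 32 / 10 cm by preset); ties break by larger bin
overlap, then smaller width, then no link; a next-run field claimed by
several predecessors keeps the one with the smallest COM distance, then
largest overlap, then smallest width, else links nobody.

**Stage 3 (gap bridging).**  Segments connect when the mean COM of one's
last ≤ 3 runs is within d (28 / 38 / 10 cm) of the mean COM of the other's
first ≤ 3 runs and the run gap is ≤ 7; conflicts resolve by most runs,
smallest gap, smallest track coverage (max COM − min COM), else no link.

**Stage 4 (trend merging).**  Fields whose COM-vs-run least-squares lines
mutually extrapolate onto each other within d (28 / 34 / 10 cm), with gap
≤ 7 and no run overlap, merge under the Stage-3 conflict ladder.  Only
fields with more than 8 runs survive.

*No-skip rule (package design choice).*  In Stages 3 and 4 a candidate is
disqualified when another qualified candidate ends before it starts.  Gap
bridging exists to cross missed-field runs; without this rule, COM jitter
produces near-tie distances that occasionally let a link jump over the true
continuation, splitting one trajectory into two interleaved chains that can
never merge (Stage 4 forbids run overlap).  With the rule, noiseless planted
fields are recovered exactly and 50/50 seeds recover a jittered, 20 %-missed
80-run field as a single chain.

Candidate processing is by ascending first-run index, greedily; boundary
points in close/far assignment belong to the bin nearer the back landmark;
"track coverage" is max COM − min COM.

**Day-level classification.**  Grid-cell tests run on 5-cm, run-averaged,
3-bin-Gaussian-smoothed traces: fields from the same rotation test at
1 − p ≥ 0.8 (the threshold is stated inconsistently in places as
1 − p ≤ 0.2; the prose reading ≥ 0.8 is implemented), ≥ 10 % of runs with a
transient in a field, ≥ 2 fields, more than L/(5w) in/out transitions,
widest field < 5w, ≥ 30 % of bins assigned, in/out mean ratio ≥ 2.  The cue
score correlates best-shift-aligned activity with a 0/1 landmark template
inside landmark zones (landmark ± half its width); constant traces are
assigned correlation 0 by convention; 200 location-randomised templates per
cell form the pooled shuffle distribution with an 80th-percentile cut.

## Shift statistics

The shift class compares a field's OLS slope (COM on global run index)
with the slopes of all circular rotations of its COM-sorted (descending)
run fields — run indices fixed.  Backward ⇔ slope ≤ 10th percentile
(linear-interpolation percentiles), forward ⇔ ≥ 90th.  An exhaustive
enumeration oracle checks the implementation for every field length ≤ 12.
Population fractions are tested against 100 within-field shuffles that
permute run fields inside each chain and re-run linking and classification.

Day fields (≥ 3 runs of one day) carry per-day slope, COM standard
deviation and adjacent-day centre distances; day-boundary events are
regressions (forward displacement) or progressions (backward), require the
earlier day field to reach its day's last run or the later to start at its
day's first run, and are significant when their magnitude strictly exceeds
the 85th (or dataset-scaled 70th) percentile of same-direction adjacent-run
shifts; the scaling is the printed-magnitude ratio rule,
85 × (9.503/10.984) = 73.539 ≈ 70.

The normal-distribution null for landmark crossing simulates 20 000
same-size samples from N(peak of the empirical 20 %-binned PDF, range/6) —
the ±3σ-covers-the-range rule.  On ~80 samples, range/6 understates the
sample σ by ~10 %, making extreme bins mildly anti-conservative; the test
suite calibrates the flagging machinery with fixed (μ, σ) for this reason.

The behaviour score is PL/100 + (PS/100 − 0.5)/0.52, clamped to [0, 1] for
reporting (division, not multiplication, reproduces a 0–1 score; the
printed formula is typographically ambiguous).  The good-performer
thresholds are PL = 22.2 % and PS = 65.7th percentile.

## Population phase

Per-cell spectra: Welch periodogram on the 1000-sample (1-cm-binned)
day-averaged trace, Hamming window 512, transform length 2992, overlap 461,
rate 1000; the spectrum is linearly detrended over 0.001–0.150 cycles/cm
and the three largest strict local maxima above 0.006 cycles/cm give
f1 < f2 < f3.  A module qualifies with > 10 cells and
|avg f1 + avg f2 − avg f3| < 0.08 · avg f3.

Phases are the angles of the 2992-point FFT — evaluated for every cell *at
the module-averaged peak frequencies* rather than each cell's own peak
bins.  Co-modular cells share the slice frequencies exactly; a single cell
straddling a neighbouring FFT bin otherwise contributes a ~1-rad phase
inconsistency (one grid step × half the trace length) that corrupts the
population circular mean.  Recovered phases match planted generator offsets
up to one global constant per component (the off-grid leakage term), which
is the natural tolerance of the method.

The population trajectory is Ψ_k(x) = atan2(Σ_i sin φ_ki r_i(x),
Σ_i cos φ_ki r_i(x)) for k = 1, 2, unwrapped along the track; bins with a
vanishing resultant carry the previous value and are flagged out of jump
statistics.  Distances between trajectories are mean same-position
Euclidean distances in sheared coordinates (Ψ1′ = Ψ1 + Ψ2/2,
Ψ2′ = (√3/2) Ψ2) after correcting whole 2π offsets of the starting points;
rotation removes each trajectory's own start first; lateral shift is the
corrected start distance normalised by the module mean.  Rotation and
lateral shift also use sheared coordinates (the shearing is defined once
for the distance; it is applied consistently).  Phase jumps are sheared
distances between adjacent 1-cm points, classified within/between
symmetric landmark expansions (35 cm for the recorded-data preset, 5 cm for
synthetic/model data), excluding 10 cm at the track ends and the reward
span; the influence index is each run's within-landmark mean minus the
run-averaged between-landmark mean.

## Synthetic data

`generate_cell` plants Gaussian bumps (σ = width/4, so three adjacent
2.5-cm bins clear the rotation null at the stated thresholds) whose COM
drifts linearly (cm/run), decays to zero within an arrest half-width of an
anchor landmark, jitters per run, disappears with a per-run miss
probability, and resets forward at day boundaries.  Noise is i.i.d.
truncated-at-zero Gaussian per bin.

`generate_module` builds co-modular cells as 1D slices of one triangular
lattice: rate_i(x) ∝ 1 + mean_j cos(2π f_j x + D_j(day, x) + φ_ij) with
φ_i3 = φ_i1 + φ_i2, so f3 = f1 + f2 exactly.  Defaults: 80-cm lattice
period and a 0.26-rad slice angle, keeping f1 and f2 resolvable by the
512-sample Welch window while all three frequencies clear the 0.006
cycles/cm floor.  Phase offsets default to an exact p × q product grid over
the rhombus (randomly translated): a uniform product grid cancels every
finite-population cross term of the rate-weighted circular mean, so the
recovered trajectory is unbiased.  Population drifts, per-day rotations and
planted discontinuities are shared by all cells, and the ground truth
records the planted trajectory in the estimator's own convention
(Ψ_k ≈ −(2π f_k x + D_k)).

Module noise is spatially correlated (Gaussian kernel, 3-cm correlation
length, SD preserved) rather than i.i.d. per 1-cm bin: calcium-indicator
dynamics smear noise over centimetres of track at running speed, and
i.i.d. 1-cm noise both misrepresents that and drowns single-bin phase
discontinuities that the fragmentation analysis targets.

What passing synthetic tests do *not* show: the generators emulate drift,
arrest, misses, jitter, coherent phase dynamics and landmark jumps, but not
calcium-transient kinetics, speed modulation, behavioural variability or
cross-day registration error, so recovery rates here bound performance on
ideal data only.

## Circuit model

The grid module is an n × n continuous-attractor sheet (full scale n = 128;
scaled preset n = 48) with four interleaved direction-preference groups,
purely inhibitory difference-of-Gaussians recurrence (β = 3/λ², γ = 1.05 β,
λ = 13 neurons, kernel amplitude 4, outgoing kernels displaced ℓ = 2
neurons along each group's preferred direction) and feedforward drive
B = A(1 + ê_i · v).  Initialisation runs 250 aperiodic steps (zero-padded
convolution, tapering envelope) then 250 periodic steps with a small
unidirectional velocity, settles 60 zero-velocity steps, applies a random
translation (the envelope pins where the lattice nucleates, so the
translation supplies the random per-experiment grid phase), and
re-nucleates from a fresh random state if six-fold symmetry stays below
threshold (a metastable defected lattice forms occasionally).  The
four-group convolution is computed with a single FFT: the 2 × 2 preference
masks are checkerboard characters, i.e. frequency translations by n/2.

Track velocity is uniform (track length / steps per run); the sheet
velocity is that velocity rotated by a per-experiment angle and scaled by a
gain of 0.09 sheet units per cm, calibrated so the pattern translates
~0.108 neurons/cm (one lattice period per ~120 cm of track).  On the scaled
sheet the rotation is drawn as a random lattice sextant plus a fixed
0.26-rad offset from the measured lattice axis — a slice near a lattice
axis degenerates the 1D tuning on a small sheet; the full preset keeps the
fully random angle.  Gaussian noise enters the velocity input (0.15
cm/step, ≈ 0.6 % of track length per run after integration) and the sensory
vectors (SD 0.1).

The hippocampal layer (N_H = 2000 full, 500 scaled) is h = ReLU(W_HG g + b)
with fixed Gaussian W_HG; b is set once at initialisation to the negative
85th percentile of the drive, giving ~15 % activation.  Every 20th step the
grid state receives the hippocampal correction.  The correction is a blend,
g ← (1 − γ_h) g + γ_h ReLU(W_GH h), γ_h = 0.5, followed by relaxation —
full replacement is runaway-unstable in continuous operation because the
learned map intrinsically advances the phase by the delay distance.
W_GH learns by online pseudoinverse (recursive least squares, inverse
correlation initialised at 100·I, kept in float64 and symmetrised
periodically) associating h(t − τ) with g(t), τ = 16 steps by default.
Hippocampal states are computed at the steps where they are consumed (the
schedule steps and their τ-lagged partners, plus sensory events, which use
the most recent state at lag ≥ τ); computing the projection every step
would dominate runtime without changing the dynamics.

Sensory events fire at landmark crossings regardless of the 20-step
schedule.  Cue vectors are fixed random (alternating left/right
populations; boundaries drive both strongly); W_HS heteroassociation is
novelty-gated — an unlearned cue is imprinted one-shot, after which the
association chases the arriving hippocampal state slowly (rate 0.05) —
and landmark corrections blend with γ_s = 0.1.  The track boundaries are
treated as strong pattern-completing inputs: the sheet state at the first
crossing is cached and re-anchors the sheet (γ = 0.9 blend plus
relaxation) on every later run, absorbing the phase slip of the VR teleport
(the track length is generically incommensurate with the grid period, so
uncorrected teleports masquerade as a systematic per-run field shift).
Plasticity (RLS and W_HS updates) also runs at sensory-event
hippocampus-to-grid updates.  Consolidation keeps end-of-run snapshots of
(W_GH, P); at each day boundary the fast weights reset to the snapshot
τ_C runs back — 4 runs at full scale (16-run days), 1 run in the scaled
preset (4-run days), preserving the 1:4 ratio of rollback to day length.
The no-plasticity control freezes all learning in the novel environment,
including first-visit imprints.

**Mechanism.**  The delayed association makes the learned map output the
grid state from τ steps ahead of its input: applied to the current state it
advances the phase, which expresses as a backward shift of fields on the
track; the advance measured from a trained map is 1.17 neurons against the
κ·v·τ prediction of 1.15, and per-run applied corrections grow with τ
(19/24/32 neurons for τ = 4/16/32).  Cumulative cross-run drift flows from
the 1/t creep of the non-forgetting RLS memory and the slow migration of
the sensory anchors, so it decelerates over learning; the consolidation
rollback produces forward day-boundary resets.

**Scaled preset.**  48 × 48 sheet, 500 hippocampal and 100 sensory cells,
1500 steps/run, 4 runs/day × 8 days, 4 pretraining runs, relaxation 10
steps.  These sizes keep a five-seed, four-condition replication study
within ordinary desktop budgets; the full preset retains the study-scale
values (128 × 128, 2000/200, 5000 steps/run, the 161-run/10-day schedule,
20 pretraining runs, τ_C = 4).

## Position decoding

The KVM decoder stores (population vector, position) pairs from a training
block and recalls by dot-product similarity (cosine available) under a
β = 1000 softmax — an argmax, with exact ties resolved to the smaller
position — restricted to keys whose position lies within 300 cm of the
ground truth.  Model evaluations slide every 5 trials with 10-trial train
and test blocks (10⁴ training samples at 1-cm resolution); the decoder
population is a 120-cell subsample chosen by farthest-point sampling on the
(φ1, φ2) torus, or an even sheet subgrid for model data.  All test
positions enter the MAE, including any whose best global match was gated
out.

## Known limitations

* The scaled circuit model reproduces the qualitative core — backward-field
  enrichment above the within-field shuffle baseline under delayed
  plasticity, near-chance fractions in the frozen control, regression
  events outnumbering progressions, and monotone weight-norm growth — but
  its seed-to-seed variability is large: the 48-neuron sheet holds only
  ~3.7 lattice periods, so pursuit dynamics between the drifting map, the
  anchors and the phase occasionally destabilise individual runs.  The
  influence-index growth over days, the decoding advantage of the plastic
  model over the frozen control, and a clean τ-ordering of backward-slope
  magnitudes did not replicate reliably at this scale and are reported as
  computed, not asserted.
* The rotation-bootstrap classifier over-labels random-walk COM
  trajectories as trending (shuffling destroys autocorrelation), which
  inflates both backward and forward fractions in any drifting control.
* The Welch/FFT phase extraction is limited by the 2992-point frequency
  grid; phases are only defined up to a global per-component constant, and
  all comparisons respect that.
* Group-level hypothesis testing (Mann-Whitney, ANOVA, etc.) is left to
  standard libraries at call sites; this package computes the quantities.
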