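# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `vwmlab`.

## Feature space and circular conventions

All three stimulus domains (orientation, color, luminance) are mapped
onto a single circle spanning 180 units, so the maximal distance
between two values is 90 and a "nonmatch" probe offset of 90 is
maximally dissimilar in every domain. For von Mises sampling and
density evaluation, signed errors are doubled onto the full 360° circle
and halved back — the standard convention for orientation-like spaces.
Consequences worth keeping in mind:

* κ is a concentration **on the doubled circle**; a κ of 12 corresponds
  to a circular SD of about 12° in the 180-unit response space.
* All densities are expressed per degree of the doubled circle, so the
  uniform component has density 1/360 and log-likelihoods are
  comparable across models and trial types.
* Luminance is generated and scored circularly like the other domains;
  a linear (reflecting) treatment would change errors near the
  endpoints of the luminance ramp and is deliberately not the default.

## Mixture model

The recall density is
`pT·VM(2Δt; κ) + (pN/m)·Σj VM(2Δj; κ) + pU/360`, with Δt the signed
error to the target, Δj to nontarget j, and m the number of nontargets.
Swap mass is split equally over nontargets. Trial types without
nontargets force pN = 0 (a swap is undefined there).

Fitting is maximum likelihood with the weights parameterized by a
softmax (the simplex constraint is exact, no penalty terms) and κ in
log space, optimized by L-BFGS-B from 20 seeded restarts plus one
moment-based start (κ initialized from the circular resultant of the
doubled errors). `log I0(κ)` uses the exponentially scaled Bessel
function, so the likelihood stays finite up to the κ bound of 10⁴;
solutions at that bound (e.g. error-free data) are flagged
`converged=False` rather than rejected. Standard errors come from a
finite-difference Hessian in the unconstrained parameterization,
delta-method-transformed to (pT, pN, pU, κ); they are advisory and NaN
when the Hessian is not invertible.

## TCC and TCC plus

The similarity function is estimated per domain as the per-offset mean
of (rating − 1)/6 over the sampled offset grid (14 offsets per domain),
linearly interpolated, with each domain's largest sampled offset mapped
to the maximal response-space distance of 90. An optional decreasing
isotonic regression is available and off by default — the raw mean is
what the normalization formula prescribes.

The response distribution is the max-signal race with independent
unit-variance channel noise over m = 180 channels (the response-wheel
resolution): `P(x) = ∫ φ(z − d′f_x) Π_{y≠x} Φ(z − d′f_y) dz`,
evaluated with a 401-point trapezoid rule over z ∈ [−8, 8 + d′]. The
quadrature is validated in the test suite against a direct Monte-Carlo
simulation of the race (5×10⁶ draws; the acceptance script recomputes
this check). A computed pmf whose mass deviates from 1 by more than
10⁻⁶ raises instead of being silently renormalized.

TCC plus mixes races centred on the target and on each nontarget:
`(1 − pSwap)·pmf(target) + pSwap·mean_j pmf(nontarget_j)`, with (d′,
pSwap) fitted jointly by bounded L-BFGS-B from three fixed starts.
d′ is bounded to [0, 6]; fits at a bound, and fits on trials whose
nontargets coincide with the target (pSwap unidentifiable), are flagged
non-converged. Responses are assigned to channels by rounding the
signed circular error to the nearest channel width.

## ERP pipeline

Windows are fixed relative to sample-array onset: baseline −0.20–0 s,
sample 0.20–0.70 s, delay 0.95–1.60 s. The delay window is 200 ms after
sample offset (0.75 s) through 50 ms before probe onset (1.65 s) —
650 ms long. Threshold comparisons in both artifact detectors are
strict (`>`): a trial at exactly 100 μV or a half-window difference of
exactly 20 μV survives.

The HEOG detector slides a 200 ms window in 20 ms steps and flags a
trial when |mean(second half) − mean(first half)| > 20 μV; with
cumulative sums each window is O(1), so a 1,000-trial set screens in
milliseconds. Subject exclusion counts surviving epochs per trial type
and removes subjects below 75 in any type they performed.

Lateralization averages the posterior cluster of each hemisphere
(midline and non-cluster channels never contribute), assigns
contra/ipsi per trial from the cued side, then averages trials within
subject × condition × load. Cells with zero surviving trials are
missing, not zero. Reductions are accumulated in float64 even when
epochs are stored as float32, which keeps the noiseless
injection-recovery exact at the 1e-9 μV level.

Band-pass filtering (zero-phase Butterworth, 0.1–30 Hz) and polyphase
downsampling are provided but skipped by default: the generator already
produces 250 Hz data. Bad-channel interpolation is a validating no-op
hook — spherical-spline interpolation needs electrode geometry the
synthetic montage does not define. ICA-based ocular/muscle cleanup is
out of scope; the amplitude and HEOG detectors are the artifact path.

## Repeated-measures ANOVA

`rm_anova` implements the classical univariate within-subject
partition for balanced fully-crossed designs by inclusion–exclusion
over cell means; every effect is tested against its interaction with
subjects. It is algebraically exact for balanced designs (the test
suite checks it against statsmodels' `AnovaRM` to 1e-8 and against a
hand-expanded small design) and fast enough for null-calibration runs
of thousands of replicates. Unbalanced data raise — there is no
imputation. No sphericity correction is applied by default;
Greenhouse–Geisser (double-centred covariance epsilon, checked against
pingouin) sits behind `correction=True`. Post hoc paired t tests are
uncorrected by default.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated. All draws come from named, seed-derived substreams:
identical configurations are bit-reproducible, and every latent
variable (memory state, mixture component, artifact event) is recorded.

**Recognition.** The discrete-slot account behind Cowan's k: the probed
item is in memory with probability min(k/load, 1); in-memory probes are
answered correctly, otherwise the subject guesses "match" with
probability 0.5. Hit − FA then equals the in-memory probability
regardless of guess bias, so k̂ recovers min(k, load). Defaults:
capacity 2.2 (homogeneous) vs 3.0 (heterogeneous) items with a 0.3-item
between-subject SD, mirroring a capacity cost of higher context-binding
demand. Match/nonmatch and cue side are exactly balanced per cell, and
each one-item heterogeneous probe domain (1O/1C/1L) receives a full
trial complement, as the blocked design requires. RTs are lognormal
(a generative convenience; no RT model is claimed).

**Recall.** Responses are drawn from the mixture model itself (3O truth
pT = 0.7, pN = 0.15, pU = 0.15, κ = 12 by default; one-item types fold
the swap mass into guessing). This makes mixture fitting a genuine
recovery problem and TCC fitting a mis-specified-model problem — which
is the realistic situation.

**Likert.** `rating = clip(round(1 + 6·exp(−offset/20°) + ε), 1, 7)`
with ε ~ N(0, 0.8) rating units and each domain's printed offset set.
The exponential scale of 20 scaled degrees gives similarity functions
with the familiar convex decay; zero offsets rate 7 and maximal offsets
rate 1 modally, as instructed raters do.

**EEG.** Epochs span −1.5–2.5 s around sample onset at 250 Hz over a
29-channel montage whose lateralized clusters are the twelve posterior
electrode pairs (TP7/8 … O1/2). The delay-active component is a boxcar
from sample onset to probe onset: contralateral cluster channels
receive `cda_amp_by_load[load]` (default −0.5/−1.5/−1.5 μV for loads
1/3/5 — amplitude grows with load and saturates at the capacity of ~3
items, enforced at construction), and homogeneous-condition trials add
−1 μV to **both** hemisphere clusters. A per-subject multiplicative
gain (SD 0.2) provides between-subject variability. Noise is an
equal-power mix of white and 1/f-shaped noise at 10 μV per channel,
with the 1/f spectrum flattened below 2 Hz — emulating recordings after
high-pass filtering, and keeping single-trial window means in the
regime where injection-recovery tolerances of a few tenths of a μV at
a few hundred trials are meaningful. Saccades are ±40 μV steps on the
HEOG channel held to epoch end (5% of trials; HEOG carries its own
5 μV white noise), blinks are 150 μV Gaussian transients on the frontal
channels (5%).

What the generator does **not** emulate: volume conduction and
topographies (artifacts are confined to their nominal channels, so ICA
has nothing to find), alpha rhythms and event-related spectral
perturbations, slow drifts, RT–accuracy coupling, serial dependencies,
and any calibrated correspondence to the human dataset's noise levels
or effect sizes. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under its stated assumptions — not
that real data of this size would yield equally tight estimates.

## Problem sizes

The default synthetic study uses 10 subjects × 100 trials per
subject × condition × load cell (one-item heterogeneous cells: 100 per
probe domain), mixture/TCC recovery studies use 20 replicates of
1,500–2,000 trials, the Monte-Carlo race oracle uses 5×10⁶ draws, and
ANOVA calibration uses 2,000 null replicates — sizes at which the
recovery tolerances asserted in the test suite are comfortably inside
the sampling error of the checks themselves.

## Known limitations

* κ's interpretation is tied to the doubled-circle convention; compare
  with other toolboxes only after matching conventions.
* The TCC variant is the simplest published form (independent channel
  noise); correlated-noise channel models are out of scope.
* Similarity beyond each domain's sampled offset range relies on the
  maximal-offset value (interpolation is clamped to [0, 1]).
* `rm_anova` is for balanced designs only, by design.
* The EDF export hook requires an mne EDF backend and raises a clear
  error without one; the binary-plus-JSON epoch store is the native
  format.
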