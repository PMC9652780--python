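# vwmlab

Analysis toolkit for lateralized visual-working-memory (VWM) experiments:
behavioral capacity estimation, model-based decomposition of continuous
recall, and the EEG pipeline that extracts the contralateral delay
activity (CDA). A matched synthetic-data generator with full ground-truth
bookkeeping makes every stage verifiable by parameter recovery, so the
pipeline can be tested end to end without access to raw human data.

It is intended for cognitive-neuroscience researchers analyzing
delayed-recognition (change detection) and delayed-estimation (recall)
tasks with concurrent EEG.

## What it computes

**Capacity (Cowan's k).** For change detection at set size *N*,

    k = N · (hit rate − false-alarm rate)

with hits defined on nonmatch trials and false alarms as "nonmatch"
responses on match trials.

**Mixture model of recall.** Continuous responses on a 180°-periodic
feature space are decomposed by maximum likelihood into target recall
(probability *pT*, von Mises precision κ on the doubled circle),
nontarget "swap" responses (*pN*, 3-item trials only) and uniform
guessing (*pU* = 1 − *pT* − *pN*):

    p(x) = pT·VM(2Δ_t; κ) + (pN/m)·Σ_j VM(2Δ_j; κ) + pU/360

**TCC model.** The target confusability competition model treats every
response-wheel value as a signal-detection channel with familiarity
d′·f(Δ) plus unit-variance noise, where f is a psychophysical similarity
function measured with 1–7 Likert ratings and normalized as
f = (S − 1)/(7 − 1); the response is the channel with the maximal
signal. "TCC plus" adds a swap component with probability *pSwap*.

**CDA pipeline.** Epoched EEG → baseline correction (−200–0 ms) →
rejection of trials exceeding 100 μV → split-half sliding-window HEOG
saccade rejection (200 ms window, 20 ms step, 20 μV threshold) →
exclusion of subjects with <75 surviving epochs in any trial type →
hemisphere-cluster averaging into contralateral and ipsilateral signals
relative to the cued hemifield → window means over the
sample-presentation (0.20–0.70 s) and delay (0.95–1.60 s) windows. The
contra − ipsi difference over the delay window is the CDA.

**Statistics.** Balanced within-subject repeated-measures ANOVA (any
number of factors, Greenhouse–Geisser optional), paired t tests, and a
Wilcoxon signed-rank test for skewed swap-rate distributions.

## Worked example

Fit the mixture and TCC-plus models to synthetic 3-item recall data
whose generative truth is pT = 0.70, pN = 0.15, pU = 0.15, κ = 12,
then refit the same trials with TCC plus (generated swaps appear as
pSwap):

```python
from vwmlab.config import GenConfig, MixtureTruth
from vwmlab.synth import gen_recall_trials, gen_likert_trials
from vwmlab.mixture import MixtureModel
from vwmlab.tcc import estimate_similarity, TCCPlusModel

cfg = GenConfig(seed=7, n_subjects=1,
                mixture_truth=MixtureTruth(pT=0.7, pN=0.15, pU=0.15, kappa=12.0))
trials = gen_recall_trials(cfg, trial_types=["3O"], trials_per_type=1500)
print(MixtureModel(trials, n_components=3).fit(restarts=20, seed=0).summary())

sim = estimate_similarity(
    gen_likert_trials(GenConfig(seed=42, n_subjects=5), "orientation"))
print(TCCPlusModel(trials, sim).fit().summary())
```

prints

```
Mixture model of delayed-estimation responses
  components: 3   trials: 1500
  log-likelihood: -7576.134   converged: True
  restarts used: 20
  parameter   estimate      se
  pT            0.6989  0.0144
  pN            0.1705  0.0135
  pU            0.1306  0.0140
  kappa        11.5848  0.6175

TCC plus model of delayed-estimation responses
  trials: 1500   log-likelihood: -6610.273   converged: True
  d'          2.0006
  pSwap       0.1758
```

The mixture estimates sit within sampling error of the generative truth
(p̂T = 0.699 vs 0.70, κ̂ = 11.6 vs 12), and the TCC-plus swap estimate
(0.176) tracks the injected 15% swap rate plus the share of guesses
that happen to land near a nontarget.

The full synthetic study — capacity, EEG pipeline, model fits and the
factorial statistics — runs end to end with

```
vwmlab report --out report/ --seed 11
```

which writes TSV tables plus a markdown summary recording whether the
qualitative signature of the design is reproduced: a homogeneity effect
present in both contralateral and ipsilateral delay-period signals that
cancels in the CDA difference wave, alongside a load effect that
survives the subtraction.

Other CLI entry points: `vwmlab simulate`, `vwmlab behavior`,
`vwmlab fit-mixture`, `vwmlab fit-tcc`, `vwmlab cda`.

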