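"""Synthetic-data generator: ground-truth structure and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import quiet_eeg
from vwmlab.behavior import recognition_summary
from vwmlab.config import GenConfig, MixtureTruth, TrialTimingSpec
from vwmlab.erp import baseline_correct, lateralize, window_means
from vwmlab.synth import (
    gen_eeg_epochs,
    gen_likert_trials,
    gen_recall_trials,
    gen_recognition_trials,
)


# ---------- recognition ----------


def test_recognition_capacity_expectations():
    # load 1 with ample capacity: probed item always in memory -> k = 1
    cfg = GenConfig(seed=1, n_subjects=1, trials_per_cell=400,
                    capacity_k=3.0, capacity_subject_sd=0.0)
    k = recognition_summary(
        gen_recognition_trials(cfg, loads=[1]), orientation_probes_only=False
    )
    assert np.allclose(k["k"], 1.0)
    # zero capacity: hit = fa = guess rate -> k near 0
    cfg0 = GenConfig(seed=2, n_subjects=1, trials_per_cell=4000,
                     capacity_k=0.0, capacity_subject_sd=0.0)
    k0 = recognition_summary(
        gen_recognition_trials(cfg0, loads=[3]), orientation_probes_only=False
    )
    assert np.abs(k0["k"]).max() < 0.3


def test_recognition_monte_carlo_capacity_recovery():
    cfg = GenConfig(seed=1, n_subjects=1, trials_per_cell=20_000,
                    capacity_k=2.5, capacity_subject_sd=0.0)
    trials = gen_recognition_trials(cfg, loads=[5])
    k = recognition_summary(trials, orientation_probes_only=False)
    est = k.loc[k["condition"] == "homogeneous", "k"].iloc[0]
    assert abs(est - 2.5) < 0.1


def test_recognition_capacity_recovery_unbiased():
    """k-hat bias over 20 replicate datasets stays below 0.05 items."""
    ests = []
    for rep in range(20):
        cfg = GenConfig(seed=100 + rep, n_subjects=1, trials_per_cell=20_000,
                        capacity_k=2.5, capacity_subject_sd=0.0)
        k = recognition_summary(
            gen_recognition_trials(cfg, loads=[5]), orientation_probes_only=False
        )
        ests.append(k.loc[k["condition"] == "homogeneous", "k"].iloc[0])
    assert abs(np.mean(ests) - 2.5) < 0.05


def test_recognition_balance_and_errors():
    cfg = GenConfig(seed=3, n_subjects=2, trials_per_cell=8)
    tr = gen_recognition_trials(cfg)
    counts = tr.groupby(["subject", "condition", "load"])["is_match"].mean()
    assert np.allclose(counts, 0.5)
    cue = tr.groupby(["subject", "condition", "load"])["cue_side"].apply(
        lambda s: (s == "left").mean()
    )
    assert np.allclose(cue, 0.5)
    with pytest.raises(ValueError):
        gen_recognition_trials(GenConfig(seed=0, trials_per_cell=7))
    with pytest.raises(ValueError):
        gen_recognition_trials(cfg, loads=[2])


def test_load1_accuracy_at_least_load5():
    cfg = GenConfig(seed=4, n_subjects=3, trials_per_cell=400)
    tr = gen_recognition_trials(cfg)
    correct = (tr["is_match"] == (tr["response"] == "match")).astype(float)
    acc = correct.groupby([tr["subject"], tr["load"]]).mean().unstack()
    assert (acc[1] >= acc[5]).all()


# ---------- recall ----------


def test_recall_noiseless_target_component():
    truth = MixtureTruth(pT=1.0, pN=0.0, pU=0.0, kappa=1e4)
    cfg = GenConfig(seed=5, n_subjects=1, mixture_truth_by_type={"1O": truth})
    tr = gen_recall_trials(cfg, trial_types=["1O"], trials_per_type=200)
    err = np.abs(
        (tr["response_deg"] - tr["target_deg"] + 90) % 180 - 90
    )
    assert (err < 2.0).all()


def test_recall_uniform_component_gof():
    truth = MixtureTruth(pT=0.0, pN=0.0, pU=1.0, kappa=5.0)
    cfg = GenConfig(seed=6, n_subjects=1, mixture_truth_by_type={"1O": truth})
    tr = gen_recall_trials(cfg, trial_types=["1O"], trials_per_type=10_000)
    hist, _ = np.histogram(tr["response_deg"], bins=18, range=(0, 180))
    p = stats.chisquare(hist).pvalue
    assert p > 0.01


def test_recall_component_frequencies():
    truth = MixtureTruth(pT=0.7, pN=0.15, pU=0.15, kappa=12.0)
    cfg = GenConfig(seed=7, n_subjects=1, mixture_truth=truth)
    tr = gen_recall_trials(cfg, trial_types=["3O"], trials_per_type=5000)
    freq = tr["truth_component"].value_counts(normalize=True)
    assert abs(freq["target"] - 0.7) < 0.02
    assert abs(freq["nontarget"] - 0.15) < 0.02
    assert abs(freq["uniform"] - 0.15) < 0.02


def test_recall_swaps_forbidden_without_nontargets():
    cfg = GenConfig(
        seed=8, n_subjects=1,
        mixture_truth_by_type={"1O": None},
    )
    cfg.mixture_truth_by_type = {
        "1O": MixtureTruth(pT=0.7, pN=0.15, pU=0.15, kappa=12.0)
    }
    with pytest.raises(ValueError, match="pN"):
        gen_recall_trials(cfg, trial_types=["1O"], trials_per_type=50)


# ---------- Likert ----------


def test_likert_endpoints_and_monotonicity():
    cfg = GenConfig(seed=9, n_subjects=1, likert_noise_sd=0.0)
    for domain in ("orientation", "color", "luminance"):
        lik = gen_likert_trials(cfg, domain)
        by_offset = lik.groupby("offset")["rating"].mean()
        assert by_offset.iloc[0] == 7  # identical stimuli
        assert by_offset.iloc[-1] == 1  # maximally dissimilar
    with pytest.raises(ValueError):
        gen_likert_trials(cfg, "pitch")


def test_likert_mean_rating_decreasing_with_offset():
    cfg = GenConfig(seed=10, n_subjects=5, similarity_scale=20.0)
    lik = gen_likert_trials(cfg, "orientation", reps_per_offset=100)
    means = lik.groupby("offset")["rating"].mean()
    sub = means.loc[[0.0, 20.0, 90.0]].to_numpy()
    assert sub[0] > sub[1] > sub[2]


# ---------- EEG ----------


def test_eeg_noiseless_cda_injection_exact():
    cfg = GenConfig(
        seed=11, n_subjects=1, trials_per_cell=4,
        eeg=quiet_eeg(cda_amp_by_load={1: -1.0, 3: -1.0, 5: -1.0},
                      bilateral_effect_amp=0.0),
    )
    ep = gen_eeg_epochs(cfg)
    wm = window_means(lateralize(baseline_correct(ep)))
    delay = wm[wm["window"] == "delay"]
    assert np.allclose(delay["diff_mean"], -1.0, atol=1e-9)


def test_eeg_bilateral_component_cancels():
    cfg = GenConfig(
        seed=12, n_subjects=1, trials_per_cell=4,
        eeg=quiet_eeg(cda_amp_by_load={1: 0.0, 3: 0.0, 5: 0.0},
                      bilateral_effect_amp=-1.0),
    )
    wm = window_means(lateralize(baseline_correct(gen_eeg_epochs(cfg))))
    delay = wm[wm["window"] == "delay"]
    homo = delay[delay["condition"] == "homogeneous"]
    assert np.allclose(homo["contra_mean"], -1.0, atol=1e-9)
    assert np.allclose(homo["ipsi_mean"], -1.0, atol=1e-9)
    assert np.allclose(delay["diff_mean"], 0.0, atol=1e-9)


def test_eeg_saccade_annotation_rate():
    cfg = GenConfig(
        seed=13, n_subjects=1, trials_per_cell=334,  # 1,000+ trials over 3 loads
        eeg=quiet_eeg(saccade_rate=0.1),
    )
    ep = gen_eeg_epochs(cfg, trials=gen_recognition_trials(cfg, loads=[1]).iloc[:1000])
    frac = ep.annotations["saccade"].mean()
    assert abs(frac - 0.1) < 0.02


def test_eeg_epoch_window_must_cover_trial():
    cfg = GenConfig(seed=14, n_subjects=1, trials_per_cell=2)
    timing = TrialTimingSpec(epoch_window=(-0.5, 1.0))
    with pytest.raises(ValueError, match="epoch window"):
        gen_eeg_epochs(cfg, timing=timing)


def test_identical_seeds_reproduce_different_seeds_differ():
    cfg_a = GenConfig(seed=15, n_subjects=1, trials_per_cell=4)
    cfg_b = GenConfig(seed=15, n_subjects=1, trials_per_cell=4)
    cfg_c = GenConfig(seed=16, n_subjects=1, trials_per_cell=4)
    ta, tb, tc = (gen_recall_trials(c, trials_per_type=30) for c in (cfg_a, cfg_b, cfg_c))
    pd.testing.assert_frame_equal(ta, tb)
    assert not ta["response_deg"].equals(tc["response_deg"])
    ea = gen_eeg_epochs(cfg_a)
    eb = gen_eeg_epochs(cfg_b)
    ec = gen_eeg_epochs(cfg_c)
    assert np.array_equal(ea.data, eb.data)
    assert not np.array_equal(ea.data, ec.data)
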