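"""ERP pipeline: baseline, artifact rejection, lateralization, window means."""

import numpy as np
import pandas as pd
import pytest

from conftest import quiet_eeg
from vwmlab.config import GenConfig
from vwmlab.erp import (
    EpochSet,
    WindowSpec,
    baseline_correct,
    detect_heog_steps,
    exclude_low_trial_subjects,
    interpolate_bad_channels,
    lateralize,
    reject_amplitude,
    window_means,
)
from vwmlab.synth import gen_eeg_epochs, gen_recognition_trials


def make_epochs(data, cue_sides=None, sfreq=250.0, t0=-1.5):
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, _ = data.shape
    assert n_ch == 3  # left, right, heog
    meta = pd.DataFrame(
        {
            "subject": np.zeros(n_trials, dtype=int),
            "condition": ["homogeneous"] * n_trials,
            "load": np.ones(n_trials, dtype=int),
            "cue_side": cue_sides if cue_sides is not None else ["left"] * n_trials,
            "trial_type": ["1O"] * n_trials,
        }
    )
    return EpochSet(
        data=data, sfreq=sfreq, t0=t0,
        ch_names=["L1", "R1", "HEOG"], ch_side=["left", "right", "eog"],
        cluster_mask=np.array([True, True, False]), heog_ch="HEOG", meta=meta,
    )


def test_baseline_constant_trace_zeroed():
    ep = make_epochs(np.full((2, 3, 1000), 5.0))
    out = baseline_correct(ep)
    assert np.allclose(out.data, 0.0, atol=1e-9)


def test_baseline_step_trace():
    data = np.full((1, 3, 1000), 7.0)
    idx_pre = np.arange(1000)[(np.arange(1000) / 250.0 - 1.5) < 0]
    data[:, :, idx_pre] = 2.0
    out = baseline_correct(make_epochs(data))
    post = out.data[0, 0, (np.arange(1000) / 250.0 - 1.5) >= 0]
    assert np.allclose(post, 5.0, atol=1e-9)


def test_baseline_means_vanish_on_random_epochs():
    rng = np.random.default_rng(0)
    ep = make_epochs(rng.normal(0, 10, (5, 3, 1000)))
    out = baseline_correct(ep)
    idx = out.window_index(WindowSpec("baseline", -0.2, 0.0))
    assert np.abs(out.data[:, :, idx].mean(axis=2)).max() < 1e-9


def test_amplitude_rejection_strict_threshold():
    data = np.zeros((3, 3, 1000))
    data[0, 1, 500] = 150.0  # blink-like spike
    data[1, 0, 400] = 99.9  # below threshold
    data[2, 2, 300] = -100.0  # exactly at threshold: "exceeding" is strict
    mask = reject_amplitude(make_epochs(data), threshold=100.0)
    assert mask.tolist() == [True, False, False]


def test_heog_step_detection_cases():
    sfreq = 250.0
    n = 1000
    heog = np.zeros((3, n))
    heog[0, 600:] = 30.0  # detectable step
    heog[1, 600:] = 15.0  # below threshold
    mask = detect_heog_steps(heog, sfreq)
    assert mask.tolist() == [True, False, False]


def test_heog_step_maximal_window_centred_on_step():
    """The largest half-difference occurs for the window split at the step."""
    sfreq, n = 250.0, 1000
    heog = np.zeros((1, n))
    step_at = 615  # aligned with a window split (step size 5 samples)
    heog[0, step_at:] = 30.0
    half = int(0.2 * sfreq / 2)
    starts = np.arange(0, n - 2 * half + 1, max(int(0.02 * sfreq), 1))
    diffs = [
        heog[0, s + half:s + 2 * half].mean() - heog[0, s:s + half].mean()
        for s in starts
    ]
    best = starts[int(np.argmax(np.abs(diffs)))]
    assert abs((best + half) - step_at) <= int(0.02 * sfreq)
    assert np.max(np.abs(diffs)) == pytest.approx(30.0, abs=1e-9)


def test_heog_epoch_shorter_than_window_errors():
    with pytest.raises(ValueError):
        detect_heog_steps(np.zeros((1, 30)), sfreq=250.0)


def test_subject_exclusion_boundary():
    meta = pd.DataFrame(
        {"subject": [0] * 100 + [1] * 100, "trial_type": ["3O"] * 200}
    )
    keep = np.ones(200, dtype=bool)
    keep[:26] = False  # subject 0 left with 74
    assert exclude_low_trial_subjects(meta, keep) == [0]
    keep[:26] = True
    keep[:25] = False  # exactly 75 survive
    assert exclude_low_trial_subjects(meta, keep) == []


def test_subject_exclusion_constructed_two_of_ten():
    rows, keep = [], []
    for s in range(10):
        for tt in ("1O", "3O"):
            n_keep = 60 if (s in (2, 7) and tt == "3O") else 80
            rows += [{"subject": s, "trial_type": tt}] * 80
            keep += [True] * n_keep + [False] * (80 - n_keep)
    out = exclude_low_trial_subjects(pd.DataFrame(rows), np.array(keep))
    assert out == [2, 7]


def test_lateralize_definitional():
    data = np.zeros((2, 3, 100))
    data[:, 1, :] = -1.0  # right cluster carries the signal
    ep = make_epochs(data, cue_sides=["left", "left"], t0=0.0)
    lat = lateralize(ep)
    assert np.allclose(lat.contra, -1.0)
    assert np.allclose(lat.ipsi, 0.0)


def test_lateralize_swap_invariance():
    """Swapping cue sides and hemisphere labels together leaves contra/ipsi."""
    rng = np.random.default_rng(1)
    data = rng.normal(size=(6, 3, 50))
    cues = ["left", "right", "left", "right", "left", "right"]
    ep = make_epochs(data, cue_sides=cues, t0=0.0)
    lat = lateralize(ep)
    flipped = make_epochs(
        data[:, [1, 0, 2], :],
        cue_sides=["right" if c == "left" else "left" for c in cues],
        t0=0.0,
    )
    lat2 = lateralize(flipped)
    np.testing.assert_allclose(lat.contra, lat2.contra)
    np.testing.assert_allclose(lat.ipsi, lat2.ipsi)


def test_window_means_constant_difference():
    data = np.zeros((2, 3, 1000))
    data[:, 0, :] = -2.0  # left cluster
    data[:, 1, :] = -1.0  # right cluster
    ep = make_epochs(data, cue_sides=["right", "right"])
    wm = window_means(lateralize(ep))
    assert np.allclose(wm["contra_mean"], -2.0)
    assert np.allclose(wm["ipsi_mean"], -1.0)
    assert np.allclose(wm["diff_mean"], -1.0)


def test_window_outside_epoch_errors():
    ep = make_epochs(np.zeros((1, 3, 100)), t0=0.0)  # epoch 0..0.4 s
    with pytest.raises(ValueError):
        window_means(lateralize(ep), [WindowSpec("delay", 0.95, 1.6)])


def test_rejection_masks_order_independent():
    cfg = GenConfig(
        seed=17, n_subjects=1, trials_per_cell=40,
        eeg=quiet_eeg(noise_sd=10.0, saccade_rate=0.2, blink_rate=0.2,
                      heog_noise_sd=5.0),
    )
    ep = baseline_correct(gen_eeg_epochs(cfg), copy=False)
    amp = reject_amplitude(ep)
    heog = detect_heog_steps(ep.heog_data(), ep.sfreq)
    assert np.array_equal(amp | heog, heog | amp)
    # both orders of sequential application reject the same trial set
    first_amp = ep.select(~amp)
    then_heog = first_amp.select(
        ~detect_heog_steps(first_amp.heog_data(), ep.sfreq)
    )
    first_heog = ep.select(~heog)
    then_amp = first_heog.select(~reject_amplitude(first_heog))
    assert then_heog.n_trials == then_amp.n_trials
    np.testing.assert_allclose(then_heog.data, then_amp.data)


def test_epochset_save_load_roundtrip(tmp_path):
    cfg = GenConfig(seed=18, n_subjects=1, trials_per_cell=4)
    ep = gen_eeg_epochs(cfg)
    ep.save(tmp_path / "store")
    back = EpochSet.load(tmp_path / "store")
    np.testing.assert_array_equal(back.data, ep.data.astype(np.float32))
    assert back.sfreq == ep.sfreq
    assert back.ch_names == ep.ch_names
    pd.testing.assert_frame_equal(
        back.meta, ep.meta, check_dtype=False
    )


def test_epochset_to_mne_roundtrip_units():
    mne = pytest.importorskip("mne")
    ep = make_epochs(np.full((2, 3, 1000), 5.0))
    arr = ep.to_mne()
    assert isinstance(arr, mne.EpochsArray)
    np.testing.assert_allclose(arr.get_data()[0, 0] * 1e6, 5.0, rtol=1e-6)


def test_interpolation_hook_validates_names():
    ep = make_epochs(np.zeros((1, 3, 100)))
    assert interpolate_bad_channels(ep, ["L1"]) is ep
    with pytest.raises(ValueError):
        interpolate_bad_channels(ep, ["nope"])


def test_noiseless_end_to_end_recovery_exact():
    """Full pipeline on zero-noise epochs reproduces injected amplitudes."""
    cfg = GenConfig(
        seed=19, n_subjects=2, trials_per_cell=4,
        eeg=quiet_eeg(cda_amp_by_load={1: -0.5, 3: -1.5, 5: -1.5},
                      bilateral_effect_amp=-1.0),
    )
    ep = baseline_correct(gen_eeg_epochs(cfg), copy=False)
    assert not reject_amplitude(ep).any()
    assert not detect_heog_steps(ep.heog_data(), ep.sfreq).any()
    wm = window_means(lateralize(ep))
    for _, row in wm.iterrows():
        expected = cfg.eeg.cda_amp_by_load[row["load"]]
        assert row["diff_mean"] == pytest.approx(expected, abs=1e-9)
        bil = -1.0 if row["condition"] == "homogeneous" else 0.0
        assert row["ipsi_mean"] == pytest.approx(bil, abs=1e-9)
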