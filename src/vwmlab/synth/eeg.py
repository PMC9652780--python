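"""Synthetic epoched EEG with an injected lateralized delay component.

Each trial's epoch spans −1.5 to +2.5 s around sample-array onset.  A
sustained negative boxcar of amplitude ``cda_amp_by_load[load]`` is
added, from sample onset to probe onset, to the posterior cluster
channels of the hemisphere contralateral to the cued hemifield; on
homogeneous-condition trials an additional ``bilateral_effect_amp``
boxcar is added to BOTH hemisphere clusters (it therefore cancels in
the contra − ipsi difference).  Noise is a pink (1/f) + white mixture;
lateral saccades appear as instantaneous steps held to the epoch end on
the HEOG channel and blinks as high-amplitude transients on the frontal
channels.  All injected artifacts are recorded in the annotations
table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..config import GenConfig, TrialTimingSpec
from ..erp import EpochSet


def _pink_noise(
    rng: np.random.Generator, shape, sfreq: float, knee_hz: float = 1.0
) -> np.ndarray:
    """Unit-variance 1/f-shaped noise along the last axis.

    The spectrum flattens below ``knee_hz``, emulating the absence of
    slow drifts in high-pass-filtered recordings.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = 1.0 / np.sqrt(np.maximum(freqs, knee_hz))
    scale[0] = 0.0  # no DC offset
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def gen_eeg_epochs(
    cfg: GenConfig,
    timing: Optional[TrialTimingSpec] = None,
    trials: Optional[pd.DataFrame] = None,
) -> EpochSet:
    """Generate an :class:`EpochSet` for a table of recognition trials.

    ``trials`` must carry subject, condition, load and cue_side columns;
    when omitted, a fresh recognition table is drawn from ``cfg``.
    """
    from .behavior import gen_recognition_trials

    timing = timing or TrialTimingSpec()
    if trials is None:
        trials = gen_recognition_trials(cfg, timing)
    for col in ("subject", "condition", "load", "cue_side"):
        if col not in trials.columns:
            raise ValueError(f"trials missing column {col!r}")
    eeg = cfg.eeg
    t0, t1 = timing.epoch_window
    if t1 - t0 < timing.probe_onset:
        raise ValueError("epoch window shorter than sample + delay period")
    n_samples = int(round((t1 - t0) * eeg.sfreq))
    times = t0 + np.arange(n_samples) / eeg.sfreq

    ch_names = list(eeg.cluster_map.keys())
    ch_side = [eeg.cluster_map[c] for c in ch_names]
    cluster_mask = np.array([s in ("left", "right") for s in ch_side])
    left_idx = np.where(cluster_mask & (np.array(ch_side) == "left"))[0]
    right_idx = np.where(cluster_mask & (np.array(ch_side) == "right"))[0]
    frontal_idx = np.where(np.array(ch_side) == "frontal")[0]
    heog_idx = ch_names.index("HEOG") if "HEOG" in ch_names else None

    n_trials = len(trials)
    n_ch = len(ch_names)
    sustained = ((times >= 0.0) & (times < timing.probe_onset)).astype(float)

    # float32 storage: epoch stores are large and the pipeline reduces in float64
    data = np.zeros((n_trials, n_ch, n_samples), dtype=np.float32)
    meta = trials[
        [c for c in ("subject", "condition", "load", "cue_side", "trial_type")
         if c in trials.columns]
    ].reset_index(drop=True)

    # per-subject multiplicative amplitude variation (same for all components)
    subjects = meta["subject"].to_numpy()
    amp_scale = {}
    for s in np.unique(subjects):
        r = cfg.rng(4, int(s), 0)
        amp_scale[s] = max(0.0, 1.0 + r.normal(0.0, eeg.subject_amp_sd))

    load = meta["load"].to_numpy()
    cda_amp = np.array(
        [eeg.cda_amp_by_load.get(int(l), 0.0) * amp_scale[s]
         for l, s in zip(load, subjects)]
    )
    bilat_amp = np.array(
        [
            (eeg.bilateral_effect_amp * amp_scale[s])
            if c == "homogeneous"
            else 0.0
            for c, s in zip(meta["condition"], subjects)
        ]
    )
    contra_is_right = meta["cue_side"].to_numpy() == "left"

    comp = cda_amp[:, None] * sustained[None, :]
    bil = bilat_amp[:, None] * sustained[None, :]
    for tr in range(n_trials):
        contra_idx = right_idx if contra_is_right[tr] else left_idx
        data[tr, contra_idx, :] += comp[tr]
        data[tr, left_idx, :] += bil[tr]
        data[tr, right_idx, :] += bil[tr]

    rng = cfg.rng(5)
    eeg_ch = np.array([i for i, s in enumerate(ch_side) if s != "eog"])
    if eeg.noise_sd > 0:
        w_pink = np.sqrt(eeg.pink_noise_frac)
        w_white = np.sqrt(1.0 - eeg.pink_noise_frac)
        chunk = max(1, 400_000 // n_samples)
        for lo in range(0, n_trials, chunk):
            hi = min(lo + chunk, n_trials)
            shape = (hi - lo, len(eeg_ch), n_samples)
            noise = w_white * rng.standard_normal(shape)
            if w_pink > 0:
                noise += w_pink * _pink_noise(rng, shape, eeg.sfreq, eeg.pink_knee_hz)
            data[np.arange(lo, hi)[:, None], eeg_ch[None, :], :] += (
                eeg.noise_sd * noise
            )
    if heog_idx is not None and eeg.heog_noise_sd > 0:
        data[:, heog_idx, :] += eeg.heog_noise_sd * rng.standard_normal(
            (n_trials, n_samples)
        )

    # artifacts with ground-truth annotations
    art_rng = cfg.rng(6)
    sacc = art_rng.random(n_trials) < eeg.saccade_rate
    blink = art_rng.random(n_trials) < eeg.blink_rate
    sacc_lat = art_rng.uniform(t0 + 0.2, t1 - 0.2, size=n_trials)
    sacc_sign = np.where(art_rng.random(n_trials) < 0.5, 1.0, -1.0)
    blink_lat = art_rng.uniform(t0 + 0.2, t1 - 0.2, size=n_trials)
    if heog_idx is not None:
        for tr in np.where(sacc)[0]:
            onset = np.searchsorted(times, sacc_lat[tr])
            data[tr, heog_idx, onset:] += sacc_sign[tr] * eeg.saccade_amp
    if len(frontal_idx):
        for tr in np.where(blink)[0]:
            pulse = eeg.blink_amp * np.exp(
                -0.5 * ((times - blink_lat[tr]) / 0.05) ** 2
            )
            data[tr, frontal_idx, :] += pulse[None, :]

    annotations = pd.DataFrame(
        {
            "saccade": sacc,
            "saccade_latency_s": np.where(sacc, sacc_lat, np.nan),
            "blink": blink,
            "blink_latency_s": np.where(blink, blink_lat, np.nan),
        }
    )
    return EpochSet(
        data=data,
        sfreq=eeg.sfreq,
        t0=t0,
        ch_names=ch_names,
        ch_side=ch_side,
        cluster_mask=cluster_mask,
        heog_ch="HEOG" if heog_idx is not None else None,
        meta=meta,
        annotations=annotations,
    )
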