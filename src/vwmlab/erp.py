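"""ERP pipeline: from epoched EEG to the contralateral delay activity.

The pipeline mirrors a standard lateralized change-detection analysis:
baseline-correct epochs on the 200 ms prestimulus interval, discard
trials exceeding 100 μV at any electrode, discard trials with step-like
horizontal-EOG deflections (split-half sliding window: 200 ms window,
20 ms step, 20 μV threshold), exclude subjects left with fewer than 75
epochs in any trial type, average the posterior electrode clusters of
each hemisphere into trial-wise contralateral and ipsilateral signals
relative to the cued hemifield, average over trials per cell, and take
time-window means over the sample-presentation window (0.200–0.700 s
after sample onset) and the delay window (0.950–1.600 s, i.e. 200 ms
after sample offset to 50 ms before probe onset).  The contralateral −
ipsilateral difference over the delay window is the CDA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from scipy import signal as sps

#: Default analysis windows, seconds relative to sample-array onset.
BASELINE_WINDOW = ("baseline", -0.200, 0.0)
SAMPLE_WINDOW = ("sample", 0.200, 0.700)
DELAY_WINDOW = ("delay", 0.950, 1.600)


@dataclass(frozen=True)
class WindowSpec:
    """A named time window [start, stop), seconds relative to sample onset."""

    name: str
    start: float
    stop: float

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("window start must precede stop")

    @classmethod
    def defaults(cls) -> List["WindowSpec"]:
        return [cls(*SAMPLE_WINDOW), cls(*DELAY_WINDOW)]


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial metadata.

    data : (n_trials, n_channels, n_samples) voltages in μV.
    t0 : time of the first sample relative to sample-array onset (s).
    ch_side : hemisphere tag per channel ({left, right, midline,
        frontal, eog}); only left/right channels with ``cluster_mask``
        set enter the lateralized analysis.
    meta : one row per trial (subject, condition, load, cue_side,
        trial_type, ...).
    annotations : ground-truth artifact bookkeeping (synthetic data only).
    """

    data: np.ndarray
    sfreq: float
    t0: float
    ch_names: List[str]
    ch_side: List[str]
    cluster_mask: np.ndarray
    heog_ch: Optional[str]
    meta: pd.DataFrame
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be > 0")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length mismatch")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta rows must equal number of trials")
        self.cluster_mask = np.asarray(self.cluster_mask, dtype=bool)
        sides = {
            s for s, m in zip(self.ch_side, self.cluster_mask) if m
        }
        if not {"left", "right"} <= sides:
            raise ValueError("need at least one left- and one right-cluster channel")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.sfreq

    def window_index(self, window: WindowSpec) -> np.ndarray:
        t = self.times
        idx = (t >= window.start) & (t < window.stop)
        if not idx.any():
            raise ValueError(f"window {window.name} outside epoch span")
        if window.start < t[0] - 0.5 / self.sfreq or window.stop > t[-1] + 1.0 / self.sfreq:
            raise ValueError(f"window {window.name} outside epoch span")
        return idx

    def heog_data(self) -> np.ndarray:
        if self.heog_ch is None or self.heog_ch not in self.ch_names:
            raise ValueError("no HEOG channel present")
        return self.data[:, self.ch_names.index(self.heog_ch), :]

    def cluster_indices(self, side: str) -> np.ndarray:
        idx = np.array(
            [i for i, (s, m) in enumerate(zip(self.ch_side, self.cluster_mask))
             if m and s == side],
            dtype=int,
        )
        if idx.size == 0:
            raise ValueError(f"no {side}-cluster channels")
        return idx

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(), sfreq=self.sfreq, t0=self.t0,
            ch_names=list(self.ch_names), ch_side=list(self.ch_side),
            cluster_mask=self.cluster_mask.copy(), heog_ch=self.heog_ch,
            meta=self.meta.copy(),
            annotations=None if self.annotations is None else self.annotations.copy(),
        )

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask], sfreq=self.sfreq, t0=self.t0,
            ch_names=list(self.ch_names), ch_side=list(self.ch_side),
            cluster_mask=self.cluster_mask.copy(), heog_ch=self.heog_ch,
            meta=self.meta.loc[mask].reset_index(drop=True),
            annotations=None if self.annotations is None
            else self.annotations.loc[mask].reset_index(drop=True),
        )

    # ---- disk format: float32 little-endian array + JSON sidecar ----

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.data.astype("<f4").tofile(d / "epochs.dat")
        sidecar = {
            "shape": list(self.data.shape),
            "dtype": "<f4",
            "units": "uV",
            "sfreq_hz": self.sfreq,
            "t0_s": self.t0,
            "ch_names": self.ch_names,
            "ch_cluster": self.ch_side,
            "cluster_mask": self.cluster_mask.astype(int).tolist(),
            "heog_ch": self.heog_ch,
            "trial_metadata": self.meta.to_dict(orient="records"),
            "artifact_annotations": None
            if self.annotations is None
            else self.annotations.to_dict(orient="records"),
        }
        (d / "epochs.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory) -> "EpochSet":
        d = Path(directory)
        sidecar = json.loads((d / "epochs.json").read_text())
        data = np.fromfile(d / "epochs.dat", dtype=sidecar["dtype"]).reshape(
            sidecar["shape"]
        )
        ann = sidecar["artifact_annotations"]
        return cls(
            data=data,
            sfreq=sidecar["sfreq_hz"],
            t0=sidecar["t0_s"],
            ch_names=sidecar["ch_names"],
            ch_side=sidecar["ch_cluster"],
            cluster_mask=np.asarray(sidecar["cluster_mask"], dtype=bool),
            heog_ch=sidecar["heog_ch"],
            meta=pd.DataFrame(sidecar["trial_metadata"]),
            annotations=None if ann is None else pd.DataFrame(ann),
        )

    # ---- interoperability ----

    def to_mne(self):
        """Convert to an :class:`mne.EpochsArray` (requires mne)."""
        import mne

        types = ["eog" if s == "eog" else "eeg" for s in self.ch_side]
        info = mne.create_info(self.ch_names, self.sfreq, ch_types=types)
        return mne.EpochsArray(
            self.data * 1e-6, info, tmin=self.t0, verbose="error"
        )

    def export_edf(self, fname) -> None:
        """EDF export hook via mne; raises if the EDF backend is unavailable."""
        epochs = self.to_mne()
        try:
            epochs.export(str(fname), fmt="edf")
        except (ImportError, RuntimeError, ValueError) as exc:
            raise RuntimeError(
                "EDF export requires an mne EDF backend (edfio)"
            ) from exc


@dataclass(frozen=True)
class CDAResult:
    """Window means for one subject x condition x load cell."""

    subject: object
    condition: object
    load: object
    window: str
    contra_mean: float
    ipsi_mean: float
    diff_mean: float
    n_trials_used: int

    def __post_init__(self) -> None:
        if abs(self.diff_mean - (self.contra_mean - self.ipsi_mean)) > 1e-9:
            raise ValueError("diff_mean must equal contra_mean - ipsi_mean")


def baseline_correct(
    epochs: EpochSet, window: Optional[WindowSpec] = None, copy: bool = True
) -> EpochSet:
    """Subtract each trial's mean over the baseline window, per channel.

    With ``copy=False`` the correction is applied in place (large epoch
    stores); baselines are accumulated in float64 regardless of storage
    dtype.
    """
    window = window or WindowSpec(*BASELINE_WINDOW)
    idx = epochs.window_index(window)
    out = epochs.copy() if copy else epochs
    base = out.data[:, :, idx].mean(axis=2, keepdims=True, dtype=np.float64)
    out.data -= base.astype(out.data.dtype)
    return out


def reject_amplitude(epochs: EpochSet, threshold: float = 100.0) -> np.ndarray:
    """Flag trials whose absolute voltage strictly exceeds ``threshold`` μV
    at any electrode.  Returns a boolean mask, True = rejected."""
    hi = epochs.data.max(axis=(1, 2))
    lo = epochs.data.min(axis=(1, 2))
    return np.maximum(hi, -lo) > threshold


def detect_heog_steps(
    heog: np.ndarray,
    sfreq: float,
    win_s: float = 0.200,
    step_s: float = 0.020,
    thresh_uv: float = 20.0,
) -> np.ndarray:
    """Split-half sliding-window saccade detector on the HEOG channel.

    A window of ``win_s`` slides in steps of ``step_s``; a trial is
    flagged when the voltage change from the mean of the first half of
    any window to the mean of its second half strictly exceeds
    ``thresh_uv`` μV in absolute value.  Returns a boolean mask,
    True = flagged.
    """
    heog = np.atleast_2d(np.asarray(heog, dtype=float))
    n_trials, n_samples = heog.shape
    half = int(round(win_s * sfreq / 2.0))
    if half < 1 or 2 * half > n_samples:
        raise ValueError("epoch shorter than the sliding window")
    step = max(int(round(step_s * sfreq)), 1)
    # cumulative sums make each half-mean an O(1) lookup
    cs = np.concatenate(
        [np.zeros((n_trials, 1)), np.cumsum(heog, axis=1)], axis=1
    )
    starts = np.arange(0, n_samples - 2 * half + 1, step)
    first = (cs[:, starts + half] - cs[:, starts]) / half
    second = (cs[:, starts + 2 * half] - cs[:, starts + half]) / half
    return (np.abs(second - first) > thresh_uv).any(axis=1)


def exclude_low_trial_subjects(
    meta: pd.DataFrame, keep_mask: np.ndarray, min_trials: int = 75
) -> List[object]:
    """Subjects with fewer than ``min_trials`` surviving epochs in any trial type.

    ``keep_mask`` is True for epochs that survived artifact rejection.
    Trial types are taken from the ``trial_type`` metadata column.
    Returns the sorted list of excluded subjects.
    """
    if "trial_type" not in meta.columns:
        raise ValueError("meta must carry a trial_type column")
    surv = meta.loc[np.asarray(keep_mask, dtype=bool)]
    counts = surv.groupby(["subject", "trial_type"]).size().unstack(fill_value=0)
    # a trial type a subject never had at all does not count against them
    present = meta.groupby(["subject", "trial_type"]).size().unstack(fill_value=0) > 0
    counts = counts.reindex_like(present).fillna(0)
    low = (counts < min_trials) & present
    return sorted(low.index[low.any(axis=1)].tolist())


@dataclass
class LateralizedERP:
    """Trial-averaged contralateral and ipsilateral cluster waveforms per cell."""

    cells: pd.DataFrame  # one row per cell: groupby keys + n_trials
    contra: np.ndarray  # (n_cells, n_samples)
    ipsi: np.ndarray
    times: np.ndarray
    sfreq: float

    @property
    def diff(self) -> np.ndarray:
        return self.contra - self.ipsi


def lateralize(
    epochs: EpochSet,
    by: Sequence[str] = ("subject", "condition", "load"),
) -> LateralizedERP:
    """Average hemisphere clusters into contra/ipsi waveforms per cell.

    Contralateral = right-cluster channels on left-cue trials and
    left-cluster channels on right-cue trials (conversely for
    ipsilateral); midline and non-cluster channels never contribute.
    Cells with zero trials are absent from the output (missing, not zero).
    """
    li = epochs.cluster_indices("left")
    ri = epochs.cluster_indices("right")
    cue = epochs.meta["cue_side"].to_numpy()
    if not np.isin(cue, ("left", "right")).all():
        raise ValueError("cue_side must be 'left' or 'right'")
    left_mean = epochs.data[:, li, :].mean(axis=1, dtype=np.float64)
    right_mean = epochs.data[:, ri, :].mean(axis=1, dtype=np.float64)
    is_left_cue = (cue == "left")[:, None]
    contra_tr = np.where(is_left_cue, right_mean, left_mean)
    ipsi_tr = np.where(is_left_cue, left_mean, right_mean)

    by = [b for b in by if b in epochs.meta.columns]
    rows, contra, ipsi = [], [], []
    for key, grp in epochs.meta.groupby(list(by), sort=True):
        sel = grp.index.to_numpy()
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(by, key), n_trials=len(sel)))
        contra.append(contra_tr[sel].mean(axis=0))
        ipsi.append(ipsi_tr[sel].mean(axis=0))
    return LateralizedERP(
        cells=pd.DataFrame(rows),
        contra=np.asarray(contra),
        ipsi=np.asarray(ipsi),
        times=epochs.times,
        sfreq=epochs.sfreq,
    )


def window_means(
    lat: LateralizedERP, windows: Optional[Sequence[WindowSpec]] = None
) -> pd.DataFrame:
    """Time-mean contra, ipsi and difference voltages per cell and window."""
    windows = list(windows) if windows is not None else WindowSpec.defaults()
    rows = []
    for w in windows:
        idx = (lat.times >= w.start) & (lat.times < w.stop)
        if not idx.any():
            raise ValueError(f"window {w.name} outside epoch span")
        c = lat.contra[:, idx].mean(axis=1)
        i = lat.ipsi[:, idx].mean(axis=1)
        for r, (cv, iv) in zip(lat.cells.to_dict(orient="records"), zip(c, i)):
            rows.append(
                {
                    **{k: v for k, v in r.items() if k != "n_trials"},
                    "window": w.name,
                    "contra_mean": cv,
                    "ipsi_mean": iv,
                    "diff_mean": cv - iv,
                    "n_trials_used": r["n_trials"],
                }
            )
    return pd.DataFrame(rows)


# ---- optional preprocessing ----


def bandpass_filter(
    epochs: EpochSet, l_freq: float = 0.1, h_freq: float = 30.0, order: int = 4
) -> EpochSet:
    """Zero-phase Butterworth band-pass, applied per trial and channel."""
    sos = sps.butter(
        order, [l_freq, h_freq], btype="bandpass", fs=epochs.sfreq, output="sos"
    )
    out = epochs.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=2)
    return out


def downsample(epochs: EpochSet, sfreq_new: float) -> EpochSet:
    """Polyphase resampling to a new sampling rate."""
    from fractions import Fraction

    frac = Fraction(sfreq_new / epochs.sfreq).limit_denominator(1000)
    out = epochs.copy()
    out.data = sps.resample_poly(out.data, frac.numerator, frac.denominator, axis=2)
    out.sfreq = sfreq_new
    return out


def interpolate_bad_channels(epochs: EpochSet, bads: Sequence[str]) -> EpochSet:
    """No-op hook for bad-channel interpolation.

    Spherical-spline interpolation needs electrode geometry that the
    synthetic montage does not define; the hook validates channel names
    and returns the input unchanged.
    """
    unknown = [b for b in bads if b not in epochs.ch_names]
    if unknown:
        raise ValueError(f"unknown channels: {unknown}")
    return epochs
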