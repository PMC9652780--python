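"""Configuration objects for the synthetic-data generator and trial timing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

#: Likert similarity offset sets actually sampled per domain, in each
#: domain's native units (orientation: degrees of a 180-degree space;
#: color: degrees of a 360-degree wheel; luminance: 8-bit RGB steps).
LIKERT_OFFSETS: Dict[str, Tuple[float, ...]] = {
    "orientation": (0, 2.5, 5, 10, 15, 20, 25, 30, 35, 40, 45, 60, 75, 90),
    "color": (0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 120, 150, 180),
    "luminance": (0, 3, 7, 14, 21, 28, 35, 42, 49, 56, 64, 85, 106, 128),
}

DOMAINS = ("orientation", "color", "luminance")
CONDITIONS = ("homogeneous", "heterogeneous")
LOADS = (1, 3, 5)
RECALL_TRIAL_TYPES = ("1O", "1O1C1L", "3O")


@dataclass
class MixtureTruth:
    """Generative mixture parameters for recall trials.

    pT: probability the response is the target plus von Mises noise.
    pN: probability of reporting a (random) nontarget plus noise; only
        meaningful for trial types that have nontargets (3O).
    pU: probability of a uniform guess.
    kappa: von Mises concentration on the doubled (360-degree) circle.
    """

    pT: float = 0.7
    pN: float = 0.15
    pU: float = 0.15
    kappa: float = 12.0

    def __post_init__(self) -> None:
        for name in ("pT", "pN", "pU"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(self.pT + self.pN + self.pU - 1.0) > 1e-9:
            raise ValueError("pT + pN + pU must equal 1 within 1e-9")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class TCCTruth:
    """Generative TCC parameters: memory-strength d' and swap probability."""

    dprime: float = 2.0
    swap_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.dprime < 0:
            raise ValueError("dprime must be >= 0")
        if not 0.0 <= self.swap_prob <= 1.0:
            raise ValueError("swap_prob outside [0, 1]")


@dataclass
class EEGSimConfig:
    """Parameters of the synthetic EEG epoch generator.

    Amplitudes are in microvolts; the sustained delay-period component is
    negative-going at electrodes contralateral to the cued hemifield, with
    a magnitude that grows with memory load and saturates at capacity.
    ``bilateral_effect_amp`` is an additive component applied to BOTH
    hemispheres on homogeneous-condition trials, emulating a
    condition effect that cancels in the contra − ipsi subtraction.
    """

    sfreq: float = 250.0
    cluster_map: Mapping[str, str] = field(default_factory=dict)
    cda_amp_by_load: Mapping[int, float] = field(
        default_factory=lambda: {1: -0.5, 3: -1.5, 5: -1.5}
    )
    bilateral_effect_amp: float = -1.0
    noise_sd: float = 10.0
    pink_noise_frac: float = 0.5
    pink_knee_hz: float = 2.0  # spectrum flattens below this, as after a high-pass
    heog_noise_sd: float = 5.0  # white noise on the ocular channel
    saccade_rate: float = 0.05
    saccade_amp: float = 40.0
    blink_rate: float = 0.05
    blink_amp: float = 150.0
    capacity_k: float = 3.0
    subject_amp_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sfreq must be > 0")
        if not self.cluster_map:
            self.cluster_map = default_cluster_map()
        sides = set(self.cluster_map.values())
        if not {"left", "right"} <= sides:
            raise ValueError("cluster_map must contain left and right clusters")
        for name, rate in (("saccade_rate", self.saccade_rate),
                           ("blink_rate", self.blink_rate),
                           ("pink_noise_frac", self.pink_noise_frac)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        loads = sorted(self.cda_amp_by_load)
        # magnitude may not grow further once load exceeds capacity (saturation)
        for lo, hi in zip(loads, loads[1:]):
            if abs(self.cda_amp_by_load[hi]) + 1e-12 < abs(self.cda_amp_by_load[lo]):
                raise ValueError("CDA amplitude magnitude must be non-decreasing with load")
            if lo >= self.capacity_k and (
                abs(self.cda_amp_by_load[hi]) > abs(self.cda_amp_by_load[lo]) + 1e-12
            ):
                raise ValueError(
                    "CDA amplitude must saturate beyond capacity_k "
                    f"(load {hi} exceeds load {lo} magnitude)"
                )


#: The twelve lateralized posterior electrode pairs of the analysis montage.
CLUSTER_PAIRS = (
    ("TP7", "TP8"), ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"),
    ("P1", "P2"), ("P3", "P4"), ("P5", "P6"), ("P7", "P8"),
    ("P9", "P10"), ("PO3", "PO4"), ("PO7", "PO8"), ("O1", "O2"),
)


def default_cluster_map() -> Dict[str, str]:
    """Channel layout of the simulated montage.

    Twelve posterior electrode pairs form the lateralized analysis
    clusters, two frontal channels carry blink artifacts, two midline
    channels are never analyzed, and HEOG carries saccade steps.
    """
    cmap: Dict[str, str] = {}
    for left, right in CLUSTER_PAIRS:
        cmap[left] = "left"
        cmap[right] = "right"
    cmap["POz"] = "midline"
    cmap["Oz"] = "midline"
    cmap["Fp1"] = "frontal"
    cmap["Fp2"] = "frontal"
    cmap["HEOG"] = "eog"
    return cmap


@dataclass
class TrialTimingSpec:
    """Event timing of a lateralized change-detection / recall trial (seconds).

    The cue (200 ms) is followed by a jittered cue–stimulus interval,
    the bilateral sample array (750 ms), an unfilled delay (900 ms) and
    the probe.  Epochs are locked to sample-array onset.
    """

    cue_dur: float = 0.200
    csi_range: Tuple[float, float] = (0.400, 0.600)
    csi_step: float = 0.050
    sample_dur: float = 0.750
    delay_dur: float = 0.900
    probe_window: float = 2.0
    epoch_window: Tuple[float, float] = (-1.5, 2.5)
    baseline_window: Tuple[float, float] = (-0.200, 0.0)

    def __post_init__(self) -> None:
        lo, hi = self.csi_range
        for v in (lo, hi):
            if abs(round(v / self.csi_step) * self.csi_step - v) > 1e-9:
                raise ValueError("csi_range values must be multiples of csi_step")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("invalid epoch window")

    @property
    def probe_onset(self) -> float:
        """Probe onset relative to sample onset (s)."""
        return self.sample_dur + self.delay_dur


@dataclass
class GenConfig:
    """Top-level configuration of the synthetic study."""

    seed: int = 0
    n_subjects: int = 10
    trials_per_cell: int = 100
    capacity_k: Mapping[str, float] = field(
        default_factory=lambda: {"homogeneous": 2.2, "heterogeneous": 3.0}
    )
    capacity_subject_sd: float = 0.3
    guess_rate_recognition: float = 0.5
    mixture_truth: MixtureTruth = field(default_factory=MixtureTruth)
    mixture_truth_by_type: Mapping[str, MixtureTruth] = field(default_factory=dict)
    tcc_truth: TCCTruth = field(default_factory=TCCTruth)
    similarity_scale: float = 20.0  # exponential-decay scale, scaled-offset degrees
    likert_noise_sd: float = 0.8  # rating-scale units
    rt_lognorm_mu: float = -0.45  # log-seconds
    rt_lognorm_sigma: float = 0.35
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.capacity_k, (int, float)):
            self.capacity_k = {c: float(self.capacity_k) for c in CONDITIONS}
        for cond, k in self.capacity_k.items():
            if k < 0:
                raise ValueError(f"capacity_k[{cond}] must be >= 0")
        if not 0.0 <= self.guess_rate_recognition <= 1.0:
            raise ValueError("guess_rate_recognition outside [0, 1]")
        if self.n_subjects < 1 or self.trials_per_cell < 1:
            raise ValueError("n_subjects and trials_per_cell must be >= 1")

    def truth_for_type(self, trial_type: str) -> MixtureTruth:
        """Mixture truth for a recall trial type; swap mass only where swaps exist."""
        if trial_type in self.mixture_truth_by_type:
            return self.mixture_truth_by_type[trial_type]
        if trial_type == "3O":
            return self.mixture_truth
        t = self.mixture_truth
        # no nontargets: fold the swap mass into guessing
        return MixtureTruth(pT=t.pT, pN=0.0, pU=t.pU + t.pN, kappa=t.kappa)

    def rng(self, *streams: int) -> np.random.Generator:
        """Independent generator for a named substream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, *streams)))

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenConfig":
        """Build a config from a plain (e.g. YAML-loaded) mapping."""
        d = dict(d)
        if "mixture_truth" in d and isinstance(d["mixture_truth"], Mapping):
            d["mixture_truth"] = MixtureTruth(**d["mixture_truth"])
        if "mixture_truth_by_type" in d:
            d["mixture_truth_by_type"] = {
                k: MixtureTruth(**v) if isinstance(v, Mapping) else v
                for k, v in d["mixture_truth_by_type"].items()
            }
        if "tcc_truth" in d and isinstance(d["tcc_truth"], Mapping):
            d["tcc_truth"] = TCCTruth(**d["tcc_truth"])
        if "eeg" in d and isinstance(d["eeg"], Mapping):
            eeg = dict(d["eeg"])
            if "cda_amp_by_load" in eeg:
                eeg["cda_amp_by_load"] = {
                    int(k): float(v) for k, v in eeg["cda_amp_by_load"].items()
                }
            d["eeg"] = EEGSimConfig(**eeg)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GenConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
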