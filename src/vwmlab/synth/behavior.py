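"""Generators for recognition, recall and Likert similarity trial tables.

Each generator consumes a :class:`~vwmlab.config.GenConfig` and draws
from seeded, named random substreams, so identical configurations
reproduce bit-identical tables and every latent variable (memory state,
mixture component, similarity shape) is recorded for recovery tests.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..circular import SPAN, wrap
from ..config import (
    CONDITIONS,
    DOMAINS,
    LIKERT_OFFSETS,
    LOADS,
    GenConfig,
    MixtureTruth,
    TrialTimingSpec,
)


def _trial_type(condition: str, load: int, probe_domain: str) -> str:
    if condition == "homogeneous":
        return f"{load}O"
    if load == 1:
        return "1" + probe_domain[0].upper()
    return "1O1C1L" if load == 3 else "5mix"


def gen_recognition_trials(
    cfg: GenConfig,
    timing: Optional[TrialTimingSpec] = None,
    loads: Sequence[int] = LOADS,
    timeout_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate lateralized delayed-recognition (change-detection) trials.

    The generative model is the discrete-slot account underlying Cowan's
    k: on each trial the probed item is in memory with probability
    ``min(k / load, 1)``; an in-memory probe yields a correct response,
    otherwise the subject responds "match" with probability
    ``guess_rate_recognition``.  Match/nonmatch probes and cue sides are
    exactly balanced within every subject x condition x load cell.
    """
    timing = timing or TrialTimingSpec()
    if not set(loads) <= set(LOADS):
        raise ValueError(f"loads must be a subset of {LOADS}")
    n = cfg.trials_per_cell
    if n % 2:
        raise ValueError("trials_per_cell must be even to balance match/nonmatch")

    rows = []
    for s in range(cfg.n_subjects):
        rng = cfg.rng(1, s)
        for cond in CONDITIONS:
            k_subj = max(
                0.0,
                rng.normal(cfg.capacity_k[cond], cfg.capacity_subject_sd),
            )
            for load in loads:
                # one-item heterogeneous arrays probe each domain; give every
                # probe-domain trial type a full complement of trials so the
                # per-trial-type exclusion rule sees comparable counts
                if cond == "heterogeneous" and load == 1:
                    nn = 3 * n
                    domains = np.repeat(DOMAINS, n)
                else:
                    nn = n
                    if cond == "heterogeneous":
                        domains = np.resize(DOMAINS, nn)
                    else:
                        domains = np.repeat("orientation", nn)
                is_match = np.tile([True, False], nn // 2)
                cue = np.tile(["left", "left", "right", "right"], -(-nn // 4))[:nn]
                perm = rng.permutation(nn)
                is_match, cue, domains = is_match[perm], cue[perm], domains[perm]

                p_mem = min(k_subj / load, 1.0)
                in_mem = rng.random(nn) < p_mem
                guess_match = rng.random(nn) < cfg.guess_rate_recognition
                # in memory -> correct; otherwise a "match"/"nonmatch" guess
                said_match = np.where(in_mem, is_match, guess_match)
                rt = rng.lognormal(cfg.rt_lognorm_mu, cfg.rt_lognorm_sigma, size=nn)
                timeout = rng.random(nn) < timeout_rate
                for i in range(nn):
                    rows.append(
                        {
                            "subject": s,
                            "experiment": 1,
                            "condition": cond,
                            "trial_type": _trial_type(cond, load, domains[i]),
                            "load": load,
                            "cue_side": cue[i],
                            "probe_domain": domains[i],
                            "is_match": bool(is_match[i]),
                            "response": np.nan
                            if timeout[i]
                            else ("match" if said_match[i] else "nonmatch"),
                            "rt_s": np.nan if timeout[i] else float(rt[i]),
                            "truth_in_memory": bool(in_mem[i]),
                            "truth_capacity": k_subj,
                        }
                    )
    return pd.DataFrame(rows)


def _sample_vm_noise(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    """Von Mises noise on the doubled circle, returned in 180-space degrees."""
    return np.rad2deg(rng.vonmises(0.0, kappa, size=size)) / 2.0


def gen_recall_trials(
    cfg: GenConfig,
    trial_types: Sequence[str] = ("1O", "1O1C1L", "3O"),
    trials_per_type: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate delayed-estimation (recall) trials from the mixture model.

    Responses are target + von Mises noise with probability pT, a random
    nontarget + noise with probability pN (3O trials only; other trial
    types have no nontargets and require pN = 0), and uniform otherwise.
    The drawn component is stored per trial as ``truth_component``.
    """
    n = trials_per_type if trials_per_type is not None else cfg.trials_per_cell
    rows = []
    for s in range(cfg.n_subjects):
        rng = cfg.rng(2, s)
        for tt in trial_types:
            truth: MixtureTruth = cfg.truth_for_type(tt)
            has_nt = tt == "3O"
            if truth.pN > 0 and not has_nt:
                raise ValueError(f"pN > 0 requested for trial type {tt} without nontargets")
            targets = rng.uniform(0.0, SPAN, size=n)
            if has_nt:
                nts = rng.uniform(0.0, SPAN, size=(n, 2))
                # keep the three item values distinct
                for j in range(2):
                    clash = np.abs(nts[:, j] - targets) < 1e-9
                    nts[clash, j] = wrap(nts[clash, j] + 7.0)
            comp = rng.choice(
                ["target", "nontarget", "uniform"],
                size=n,
                p=[truth.pT, truth.pN, truth.pU],
            )
            eps = _sample_vm_noise(rng, truth.kappa, n)
            resp = wrap(targets + eps)
            if has_nt:
                which = rng.integers(0, 2, size=n)
                chosen_nt = nts[np.arange(n), which]
                resp = np.where(comp == "nontarget", wrap(chosen_nt + eps), resp)
            uni = rng.uniform(0.0, SPAN, size=n)
            resp = np.where(comp == "uniform", uni, resp)
            rt = rng.lognormal(cfg.rt_lognorm_mu + 0.4, cfg.rt_lognorm_sigma, size=n)
            probed = rng.integers(0, 3, size=n) if has_nt else np.zeros(n, dtype=int)
            for i in range(n):
                rows.append(
                    {
                        "subject": s,
                        "experiment": 2,
                        "trial_type": tt,
                        "target_deg": float(targets[i]),
                        "nontarget1_deg": float(nts[i, 0]) if has_nt else np.nan,
                        "nontarget2_deg": float(nts[i, 1]) if has_nt else np.nan,
                        "probed_location": int(probed[i]),
                        "response_deg": float(resp[i]),
                        "rt_s": float(rt[i]),
                        "truth_component": comp[i],
                    }
                )
    return pd.DataFrame(rows)


def gen_likert_trials(
    cfg: GenConfig, domain: str, reps_per_offset: int = 10
) -> pd.DataFrame:
    """Simulate Likert similarity ratings monotone in stimulus offset.

    Ratings follow ``clip(round(1 + 6 s(offset) + noise), 1, 7)`` with an
    exponentially decaying similarity shape
    ``s(offset) = exp(-scaled_offset / similarity_scale)``, where offsets
    are rescaled so each domain's maximal offset maps to 90 (the maximal
    distance of the common 180-unit space).
    """
    if domain not in LIKERT_OFFSETS:
        raise ValueError(f"unknown domain {domain!r}")
    offsets = np.asarray(LIKERT_OFFSETS[domain], dtype=float)
    scaled = offsets / offsets.max() * 90.0
    rows = []
    for s in range(cfg.n_subjects):
        rng = cfg.rng(3, s, DOMAINS.index(domain))
        for off, soff in zip(offsets, scaled):
            sim = np.exp(-soff / cfg.similarity_scale)
            noise = rng.normal(0.0, cfg.likert_noise_sd, size=reps_per_offset)
            rating = np.clip(np.round(1.0 + 6.0 * sim + noise), 1, 7).astype(int)
            for r in rating:
                rows.append(
                    {
                        "subject": s,
                        "domain": domain,
                        "offset": float(off),
                        "rating": int(r),
                        "truth_similarity": float(sim),
                    }
                )
    return pd.DataFrame(rows)
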