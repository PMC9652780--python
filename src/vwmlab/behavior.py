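"""Behavioral estimators for delayed recognition and delayed recall.

Delayed recognition (change detection) performance is summarized by
Cowan's k, ``k = N * (hit - fa)`` where N is the set size, the hit rate
is the proportion of correct ("nonmatch") responses on nonmatch trials
and the false-alarm rate the proportion of incorrect ("nonmatch")
responses on match trials.  Delayed recall responses are scored by the
minimal circular distance to the target on the 180-degree feature space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import SPAN, circ_dist


def cowans_k(hit_rate: float, fa_rate: float, set_size: int) -> float:
    """Change-detection capacity estimate: set_size * (hit_rate - fa_rate).

    Parameters
    ----------
    hit_rate : float in [0, 1]
        Proportion of "nonmatch" responses on nonmatch trials.
    fa_rate : float in [0, 1]
        Proportion of "nonmatch" responses on match trials.
    set_size : int >= 1
        Number of items in the memory array.

    Returns
    -------
    float
        Capacity in items; may be negative (no clipping is applied).
    """
    hit = np.asarray(hit_rate, dtype=float)
    fa = np.asarray(fa_rate, dtype=float)
    if np.any((hit < 0) | (hit > 1)) or np.any((fa < 0) | (fa > 1)):
        raise ValueError("rates must lie in [0, 1]")
    if np.any(np.asarray(set_size) < 1):
        raise ValueError("set_size must be >= 1")
    out = set_size * (hit - fa)
    return float(out) if out.ndim == 0 else out


def recall_error(response_deg, target_deg):
    """Absolute circular response error on the 180-degree space, in [0, 90]."""
    r = np.asarray(response_deg, dtype=float)
    t = np.asarray(target_deg, dtype=float)
    if np.any((r < 0) | (r >= SPAN)) or np.any((t < 0) | (t >= SPAN)):
        raise ValueError(f"angles must lie in [0, {SPAN})")
    return circ_dist(r, t)


def recognition_summary(
    trials: pd.DataFrame, orientation_probes_only: bool = True
) -> pd.DataFrame:
    """Per subject x condition x load hit rate, false-alarm rate and Cowan's k.

    Timeout trials (missing response) are excluded.  When
    ``orientation_probes_only`` is set, heterogeneous-condition cells are
    restricted to trials probing an orientation item, so that probe
    appearance is matched across conditions.  A cell that ends up with no
    match or no nonmatch trials is reported with NaN rates and k rather
    than zeros.

    Parameters
    ----------
    trials : DataFrame
        Columns: subject, condition, load, is_match (bool), response
        ("match"/"nonmatch", NaN for timeout), and optionally probe_domain.

    Returns
    -------
    DataFrame with columns subject, condition, load, n_trials, hit_rate,
    fa_rate, k.
    """
    df = trials.copy()
    df = df[df["response"].notna()]
    if orientation_probes_only and "probe_domain" in df.columns:
        keep = (df["condition"] != "heterogeneous") | (
            df["probe_domain"] == "orientation"
        )
        df = df[keep]

    rows = []
    for (subj, cond, load), cell in df.groupby(
        ["subject", "condition", "load"], sort=True
    ):
        is_match = cell["is_match"].astype(bool)
        said_nonmatch = cell["response"] == "nonmatch"
        n_nonmatch = int((~is_match).sum())
        n_match = int(is_match.sum())
        if n_nonmatch == 0 or n_match == 0:
            hit = fa = k = np.nan
        else:
            hit = float(said_nonmatch[~is_match].mean())
            fa = float(said_nonmatch[is_match].mean())
            k = cowans_k(hit, fa, int(load))
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "load": int(load),
                "n_trials": len(cell),
                "hit_rate": hit,
                "fa_rate": fa,
                "k": k,
            }
        )
    return pd.DataFrame(rows)
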