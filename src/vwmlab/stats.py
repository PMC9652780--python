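"""Within-subject factorial statistics.

``rm_anova`` implements the classical univariate repeated-measures
ANOVA for fully-crossed balanced designs with subject as a random
blocking factor: each within-subject effect is tested against its
interaction with subjects.  Sums of squares are computed by the
inclusion–exclusion (Möbius) decomposition of cell means, which is
exact for balanced designs and fast enough for null-calibration
simulations with thousands of replicates.  No sphericity correction is
applied by default; Greenhouse–Geisser adjustment is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class AnovaResult:
    """One effect line of a repeated-measures ANOVA table."""

    effect: str
    F: float
    df: Tuple[int, int]
    p: float
    gg_epsilon: Optional[float] = None
    p_gg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _subsets(items: Sequence[int]):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def _pure_effect(Y: np.ndarray, axes: Tuple[int, ...]) -> np.ndarray:
    """Inclusion–exclusion estimate of the pure interaction term over `axes`.

    Returns an array broadcastable to Y.shape that is constant along all
    axes not in `axes`.
    """
    all_axes = tuple(range(Y.ndim))
    term = np.zeros_like(Y, shape=[1] * Y.ndim)
    for sub in _subsets(axes):
        collapse = tuple(a for a in all_axes if a not in sub)
        m = Y.mean(axis=collapse, keepdims=True) if collapse else Y
        term = term + (-1) ** (len(axes) - len(sub)) * m
    return term


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: Sequence[str] = (),
    correction: bool = False,
) -> List[AnovaResult]:
    """Repeated-measures ANOVA for a balanced fully-crossed design.

    Parameters
    ----------
    data : long-format DataFrame with one observation per subject x cell
        (replicates within a cell are averaged when balanced).
    dv, subject, within : column names of the dependent variable, the
        subject identifier, and the within-subject factors.
    correction : apply Greenhouse–Geisser sphericity adjustment.

    Returns
    -------
    list of AnovaResult, one per main effect and interaction.
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within-subject factor")
    for col in [dv, subject, *within]:
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")

    counts = data.groupby([subject, *within], sort=True)[dv].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")
    cell = data.groupby([subject, *within], sort=True)[dv].mean()
    subjects = cell.index.get_level_values(0).unique()
    levels = [cell.index.get_level_values(i + 1).unique() for i in range(len(within))]
    n_subj = len(subjects)
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    shape = (n_subj, *[len(lv) for lv in levels])
    expected = int(np.prod(shape))
    if len(cell) != expected:
        raise ValueError("design is not fully crossed")
    Y = cell.to_numpy(dtype=float).reshape(shape)

    results: List[AnovaResult] = []
    factor_axes = {name: i + 1 for i, name in enumerate(within)}
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            axes = tuple(factor_axes[f] for f in combo)
            eff = _pure_effect(Y, axes)
            err = _pure_effect(Y, (0, *axes))
            n_cells_eff = int(np.prod([shape[a] for a in axes]))
            ss_eff = float((eff**2).sum()) * Y.size / eff.size
            ss_err = float((err**2).sum()) * Y.size / err.size
            df_eff = int(np.prod([shape[a] - 1 for a in axes]))
            df_err = (n_subj - 1) * df_eff
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            if ms_err <= 0:
                F = 0.0 if ms_eff <= 0 else np.inf
            else:
                F = ms_eff / ms_err
            p = float(sstats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
            eps = p_gg = None
            if correction:
                eps = _gg_epsilon(Y, axes, n_cells_eff)
                p_gg = float(sstats.f.sf(F, df_eff * eps, df_err * eps))
            results.append(
                AnovaResult(
                    effect=" x ".join(combo),
                    F=float(max(F, 0.0)),
                    df=(df_eff, df_err),
                    p=min(max(p, 0.0), 1.0),
                    gg_epsilon=eps,
                    p_gg=p_gg,
                )
            )
    return results


def _gg_epsilon(Y: np.ndarray, axes: Tuple[int, ...], n_cells: int) -> float:
    """Greenhouse–Geisser epsilon for one within-subject effect."""
    other = tuple(a for a in range(1, Y.ndim) if a not in axes)
    M = Y.mean(axis=other) if other else Y
    M = M.reshape(M.shape[0], -1)  # subjects x effect cells
    k = M.shape[1]
    S = np.cov(M, rowvar=False)
    # double-centre the covariance matrix
    Sc = S - S.mean(0, keepdims=True) - S.mean(1, keepdims=True) + S.mean()
    num = (np.trace(Sc)) ** 2
    den = (k - 1) * float((Sc**2).sum())
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> Dict[str, float]:
    """Two-sided paired t test.

    Returns a dict with t, df, p and a ``degenerate`` flag set when the
    differences have zero variance (t is 0 or infinite by convention).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return {"t": 0.0, "df": len(d) - 1, "p": 1.0, "degenerate": True}
        return {
            "t": float(np.inf) * np.sign(d.mean()),
            "df": len(d) - 1,
            "p": 0.0,
            "degenerate": True,
        }
    t, p = sstats.ttest_rel(a, b)
    return {"t": float(t), "df": len(d) - 1, "p": float(p), "degenerate": False}


def anova_table(results: List[AnovaResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of AnovaResult."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df_num": r.df[0],
                "df_den": r.df[1],
                "p": r.p,
                "gg_epsilon": r.gg_epsilon,
                "p_gg": r.p_gg,
            }
            for r in results
        ]
    )
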