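"""Target confusability competition (TCC) modelling.

The TCC model treats continuous recall as a signal-detection race: every
value on the response wheel is a channel whose familiarity signal is
``d' * f(offset to target)`` plus unit-variance Gaussian noise, where
``f`` is a psychophysical similarity function measured independently
with Likert ratings and normalized to [0, 1] via
``f = (S - Smin) / (Smax - Smin)`` with Smin = 1, Smax = 7.  The
response is the channel with the maximal signal, so memory strength is
summarized by the single parameter ``d'``.  The "TCC plus" variant adds
a swap component: with probability ``pSwap`` the race is centred on a
nontarget instead of the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .circular import MAX_DIST, signed_error
from .config import LIKERT_OFFSETS

LIKERT_MIN, LIKERT_MAX = 1.0, 7.0
N_CHANNELS = 180  # response-wheel resolution shared by all domains
_Z_POINTS = 401  # trapezoid quadrature order over the decision axis


@dataclass
class SimilarityFunction:
    """Psychophysical similarity vs stimulus offset, normalized to [0, 1].

    ``offsets`` are in the domain's native units; internally they are
    rescaled so the largest sampled offset maps to the maximal distance
    (90) of the common 180-unit response space.
    """

    domain: str
    offsets: np.ndarray
    f: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.offsets.shape != self.f.shape:
            raise ValueError("offsets and f must have the same shape")
        order = np.argsort(self.offsets)
        self.offsets = self.offsets[order]
        self.f = self.f[order]
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("similarity values must lie in [0, 1]")
        if self.f[0] != self.f.max():
            raise ValueError("f(0) must be the maximum sampled value")

    def at_distance(self, dist_deg) -> np.ndarray:
        """Similarity at circular distances (degrees of the 180-space)."""
        scale = self.offsets.max() / MAX_DIST
        return np.clip(
            np.interp(np.asarray(dist_deg, float) * scale, self.offsets, self.f),
            0.0, 1.0,
        )

    def channel_values(self, m: int = N_CHANNELS) -> np.ndarray:
        """Similarity of each of m response channels to a target at channel 0."""
        k = np.arange(m)
        dist = np.minimum(k, m - k) * (180.0 / m)
        return self.at_distance(dist)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "f": self.f})


def estimate_similarity(
    likert: pd.DataFrame,
    domain: Optional[str] = None,
    isotonic: bool = False,
) -> SimilarityFunction:
    """Estimate the similarity function from Likert trials.

    Per trial, ``f = (rating - 1) / 6``; the function is the per-offset
    mean.  With ``isotonic=True`` a decreasing isotonic regression is
    applied (off by default).  Every offset of the domain's sampled set
    must be present; missing offsets raise with the list of gaps.
    """
    df = likert
    if domain is not None:
        df = df[df["domain"] == domain]
    else:
        doms = df["domain"].unique()
        if len(doms) != 1:
            raise ValueError(f"multiple domains present ({list(doms)}); pass domain=")
        domain = doms[0]
    if domain not in LIKERT_OFFSETS:
        raise ValueError(f"unknown domain {domain!r}")

    expected = np.asarray(LIKERT_OFFSETS[domain], dtype=float)
    ratings = df["rating"].to_numpy(dtype=float)
    if np.any((ratings < LIKERT_MIN) | (ratings > LIKERT_MAX)):
        raise ValueError("ratings must lie in 1..7")
    per_trial_f = (ratings - LIKERT_MIN) / (LIKERT_MAX - LIKERT_MIN)
    grouped = (
        pd.DataFrame({"offset": df["offset"].to_numpy(dtype=float), "f": per_trial_f})
        .groupby("offset")["f"]
        .mean()
    )
    missing = sorted(set(expected) - set(grouped.index))
    if missing:
        raise ValueError(f"missing Likert offsets for {domain}: {missing}")
    f = grouped.reindex(expected).to_numpy()
    if isotonic:
        iso = optimize.isotonic_regression(f, increasing=False)
        f = np.asarray(iso.x)
    return SimilarityFunction(
        domain=domain, offsets=expected, f=np.clip(f, 0.0, 1.0),
        interpolation="linear+isotonic" if isotonic else "linear",
    )


def tcc_response_pmf(
    dprime: float, sim: SimilarityFunction, m: int = N_CHANNELS
) -> np.ndarray:
    """Probability of choosing each response channel given a target at channel 0.

    Implements the max-signal rule with independent unit-variance channel
    noise:  P(x) = ∫ φ(z − d'f_x) Π_{y≠x} Φ(z − d'f_y) dz, evaluated by
    fixed-order trapezoid quadrature over z ∈ [−8, 8 + d'].
    """
    if dprime < 0:
        raise ValueError("dprime must be >= 0")
    if m < 2:
        raise ValueError("need at least 2 channels")
    f = sim.channel_values(m)
    z = np.linspace(-8.0, 8.0 + dprime, _Z_POINTS)
    zc = z[:, None] - dprime * f[None, :]
    logcdf = stats.norm.logcdf(zc)
    logpdf = stats.norm.logpdf(zc)
    total = logcdf.sum(axis=1)
    integrand = np.exp(logpdf + total[:, None] - logcdf)
    pmf = integrate.trapezoid(integrand, z, axis=0)
    if abs(pmf.sum() - 1.0) > 1e-6:
        raise RuntimeError(f"quadrature failure: pmf sums to {pmf.sum():.8f}")
    return pmf


def _response_channel(response_deg, reference_deg, m: int) -> np.ndarray:
    """Channel index of a response relative to a reference value."""
    err = signed_error(response_deg, reference_deg)
    return np.round(err / (180.0 / m)).astype(int) % m


@dataclass
class TCCResults:
    """Fitted TCC parameters with likelihood and convergence diagnostics."""

    dprime: float
    loglik: float
    converged: bool
    n_trials: int
    swap_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dprime < 0:
            raise ValueError("dprime must be >= 0")
        if self.swap_prob is not None and not 0.0 <= self.swap_prob <= 1.0:
            raise ValueError("swap_prob outside [0, 1]")

    @property
    def params(self) -> Dict[str, float]:
        out = {"dprime": self.dprime}
        if self.swap_prob is not None:
            out["swap_prob"] = self.swap_prob
        return out

    def summary(self) -> str:
        kind = "TCC plus" if self.swap_prob is not None else "TCC"
        lines = [
            f"{kind} model of delayed-estimation responses",
            f"  trials: {self.n_trials}   log-likelihood: {self.loglik:.3f}"
            f"   converged: {self.converged}",
            f"  d'        {self.dprime:8.4f}",
        ]
        if self.swap_prob is not None:
            lines.append(f"  pSwap     {self.swap_prob:8.4f}")
        return "\n".join(lines)


class TCCModel:
    """Single-parameter TCC fit: MLE of d' given a similarity function."""

    def __init__(
        self,
        trials: pd.DataFrame,
        sim: SimilarityFunction,
        m: int = N_CHANNELS,
        dprime_bounds: tuple = (0.0, 6.0),
    ):
        if len(trials) < 50:
            raise ValueError("need at least 50 trials")
        self.trials = trials.reset_index(drop=True)
        self.sim = sim
        self.m = m
        self.dprime_bounds = dprime_bounds
        idx = _response_channel(
            self.trials["response_deg"].to_numpy(dtype=float),
            self.trials["target_deg"].to_numpy(dtype=float),
            m,
        )
        self._counts = np.bincount(idx, minlength=m)
        self.nobs = len(self.trials)

    def loglike(self, dprime: float) -> float:
        pmf = tcc_response_pmf(dprime, self.sim, self.m)
        with np.errstate(divide="ignore"):
            lp = np.log(pmf)
        ll = float(np.dot(self._counts, lp))
        if not np.isfinite(ll):
            raise RuntimeError("non-finite TCC log-likelihood")
        return ll

    def fit(self) -> TCCResults:
        lo, hi = self.dprime_bounds
        res = optimize.minimize_scalar(
            lambda d: -self.loglike(d), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        d = float(res.x)
        at_bound = d <= lo + 1e-3 or d >= hi - 1e-3
        return TCCResults(
            dprime=d, loglik=-float(res.fun),
            converged=bool(res.success) and not at_bound, n_trials=self.nobs,
        )


class TCCPlusModel:
    """TCC with a swap component: joint MLE of (d', pSwap) on 3-item trials.

    The response pmf is a mixture of races centred on the target and on
    each nontarget: (1 − pSwap)·pmf(target) + pSwap·mean_j pmf(nontarget_j).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        sim: SimilarityFunction,
        m: int = N_CHANNELS,
        dprime_bounds: tuple = (0.0, 6.0),
    ):
        if len(trials) < 50:
            raise ValueError("need at least 50 trials")
        nt_cols = sorted(
            c for c in trials.columns if c.startswith("nontarget") and c.endswith("_deg")
        )
        if len(nt_cols) != 2 or trials[nt_cols].isna().any().any():
            raise ValueError("TCC plus requires exactly 2 nontargets per trial")
        self.trials = trials.reset_index(drop=True)
        self.sim = sim
        self.m = m
        self.dprime_bounds = dprime_bounds
        resp = self.trials["response_deg"].to_numpy(dtype=float)
        targ = self.trials["target_deg"].to_numpy(dtype=float)
        self._idx_t = _response_channel(resp, targ, m)
        self._idx_n = np.stack(
            [_response_channel(resp, self.trials[c].to_numpy(dtype=float), m)
             for c in nt_cols],
            axis=1,
        )
        # nontargets coincident with the target make pSwap unidentifiable
        nt_dist = np.abs(
            signed_error(self.trials[nt_cols].to_numpy(dtype=float), targ[:, None])
        )
        self._identifiable = bool(nt_dist.max() > 1e-6)
        self.nobs = len(self.trials)

    def loglike(self, dprime: float, swap_prob: float) -> float:
        pmf = tcc_response_pmf(dprime, self.sim, self.m)
        p = (1.0 - swap_prob) * pmf[self._idx_t] + swap_prob * pmf[self._idx_n].mean(
            axis=1
        )
        with np.errstate(divide="ignore"):
            ll = float(np.log(p).sum())
        if not np.isfinite(ll):
            raise RuntimeError("non-finite TCC-plus log-likelihood")
        return ll

    def fit(self) -> TCCResults:
        lo, hi = self.dprime_bounds

        def nll(x):
            try:
                return -self.loglike(float(x[0]), float(x[1]))
            except RuntimeError:
                return np.inf

        best = None
        for d0, s0 in ((2.0, 0.1), (1.0, 0.3), (3.0, 0.05)):
            res = optimize.minimize(
                nll, np.array([d0, s0]), method="L-BFGS-B",
                bounds=[(lo, hi), (0.0, 1.0)],
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("TCC-plus optimization failed")
        d, ps = float(best.x[0]), float(best.x[1])
        at_bound = d <= lo + 1e-3 or d >= hi - 1e-3
        return TCCResults(
            dprime=d, swap_prob=ps, loglik=-float(best.fun),
            converged=bool(best.success) and not at_bound and self._identifiable,
            n_trials=self.nobs,
        )


def fit_tcc(trials: pd.DataFrame, sim: SimilarityFunction, **kw) -> TCCResults:
    """Convenience wrapper: ``TCCModel(trials, sim).fit()``."""
    return TCCModel(trials, sim, **kw).fit()


def fit_tcc_plus(trials: pd.DataFrame, sim: SimilarityFunction, **kw) -> TCCResults:
    """Convenience wrapper: ``TCCPlusModel(trials, sim).fit()``."""
    return TCCPlusModel(trials, sim, **kw).fit()


def simulate_tcc_responses(
    dprime: float,
    sim: SimilarityFunction,
    targets_deg: Sequence[float],
    rng: np.random.Generator,
    nontargets_deg: Optional[np.ndarray] = None,
    swap_prob: float = 0.0,
    m: int = N_CHANNELS,
) -> np.ndarray:
    """Draw responses from the TCC (or TCC-plus) generative model.

    Each response is a channel drawn from the max-rule pmf centred on
    the target, or — with probability ``swap_prob`` — on a random
    nontarget.  Returns response values in degrees of the 180-space.
    """
    targets = np.asarray(targets_deg, dtype=float)
    pmf = tcc_response_pmf(dprime, sim, m)
    offs = rng.choice(m, size=len(targets), p=pmf / pmf.sum())
    centre = targets.copy()
    if swap_prob > 0:
        if nontargets_deg is None:
            raise ValueError("swap_prob > 0 requires nontargets")
        nts = np.asarray(nontargets_deg, dtype=float)
        swap = rng.random(len(targets)) < swap_prob
        which = rng.integers(0, nts.shape[1], size=len(targets))
        centre[swap] = nts[np.arange(len(targets)), which][swap]
    return np.mod(centre + offs * (180.0 / m), 180.0)
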