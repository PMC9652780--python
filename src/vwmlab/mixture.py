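"""Mixture modelling of delayed-estimation responses.

The error distribution of continuous recall on a 180-degree feature
space is decomposed into up to three components:

* target recall with probability ``pT`` and von Mises precision
  ``kappa`` (concentration on the doubled, 360-degree circle),
* nontarget ("swap") responses with probability ``pN``, sharing the
  same precision, with mass split equally over the nontargets,
* uniform guessing with probability ``pU = 1 - pT - pN``.

Densities are expressed per degree on the doubled circle, so the
uniform component has density 1/360 and a model with ``kappa = 0``
coincides with pure guessing.  Fitting is maximum likelihood with a
softmax parameterization of the mixture weights (the simplex constraint
is exact) and log-parameterized kappa, refined over seeded random
restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .circular import signed_error

KAPPA_MAX = 1e4
_LOG_360 = np.log(360.0)


def _log_i0(kappa):
    """log of the modified Bessel function I0, stable for large kappa."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.ive(0, kappa)) + kappa


def vm_logpdf_deg(err_deg, kappa: float):
    """Log density (per degree) of a signed 180-space error under von Mises
    noise with concentration ``kappa`` on the doubled circle."""
    ang = np.deg2rad(2.0 * np.asarray(err_deg, dtype=float))
    return kappa * np.cos(ang) - _LOG_360 - _log_i0(kappa)


def _nontarget_matrix(trials: pd.DataFrame) -> Optional[np.ndarray]:
    """(n, m) nontarget angles or None if the trials have no nontargets."""
    cols = [c for c in trials.columns if c.startswith("nontarget") and c.endswith("_deg")]
    if cols:
        mat = trials[sorted(cols)].to_numpy(dtype=float)
        if np.isnan(mat).all():
            return None
        return mat
    if "nontargets_deg" in trials.columns:
        lists = trials["nontargets_deg"].tolist()
        if all(len(v) == 0 for v in lists):
            return None
        return np.asarray(lists, dtype=float)
    return None


def mixture_loglik(params: Sequence[float], trials: pd.DataFrame) -> float:
    """Log-likelihood (nats) of (pT, pN, pU, kappa) for a table of recall trials.

    Trials supply ``target_deg``, ``response_deg`` and, for trial types
    with nontargets, ``nontarget1_deg``/``nontarget2_deg`` columns.  A
    nonzero ``pN`` on trials without nontargets is an error.
    """
    pT, pN, pU, kappa = (float(v) for v in params)
    for name, p in (("pT", pT), ("pN", pN), ("pU", pU)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if abs(pT + pN + pU - 1.0) > 1e-8:
        raise ValueError("mixture weights must sum to 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")

    err_t = signed_error(trials["response_deg"].to_numpy(dtype=float),
                         trials["target_deg"].to_numpy(dtype=float))
    nt = _nontarget_matrix(trials)
    if pN > 0 and (nt is None or np.isnan(nt).any()):
        raise ValueError("pN > 0 requested for trials without nontargets")

    # log-sum-exp over components, all densities per degree on the doubled circle
    parts = []
    with np.errstate(divide="ignore"):
        if pT > 0:
            parts.append(np.log(pT) + vm_logpdf_deg(err_t, kappa))
        if pN > 0 and nt is not None:
            m = nt.shape[1]
            err_n = signed_error(
                trials["response_deg"].to_numpy(dtype=float)[:, None], nt
            )
            comp = special.logsumexp(vm_logpdf_deg(err_n, kappa), axis=1)
            parts.append(np.log(pN / m) + comp)
        if pU > 0:
            parts.append(np.full(len(trials), np.log(pU) - _LOG_360))
    if not parts:
        raise ValueError("all mixture weights zero")
    ll = special.logsumexp(np.stack(parts, axis=0), axis=0)
    return float(ll.sum())


def _unpack(theta: np.ndarray, n_components: int):
    if n_components == 3:
        a = np.array([theta[0], theta[1], 0.0])
        kappa = float(np.exp(theta[2]))
    else:
        a = np.array([theta[0], -np.inf, 0.0])
        kappa = float(np.exp(theta[1]))
    w = np.exp(a - special.logsumexp(a))
    return float(w[0]), float(w[1]), float(w[2]), min(kappa, KAPPA_MAX)


@dataclass
class MixtureResults:
    """Fitted mixture parameters with likelihood and convergence diagnostics."""

    pT: float
    pN: float
    pU: float
    kappa: float
    loglik: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    n_components: int
    bse: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.pT + self.pN + self.pU - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1 within 1e-8")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    @property
    def params(self) -> Dict[str, float]:
        return {"pT": self.pT, "pN": self.pN, "pU": self.pU, "kappa": self.kappa}

    def summary(self) -> str:
        lines = [
            "Mixture model of delayed-estimation responses",
            f"  components: {self.n_components}   trials: {self.n_trials}",
            f"  log-likelihood: {self.loglik:.3f}   converged: {self.converged}",
            f"  restarts used: {self.n_restarts_used}",
            "  parameter   estimate      se",
        ]
        for name, val in self.params.items():
            se = self.bse.get(name, np.nan)
            lines.append(f"  {name:<10}  {val:8.4f}  {se:6.4f}" if np.isfinite(se)
                         else f"  {name:<10}  {val:8.4f}       -")
        return "\n".join(lines)


class MixtureModel:
    """Maximum-likelihood mixture model of recall errors.

    Parameters
    ----------
    trials : DataFrame
        Recall trials with target_deg, response_deg and (for 3-component
        fits) nontarget angle columns.
    n_components : {2, 3}
        2 = target + guess; 3 = target + swap + guess.  The 3-component
        model requires trials with nontargets.
    """

    def __init__(self, trials: pd.DataFrame, n_components: int = 3):
        if n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if len(trials) < 20:
            raise ValueError("need at least 20 trials")
        nt = _nontarget_matrix(trials)
        if n_components == 3 and (nt is None or np.isnan(nt).any()):
            raise ValueError("3-component model requires trials with nontargets")
        self.trials = trials.reset_index(drop=True)
        self.n_components = n_components
        self.nobs = len(self.trials)

    def loglike(self, params: Sequence[float]) -> float:
        return mixture_loglik(params, self.trials)

    def _neg_loglik(self, theta: np.ndarray) -> float:
        pT, pN, pU, kappa = _unpack(theta, self.n_components)
        try:
            nll = -mixture_loglik((pT, pN, pU, kappa), self.trials)
        except (ValueError, FloatingPointError):
            return np.inf
        return nll if np.isfinite(nll) else np.inf

    def _moment_start(self) -> np.ndarray:
        """Data-driven initial point: circular resultant of doubled errors."""
        err = signed_error(self.trials["response_deg"], self.trials["target_deg"])
        ang = np.deg2rad(2.0 * err)
        r = float(np.hypot(np.mean(np.cos(ang)), np.mean(np.sin(ang))))
        r = min(max(r, 1e-3), 0.999)
        # A^-1(r) approximation for the vM concentration (Fisher 1993)
        if r < 0.53:
            kappa = 2 * r + r**3 + 5 * r**5 / 6
        elif r < 0.85:
            kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
        else:
            kappa = 1 / (r**3 - 4 * r**2 + 3 * r)
        if self.n_components == 3:
            return np.array([1.0, -1.0, np.log(max(kappa, 0.5))])
        return np.array([1.0, np.log(max(kappa, 0.5))])

    def fit(self, restarts: int = 20, seed: int = 0) -> MixtureResults:
        """Fit by bounded multi-start L-BFGS-B; deterministic given seed."""
        rng = np.random.default_rng(seed)
        ndim = 3 if self.n_components == 3 else 2
        bounds = [(-20.0, 20.0)] * (ndim - 1) + [(np.log(1e-3), np.log(KAPPA_MAX))]
        starts = [self._moment_start()]
        for _ in range(max(restarts - 1, 0)):
            theta = np.concatenate(
                [rng.normal(0.0, 2.0, size=ndim - 1), [rng.normal(np.log(8.0), 1.0)]]
            )
            starts.append(theta)

        best = None
        failures = []
        for theta0 in starts:
            res = optimize.minimize(
                self._neg_loglik, theta0, method="L-BFGS-B", bounds=bounds
            )
            if not np.isfinite(res.fun):
                failures.append(res.message)
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(f"all restarts failed: {failures}")

        pT, pN, pU, kappa = _unpack(best.x, self.n_components)
        at_kappa_bound = best.x[-1] >= np.log(KAPPA_MAX) - 1e-3
        converged = bool(best.success) and not at_kappa_bound
        bse = self._standard_errors(best.x)
        return MixtureResults(
            pT=pT, pN=pN, pU=pU, kappa=kappa,
            loglik=-float(best.fun), n_trials=self.nobs,
            converged=converged, n_restarts_used=len(starts),
            n_components=self.n_components, bse=bse,
        )

    def _standard_errors(self, theta: np.ndarray) -> Dict[str, float]:
        """Delta-method SEs from a finite-difference Hessian; NaN on failure."""
        try:
            h = 1e-4
            n = len(theta)
            hess = np.empty((n, n))
            f0 = self._neg_loglik(theta)
            for i in range(n):
                for j in range(i, n):
                    ei = np.eye(n)[i] * h
                    ej = np.eye(n)[j] * h
                    fij = self._neg_loglik(theta + ei + ej)
                    fi = self._neg_loglik(theta + ei)
                    fj = self._neg_loglik(theta + ej)
                    hess[i, j] = hess[j, i] = (fij - fi - fj + f0) / h**2
            cov = np.linalg.inv(hess)
            # jacobian of (pT, pN, pU, kappa) wrt theta
            names = ["pT", "pN", "pU", "kappa"]
            jac = np.empty((4, n))
            for j in range(n):
                up = np.array(_unpack(theta + np.eye(n)[j] * h, self.n_components))
                dn = np.array(_unpack(theta - np.eye(n)[j] * h, self.n_components))
                jac[:, j] = (up - dn) / (2 * h)
            var = np.einsum("ij,jk,ik->i", jac, cov, jac)
            return {nm: float(np.sqrt(v)) if v > 0 else np.nan
                    for nm, v in zip(names, var)}
        except np.linalg.LinAlgError:
            return {}


def fit_mixture(
    trials: pd.DataFrame, n_components: int = 3, restarts: int = 20, seed: int = 0
) -> MixtureResults:
    """Convenience wrapper: ``MixtureModel(trials, n_components).fit(...)``."""
    return MixtureModel(trials, n_components=n_components).fit(
        restarts=restarts, seed=seed
    )


def swap_rate_test(pn_values: Sequence[float]) -> Dict[str, object]:
    """Test whether per-subject swap rates (pN) exceed zero.

    Reports a one-sample t test and a Wilcoxon signed-rank test against
    zero, plus a Shapiro–Wilk normality check on the pN distribution;
    the headline test is the Wilcoxon when normality is rejected
    (p < .05), the t test otherwise.
    """
    pn = np.asarray(pn_values, dtype=float)
    if len(pn) < 5:
        raise ValueError("need at least 5 subjects")
    t_stat, t_p = stats.ttest_1samp(pn, 0.0, alternative="greater")
    sw_stat, sw_p = stats.shapiro(pn) if len(np.unique(pn)) > 1 else (np.nan, np.nan)

    if np.all(pn == 0):
        wilcoxon = {"z": np.nan, "p": np.nan, "degenerate": True}
    else:
        res = stats.wilcoxon(pn, alternative="greater", method="approx")
        wilcoxon = {
            "z": float(res.zstatistic), "p": float(res.pvalue), "degenerate": False,
        }
    normal = bool(np.isfinite(sw_p) and sw_p >= 0.05)
    headline = "t" if normal or wilcoxon["degenerate"] else "wilcoxon"
    return {
        "n": len(pn),
        "mean_pn": float(pn.mean()),
        "t": float(t_stat),
        "t_p": float(t_p),
        "shapiro_p": float(sw_p) if np.isfinite(sw_p) else np.nan,
        "wilcoxon": wilcoxon,
        "headline": headline,
        "significant": bool(
            (wilcoxon["p"] < 0.05) if headline == "wilcoxon" else (t_p < 0.05)
        ),
    }
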