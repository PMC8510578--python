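"""Maximum-likelihood competition between graded, quantized, and all-or-none
learning models.

Each larva contributes one observation: the fraction ``p`` of its ``n``
post-training decisions that were approaches, grouped by training dose
``n_c``.  The binomial counting noise of a mean of ``n`` correlated binary
choices is approximated by a Gaussian with variance

    sigma^2 = sigma_tilde^2 * p_bar * (1 - p_bar) / n

where ``sigma_tilde`` is a global scale absorbing the (negative) serial
correlation of successive choices (``sigma_tilde < 1`` when consecutive
choices anti-correlate).  Five model variants compete:

=====================  =============================================  ========
name                   population density of p at dose n_c            k (8 doses)
=====================  =============================================  ========
shifting_mean          N(mu(n_c), binomial-scaled, global s~)          9
graded                 N(mu(n_c), sigma(n_c)/sqrt(n))                  16
quantized              f_u(n_c) N(mu_u) + (1-f_u(n_c)) N(mu_t)         11
three_cluster          three fixed means, per-dose simplex weights     20
all_or_none            quantized with f_u(n_c) = lambda**n_c           4
=====================  =============================================  ========

The all-or-none model is the memoryless hypothesis: every training cycle
converts a fixed fraction ``1 - lambda`` of the remaining untrained larvae,
so the untrained fraction decays exponentially with dose.  Models are ranked
by AIC and BIC; the trained fraction at each dose carries a
profile-likelihood interval defined by a half-unit log-likelihood drop.

Estimators follow the scikit-learn convention: hyper-parameters in
``__init__``, data only in :meth:`fit`, fitted attributes with a trailing
underscore, ``score_samples`` returning per-larva log densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, logsumexp
from sklearn.base import BaseEstimator

from .data import ExperimentGroup, Phase

__all__ = [
    "gaussian_density",
    "variance_model",
    "preference_table",
    "LearningCurveModel",
    "ShiftingMeanModel",
    "GradedLearningModel",
    "QuantizedLearningModel",
    "ThreeClusterModel",
    "AllOrNoneModel",
    "MODEL_REGISTRY",
    "fit_model",
    "log_likelihood",
    "compare_models",
    "TrainedFractionEstimate",
    "trained_fraction",
    "untrained_fraction_curve",
]

VAR_FLOOR = 1e-6  # keeps densities finite when a proposed mean hits 0 or 1
_FCLIP = 1e-4  # fraction clip when mapping to/from logit scale


def gaussian_density(x, mu, sigma):
    """Untruncated normal density; the likelihood building block."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / np.sqrt(2.0 * math.pi * sigma**2)


def variance_model(p_bar, n, sigma_tilde: float, floor: float = VAR_FLOOR):
    """Serial-correlation-adjusted counting variance of a mean of ``n``
    choices: ``sigma_tilde**2 * p_bar * (1 - p_bar) / n``, floored."""
    p_bar = np.asarray(p_bar, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("decision count n must be >= 1")
    if np.any((p_bar < 0) | (p_bar > 1)):
        raise ValueError("p_bar must lie in [0, 1]")
    return np.maximum(sigma_tilde**2 * p_bar * (1.0 - p_bar) / n, floor)


def preference_table(
    groups, phase: Phase = Phase.POST, include_pre: bool = False
) -> pd.DataFrame:
    """Build the model input: one row per larva with columns
    ``dose`` (training cycles), ``p`` (approach fraction), ``n`` (decisions).
    Larvae with no decisions in the phase are excluded (they carry no
    likelihood weight).  With ``include_pre`` the PRE phase enters as extra
    dose-0 observations."""
    rows = []
    for g in groups:
        for rec in g.larvae:
            a, v = rec.phase_counts(phase)
            if a + v >= 1:
                rows.append({"dose": rec.n_cycles, "p": a / (a + v), "n": a + v})
            if include_pre:
                a0, v0 = rec.phase_counts(Phase.PRE)
                if a0 + v0 >= 1:
                    rows.append({"dose": 0, "p": a0 / (a0 + v0), "n": a0 + v0})
    return pd.DataFrame(rows, columns=["dose", "p", "n"])


def _as_arrays(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Validate input and return (dose_levels, dose_idx, p, n)."""
    if isinstance(X, pd.DataFrame):
        dose = X["dose"].to_numpy(dtype=float)
        p = X["p"].to_numpy(dtype=float)
        n = X["n"].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("X must be a (dose, p, n) DataFrame or an (N, 3) array")
        dose, p, n = arr[:, 0], arr[:, 1], arr[:, 2]
    if len(p) < 2:
        raise ValueError("need at least 2 larvae to fit")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("preferences p must lie in [0, 1]")
    if np.any(n < 1):
        raise ValueError("larvae with n = 0 must be excluded before fitting")
    levels = np.unique(dose)
    idx = np.searchsorted(levels, dose)
    return levels, idx, p, n


def _log_norm(p, mu, var):
    return -0.5 * np.log(2.0 * math.pi * var) - (p - mu) ** 2 / (2.0 * var)


def _pclip(f):
    return np.clip(f, _FCLIP, 1.0 - _FCLIP)


@dataclass(frozen=True)
class TrainedFractionEstimate:
    """Best-fit trained fraction with its half-unit profile interval."""

    f0: float
    lo: float
    hi: float
    loglik_at_f0: float


class LearningCurveModel(BaseEstimator):
    """Base class: multi-start box-constrained maximum likelihood on an
    unconstrained reparameterization (logit for probabilities and mixture
    fractions, log for scales)."""

    model_name: str = ""

    def __init__(self, n_starts: int = 20, random_state: int = 0, tol: float = 1e-8,
                 max_iter: int = 1000):
        self.n_starts = n_starts
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    # -- per-model interface -------------------------------------------------
    def _n_params(self, n_doses: int) -> int:
        raise NotImplementedError

    def _unpack(self, z: np.ndarray, levels: np.ndarray) -> dict:
        raise NotImplementedError

    def _pack(self, theta: dict, levels: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _loglik_terms(self, theta: dict, levels, idx, p, n) -> np.ndarray:
        """Per-observation log density."""
        raise NotImplementedError

    def _heuristic_theta(self, levels, idx, p, n) -> dict:
        raise NotImplementedError

    def _validate_theta(self, theta: dict, levels: np.ndarray) -> None:
        raise NotImplementedError

    # -- shared machinery ----------------------------------------------------
    def log_likelihood(self, X, theta: dict) -> float:
        levels, idx, p, n = _as_arrays(X)
        self._validate_theta(theta, levels)
        return float(self._loglik_terms(theta, levels, idx, p, n).sum())

    def fit(self, X, y=None, extra_starts: list[dict] | None = None):
        """Maximize the log-likelihood over multiple starts.

        ``extra_starts`` may carry additional full parameter dictionaries
        (e.g. the embedded optimum of a nested model) used as warm starts.
        """
        levels, idx, p, n = _as_arrays(X)
        rng = np.random.default_rng(self.random_state)

        starts = [self._pack(self._heuristic_theta(levels, idx, p, n), levels)]
        for theta in extra_starts or []:
            starts.append(self._pack(theta, levels))
        dim = len(starts[0])
        base = starts[0]
        for _ in range(self.n_starts):
            starts.append(base + rng.normal(0.0, 1.5, size=dim))

        def nll(z):
            th = self._unpack(z, levels)
            val = self._loglik_terms(th, levels, idx, p, n).sum()
            return -val if np.isfinite(val) else 1e12

        best = None
        n_converged = 0
        for z0 in starts:
            res = optimize.minimize(
                nll, z0, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol},
            )
            if not np.isfinite(res.fun):
                continue
            n_converged += int(res.success)
            if best is None or res.fun < best.fun - 1e-10 or (
                abs(res.fun - best.fun) <= 1e-10
                and tuple(self._unpack(res.x, levels).items()) < tuple(
                    self._unpack(best.x, levels).items())
            ):
                best = res
        if best is None:
            raise RuntimeError(f"{self.model_name}: no start produced a finite optimum")

        self.dose_levels_ = levels
        self.theta_ = self._unpack(best.x, levels)
        self.loglik_ = float(-best.fun)
        self.k_ = self._n_params(len(levels))
        self.n_obs_ = len(p)
        self.aic_ = 2.0 * self.k_ - 2.0 * self.loglik_
        self.bic_ = self.k_ * math.log(self.n_obs_) - 2.0 * self.loglik_
        self.converged_ = n_converged > 0
        self.n_starts_ = len(starts)
        return self

    def score_samples(self, X) -> np.ndarray:
        levels, idx, p, n = _as_arrays(X)
        return self._loglik_terms(self.theta_, levels, idx, p, n)

    def score(self, X, y=None) -> float:
        """Mean per-larva log density under the fitted parameters."""
        return float(np.mean(self.score_samples(X)))


def _check_prob(name, v):
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name}={v} outside [0, 1]")


class ShiftingMeanModel(LearningCurveModel):
    """Single Gaussian per dose with a shared variance scale: the mean shifts
    with training but the population stays unimodal."""

    model_name = "shifting_mean"

    def _n_params(self, d):
        return d + 1

    def _unpack(self, z, levels):
        return {"mu": tuple(expit(z[:-1])), "sigma_tilde": float(np.exp(z[-1]))}

    def _pack(self, theta, levels):
        return np.concatenate([logit(_pclip(np.asarray(theta["mu"]))),
                               [math.log(theta["sigma_tilde"])]])

    def _validate_theta(self, theta, levels):
        for m in theta["mu"]:
            _check_prob("mu", m)
        if theta["sigma_tilde"] <= 0:
            raise ValueError("sigma_tilde must be positive")
        if len(theta["mu"]) != len(levels):
            raise ValueError("one mean per dose level required")

    def _loglik_terms(self, theta, levels, idx, p, n):
        mu = np.asarray(theta["mu"])[idx]
        var = variance_model(mu, n, theta["sigma_tilde"])
        return _log_norm(p, mu, var)

    def _heuristic_theta(self, levels, idx, p, n):
        mu = np.array([
            np.average(p[idx == i], weights=n[idx == i]) for i in range(len(levels))
        ])
        return {"mu": tuple(_pclip(mu)), "sigma_tilde": 1.0}


class GradedLearningModel(LearningCurveModel):
    """Graded learning: one Gaussian whose mean and spread are free functions
    of dose; every animal drifts with training."""

    model_name = "graded"

    def _n_params(self, d):
        return 2 * d

    def _unpack(self, z, levels):
        d = len(levels)
        return {"mu": tuple(expit(z[:d])), "sigma": tuple(np.exp(z[d:]))}

    def _pack(self, theta, levels):
        return np.concatenate([
            logit(_pclip(np.asarray(theta["mu"]))), np.log(np.asarray(theta["sigma"]))
        ])

    def _validate_theta(self, theta, levels):
        for m in theta["mu"]:
            _check_prob("mu", m)
        if any(s <= 0 for s in theta["sigma"]):
            raise ValueError("sigma must be positive")
        if len(theta["mu"]) != len(levels) or len(theta["sigma"]) != len(levels):
            raise ValueError("one (mu, sigma) pair per dose level required")

    def _loglik_terms(self, theta, levels, idx, p, n):
        mu = np.asarray(theta["mu"])[idx]
        sig = np.asarray(theta["sigma"])[idx]
        var = np.maximum(sig**2 / n, VAR_FLOOR)
        return _log_norm(p, mu, var)

    def _heuristic_theta(self, levels, idx, p, n):
        # per-dose closed-form MLE of (mu, sigma)
        mu, sig = [], []
        for i in range(len(levels)):
            sel = idx == i
            m = np.average(p[sel], weights=n[sel])
            s2 = np.mean(n[sel] * (p[sel] - m) ** 2)
            mu.append(m)
            sig.append(math.sqrt(max(s2, 1e-4)))
        return {"mu": tuple(_pclip(np.array(mu))), "sigma": tuple(sig)}


class QuantizedLearningModel(LearningCurveModel):
    """Quantized learning: two fixed behavioral states (untrained mean
    ``mu_u``, trained mean ``mu_t``); training only moves the per-dose
    untrained weight ``f_u(n_c)``."""

    model_name = "quantized"

    def _n_params(self, d):
        return d + 3

    def _unpack(self, z, levels):
        return {
            "mu_u": float(expit(z[0])),
            "mu_t": float(expit(z[1])),
            "sigma_tilde": float(np.exp(z[2])),
            "f_u": tuple(expit(z[3:])),
        }

    def _pack(self, theta, levels):
        return np.concatenate([
            [logit(_pclip(theta["mu_u"])), logit(_pclip(theta["mu_t"])),
             math.log(theta["sigma_tilde"])],
            logit(_pclip(np.asarray(theta["f_u"]))),
        ])

    def _validate_theta(self, theta, levels):
        _check_prob("mu_u", theta["mu_u"])
        _check_prob("mu_t", theta["mu_t"])
        if theta["sigma_tilde"] <= 0:
            raise ValueError("sigma_tilde must be positive")
        for f in theta["f_u"]:
            _check_prob("f_u", f)
        if len(theta["f_u"]) != len(levels):
            raise ValueError("one f_u per dose level required")

    def _loglik_terms(self, theta, levels, idx, p, n):
        fu = np.asarray(theta["f_u"])[idx]
        lu = _log_norm(p, theta["mu_u"], variance_model(theta["mu_u"], n, theta["sigma_tilde"]))
        lt = _log_norm(p, theta["mu_t"], variance_model(theta["mu_t"], n, theta["sigma_tilde"]))
        with np.errstate(divide="ignore"):
            return logsumexp(
                np.stack([np.log(fu) + lu, np.log1p(-fu) + lt]), axis=0
            )

    def _heuristic_theta(self, levels, idx, p, n, split: float = 0.4):
        low, high = p < split, p >= split
        mu_u = np.average(p[low], weights=n[low]) if low.any() else p.min()
        mu_t = np.average(p[high], weights=n[high]) if high.any() else p.max()
        f_u = np.array([
            max((p[idx == i] < split).mean(), 1e-3) for i in range(len(levels))
        ])
        return {"mu_u": float(mu_u), "mu_t": float(mu_t), "sigma_tilde": 1.0,
                "f_u": tuple(_pclip(f_u))}


class ThreeClusterModel(LearningCurveModel):
    """Three fixed clusters with per-dose simplex weights — probes for an
    intermediate behavioral state between untrained and trained."""

    model_name = "three_cluster"

    def _n_params(self, d):
        return 2 * d + 4

    def _unpack(self, z, levels):
        # ordered means mu1 <= mu2 <= mu3 via stick-breaking in [0, 1]
        m1 = expit(z[0])
        m2 = m1 + (1.0 - m1) * expit(z[1])
        m3 = m2 + (1.0 - m2) * expit(z[2])
        d = len(levels)
        a = z[4:4 + d]
        b = z[4 + d:]
        shift = np.maximum(np.maximum(a, b), 0.0)  # stable simplex softmax
        ea, eb, e0 = np.exp(a - shift), np.exp(b - shift), np.exp(-shift)
        den = e0 + ea + eb
        return {
            "mu": (float(m1), float(m2), float(m3)),
            "sigma_tilde": float(np.exp(z[3])),
            "f1": tuple(ea / den),
            "f2": tuple(eb / den),
        }

    def _pack(self, theta, levels):
        m1, m2, m3 = theta["mu"]
        z1 = logit(_pclip(m1))
        z2 = logit(_pclip((m2 - m1) / max(1.0 - m1, 1e-9)))
        z3 = logit(_pclip((m3 - m2) / max(1.0 - m2, 1e-9)))
        f1 = _pclip(np.asarray(theta["f1"]))
        f2 = _pclip(np.asarray(theta["f2"]))
        f3 = np.maximum(1.0 - f1 - f2, _FCLIP)
        return np.concatenate([
            [z1, z2, z3, math.log(theta["sigma_tilde"])],
            np.log(f1 / f3), np.log(f2 / f3),
        ])

    def _validate_theta(self, theta, levels):
        for m in theta["mu"]:
            _check_prob("mu", m)
        if theta["sigma_tilde"] <= 0:
            raise ValueError("sigma_tilde must be positive")
        f1 = np.asarray(theta["f1"])
        f2 = np.asarray(theta["f2"])
        if np.any(f1 < 0) or np.any(f2 < 0) or np.any(f1 + f2 > 1.0 + 1e-9):
            raise ValueError("cluster weights must lie on the simplex")
        if len(f1) != len(levels) or len(f2) != len(levels):
            raise ValueError("one (f1, f2) pair per dose level required")

    def _loglik_terms(self, theta, levels, idx, p, n):
        st = theta["sigma_tilde"]
        f1 = np.asarray(theta["f1"])[idx]
        f2 = np.asarray(theta["f2"])[idx]
        f3 = np.maximum(1.0 - f1 - f2, 0.0)
        terms = []
        for mu, f in zip(theta["mu"], (f1, f2, f3)):
            lg = _log_norm(p, mu, variance_model(mu, n, st))
            with np.errstate(divide="ignore"):
                terms.append(np.where(f > 0, np.log(np.maximum(f, 1e-300)) + lg, -np.inf))
        return logsumexp(np.stack(terms), axis=0)

    def _heuristic_theta(self, levels, idx, p, n):
        q = QuantizedLearningModel()._heuristic_theta(levels, idx, p, n)
        lo, hi = sorted((q["mu_u"], q["mu_t"]))
        fu = np.asarray(q["f_u"])
        f1 = fu if q["mu_u"] <= q["mu_t"] else 1.0 - fu
        return {
            "mu": (lo, (lo + hi) / 2.0, hi),
            "sigma_tilde": 1.0,
            "f1": tuple(_pclip(f1 * (1 - 2 * _FCLIP))),
            "f2": tuple(np.full(len(levels), 2 * _FCLIP)),
        }


class AllOrNoneModel(LearningCurveModel):
    """All-or-none (memoryless, exponential-fraction) learning: the quantized
    model with the untrained weight constrained to ``lambda**n_c`` — each
    cycle trains a fixed fraction ``1 - lambda`` of untrained larvae."""

    model_name = "all_or_none"

    def _n_params(self, d):
        return 4

    def _unpack(self, z, levels):
        return {
            "mu_u": float(expit(z[0])),
            "mu_t": float(expit(z[1])),
            "sigma_tilde": float(np.exp(z[2])),
            "lam": float(expit(z[3])),
        }

    def _pack(self, theta, levels):
        return np.array([
            logit(_pclip(theta["mu_u"])), logit(_pclip(theta["mu_t"])),
            math.log(theta["sigma_tilde"]), logit(_pclip(theta["lam"])),
        ])

    def _validate_theta(self, theta, levels):
        _check_prob("mu_u", theta["mu_u"])
        _check_prob("mu_t", theta["mu_t"])
        _check_prob("lam", theta["lam"])
        if theta["sigma_tilde"] <= 0:
            raise ValueError("sigma_tilde must be positive")

    def untrained_fractions(self, levels=None) -> np.ndarray:
        levels = self.dose_levels_ if levels is None else np.asarray(levels)
        return self.theta_["lam"] ** levels

    def _loglik_terms(self, theta, levels, idx, p, n):
        fu = (theta["lam"] ** levels)[idx]
        lu = _log_norm(p, theta["mu_u"], variance_model(theta["mu_u"], n, theta["sigma_tilde"]))
        lt = _log_norm(p, theta["mu_t"], variance_model(theta["mu_t"], n, theta["sigma_tilde"]))
        with np.errstate(divide="ignore"):
            return logsumexp(
                np.stack([np.log(np.maximum(fu, 1e-300)) + lu,
                          np.log(np.maximum(1.0 - fu, 1e-300)) + lt]), axis=0
            )

    def _heuristic_theta(self, levels, idx, p, n, split: float = 0.4):
        q = QuantizedLearningModel()._heuristic_theta(levels, idx, p, n, split)
        fu = np.asarray(q["f_u"])
        pos = levels > 0
        lam = float(np.mean(fu[pos] ** (1.0 / levels[pos]))) if pos.any() else 0.5
        return {"mu_u": q["mu_u"], "mu_t": q["mu_t"], "sigma_tilde": 1.0,
                "lam": float(np.clip(lam, 0.05, 0.95))}


MODEL_REGISTRY: dict[str, type[LearningCurveModel]] = {
    cls.model_name: cls
    for cls in (ShiftingMeanModel, GradedLearningModel, QuantizedLearningModel,
                ThreeClusterModel, AllOrNoneModel)
}


def fit_model(X, name: str, **estimator_kwargs) -> LearningCurveModel:
    """Fit one named model variant and return the fitted estimator."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}")
    extra_starts = estimator_kwargs.pop("extra_starts", None)
    return cls(**estimator_kwargs).fit(X, extra_starts=extra_starts)


def log_likelihood(X, name: str, theta: dict) -> float:
    """Log-likelihood of the data under a named model at parameters ``theta``."""
    cls = MODEL_REGISTRY[name]
    return cls().log_likelihood(X, theta)


def _embed_aon_in_quantized(aon: AllOrNoneModel) -> dict:
    t = aon.theta_
    return {"mu_u": t["mu_u"], "mu_t": t["mu_t"], "sigma_tilde": t["sigma_tilde"],
            "f_u": tuple(aon.untrained_fractions())}


def _embed_quantized_in_three_cluster(q: QuantizedLearningModel) -> dict:
    t = q.theta_
    lo, hi = sorted((t["mu_u"], t["mu_t"]))
    fu = np.asarray(t["f_u"])
    f_low = fu if t["mu_u"] <= t["mu_t"] else 1.0 - fu
    return {
        "mu": (lo, (lo + hi) / 2.0, hi),
        "sigma_tilde": t["sigma_tilde"],
        "f1": tuple(np.clip(f_low, _FCLIP, 1 - 3 * _FCLIP)),
        "f2": tuple(np.full(len(fu), _FCLIP)),
    }


def compare_models(
    X, names: list[str] | None = None, **estimator_kwargs
) -> tuple[pd.DataFrame, dict[str, LearningCurveModel]]:
    """Fit several model variants and rank them.

    Nested pairs are warm-started from the embedded optimum of the smaller
    model (all_or_none -> quantized -> three_cluster), which enforces the
    nesting inequalities at the optimizer level.  Returns the comparison
    table (k, loglik, delta_logP relative to the best log-likelihood,
    delta_aic / delta_bic relative to the minima) and the fitted estimators.
    """
    names = list(names or MODEL_REGISTRY)
    if len(names) < 1:
        raise ValueError("at least one model required")
    fits: dict[str, LearningCurveModel] = {}
    errors: dict[str, str] = {}

    def _fit(name, extra=None):
        try:
            fits[name] = fit_model(X, name, extra_starts=extra, **estimator_kwargs)
        except Exception as exc:  # propagate per-row, keep other fits alive
            errors[name] = str(exc)

    for name in names:
        if name == "quantized":
            extra = []
            if "all_or_none" in fits:
                extra.append(_embed_aon_in_quantized(fits["all_or_none"]))
            _fit(name, extra)
        elif name == "three_cluster":
            extra = []
            if "quantized" in fits:
                extra.append(_embed_quantized_in_three_cluster(fits["quantized"]))
            _fit(name, extra)
        else:
            _fit(name)

    rows = []
    ll_best = max((f.loglik_ for f in fits.values()), default=math.nan)
    aic_min = min((f.aic_ for f in fits.values()), default=math.nan)
    bic_min = min((f.bic_ for f in fits.values()), default=math.nan)
    for name in names:
        if name in fits:
            f = fits[name]
            rows.append({
                "model": name, "k": f.k_, "loglik": f.loglik_,
                "delta_logP": f.loglik_ - ll_best,
                "delta_aic": f.aic_ - aic_min, "delta_bic": f.bic_ - bic_min,
                "converged": f.converged_, "error": "",
            })
        else:
            rows.append({"model": name, "k": np.nan, "loglik": np.nan,
                         "delta_logP": np.nan, "delta_aic": np.nan,
                         "delta_bic": np.nan, "converged": False,
                         "error": errors[name]})
    table = pd.DataFrame(rows)
    table["rank_bic"] = table["delta_bic"].rank(method="min")
    table["rank_aic"] = table["delta_aic"].rank(method="min")
    return table, fits


def _profile_loglik(f_t: float, log_nu: np.ndarray, log_nt: np.ndarray) -> float:
    """Profile log-likelihood of one dose group in the trained fraction
    ``f_t`` with the component densities fixed."""
    with np.errstate(divide="ignore"):
        terms = np.stack([
            np.where(f_t < 1.0, math.log(max(1.0 - f_t, 1e-300)), -np.inf) + log_nu,
            np.where(f_t > 0.0, math.log(max(f_t, 1e-300)), -np.inf) + log_nt,
        ])
    return float(logsumexp(terms, axis=0).sum())


def trained_fraction(
    X_dose, mu_u: float, mu_t: float, sigma_tilde: float, root_tol: float = 1e-4
) -> TrainedFractionEstimate:
    """Trained fraction of a single dose/protocol group with its
    profile-likelihood interval.

    The component means and variance scale are held fixed (taken from a
    global quantized fit); the interval is the connected set of ``f`` around
    the optimum where the log-likelihood stays within 1/2 of its maximum,
    clipped to [0, 1].
    """
    if isinstance(X_dose, pd.DataFrame):
        p = X_dose["p"].to_numpy(dtype=float)
        n = X_dose["n"].to_numpy(dtype=float)
    else:
        arr = np.asarray(X_dose, dtype=float)
        p, n = arr[:, 0], arr[:, 1]
    if p.size == 0:
        raise ValueError("empty group")
    log_nu = _log_norm(p, mu_u, variance_model(mu_u, n, sigma_tilde))
    log_nt = _log_norm(p, mu_t, variance_model(mu_t, n, sigma_tilde))

    g = lambda f: _profile_loglik(f, log_nu, log_nt)
    res = optimize.minimize_scalar(lambda f: -g(f), bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": root_tol / 10})
    candidates = [(g(0.0), 0.0), (g(1.0), 1.0), (-res.fun, float(res.x))]
    g0, f0 = max(candidates)
    target = g0 - 0.5

    def _edge(a, b):
        """Root of g(f) - target on [a, b] (g is concave: unique crossing)."""
        return float(optimize.brentq(lambda f: g(f) - target, a, b, xtol=root_tol))

    lo = 0.0 if g(0.0) >= target else _edge(0.0, f0)
    hi = 1.0 if g(1.0) >= target else _edge(f0, 1.0)
    return TrainedFractionEstimate(f0=f0, lo=min(lo, f0), hi=max(hi, f0),
                                   loglik_at_f0=g0)


def untrained_fraction_curve(
    X, quantized: QuantizedLearningModel, all_or_none: AllOrNoneModel | None = None
) -> pd.DataFrame:
    """Per-dose untrained fractions from the quantized fit with half-unit
    profile intervals, plus (optionally) the memoryless exponential-decay
    overlay ``lambda**n_c`` from the all-or-none fit."""
    levels, idx, p, n = _as_arrays(X)
    t = quantized.theta_
    rows = []
    for i, dose in enumerate(levels):
        sel = idx == i
        sub = pd.DataFrame({"p": p[sel], "n": n[sel]})
        est = trained_fraction(sub, t["mu_u"], t["mu_t"], t["sigma_tilde"])
        rows.append({
            "dose": dose,
            "f_untrained": 1.0 - est.f0,
            "f_untrained_lo": 1.0 - est.hi,
            "f_untrained_hi": 1.0 - est.lo,
        })
    out = pd.DataFrame(rows)
    if all_or_none is not None:
        out["f_untrained_memoryless"] = all_or_none.theta_["lam"] ** out["dose"]
    return out
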