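"""Differential-methylation calls and FDR control on posterior differences.

The per-CpG posterior mean differences d_i = E(pi_i1 | y) - E(pi_i2 | y)
are marginally independent once the latent field is integrated out, so a
nonparametric-style mixture FDR procedure applies directly.  We model

    d_i ~ pi_- N[-1,1](theta_-, xi_-^2) + pi_0 N[-1,1](0, xi_0^2)
          + pi_+ N[-1,1](theta_+, xi_+^2)

where N[-1,1] is the normal density truncated to [-1, 1], theta_0 = 0 is
fixed under the null, and pi_0 >= pi_- + pi_+ is imposed (most CpGs are not
differentially methylated).  The local false discovery rate of a CpG is its
posterior null probability P(z_i = "0"); the global FDR of the calling rule
|d_i| >= t is the tail average of the local FDRs, and t is the smallest
threshold keeping that average below the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp, ndtr
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "TruncatedNormalMixture",
    "FDRResult",
    "em_fit_mixture",
    "component_posteriors",
    "fdr_at_threshold",
    "select_threshold",
    "call_dmrs",
    "per_chromosome_fdr",
    "analyze_profile",
]

_MIN_POINTS = 30
_XI_LO, _XI_HI = 1e-3, 2.0
_THETA_EPS = 1e-4


def _tnorm_logpdf(d: np.ndarray, loc: float, scale: float) -> np.ndarray:
    """Log density of N(loc, scale^2) truncated to [-1, 1] (scalar params)."""
    z = (d - loc) / scale
    a, b = (-1.0 - loc) / scale, (1.0 - loc) / scale
    # log(Phi(b) - Phi(a)) stably via log_ndtr
    la, lb = log_ndtr(a), log_ndtr(b)
    logz = lb + np.log1p(-np.exp(min(la - lb, -1e-12)))
    return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi) - np.log(scale) - logz


def _tnorm_suffstat_obj(theta: float, xi: float, r_sum: float,
                        s1: float, s2: float) -> float:
    """Weighted truncated-normal log-likelihood from sufficient statistics
    (sum of weights, weighted sum, weighted sum of squares)."""
    if xi <= 0:
        return -np.inf
    a, b = (-1.0 - theta) / xi, (1.0 - theta) / xi
    logz = float(np.log(max(ndtr(b) - ndtr(a), 1e-300)))
    quad = s2 - 2.0 * theta * s1 + theta * theta * r_sum
    return (-0.5 * quad / (xi * xi)
            - r_sum * (0.5 * np.log(2.0 * np.pi) + np.log(xi) + logz))


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _maximize_1d(fun, lo, hi, current, xatol=1e-6):
    """Golden-section maximization on [lo, hi], never worse than
    ``current``."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d_ = a + _GOLDEN * (b - a)
    fc, fd = fun(c), fun(d_)
    while b - a > xatol:
        if fc >= fd:
            b, d_, fd = d_, c, fc
            c = b - _GOLDEN * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d_, fd
            d_ = a + _GOLDEN * (b - a)
            fd = fun(d_)
    x = c if fc >= fd else d_
    fx = max(fc, fd)
    return float(x) if fx >= fun(current) else float(current)


# -- numba fast path of the EM loop (numpy fallback lives in _em_once) ----

def _em_loop_py(d, w, means, var, tol, max_iter):  # pragma: no cover
    """EM on (d, start params); written in scalar style so numba can
    compile it.  Returns (w, means, var, loglik, trace, n_trace, conv)."""
    n = d.size
    trace = np.empty(max_iter)
    nt = 0
    ll_prev = -np.inf
    w_prev = w.copy()
    means_prev = means.copy()
    var_prev = var.copy()
    converged = False
    log2pi = np.log(2.0 * np.pi)
    for _ in range(max_iter):
        sd = np.sqrt(var)
        const = np.empty(3)
        for k in range(3):
            a = (-1.0 - means[k]) / sd[k]
            b = (1.0 - means[k]) / sd[k]
            z = (0.5 * math.erfc(-b / np.sqrt(2.0))
                 - 0.5 * math.erfc(-a / np.sqrt(2.0)))
            const[k] = (np.log(w[k]) - 0.5 * log2pi - np.log(sd[k])
                        - np.log(max(z, 1e-300)))
        ll = 0.0
        r_sum = np.zeros(3)
        s1 = np.zeros(3)
        s2 = np.zeros(3)
        lc = np.empty(3)
        for i in range(n):
            mx = -np.inf
            for k in range(3):
                zz = (d[i] - means[k]) / sd[k]
                lc[k] = const[k] - 0.5 * zz * zz
                if lc[k] > mx:
                    mx = lc[k]
            s = 0.0
            for k in range(3):
                lc[k] = np.exp(lc[k] - mx)
                s += lc[k]
            ll += np.log(s) + mx
            for k in range(3):
                r = lc[k] / s
                r_sum[k] += r
                s1[k] += r * d[i]
                s2[k] += r * d[i] * d[i]
        if ll < ll_prev - 1e-10:
            w, means, var = w_prev, means_prev, var_prev
            converged = True
            break
        trace[nt] = ll
        nt += 1
        if ll - ll_prev < tol * n and nt > 1:
            converged = True
            break
        ll_prev = ll
        w_prev = w.copy()
        means_prev = means.copy()
        var_prev = var.copy()
        # M-step: weights (closed form + projection)
        w = r_sum / n
        if w[1] < w[0] + w[2]:
            scale = w[1] / (w[0] + w[2])
            w[0] *= scale
            w[2] *= scale
            w /= w.sum()
        means = means.copy()
        var = var.copy()
        for k in range(3):
            if r_sum[k] < 1e-12:
                continue
            if k != 1:
                lo = -1.0 if k == 0 else _THETA_EPS
                hi = -_THETA_EPS if k == 0 else 1.0
                means[k] = _golden_nb(lo, hi, means[k], np.sqrt(var[k]),
                                      r_sum[k], s1[k], s2[k], True)
            xi = _golden_nb(_XI_LO, _XI_HI, means[k], np.sqrt(var[k]),
                            r_sum[k], s1[k], s2[k], False)
            var[k] = xi * xi
    return w, means, var, ll_prev, trace, nt, converged


def _suff_obj_scalar(theta, xi, r_sum, s1, s2):  # pragma: no cover
    a = (-1.0 - theta) / xi
    b = (1.0 - theta) / xi
    z = (0.5 * math.erfc(-b / np.sqrt(2.0))
         - 0.5 * math.erfc(-a / np.sqrt(2.0)))
    quad = s2 - 2.0 * theta * s1 + theta * theta * r_sum
    return (-0.5 * quad / (xi * xi)
            - r_sum * (0.5 * np.log(2.0 * np.pi) + np.log(xi)
                       + np.log(max(z, 1e-300))))


def _golden_nb_py(lo, hi, theta, xi, r_sum, s1, s2,
                  over_theta):  # pragma: no cover
    golden = (np.sqrt(5.0) - 1.0) / 2.0

    def f(v):
        if over_theta:
            return _suff_obj_scalar(v, xi, r_sum, s1, s2)
        return _suff_obj_scalar(theta, v, r_sum, s1, s2)

    a, b = lo, hi
    c = b - golden * (b - a)
    e = a + golden * (b - a)
    fc, fe = f(c), f(e)
    while b - a > 1e-6:
        if fc >= fe:
            b, e, fe = e, c, fc
            c = b - golden * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, e, fe
            e = a + golden * (b - a)
            fe = f(e)
    x = c if fc >= fe else e
    fx = fc if fc >= fe else fe
    cur = theta if over_theta else xi
    return x if fx >= f(cur) else cur


try:  # pragma: no cover - exercised implicitly through fit()
    from numba import njit as _njit

    # compile bottom-up so each njit function resolves njit callees
    _suff_obj_scalar = _njit(cache=True)(_suff_obj_scalar)
    _golden_nb = _njit(cache=True)(_golden_nb_py)
    _em_loop = _njit(cache=True)(_em_loop_py)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _golden_nb = _golden_nb_py
    _em_loop = _em_loop_py
    _HAVE_NUMBA = False


class TruncatedNormalMixture(BaseEstimator):
    """Three-component truncated-normal mixture on [-1, 1], EM-fitted.

    Components are ordered (negative, null, positive): the null center is
    fixed at 0 and the identifiability constraint
    ``weights_[1] >= weights_[0] + weights_[2]`` is enforced by projection.
    Multiple randomized restarts guard against local maxima.

    Parameters
    ----------
    n_starts : randomized EM initializations (best final likelihood wins).
    tol : convergence tolerance on the increment of the mean per-sample
        log-likelihood (the ``sklearn.mixture`` convention).
    max_iter : EM iteration cap per start.
    random_state : seed of the jitter stream.

    Attributes
    ----------
    weights_ : (3,) mixing proportions (pi_-, pi_0, pi_+).
    means_ : (3,) component centers (theta_-, 0, theta_+).
    variances_ : (3,) component variances (xi_-^2, xi_0^2, xi_+^2).
    converged_ : bool; loglik_ : final log-likelihood;
    loglik_trace_ : per-iteration log-likelihoods of the winning start.
    """

    def __init__(self, n_starts: int = 10, tol: float = 1e-8,
                 max_iter: int = 2000, random_state=None):
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ------------------------------------------------------
    @staticmethod
    def _project_weights(w: np.ndarray) -> np.ndarray:
        if w[1] < w[0] + w[2]:
            scale = w[1] / (w[0] + w[2])
            w = np.array([w[0] * scale, w[1], w[2] * scale])
            w = w / w.sum()
        return w

    @staticmethod
    def _log_components(d, means, variances):
        sds = np.sqrt(variances)
        return np.stack([_tnorm_logpdf(d, means[k], sds[k])
                         for k in range(3)], axis=1)

    def _em_once(self, d, w, means, var):
        trace = []
        prev = (w, means, var)
        ll_prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            logc = self._log_components(d, means, var) + np.log(w)
            ll = float(np.sum(logsumexp(logc, axis=1)))
            if ll < ll_prev - 1e-10:
                w, means, var = prev        # reject deteriorating update
                ll = ll_prev
                converged = True
                break
            trace.append(ll)
            if ll - ll_prev < self.tol * d.size and np.isfinite(ll_prev):
                converged = True
                break
            ll_prev = ll
            prev = (w, means, var)
            resp = np.exp(logc - logsumexp(logc, axis=1, keepdims=True))
            # M-step: weights in closed form (+ identifiability projection)
            w = self._project_weights(resp.mean(axis=0))
            # component parameters by 1-D maximization on sufficient stats
            means = means.copy()
            var = var.copy()
            for k in range(3):
                r_sum = float(resp[:, k].sum())
                if r_sum < 1e-12:
                    continue
                s1 = float(resp[:, k] @ d)
                s2 = float(resp[:, k] @ (d * d))
                if k != 1:
                    lo, hi = ((-1.0, -_THETA_EPS) if k == 0
                              else (_THETA_EPS, 1.0))
                    means[k] = _maximize_1d(
                        lambda t: _tnorm_suffstat_obj(
                            t, np.sqrt(var[k]), r_sum, s1, s2),
                        lo, hi, means[k])
                xi = _maximize_1d(
                    lambda s: _tnorm_suffstat_obj(
                        means[k], s, r_sum, s1, s2),
                    _XI_LO, _XI_HI, np.sqrt(var[k]))
                var[k] = xi * xi
        return w, means, var, ll_prev if trace else -np.inf, trace, converged

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float).ravel()
        if d.size < _MIN_POINTS:
            raise ValueError(
                f"need at least {_MIN_POINTS} d values to fit the mixture; "
                "pool chromosomes or use the genome-wide mode")
        if not np.all(np.isfinite(d)):
            raise ValueError("d contains non-finite values")
        if np.any(np.abs(d) > 1.0 + 1e-9):
            raise ValueError("d values must lie in [-1, 1]")
        d = np.clip(d, -1.0, 1.0)
        if np.ptp(d) == 0.0:
            raise ValueError("degenerate input: all d values identical")
        rng = np.random.default_rng(self.random_state)
        q90 = max(float(np.quantile(np.abs(d), 0.9)), 5 * _THETA_EPS)
        sd = min(max(float(np.std(d)), _XI_LO * 2), _XI_HI * 0.9)
        best = None
        for start in range(self.n_starts):
            if start == 0:
                w = np.array([0.1, 0.8, 0.1])
                means = np.array([-q90, 0.0, q90])
                var = np.array([sd, sd, sd]) ** 2
            else:
                jt = rng.uniform(0.5, 1.5, size=2)
                jx = rng.uniform(0.5, 2.0, size=3)
                side = rng.uniform(0.02, 0.2, size=2)
                w = self._project_weights(
                    np.array([side[0], 1 - side.sum(), side[1]]))
                means = np.array([
                    np.clip(-q90 * jt[0], -1.0, -_THETA_EPS), 0.0,
                    np.clip(q90 * jt[1], _THETA_EPS, 1.0)])
                var = np.clip(sd * jx, _XI_LO, _XI_HI) ** 2
            if _HAVE_NUMBA:
                wf, mf, vf, ll, trace, nt, conv = _em_loop(
                    d, w, means, var, self.tol, self.max_iter)
                out = (wf, mf, vf, ll, list(trace[:nt]), conv)
            else:
                out = self._em_once(d, w, means, var)
            if best is None or out[3] > best[3]:
                best = out
        w, means, var, ll, trace, converged = best
        if not converged:
            logger.warning("EM did not converge within max_iter; "
                           "returning best iterate")
        self.weights_ = np.asarray(w)
        self.means_ = np.asarray(means)
        self.variances_ = np.asarray(var)
        self.loglik_ = ll
        self.loglik_trace_ = np.asarray(trace)
        self.converged_ = bool(converged)
        self.n_iter_ = len(trace)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior component probabilities, columns (neg, null, pos)."""
        d = np.clip(np.asarray(X, dtype=float).ravel(), -1.0, 1.0)
        logc = (self._log_components(d, self.means_, self.variances_)
                + np.log(self.weights_))
        return np.exp(logc - logsumexp(logc, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        """Hard component labels: -1 (hypo), 0 (null), +1 (hyper)."""
        return np.argmax(self.predict_proba(X), axis=1) - 1

    def score(self, X, y=None) -> float:
        d = np.clip(np.asarray(X, dtype=float).ravel(), -1.0, 1.0)
        logc = (self._log_components(d, self.means_, self.variances_)
                + np.log(self.weights_))
        return float(np.mean(logsumexp(logc, axis=1)))


def em_fit_mixture(d, n_starts: int = 10, tol: float = 1e-8,
                   max_iter: int = 2000, seed=None) -> TruncatedNormalMixture:
    """Fit the three-component truncated-normal mixture to d values."""
    return TruncatedNormalMixture(n_starts=n_starts, tol=tol,
                                  max_iter=max_iter,
                                  random_state=seed).fit(d)


def component_posteriors(d, fit: TruncatedNormalMixture) -> np.ndarray:
    """P(z_i = k | d_i) for k in (neg, null, pos); rows sum to one."""
    return fit.predict_proba(d)


# ---------------------------------------------------------------------------
# global FDR
# ---------------------------------------------------------------------------

@dataclass
class FDRResult:
    """Chosen |d| threshold, estimated FDR there, and per-CpG call flags."""

    threshold: float
    fdr: float
    significant: np.ndarray
    n_neg: int
    n_pos: int
    target: float


def fdr_at_threshold(posteriors: np.ndarray, d: np.ndarray,
                     t: float) -> float:
    """Estimated FDR of the rule |d_i| >= t: the mean posterior null
    probability over the two tails; 0 when no CpG lies in the tails."""
    if t <= 0:
        raise ValueError("threshold must be > 0")
    d = np.asarray(d, dtype=float)
    tail = (d <= -t) | (d >= t)
    if not np.any(tail):
        logger.debug("empty tail at t=%g; FDR defined as 0", t)
        return 0.0
    return float(np.mean(posteriors[tail, 1]))


def select_threshold(posteriors: np.ndarray, d: np.ndarray,
                     target_fdr: float = 0.05) -> FDRResult:
    """Smallest |d| threshold whose estimated FDR stays below the target.

    Candidates are the observed distinct |d_i| > 0; choosing the smallest
    qualifying candidate maximizes the number of calls subject to the
    bound.  When no candidate qualifies, nothing is called (t = +inf).
    """
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must be in (0, 1)")
    d = np.asarray(d, dtype=float)
    finite = np.isfinite(d)
    candidates = np.unique(np.abs(d[finite]))
    candidates = candidates[candidates > 0]
    for t in candidates:
        est = fdr_at_threshold(posteriors, np.where(finite, d, 0.0), t)
        if est <= target_fdr:
            sig = finite & (np.abs(d) >= t)
            return FDRResult(threshold=float(t), fdr=est, significant=sig,
                             n_neg=int(np.sum(d[sig] < 0)),
                             n_pos=int(np.sum(d[sig] > 0)),
                             target=target_fdr)
    return FDRResult(threshold=np.inf, fdr=np.nan,
                     significant=np.zeros(d.shape, dtype=bool),
                     n_neg=0, n_pos=0, target=target_fdr)


def per_chromosome_fdr(profile: pd.DataFrame, target_fdr: float = 0.05,
                       seed=None, min_sites: int = _MIN_POINTS):
    """Mixture + threshold per chromosome, aggregated by pooling the calls.

    Chromosomes with fewer than ``min_sites`` finite d values fall back to
    the genome-wide fit.  Returns (flags, per-chromosome results dict).
    """
    d_all = profile["d"].to_numpy(dtype=float)
    finite = np.isfinite(d_all)
    flags = np.zeros(len(profile), dtype=bool)
    results = {}
    global_fit = None
    for chrom in pd.unique(profile["chrom"]):
        idx = (profile["chrom"] == chrom).to_numpy()
        d = d_all[idx]
        if np.sum(np.isfinite(d)) < min_sites:
            logger.warning("chromosome %s has too few CpGs; "
                           "falling back to the genome-wide fit", chrom)
            if global_fit is None:
                global_fit = em_fit_mixture(d_all[finite], seed=seed)
            fit = global_fit
        else:
            fit = em_fit_mixture(d[np.isfinite(d)], seed=seed)
        post = component_posteriors(np.where(np.isfinite(d), d, 0.0), fit)
        res = select_threshold(post, d, target_fdr)
        flags[idx] = res.significant
        results[chrom] = (fit, res)
    return flags, results


# ---------------------------------------------------------------------------
# DMR assembly
# ---------------------------------------------------------------------------

def call_dmrs(profile: pd.DataFrame, significant: np.ndarray,
              min_cpg: int = 5, min_diff: float = 0.33) -> pd.DataFrame:
    """Merge qualifying CpGs into differentially methylated regions.

    Within one chunk, maximal runs of consecutive CpGs that are significant,
    have |d_i| >= min_diff, and share the sign of d become a DMR when at
    least ``min_cpg`` long.  Runs never span chunk boundaries.  Defaults
    follow the conventional calling rule: 5 CpGs minimum, 33% methylation
    difference, at the FDR threshold applied upstream.
    """
    significant = np.asarray(significant, dtype=bool)
    if len(significant) != len(profile):
        raise ValueError("flags and profile must be aligned")
    d = profile["d"].to_numpy(dtype=float)
    chunk = (profile["chunk"].to_numpy() if "chunk" in profile.columns
             else np.zeros(len(profile), dtype=int))
    ok = significant & np.isfinite(d) & (np.abs(d) >= min_diff)
    sign = np.sign(d)
    rows = []
    n = len(profile)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i + 1
        while (j < n and ok[j] and sign[j] == sign[i]
               and chunk[j] == chunk[i]):
            j += 1
        if j - i >= min_cpg:
            pos = profile["pos"].to_numpy()
            rows.append({
                "chrom": profile["chrom"].iloc[i],
                "start": int(pos[i]),
                "end": int(pos[j - 1]),
                "n_cpg": j - i,
                "mean_d": float(np.mean(d[i:j])),
                "sign": int(sign[i]),
            })
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg",
                                       "mean_d", "sign"])


def analyze_profile(profile: pd.DataFrame, target_fdr: float = 0.05,
                    min_cpg: int = 5, min_diff: float = 0.33,
                    per_chromosome: bool = False, seed=None):
    """FDR procedure + DMR assembly on an inference profile.

    Adds p_neg/p_null/p_pos and significance columns to a copy of the
    profile and returns (annotated profile, DMR table, report dict).
    """
    profile = profile.copy()
    d = profile["d"].to_numpy(dtype=float)
    finite = np.isfinite(d)
    if per_chromosome:
        flags, per_chrom = per_chromosome_fdr(profile, target_fdr, seed=seed)
        fit, _ = next(iter(per_chrom.values()))
        post = np.full((len(profile), 3), np.nan)
        for chrom, (cfit, _res) in per_chrom.items():
            idx = (profile["chrom"] == chrom).to_numpy() & finite
            post[idx] = component_posteriors(d[idx], cfit)
        report = {
            "mode": "per-chromosome",
            "per_chromosome": {
                str(c): {"threshold": float(r.threshold), "fdr": float(r.fdr)}
                for c, (_f, r) in per_chrom.items()},
        }
    else:
        fit = em_fit_mixture(d[finite], seed=seed)
        post = np.full((len(profile), 3), np.nan)
        post[finite] = component_posteriors(d[finite], fit)
        res = select_threshold(post[finite], d[finite], target_fdr)
        flags = np.zeros(len(profile), dtype=bool)
        flags[finite] = res.significant
        report = {
            "mode": "genome-wide",
            "threshold": float(res.threshold),
            "estimated_fdr": float(res.fdr),
            "n_neg": res.n_neg, "n_pos": res.n_pos,
        }
    report["mixture"] = {
        "weights": fit.weights_.tolist(),
        "means": fit.means_.tolist(),
        "variances": fit.variances_.tolist(),
        "loglik": float(fit.loglik_),
        "converged": bool(fit.converged_),
    }
    profile["p_neg"], profile["p_null"], profile["p_pos"] = post.T
    profile["significant"] = flags
    dmrs = call_dmrs(profile, flags, min_cpg=min_cpg, min_diff=min_diff)
    report["n_dmrs"] = int(len(dmrs))
    report["n_significant_cpgs"] = int(flags.sum())
    return profile, dmrs, report
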