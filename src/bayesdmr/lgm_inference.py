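"""Approximate posterior inference for the latent Gaussian methylation model.

Model, per group g, over a chunk of m CpGs with replicates r = 1..R:

    y_igr | pi_igr   ~ Binomial(n_igr, pi_igr)
    logit(pi_igr)    = eta_igr,   eta_igr | mu_ig ~ N(mu_ig, sigma_g^2)
    mu_ig | mu_i-1,g ~ N(mu_i-1,g, rho_ig^2),  rho_ig^2 = rho_g^2 * |p_i - p_i-1|
    sigma_g^-2, rho_g^-2 ~ Gamma(0.1, rate=0.1)   (mean 1, variance 10)

The latent methylation profile mu_.g is a nonstationary first-order random
walk whose increment variance grows with the genomic distance between
consecutive CpGs, so smoothing adapts to CpG spacing.  With a single
replicate the random effect collapses (sigma_g^2 = 0) and mu enters the
binomial likelihood directly.

Inference follows the integrated-nested-Laplace recipe: a Gaussian (Laplace)
approximation to p(x | y, theta) at each hyperparameter point, a Laplace
approximation to the hyperparameter marginal p(theta | y), numerical
integration of theta over a standardized grid around its mode, and
Gauss-Hermite quadrature to map latent Gaussian marginals of mu through the
inverse logit.  All linear algebra exploits the banded structure of the
joint precision (replicate effects interleaved with their site's mu).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse, stats
from scipy.linalg import cho_solve_banded, cholesky_banded
from scipy.optimize import minimize
from scipy.special import expit

from .config import InferenceConfig
from .io_preprocess import Chunk, MethylationTable, chunk_genome

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "PrecisionStructure",
    "GaussianApprox",
    "HyperGrid",
    "build_joint_precision",
    "gaussian_approximation",
    "log_marginal_theta",
    "explore_hyperparameters",
    "posterior_profiles",
    "overdispersion_variance",
    "run_inference",
]

_GAMMA_SHAPE = 0.1
_GAMMA_RATE = 0.1


@dataclass(frozen=True)
class Hyperparameters:
    """Variance hyperparameters of one group.

    ``rho2`` is the global smoothing variance per base pair; ``sigma2`` the
    replicate random-effect variance, ``None`` for the collapsed
    single-replicate model.
    """

    rho2: float
    sigma2: Optional[float] = None

    @property
    def collapsed(self) -> bool:
        return self.sigma2 is None


class InferenceError(RuntimeError):
    pass


@dataclass
class PrecisionStructure:
    """Banded prior precision of the joint latent vector of one group.

    Layout interleaves, per site i, the replicate effects eta_ir for the
    observed replicates followed by mu_i; this bounds the bandwidth by
    1 + max observed replicates per site.  ``ab`` is the lower-banded
    storage understood by :func:`scipy.linalg.cholesky_banded`.
    """

    ab: np.ndarray            # (bw + 1, n) lower-banded prior precision
    n: int
    bandwidth: int
    mu_index: np.ndarray      # (m,) latent index of mu_i
    lik_index: np.ndarray     # latent indices carrying a binomial term
    lik_y: np.ndarray
    lik_n: np.ndarray
    collapsed: bool
    _csr: Optional[sparse.csr_matrix] = field(default=None, repr=False)

    @property
    def matrix(self) -> sparse.csr_matrix:
        """Prior precision as a sparse symmetric matrix (built lazily)."""
        if self._csr is None:
            diags, offs = [], []
            for k in range(self.bandwidth + 1):
                band = self.ab[k, : self.n - k]
                if k == 0:
                    diags.append(band)
                    offs.append(0)
                elif np.any(band):
                    diags.extend([band, band])
                    offs.extend([-k, k])
            self._csr = sparse.diags(
                diags, offs, shape=(self.n, self.n)).tocsr()
        return self._csr


def _group_observations(table: MethylationTable, group: int):
    """Per-site observed (y, n) for a group; totals <= 0 count as missing."""
    cols = table.group_columns(group)
    y = table.meth[:, cols]
    n = table.total[:, cols]
    obs = np.isfinite(n) & (n > 0)
    return y, n, obs, len(cols)


def build_joint_precision(chunk: Chunk, group: int, theta: Hyperparameters,
                          level_precision: float = 1e-5,
                          distance_cap: float = None) -> PrecisionStructure:
    """Assemble the banded prior precision Q(theta) of one group's latents.

    The mu block carries the distance-adaptive random-walk terms
    1 / (rho_g^2 * d_i) for each consecutive pair plus a weak anchoring
    precision ``level_precision`` on every diagonal (the random walk is
    intrinsic; anchoring stands in for a diffuse level prior).  With a
    replicate layer, eta rows carry 1/sigma^2, eta-mu couplings -1/sigma^2
    and each mu diagonal an extra R_i/sigma^2.
    """
    table = chunk.table
    m = table.n_sites
    if m < 1:
        raise ValueError("empty chunk")
    if level_precision <= 0:
        raise ValueError("level_precision must be > 0")
    d = np.diff(table.pos).astype(float)
    if np.any(d <= 0):
        raise ValueError(f"non-positive CpG spacing in chunk {chunk.index}")
    if distance_cap is not None:
        d = np.minimum(d, float(distance_cap))
    y, n, obs, R = _group_observations(table, group)
    collapsed = theta.collapsed
    if collapsed and R > 1:
        raise ValueError("collapsed model requires a single replicate")
    if not collapsed and theta.sigma2 is not None and theta.sigma2 <= 0:
        raise ValueError("sigma2 must be > 0 for the replicate layer")
    if theta.rho2 <= 0:
        raise ValueError("rho2 must be > 0")
    inv_rho2 = 1.0 / (theta.rho2 * d) if m > 1 else np.empty(0)

    if collapsed:
        nlat = m
        mu_index = np.arange(m)
        bw = 1 if m > 1 else 0
        ab = np.zeros((bw + 1, nlat))
        ab[0, :] = level_precision
        if m > 1:
            ab[0, :-1] += inv_rho2
            ab[0, 1:] += inv_rho2
            ab[1, :-1] = -inv_rho2
        lik = obs[:, 0]
        lik_index = mu_index[lik]
        lik_y = y[lik, 0]
        lik_n = n[lik, 0]
    else:
        tau = 1.0 / theta.sigma2
        r_i = obs.sum(axis=1)                      # observed replicates/site
        mu_index = np.cumsum(r_i + 1) - 1          # mu after its site's etas
        nlat = int(mu_index[-1]) + 1
        bw = int(r_i.max()) + 1 if m > 1 else int(r_i.max())
        bw = max(bw, 1)
        ab = np.zeros((bw + 1, nlat))
        eta_rows, lik_y_l, lik_n_l = [], [], []
        for i in range(m):
            base = mu_index[i] - r_i[i]
            for k, r in enumerate(np.flatnonzero(obs[i])):
                eta_rows.append(base + k)
                lik_y_l.append(y[i, r])
                lik_n_l.append(n[i, r])
        eta_rows = np.array(eta_rows, dtype=np.int64)
        ab[0, eta_rows] = tau                      # eta diagonal
        # eta-mu coupling: row mu_index[i], col eta -> band k = mu - eta
        for i in range(m):
            for k in range(1, r_i[i] + 1):
                ab[k, mu_index[i] - k] = -tau
        ab[0, mu_index] = r_i * tau + level_precision
        if m > 1:
            ab[0, mu_index[:-1]] += inv_rho2
            ab[0, mu_index[1:]] += inv_rho2
            step = mu_index[1:] - mu_index[:-1]    # = 1 + r_{i+1}
            ab[step, mu_index[:-1]] = -inv_rho2
        lik_index = eta_rows
        lik_y = np.array(lik_y_l, dtype=float)
        lik_n = np.array(lik_n_l, dtype=float)
    return PrecisionStructure(ab=ab, n=nlat, bandwidth=bw,
                              mu_index=mu_index, lik_index=lik_index,
                              lik_y=lik_y, lik_n=lik_n, collapsed=collapsed)


# ---------------------------------------------------------------------------
# Gaussian (Laplace) approximation to p(x | y, theta)
# ---------------------------------------------------------------------------

@dataclass
class GaussianApprox:
    """Mode and curvature of the latent posterior at fixed hyperparameters."""

    mode: np.ndarray
    mu_mean: np.ndarray
    mu_var: np.ndarray
    logdet_prior: float
    logdet_post: float
    loglik_mode: float        # binomial log-likelihood at the mode
    prior_quad: float         # x_hat' Q x_hat
    converged: bool
    n_iter: int
    prec: PrecisionStructure
    chol_post: np.ndarray = field(default=None, repr=False)


def _band_logdet(cb: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(cb[0])))


def _binom_loglik(eta, y, n):
    # log C(n, y) omitted: constant in the latents and hyperparameters
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def _takahashi_band(cb: np.ndarray) -> np.ndarray:
    """Selected inversion of a banded SPD matrix from its banded Cholesky.

    Returns the lower band of the inverse; row 0 is the diagonal of the
    inverse.  Recursion of Takahashi/Erisman-Tinney restricted to the band
    (the band is closed under the recursion for banded matrices).
    """
    bw1, nn = cb.shape
    return _takahashi_impl(np.ascontiguousarray(cb), bw1, nn)


def _takahashi_py(cb, bw1, nn):
    S = np.zeros((bw1, nn))
    bw = bw1 - 1
    for j in range(nn - 1, -1, -1):
        djj = cb[0, j]
        K = min(bw, nn - 1 - j)
        # l[k] = L[j+k, j] / L[j, j], k = 1..K
        for i in range(K, 0, -1):
            acc = 0.0
            for k in range(1, K + 1):
                if k >= i:
                    s = S[k - i, j + i]
                else:
                    s = S[i - k, j + k]
                acc += cb[k, j] * s
            S[i, j] = -acc / djj
        acc = 0.0
        for k in range(1, K + 1):
            acc += cb[k, j] * S[k, j]
        S[0, j] = 1.0 / (djj * djj) - acc / djj
    return S


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _takahashi_impl = njit(cache=True)(_takahashi_py)
except Exception:  # pragma: no cover
    _takahashi_impl = _takahashi_py


def gaussian_approximation(chunk: Chunk, group: int, theta: Hyperparameters,
                           config: InferenceConfig = None,
                           x0: np.ndarray = None,
                           want_variances: bool = True,
                           prec: PrecisionStructure = None) -> GaussianApprox:
    """Newton-Raphson Laplace approximation of the latent posterior.

    Maximizes sum_(i,r) [y eta - n log(1 + e^eta)] - x'Qx/2 with an
    overflow-safe logistic; converged when the max absolute gradient falls
    below ``newton_tol``.  Marginal means/variances of the mu components
    come from banded selected inversion of the curvature precision.
    """
    config = config or InferenceConfig()
    if prec is None:
        prec = build_joint_precision(chunk, group, theta,
                                     config.level_precision,
                                     config.distance_cap)
    Q = prec.matrix
    x = np.zeros(prec.n) if x0 is None else np.array(x0, dtype=float)
    li, yv, nv = prec.lik_index, prec.lik_y, prec.lik_n

    def objective(xv):
        return (_binom_loglik(xv[li], yv, nv)
                - 0.5 * float(xv @ (Q @ xv)))

    obj = objective(x)
    converged = False
    cb = None
    it = 0
    for it in range(1, config.newton_max_iter + 1):
        p = expit(x[li])
        grad = -(Q @ x)
        np.add.at(grad, li, yv - nv * p)
        if np.max(np.abs(grad), initial=0.0) < config.newton_tol:
            converged = True
            break
        w = nv * p * (1.0 - p)
        ab_post = prec.ab.copy()
        np.add.at(ab_post[0], li, w)
        cb = cholesky_banded(ab_post, lower=True)
        dx = cho_solve_banded((cb, True), grad)
        step = 1.0
        for _ in range(40):
            cand = x + step * dx
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                x, obj = cand, cand_obj
                break
            step *= 0.5
        else:
            break
    if not converged:
        raise InferenceError(
            f"Newton did not converge on chunk {chunk.index} "
            f"(group {group + 1}, {it} iterations)")
    # curvature at the accepted mode
    p = expit(x[li])
    w = nv * p * (1.0 - p)
    ab_post = prec.ab.copy()
    np.add.at(ab_post[0], li, w)
    cb = cholesky_banded(ab_post, lower=True)
    cb_prior = cholesky_banded(prec.ab, lower=True)
    mu_mean = x[prec.mu_index]
    if want_variances:
        S = _takahashi_band(cb)
        mu_var = S[0][prec.mu_index].copy()
        if np.any(mu_var <= 0):
            raise InferenceError("non-positive marginal variance")
    else:
        mu_var = np.full(len(prec.mu_index), np.nan)
    return GaussianApprox(
        mode=x, mu_mean=mu_mean, mu_var=mu_var,
        logdet_prior=_band_logdet(cb_prior), logdet_post=_band_logdet(cb),
        loglik_mode=_binom_loglik(x[li], yv, nv),
        prior_quad=float(x @ (Q @ x)),
        converged=converged, n_iter=it, prec=prec, chol_post=cb)


# ---------------------------------------------------------------------------
# Laplace approximation to p(theta | y)
# ---------------------------------------------------------------------------

def _log_prior_theta(theta: Hyperparameters) -> float:
    """Gamma(0.1, rate 0.1) priors on the precisions (mean 1, variance 10),
    with the Jacobian of the log-precision parameterization."""
    total = 0.0
    for v in ([theta.rho2] if theta.collapsed else
              [theta.sigma2, theta.rho2]):
        tau = 1.0 / v
        total += stats.gamma.logpdf(tau, a=_GAMMA_SHAPE,
                                    scale=1.0 / _GAMMA_RATE) + np.log(tau)
    return float(total)


def log_marginal_theta(chunk: Chunk, group: int, theta: Hyperparameters,
                       config: InferenceConfig = None,
                       x0: np.ndarray = None,
                       return_approx: bool = False):
    """Laplace approximation to log p(theta | y) up to an additive constant.

    log p(y | x_hat) + log p(x_hat | theta) + log p(theta)
    - log p~_G(x_hat | y, theta); the Gaussian normalizers reduce to half
    log-determinants of the prior and curvature precisions.
    """
    config = config or InferenceConfig()
    ga = gaussian_approximation(chunk, group, theta, config, x0=x0,
                                want_variances=False)
    val = (ga.loglik_mode
           + 0.5 * ga.logdet_prior - 0.5 * ga.prior_quad
           - 0.5 * ga.logdet_post
           + _log_prior_theta(theta))
    return (val, ga) if return_approx else val


@dataclass
class HyperGrid:
    """Integration grid over one group's hyperparameters.

    ``points`` are Hyperparameters, ``weights`` normalized probabilities
    (equal-volume cells in mode-standardized coordinates, so weights are
    proportional to the posterior density).
    """

    points: list
    weights: np.ndarray
    log_density: np.ndarray
    mode_index: int
    collapsed: bool

    def posterior_mean_variances(self):
        """Grid-posterior means of (sigma2, rho2); sigma2 is None when
        collapsed."""
        rho2 = float(sum(w * p.rho2 for p, w in zip(self.points,
                                                    self.weights)))
        if self.collapsed:
            return None, rho2
        sig2 = float(sum(w * p.sigma2 for p, w in zip(self.points,
                                                      self.weights)))
        return sig2, rho2


def _theta_from_logprec(z, collapsed: bool) -> Hyperparameters:
    if collapsed:
        return Hyperparameters(rho2=float(np.exp(-z[0])))
    return Hyperparameters(sigma2=float(np.exp(-z[0])),
                           rho2=float(np.exp(-z[1])))


def explore_hyperparameters(chunk: Chunk, group: int,
                            config: InferenceConfig = None) -> HyperGrid:
    """Locate the hyperparameter posterior mode and build a weighted grid.

    Works in log-precision coordinates (start 0).  The grid is axis-aligned
    in Hessian-standardized coordinates with step ``grid_step`` standard
    deviations, extended in each direction until the log-density drops by
    more than ``log_density_drop``.  On optimizer failure a fixed grid over
    log-precision [-4, 4] is used instead.
    """
    config = config or InferenceConfig()
    _, _, obs, R = _group_observations(chunk.table, group)
    collapsed = R == 1
    dim = 1 if collapsed else 2
    warm = {"x": None}

    def f(z):
        theta = _theta_from_logprec(z, collapsed)
        try:
            val, ga = log_marginal_theta(chunk, group, theta, config,
                                         x0=warm["x"], return_approx=True)
        except InferenceError:
            return -np.inf
        warm["x"] = ga.mode
        return val

    z0 = np.zeros(dim)
    try:
        res = minimize(lambda z: -f(z), z0, method="Nelder-Mead",
                       options={"xatol": 0.01, "fatol": 1e-4,
                                "maxiter": 300})
        if not np.isfinite(res.fun):
            raise InferenceError("non-finite hyperparameter objective")
        z_mode, f_mode = res.x, -res.fun
        ok = bool(res.success) or res.status == 2  # maxiter: keep best point
    except Exception:
        ok = False
    if not ok:
        logger.warning("hyperparameter optimization failed on chunk %d "
                       "group %d; using fixed fallback grid",
                       chunk.index, group + 1)
        axes = [np.linspace(-4.0, 4.0, 7)] * dim
        zs = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, dim)
        logd = np.array([f(z) for z in zs])
        return _finalize_grid(zs, logd, collapsed)

    # finite-difference Hessian of -f at the mode, standardized directions
    h = 0.3
    H = np.zeros((dim, dim))
    fc = f_mode
    for a in range(dim):
        ea = np.zeros(dim)
        ea[a] = h
        fp, fm = f(z_mode + ea), f(z_mode - ea)
        H[a, a] = -(fp - 2 * fc + fm) / h**2
        for b in range(a + 1, dim):
            eb = np.zeros(dim)
            eb[b] = h
            fpp, fpm = f(z_mode + ea + eb), f(z_mode + ea - eb)
            fmp, fmm = f(z_mode - ea + eb), f(z_mode - ea - eb)
            H[a, b] = H[b, a] = -(fpp - fpm - fmp + fmm) / (4 * h**2)
    try:
        evals, evecs = np.linalg.eigh(H)
        if np.any(evals <= 1e-8):
            raise np.linalg.LinAlgError
        dirs = evecs @ np.diag(1.0 / np.sqrt(evals))   # unit-SD directions
    except np.linalg.LinAlgError:
        dirs = np.eye(dim)

    # extend each axis until the density has dropped by > log_density_drop
    step = config.grid_step
    max_steps = 6
    axis_offsets = []
    cache = {}

    def f_at(offset):
        key = tuple(np.round(offset, 10))
        if key not in cache:
            cache[key] = f(z_mode + dirs @ (step * np.asarray(offset)))
        return cache[key]

    for a in range(dim):
        offs = [0]
        for sign in (1, -1):
            for k in range(1, max_steps + 1):
                o = np.zeros(dim)
                o[a] = sign * k
                if f_at(o) < f_mode - config.log_density_drop:
                    break
                offs.append(sign * k)
        axis_offsets.append(sorted(offs))
    grids = np.meshgrid(*axis_offsets, indexing="ij")
    offsets = np.stack(grids, -1).reshape(-1, dim)
    zs = z_mode + (offsets * step) @ dirs.T
    logd = np.array([f_at(o) for o in offsets])
    return _finalize_grid(zs, logd, collapsed)


def _finalize_grid(zs, logd, collapsed) -> HyperGrid:
    keep = np.isfinite(logd)
    zs, logd = zs[keep], logd[keep]
    w = np.exp(logd - logd.max())
    w /= w.sum()
    points = [_theta_from_logprec(z, collapsed) for z in zs]
    return HyperGrid(points=points, weights=w, log_density=logd,
                     mode_index=int(np.argmax(logd)), collapsed=collapsed)


# ---------------------------------------------------------------------------
# posterior methylation profiles
# ---------------------------------------------------------------------------

def _gauss_hermite_expit(mean, var, nodes: int = 20):
    """E[expit(Z)] and E[expit(Z)^2] for Z ~ N(mean, var), vectorized."""
    xg, wg = np.polynomial.hermite.hermgauss(nodes)
    z = mean[..., None] + np.sqrt(2.0 * var)[..., None] * xg
    p = expit(z)
    w = wg / np.sqrt(np.pi)
    return p @ w, (p * p) @ w


def _group_profile(chunk: Chunk, group: int, config: InferenceConfig):
    """Posterior mean/SD of pi_ig mixed over the hyperparameter grid."""
    grid = explore_hyperparameters(chunk, group, config)
    m = chunk.table.n_sites
    e1 = np.zeros(m)
    e2 = np.zeros(m)
    x0 = None
    for theta, w in zip(grid.points, grid.weights):
        if w < 1e-12:
            continue
        ga = gaussian_approximation(chunk, group, theta, config, x0=x0)
        x0 = ga.mode
        m1, m2 = _gauss_hermite_expit(ga.mu_mean, ga.mu_var,
                                      config.quad_nodes)
        e1 += w * m1
        e2 += w * m2
    sd = np.sqrt(np.maximum(e2 - e1 * e1, 0.0))
    return e1, sd, grid


def posterior_profiles(chunk: Chunk, config: InferenceConfig = None):
    """Posterior methylation probabilities of both groups and their
    difference d_i = E(pi_i1 | y) - E(pi_i2 | y) for one chunk.

    Returns a pandas DataFrame (chrom, pos, meanmeth_g1, sd_g1,
    meanmeth_g2, sd_g2, d) with the per-group hyperparameter grids in
    ``attrs``.
    """
    import pandas as pd

    config = config or InferenceConfig()
    mean1, sd1, grid1 = _group_profile(chunk, 0, config)
    mean2, sd2, grid2 = _group_profile(chunk, 1, config)
    df = pd.DataFrame({
        "chrom": chunk.table.chrom,
        "pos": chunk.table.pos,
        "meanmeth_g1": mean1, "sd_g1": sd1,
        "meanmeth_g2": mean2, "sd_g2": sd2,
        "d": mean1 - mean2,
    })
    df["chunk"] = chunk.index
    df.attrs["hyper_grids"] = (grid1, grid2)
    return df


def overdispersion_variance(n, mu, sigma2, rho2_i):
    """Approximate marginal count variance under the hierarchical model.

    V(Y) ~= n pi (1 - pi) {1 + (sigma^2 + rho_i^2)(n - 1) pi (1 - pi)}
    with pi = expit(mu): the binomial variance times an overdispersion
    factor combining replicate variability and the latent-field variance.
    """
    n = np.asarray(n, dtype=float)
    pi = expit(np.asarray(mu, dtype=float))
    v = pi * (1.0 - pi)
    return n * v * (1.0 + (sigma2 + rho2_i) * (n - 1.0) * v)


def run_inference(table: MethylationTable, config: InferenceConfig = None):
    """Genome-wide inference: chunk, fit each chunk independently, concat.

    Chunks are independent blocks of the precision matrix, so the result is
    identical whether chunks are processed serially or in parallel.  Failing
    chunks are reported in ``attrs['chunk_errors']`` and contribute NaN
    profiles rather than aborting the run.
    """
    import pandas as pd

    config = config or InferenceConfig()
    chunks = chunk_genome(table, config.gap_threshold)
    frames, errors, grids = [], [], {}
    for chunk in chunks:
        try:
            df = posterior_profiles(chunk, config)
            grids[chunk.index] = df.attrs["hyper_grids"]
        except Exception as exc:
            logger.warning("chunk %d (%s) failed: %s",
                           chunk.index, chunk.chrom, exc)
            errors.append((chunk.index, str(exc)))
            df = pd.DataFrame({
                "chrom": chunk.table.chrom, "pos": chunk.table.pos,
                "meanmeth_g1": np.nan, "sd_g1": np.nan,
                "meanmeth_g2": np.nan, "sd_g2": np.nan, "d": np.nan,
                "chunk": chunk.index,
            })
        frames.append(df)
    if not frames:
        out = pd.DataFrame(columns=["chrom", "pos", "meanmeth_g1", "sd_g1",
                                    "meanmeth_g2", "sd_g2", "d", "chunk"])
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["chunk_errors"] = errors
    out.attrs["hyper_grids"] = grids
    return out
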