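"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.special import expit

from bayesdmr.io_preprocess import Chunk, MethylationTable
from bayesdmr.simulator import simulate_positions


def make_table(pos, meth, total, groups, chrom="chr1"):
    pos = np.asarray(pos)
    return MethylationTable(
        np.array([chrom] * len(pos), dtype=object), pos,
        np.asarray(meth, dtype=float), np.asarray(total, dtype=float),
        np.asarray(groups))


def make_chunk(pos, meth, total, groups, chrom="chr1", index=0):
    table = make_table(pos, meth, total, groups, chrom)
    return Chunk(chrom, table, index, 0, table.n_sites)


def simulate_generative(m, R, lam, sigma2, rho2, seed, mean_gap=100.0):
    """Draw counts from the hierarchical model itself (one group's data,
    mirrored into both group slots so the table validates)."""
    rng = np.random.default_rng(seed)
    pos = simulate_positions(m, mean_gap, rng)
    d = np.diff(pos)
    incr = rng.normal(0.0, 1.0, m - 1) * np.sqrt(rho2 * d)
    mu = np.concatenate([[0.0], np.cumsum(incr)])
    eta = mu[:, None] + rng.normal(0.0, np.sqrt(sigma2), (m, R))
    n = rng.poisson(lam, (m, R)).astype(float)
    y = rng.binomial(n.astype(np.int64), expit(eta)).astype(float)
    y[n == 0] = np.nan
    n = np.where(n == 0, np.nan, n)
    meth = np.concatenate([y, y], axis=1)
    total = np.concatenate([n, n], axis=1)
    chunk = make_chunk(pos, meth, total, [0] * R + [1] * R)
    return chunk, mu


# ---------------------------------------------------------------------------
# dense brute-force oracles (independent of the banded implementation)
# ---------------------------------------------------------------------------

def band_to_dense(ab):
    """Expand scipy lower-banded storage to a dense symmetric matrix."""
    bw1, n = ab.shape
    Q = np.zeros((n, n))
    for k in range(bw1):
        for j in range(n - k):
            Q[j + k, j] = ab[k, j]
            Q[j, j + k] = ab[k, j]
    return Q


def dense_newton_oracle(Q, lik_index, y, n, tol=1e-12, max_iter=200):
    """Posterior mode and covariance by dense Newton iterations."""
    size = Q.shape[0]
    x = np.zeros(size)
    H = Q.copy()
    for _ in range(max_iter):
        p = expit(x[lik_index])
        g = -(Q @ x)
        np.add.at(g, lik_index, y - n * p)
        if np.max(np.abs(g)) < tol:
            break
        w = np.zeros(size)
        np.add.at(w, lik_index, n * p * (1 - p))
        H = Q + np.diag(w)
        x = x + np.linalg.solve(H, g)
    p = expit(x[lik_index])
    w = np.zeros(size)
    np.add.at(w, lik_index, n * p * (1 - p))
    H = Q + np.diag(w)
    return x, np.linalg.inv(H)


def rw1_dense_precision(pos, rho2, eps):
    """Anchored RW(1) precision over mu, assembled from first principles."""
    m = len(pos)
    Q = eps * np.eye(m)
    for i, d in enumerate(np.diff(np.asarray(pos, dtype=float))):
        ir = 1.0 / (rho2 * d)
        Q[i, i] += ir
        Q[i + 1, i + 1] += ir
        Q[i, i + 1] -= ir
        Q[i + 1, i] -= ir
    return Q


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
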