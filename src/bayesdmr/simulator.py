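"""WGBS benchmark-data simulator with per-CpG ground truth.

Generates two-group bisulfite count datasets that are deliberately NOT
drawn from the inference model: a shared two-state (methylated /
unmethylated) baseline along the CpG sequence, differentially methylated
regions where one group's methylation probability is shifted by
``delta_meth``, logit-scale site noise of standard deviation ``s0``,
random status switching between the groups with probability ``delta``
(methylation-call error: noise, not signal), and Poisson(lambda) read
depths with binomial methylated counts.

The benchmark design varies replicates r in {1,2,3}, mean depth in
{10,30}, s0 in {0.1,0.2,0.3}, delta_meth in {0.2,0.3,0.5,0.7} and delta in
{0,0.05,0.1}: 216 parameter combinations, each simulated five times with
5000 CpGs.  True DMRs occupy at most 5% of the CpGs (never more than 20%)
with a median length around 15 CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import expit, logit

from .io_preprocess import MethylationTable

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_positions",
    "simulate_truth",
    "apply_noise_and_switching",
    "simulate_reads",
    "simulate_dataset",
    "benchmark_grid",
    "calibrate_noise",
    "GRID_REPLICATES",
    "GRID_DEPTHS",
    "GRID_NOISE",
    "GRID_DELTA_METH",
    "GRID_SWITCH",
]

GRID_REPLICATES = (1, 2, 3)
GRID_DEPTHS = (10.0, 30.0)
GRID_NOISE = (0.1, 0.2, 0.3)
GRID_DELTA_METH = (0.2, 0.3, 0.5, 0.7)
GRID_SWITCH = (0.0, 0.05, 0.1)


@dataclass(frozen=True)
class SimulationConfig:
    """One benchmark scenario.

    ``s0`` is the standard deviation of the logit-scale site noise
    (one draw per site per group, shared across that group's replicates).
    ``dmr_budget`` caps the fraction of CpGs inside true DMRs; DMR lengths
    are ``dmr_len_offset + Geometric(dmr_len_p)`` CpGs, giving a median of
    15 with the defaults.  Baseline methylation states follow a two-state
    Markov chain with stay-probability ``persistence`` emitting
    probabilities ``p_high`` / ``p_low``.
    """

    n_cpg: int = 5000
    replicates: int = 3
    depth: float = 30.0           # Poisson mean read depth (lambda)
    s0: float = 0.2               # logit-scale noise SD
    delta_meth: float = 0.3       # methylation difference inside DMRs
    switch_prob: float = 0.0      # group status-swap probability (delta)
    p_high: float = 0.8
    p_low: float = 0.2
    persistence: float = 0.97
    dmr_budget: float = 0.05      # max fraction of CpGs inside true DMRs
    dmr_len_offset: int = 9
    dmr_len_p: float = 0.12
    mean_gap: float = 100.0       # mean CpG spacing, bp
    per_replicate_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.dmr_budget <= 0.2):
            raise ValueError("dmr_budget must be in (0, 0.2]")
        for p in (self.p_high, self.p_low, self.switch_prob,
                  self.persistence):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class SimulatedDataset:
    """Counts plus per-CpG ground truth of one simulated scenario."""

    table: MethylationTable
    truth: np.ndarray                  # (n_cpg,) bool: inside a true DMR
    dmr_intervals: list                # (start_idx, stop_idx, group) tuples
    probabilities: np.ndarray          # (n_cpg, 2) realized pi per group
    baseline_high: np.ndarray          # (n_cpg,) baseline methylated status
    config: SimulationConfig = field(repr=False, default=None)


def simulate_positions(n_cpg: int, mean_gap: float = 100.0,
                       rng=None) -> np.ndarray:
    """Strictly increasing 1-based coordinates with geometric gaps.

    Gap ~ Geometric(1/mean_gap) on {1, 2, ...} (mean ``mean_gap``); the
    first CpG sits at position 1.
    """
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    rng = np.random.default_rng(rng)
    gaps = rng.geometric(1.0 / mean_gap, size=n_cpg - 1)
    return np.concatenate([[1], 1 + np.cumsum(gaps)]).astype(np.int64)


def _draw_dmr_intervals(config: SimulationConfig, rng) -> list:
    """Non-overlapping DMR intervals within the CpG-count budget."""
    n = config.n_cpg
    budget = int(np.floor(config.dmr_budget * n))
    if config.delta_meth == 0.0 or budget == 0:
        return []
    min_len = config.dmr_len_offset + 1
    if budget < min_len:
        raise ValueError("DMR budget smaller than the minimum DMR length")
    occupied = np.zeros(n, dtype=bool)
    intervals = []
    used = 0
    while True:
        length = config.dmr_len_offset + int(rng.geometric(config.dmr_len_p))
        if used + length > budget or length >= n:
            break
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, n - length + 1))
            lo = max(start - 1, 0)
            hi = min(start + length + 1, n)   # 1-CpG margin between DMRs
            if not occupied[lo:hi].any():
                occupied[start:start + length] = True
                group = int(rng.integers(0, 2))
                intervals.append((start, start + length, group))
                used += length
                placed = True
                break
        if not placed:
            break
    intervals.sort()
    return intervals


def simulate_truth(config: SimulationConfig, positions: np.ndarray,
                   rng=None):
    """Baseline status sequence, DMR intervals and per-CpG truth labels.

    The two groups share a first-order Markov baseline of methylated /
    unmethylated states.  Inside each DMR one randomly chosen group's
    methylation probability is shifted by ``delta_meth`` toward the
    opposite state (clipped to [0, 1]); exactly the in-DMR CpGs are
    labeled as truly differential.
    """
    rng = np.random.default_rng(rng)
    n = config.n_cpg
    if len(positions) != n:
        raise ValueError("positions length must equal n_cpg")
    stay = config.persistence
    u = rng.random(n)
    high = np.empty(n, dtype=bool)
    high[0] = u[0] < 0.5
    flip = u[1:] >= stay
    high[1:] = high[0] ^ (np.cumsum(flip) % 2).astype(bool)
    intervals = _draw_dmr_intervals(config, rng)
    truth = np.zeros(n, dtype=bool)
    base = np.where(high, config.p_high, config.p_low)
    probs = np.stack([base, base], axis=1).astype(float)
    for start, stop, group in intervals:
        truth[start:stop] = True
        seg = slice(start, stop)
        shift = np.where(high[seg], -config.delta_meth, config.delta_meth)
        probs[seg, group] = np.clip(probs[seg, group] + shift, 0.0, 1.0)
    if truth.sum() > 0.2 * n:  # pragma: no cover - guarded by budget cap
        raise RuntimeError("true-DM fraction exceeded 20%")
    return high, probs, truth, intervals


def apply_noise_and_switching(config: SimulationConfig, probs: np.ndarray,
                              rng=None) -> np.ndarray:
    """Logit-scale noise then group status switching.

    pi_ig = expit(logit(pi_ig) + eps_ig) with eps_ig ~ N(0, s0^2), one
    draw per (site, group) shared by that group's replicates; then with
    probability ``switch_prob`` per CpG the two groups' probabilities are
    swapped for all replicates.  Switched sites stay unlabeled: they are
    methylation-call error, not signal.

    Returns probabilities of shape (n_cpg, 2) or, with
    ``per_replicate_noise``, (n_cpg, 2, replicates).
    """
    rng = np.random.default_rng(rng)
    n = probs.shape[0]
    eps_shape = ((n, 2, config.replicates) if config.per_replicate_noise
                 else (n, 2))
    eps = rng.normal(0.0, config.s0, size=eps_shape)
    clipped = np.clip(probs, 1e-12, 1.0 - 1e-12)
    if config.per_replicate_noise:
        noisy = expit(logit(clipped)[:, :, None] + eps)
    else:
        noisy = expit(logit(clipped) + eps)
    # exact 0/1 probabilities stay exact (logit would saturate anyway)
    exact = (probs == 0.0) | (probs == 1.0)
    if config.per_replicate_noise:
        noisy[exact, :] = probs[exact, None]
    else:
        noisy[exact] = probs[exact]
    swap = rng.random(n) < config.switch_prob
    noisy[swap] = noisy[swap, ::-1]
    return noisy


def simulate_reads(config: SimulationConfig, probabilities: np.ndarray,
                   positions: np.ndarray, rng=None,
                   depth_pool: np.ndarray = None) -> MethylationTable:
    """Poisson depths and binomial methylated counts for every sample.

    ``depth_pool`` optionally resamples read depths from an empirical
    distribution instead of Poisson(lambda).  Zero-depth observations are
    recorded as missing.
    """
    rng = np.random.default_rng(rng)
    n = probabilities.shape[0]
    R = config.replicates
    if probabilities.ndim == 2:
        probabilities = np.repeat(probabilities[:, :, None], R, axis=2)
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    if depth_pool is not None:
        depth_pool = np.asarray(depth_pool)
        depths = rng.choice(depth_pool, size=(n, 2, R)).astype(float)
    else:
        depths = rng.poisson(config.depth, size=(n, 2, R)).astype(float)
    meth = rng.binomial(depths.astype(np.int64), probabilities).astype(float)
    missing = depths == 0
    meth[missing] = np.nan
    total = depths.copy()
    total[missing] = np.nan
    # columns: group-1 replicates then group-2 replicates
    meth2 = np.concatenate([meth[:, 0, :], meth[:, 1, :]], axis=1)
    total2 = np.concatenate([total[:, 0, :], total[:, 1, :]], axis=1)
    groups = np.array([0] * R + [1] * R)
    samples = [f"g1_r{r + 1}" for r in range(R)] + \
              [f"g2_r{r + 1}" for r in range(R)]
    chrom = np.array(["chrSim"] * n, dtype=object)
    return MethylationTable(chrom, positions, meth2, total2, groups, samples)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full pipeline: positions -> truth -> noise/switching -> reads.

    Deterministic given ``config.seed``; truth is never written into the
    count table, so blind evaluation is possible.
    """
    rng = np.random.default_rng(config.seed)
    positions = simulate_positions(config.n_cpg, config.mean_gap, rng)
    high, probs, truth, intervals = simulate_truth(config, positions, rng)
    noisy = apply_noise_and_switching(config, probs, rng)
    table = simulate_reads(config, noisy, positions, rng)
    return SimulatedDataset(table=table, truth=truth,
                            dmr_intervals=intervals,
                            probabilities=noisy if noisy.ndim == 2
                            else noisy.mean(axis=2),
                            baseline_high=high, config=config)


def benchmark_grid(n_cpg: int = 5000, n_seeds: int = 5,
                   base_seed: int = 0) -> list:
    """The full benchmark: every (r, depth, s0, delta_meth, delta)
    combination, each as ``n_seeds`` seed-distinct datasets.

    3 x 2 x 3 x 4 x 3 = 216 combinations; with the defaults 1080 dataset
    configs totalling 5,400,000 CpGs.
    """
    configs = []
    combos = list(product(GRID_REPLICATES, GRID_DEPTHS, GRID_NOISE,
                          GRID_DELTA_METH, GRID_SWITCH))
    for idx, (r, lam, s0, dm, delta) in enumerate(combos):
        for s in range(n_seeds):
            configs.append(SimulationConfig(
                n_cpg=n_cpg, replicates=r, depth=lam, s0=s0,
                delta_meth=dm, switch_prob=delta,
                seed=(base_seed + idx * n_seeds + s) % (2**31 - 1)))
    return configs


def calibrate_noise(s0: float, baseline: float = 0.8, n: int = 100_000,
                    seed: int = 0) -> dict:
    """Monte-Carlo mapping from the logit-scale noise SD to the induced
    perturbation of the methylation probability (user diagnostic)."""
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, s0, size=n)
    p = expit(logit(baseline) + eps)
    return {
        "s0": float(s0),
        "baseline": float(baseline),
        "mean_probability": float(np.mean(p)),
        "sd_probability": float(np.std(p)),
        "mean_abs_shift": float(np.mean(np.abs(p - baseline))),
    }
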