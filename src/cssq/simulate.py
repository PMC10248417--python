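"""Simulated ChIP-seq experiments with known induced differential binding.

The generator mimics a normalized, zero-inflated, four-tier ChIP-seq signal:
a real (or synthetic) background-subtracted base vector is pushed through the
standard transform stage (Anscombe, k-means k=4, U normalization), its
normalized distribution is split into two normal components — one covering the
L tier, one covering M+H+S — and four replicate datasets are drawn from those
components by truncated-normal sampling that preserves each tier's point
count, min, max and the base's zero-inflation level. Ground-truth differential
binding is induced on a random region subset by shifting the 3rd and 4th
datasets (the C group) by a 2-6x multiple of the tier SD, clamped to [0, 1].
Each dataset is then amplified by a U factor drawn from a KDE over estimated
maxima of real datasets and reverse-Anscombe transformed back to counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signal import (
    ANSCOMBE_AT_ZERO,
    ClusterModelEntry,
    anscombe_transform,
    cluster_column,
    estimate_u,
    inverse_anscombe,
)

#: Estimated-maximum values printed for the four simulated replicates of the
#: reference experiment; default pool for the U_sim kernel density estimate.
DEFAULT_U_POOL = (59.2, 56.0, 53.0, 56.0)

#: Column layout of a simulated experiment; induction targets the last two.
DEFAULT_DATASET_IDS = ("J1", "J2", "C1", "C2")


@dataclass
class BaseDistribution:
    """Two-component normal summary of a normalized base dataset.

    ``labels`` keeps each region's tier so that the same region draws from the
    same tier in every replicate; tier sizes/mins/maxs are therefore preserved
    exactly. ``zero_fraction`` is the proportion of raw-zero regions.
    """

    low_mean: float
    low_var: float
    high_mean: float
    high_var: float
    sizes: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    zero_fraction: float
    labels: np.ndarray

    @property
    def q(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return self.sizes.size


@dataclass
class SimulationConfig:
    """Knobs of one simulated experiment.

    dbi_fraction
        Proportion of regions induced as true differential binding (0 for a
        pure-null experiment).
    multiplier_mode
        ``"variable"`` draws the shift multiplier uniformly on [2, 6] per
        region; an integer in 2..6 fixes it.
    direction_up_prob
        Probability an induced region is shifted up. A "down" draw on an
        L-tier region is flipped to "up": subtracting multiples of the tier SD
        from a background-level signal clamps to ~0 and produces no binding
        difference, so essentially all induced changes at background are
        gains (the emergent up-fraction is ~0.5 + 0.5 * P(L)).
    u_pool
        Estimated maxima of real datasets feeding the U_sim KDE.
    """

    n_datasets: int = 4
    dataset_ids: tuple[str, ...] = DEFAULT_DATASET_IDS
    dbi_fraction: float = 0.025
    multiplier_mode: object = "variable"
    direction_up_prob: float = 0.5
    u_pool: tuple[float, ...] = DEFAULT_U_POOL
    integerize: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.dbi_fraction < 1:
            raise ValueError("dbi_fraction must be in [0, 1)")
        if self.multiplier_mode != "variable":
            m = int(self.multiplier_mode)
            if not 2 <= m <= 6:
                raise ValueError("fixed multiplier must lie in 2..6")
        if len(self.dataset_ids) != self.n_datasets:
            raise ValueError("dataset_ids must match n_datasets")
        if self.n_datasets != 4:
            raise ValueError("the simulation layout is fixed at 4 datasets (2 vs 2)")


@dataclass
class SimulatedExperiment:
    """One generated experiment: counts, ground truth and intermediates."""

    counts: pd.DataFrame
    truth: pd.DataFrame
    u_sims: np.ndarray
    normalized: np.ndarray
    base_distribution: BaseDistribution
    config: SimulationConfig
    base_model: ClusterModelEntry | None = None


def fit_base(
    values: np.ndarray, labels: np.ndarray, u: float | None = None
) -> BaseDistribution:
    """Fit the two-component summary of a normalized, clustered base vector.

    The low normal is fit on all L members (including the raw-zero spike —
    zero inflation is reimposed separately at sampling time); the high normal
    on the union of M, H and S members. Per-tier sizes, minima and maxima are
    recorded verbatim.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        raise ValueError("every cluster must be non-empty to fit the base")
    low = values[labels == 0]
    high = values[labels > 0]
    mins = np.array([values[labels == c].min() for c in range(k)])
    maxs = np.array([values[labels == c].max() for c in range(k)])
    if u is not None:
        zero_threshold = (ANSCOMBE_AT_ZERO + 1e-9) / u
    else:
        zero_threshold = 0.0
    zero_fraction = float(np.mean(values <= zero_threshold))
    return BaseDistribution(
        low_mean=float(low.mean()),
        low_var=float(low.var(ddof=1)) if low.size > 1 else 0.0,
        high_mean=float(high.mean()),
        high_var=float(high.var(ddof=1)) if high.size > 1 else 0.0,
        sizes=sizes,
        mins=mins,
        maxs=maxs,
        zero_fraction=zero_fraction,
        labels=labels.copy(),
    )


def _truncated_draw(
    rng: np.random.Generator, mean: float, var: float, lo: float, hi: float, size: int
) -> np.ndarray:
    sd = np.sqrt(var)
    if sd == 0 or lo == hi:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_dataset(
    bd: BaseDistribution, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replicate on the normalized scale.

    Each region draws from its tier's parent component (low normal for L, high
    normal for M/H/S) truncated to the tier's [min, max]; a random subset of L
    regions is then set to exactly 0 to reproduce the base's zero inflation.

    Returns ``(values, labels)`` with ``labels`` equal to the base tier
    assignment.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = np.empty(bd.q)
    for c in range(bd.k):
        idx = np.flatnonzero(bd.labels == c)
        mean, var = (bd.low_mean, bd.low_var) if c == 0 else (bd.high_mean, bd.high_var)
        values[idx] = _truncated_draw(rng, mean, var, bd.mins[c], bd.maxs[c], idx.size)
    n_zero = int(round(bd.zero_fraction * bd.q))
    l_idx = np.flatnonzero(bd.labels == 0)
    if n_zero > l_idx.size:
        warnings.warn("zero fraction exceeds L-tier size; zeroing the whole L tier")
        n_zero = l_idx.size
    if n_zero:
        values[rng.choice(l_idx, size=n_zero, replace=False)] = 0.0
    return values, bd.labels.copy()


def induce_db(
    sims: list[np.ndarray],
    labels: np.ndarray,
    cfg: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Induce ground-truth differential binding on the 3rd and 4th datasets.

    A region subset of size ``round(dbi_fraction * q)`` is drawn once; each
    selected region gets one direction and one multiplier m, applied to both
    targeted datasets as ``value +- m * SD(tier of the value, that dataset)``,
    clamped to [0, 1]. Down draws on L-tier regions are flipped up (see
    :class:`SimulationConfig`). Returns modified copies and the truth table.
    """
    if len(sims) != 4:
        raise ValueError("expected exactly 4 simulated datasets")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    q = sims[0].size
    n_ind = int(round(cfg.dbi_fraction * q))
    if n_ind < 1:
        raise ValueError("dbi_fraction * q < 1: nothing to induce")
    chosen = np.sort(rng.choice(q, size=n_ind, replace=False))
    up = rng.random(n_ind) < cfg.direction_up_prob
    up |= labels[chosen] == 0  # background-level regions can only gain signal
    if cfg.multiplier_mode == "variable":
        mult = rng.uniform(2.0, 6.0, size=n_ind)
    else:
        mult = np.full(n_ind, float(int(cfg.multiplier_mode)))

    out = [s.copy() for s in sims]
    k = int(labels.max()) + 1
    for d in (2, 3):
        tier_sd = np.array(
            [
                sims[d][labels == c].std(ddof=1) if (labels == c).sum() > 1 else 0.0
                for c in range(k)
            ]
        )
        shift = mult * tier_sd[labels[chosen]]
        out[d][chosen] = np.clip(
            sims[d][chosen] + np.where(up, shift, -shift), 0.0, 1.0
        )

    truth = pd.DataFrame(
        {
            "region": np.arange(q),
            "induced": np.zeros(q, dtype=bool),
            "direction": np.full(q, "", dtype=object),
            "multiplier": np.full(q, np.nan),
        }
    )
    truth.loc[chosen, "induced"] = True
    truth.loc[chosen, "direction"] = np.where(up, "up", "down")
    truth.loc[chosen, "multiplier"] = mult
    return out, truth


def sample_usim(
    u_pool, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw n positive U factors from a Gaussian KDE (Silverman bandwidth)
    fitted on the pool of real-dataset estimated maxima; non-positive draws
    are rejected and redrawn."""
    u_pool = np.asarray(u_pool, dtype=float)
    if u_pool.size < 2:
        raise ValueError("u_pool needs >= 2 values to fit a KDE")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kde = stats.gaussian_kde(u_pool, bw_method="silverman")
    draws = np.empty(0)
    for _ in range(100):
        new = kde.resample(n, seed=rng).ravel()
        draws = np.concatenate([draws, new[new > 0]])
        if draws.size >= n:
            return draws[:n]
    raise RuntimeError("could not draw positive U_sim values")


def realize_counts(
    normalized: np.ndarray, u_sims: np.ndarray, integerize: bool = True
) -> np.ndarray:
    """Map normalized simulated values back to the count scale.

    Per dataset: multiply by its U_sim (to the Anscombe scale), reverse the
    Anscombe transform (floored at 0) and optionally round to integer counts.
    """
    normalized = np.asarray(normalized, dtype=float)
    counts = inverse_anscombe(normalized * np.asarray(u_sims, dtype=float)[None, :])
    return np.rint(counts) if integerize else counts


def make_synthetic_base(
    q: int,
    seed: int | np.random.Generator | None = None,
    zero_fraction: float = 0.40,
    proportions: tuple[float, float, float, float] = (0.15, 0.20, 0.15, 0.10),
) -> np.ndarray:
    """Synthetic zero-inflated four-tier base signal on the count scale.

    Emulates the shape of a real background-subtracted promoter-mark dataset:
    a mode of exact zeros plus a near-zero low tier, and three Gaussian bumps
    at increasing means with increasing spread (on the variance-stabilized
    scale), placed so the estimated maximum U lands in the mid-50s as seen in
    real data. ``proportions`` are the non-zero (L-spread, M, H, S) fractions.
    """
    if q < 1000:
        raise ValueError("q must be >= 1000 for a stable four-tier fit")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if zero_fraction + sum(proportions) > 1.0 + 1e-9:
        raise ValueError("zero_fraction + proportions must not exceed 1")
    n_zero = int(round(zero_fraction * q))
    n_l, n_m, n_h, n_s = (int(round(p * q)) for p in proportions)
    n_zero += q - (n_zero + n_l + n_m + n_h + n_s)  # rounding slack to zeros
    # components on the Anscombe scale (mean, sd, lo, hi)
    parts = [
        np.full(n_zero, ANSCOMBE_AT_ZERO),
        _truncated_draw(rng, 5.0, 2.5**2, 1.5, 11.0, n_l),
        _truncated_draw(rng, 18.0, 2.5**2, 12.5, 24.0, n_m),
        _truncated_draw(rng, 32.0, 3.0**2, 25.0, 39.0, n_h),
        _truncated_draw(rng, 44.0, 4.5**2, 39.5, 60.0, n_s),
    ]
    ansc = np.concatenate(parts)
    rng.shuffle(ansc)
    return np.rint(inverse_anscombe(ansc))


def generate_experiment(
    base: np.ndarray,
    cfg: SimulationConfig,
    seed: int | None = None,
    k: int = 4,
    restarts: int = 20,
) -> SimulatedExperiment:
    """Generate one simulated experiment from a count-scale base vector.

    Orchestrates: transform + cluster the base -> fit the two-component
    summary -> draw 4 replicates -> induce differential binding (unless
    ``dbi_fraction == 0``) -> draw U_sim factors -> realize counts.
    Deterministic given the seed (``seed`` overrides ``cfg.seed``).
    """
    root = seed if seed is not None else cfg.seed
    ss = np.random.SeedSequence(root if root is not None else np.random.SeedSequence().entropy)
    s_cluster, s_sample, s_induce, s_usim = ss.spawn(4)

    base = np.asarray(base, dtype=float)
    ansc = anscombe_transform(base)
    labels, entry = cluster_column(
        ansc, k=k, restarts=restarts,
        seed=int(s_cluster.generate_state(1)[0]) % (2**31), dataset_id="base",
    )
    entry.u = estimate_u(entry)
    norm_base = ansc / entry.u
    bd = fit_base(norm_base, labels, u=entry.u)

    sample_rng = np.random.default_rng(s_sample)
    sims = [sample_dataset(bd, sample_rng)[0] for _ in range(cfg.n_datasets)]

    if cfg.dbi_fraction > 0:
        sims, truth = induce_db(sims, bd.labels, cfg, np.random.default_rng(s_induce))
    else:
        truth = pd.DataFrame(
            {
                "region": np.arange(bd.q),
                "induced": np.zeros(bd.q, dtype=bool),
                "direction": np.full(bd.q, "", dtype=object),
                "multiplier": np.full(bd.q, np.nan),
            }
        )

    u_sims = sample_usim(cfg.u_pool, cfg.n_datasets, np.random.default_rng(s_usim))
    # normalized sims are constrained to [0, 1] to avoid outliers (the base
    # S-tier tail can exceed U, i.e. 1 on the normalized scale)
    normalized = np.clip(np.column_stack(sims), 0.0, 1.0)
    counts = realize_counts(normalized, u_sims, integerize=cfg.integerize)
    counts_df = pd.DataFrame(
        counts,
        columns=list(cfg.dataset_ids),
        index=pd.Index([f"region_{i}" for i in range(bd.q)], name="region_id"),
    )
    truth.index = counts_df.index
    return SimulatedExperiment(
        counts=counts_df,
        truth=truth,
        u_sims=u_sims,
        normalized=normalized,
        base_distribution=bd,
        config=cfg,
        base_model=entry,
    )
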