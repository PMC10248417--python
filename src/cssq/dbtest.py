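"""Differential-binding test: cluster-variance Welch statistic with an
exhaustive column-permutation null.

With only a handful of replicates per group, per-region sample variances are
useless; instead each observation borrows the variance of the k-means cluster
it falls in within its own dataset. The region statistic is a Welch-type

    T = (mean_J - mean_C) / sqrt(sigma2_J/n_J + sigma2_C/n_C)

where sigma2 for a group is the average, over its replicates, of the
(normalized-scale) variance of the cluster each replicate observation belongs
to. The null distribution is built by exhaustively re-partitioning the n
replicate columns into alternative two-group designs (excluding the original
partition and, for balanced designs, its mirror), computing T for every region
under every regrouping, and pooling all q*z statistics. Region p-values are
the pooled exceedance fraction on |T|, corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .signal import CLUSTER_NAMES, ClusterModel, SignalMatrix, preprocess

#: Maximum total replicates for exhaustive null enumeration.
_MAX_N_EXHAUSTIVE = 12


@dataclass(frozen=True)
class GroupDesign:
    """Two-group replicate design (group J vs group C)."""

    group_j: tuple[str, ...]
    group_c: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_j) & set(self.group_c):
            raise ValueError("groups must be disjoint")
        if len(set(self.group_j)) != len(self.group_j) or len(
            set(self.group_c)
        ) != len(self.group_c):
            raise ValueError("duplicate dataset id within a group")
        if self.n_j < 2 or self.n_c < 2:
            raise ValueError("need >= 2 replicates per group for a permutation null")

    @property
    def n_j(self) -> int:
        return len(self.group_j)

    @property
    def n_c(self) -> int:
        return len(self.group_c)

    @property
    def n(self) -> int:
        return self.n_j + self.n_c

    @property
    def dataset_ids(self) -> tuple[str, ...]:
        return self.group_j + self.group_c

    @classmethod
    def from_string(cls, spec: str) -> "GroupDesign":
        """Parse the shell syntax ``J1,J2:C1,C2``."""
        try:
            j_part, c_part = spec.split(":")
        except ValueError as exc:
            raise ValueError("design must be '<J ids>:<C ids>' comma-separated") from exc
        return cls(
            tuple(s.strip() for s in j_part.split(",") if s.strip()),
            tuple(s.strip() for s in c_part.split(",") if s.strip()),
        )


def filter_regions(matrix: SignalMatrix) -> np.ndarray:
    """Boolean mask of regions with IP-IN above zero in at least one dataset."""
    if matrix.stage != "raw":
        raise ValueError("filter_regions operates on the raw IP-IN matrix")
    keep = matrix.values.max(axis=1) > 0
    if not keep.any():
        raise ValueError("no signal: every region is zero in every dataset")
    return keep


def null_grouping_count(n_j: int, n_c: int) -> int:
    """Closed-form number of alternative regroupings.

    Balanced designs: C(n, n_j)/2 - 1 (each partition coincides with its
    J<->C mirror). Unbalanced: C(n, n_j) - 1 (no mirrors share the sizes).
    """
    n = n_j + n_c
    if n_j == n_c:
        return comb(n, n_j) // 2 - 1
    return comb(n, n_j) - 1


def enumerate_null_groupings(design: GroupDesign) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All alternative (J, C) partitions of the replicate columns.

    Every size-n_j subset is a candidate J group; for balanced designs each
    partition is collapsed with its J<->C mirror; the original partition is
    always excluded. The count equals :func:`null_grouping_count`.
    """
    if design.n > _MAX_N_EXHAUSTIVE:
        raise ValueError(
            f"n = {design.n} replicates: exhaustive enumeration too large; "
            "subsample replicates explicitly"
        )
    z = null_grouping_count(design.n_j, design.n_c)
    if z < 1:
        raise ValueError("insufficient replicates: no alternative regroupings exist")
    ids = design.dataset_ids
    orig = frozenset(design.group_j)
    balanced = design.n_j == design.n_c
    seen: set = set()
    out: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    for combo in combinations(ids, design.n_j):
        j = frozenset(combo)
        c = frozenset(ids) - j
        if j == orig or (balanced and c == orig):
            continue
        key = frozenset((j, c)) if balanced else j
        if key in seen:
            continue
        seen.add(key)
        out.append(
            (tuple(i for i in ids if i in j), tuple(i for i in ids if i in c))
        )
    assert len(out) == z
    return out


def _as_tier_index(label) -> int:
    if isinstance(label, str):
        return CLUSTER_NAMES.index(label)
    return int(label)


def estimate_row_variance(
    labels_by_dataset: dict[str, object], model: ClusterModel, normalized: bool = True
) -> float:
    """Group variance for one region: average cluster variance of its replicates.

    ``labels_by_dataset`` maps each replicate dataset id to the tier (letter or
    index) its observation fell in; the variance of that cluster, taken from
    the dataset's own model (divided by U^2 when ``normalized``), is averaged
    across replicates.
    """
    if not labels_by_dataset:
        raise ValueError("no replicate labels given")
    vs = []
    for ds, label in labels_by_dataset.items():
        entry = model[ds]
        v = float(entry.variances[_as_tier_index(label)])
        if normalized:
            if entry.u is None:
                raise ValueError(f"{ds}: model has no U; run estimate_u first")
            v /= entry.u**2
        vs.append(v)
    return float(np.mean(vs))


def welch_statistic(mean_j, mean_c, sigma2_j, sigma2_c, n_j: int, n_c: int):
    """Welch-type statistic; vectorized over regions.

    Zero pooled variance yields 0 for a zero mean difference and a signed
    infinity sentinel otherwise (ranked above every finite statistic).
    """
    mean_j = np.asarray(mean_j, dtype=float)
    mean_c = np.asarray(mean_c, dtype=float)
    denom = np.sqrt(np.asarray(sigma2_j) / n_j + np.asarray(sigma2_c) / n_c)
    diff = mean_j - mean_c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t if t.ndim else float(t)


def _cell_variances(matrix: SignalMatrix, model: ClusterModel) -> np.ndarray:
    """q x n matrix of normalized-scale cluster variances per observation."""
    if matrix.labels is None:
        raise ValueError("matrix has no cluster labels")
    out = np.empty_like(matrix.values)
    for j, ds in enumerate(matrix.dataset_ids):
        entry = model[ds]
        lut = entry.variances / entry.u**2
        out[:, j] = lut[matrix.labels[:, j]]
    return out


def _group_stats(
    matrix: SignalMatrix, cell_var: np.ndarray, group: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    idx = [matrix.dataset_ids.index(ds) for ds in group]
    return matrix.values[:, idx].mean(axis=1), cell_var[:, idx].mean(axis=1)


def observed_statistics(
    matrix: SignalMatrix, model: ClusterModel, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-region (mean_j, mean_c, sigma2_j, sigma2_c, T_obs) on the normalized scale."""
    cell_var = _cell_variances(matrix, model)
    mean_j, s2_j = _group_stats(matrix, cell_var, design.group_j)
    mean_c, s2_c = _group_stats(matrix, cell_var, design.group_c)
    t = welch_statistic(mean_j, mean_c, s2_j, s2_c, design.n_j, design.n_c)
    return mean_j, mean_c, s2_j, s2_c, t


def null_statistics(
    matrix: SignalMatrix,
    model: ClusterModel,
    groupings: list[tuple[tuple[str, ...], tuple[str, ...]]],
    n_j: int,
    n_c: int,
) -> np.ndarray:
    """q x z matrix of Welch statistics under the alternative regroupings."""
    cell_var = _cell_variances(matrix, model)
    cols = []
    for j_ids, c_ids in groupings:
        mean_j, s2_j = _group_stats(matrix, cell_var, j_ids)
        mean_c, s2_c = _group_stats(matrix, cell_var, c_ids)
        cols.append(welch_statistic(mean_j, mean_c, s2_j, s2_c, n_j, n_c))
    return np.column_stack(cols)


def pooled_pvalues(
    t_obs: np.ndarray, t_null: np.ndarray, pseudo: bool = False
) -> np.ndarray:
    """Pooled permutation p-values on |T|.

    p_i = #{(l, k): |T_l^k| > |T_i^obs|} / (q*z), counted over the entire
    pooled null (all regions x all regroupings). Ties count as "not greater"
    (strict inequality), so the minimum attainable p is 0; ``pseudo`` adds one
    to numerator and denominator for log-scale plotting.

    A region with |T_obs| = 0 (zero observed group difference) gets p = 1:
    every null statistic ties-or-exceeds zero, and a zero difference is never
    evidence of differential binding.
    """
    t_null = np.asarray(t_null, dtype=float)
    if t_null.size == 0:
        raise ValueError("empty null pool")
    pool = np.sort(np.abs(t_null), axis=None)
    n = pool.size
    abs_obs = np.abs(np.asarray(t_obs, dtype=float))
    greater = n - np.searchsorted(pool, abs_obs, side="right")
    p = (greater + 1) / (n + 1) if pseudo else greater / n
    return np.where(abs_obs == 0, 1.0, p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_c, mean_j, eps: float | None = None):
    """Signed fold change of group C relative to group J.

    FC = mean_C/mean_J when mean_C >= mean_J, else -mean_J/mean_C, so |FC| >= 1
    and the sign encodes direction. Zero denominators are replaced by ``eps``
    (caller-supplied; typically the smallest positive normalized value) to
    keep extreme changes finite but top-ranked; two zero means give FC = 1.
    """
    mean_c = np.atleast_1d(np.asarray(mean_c, dtype=float))
    mean_j = np.atleast_1d(np.asarray(mean_j, dtype=float))
    if np.any(mean_c < 0) or np.any(mean_j < 0):
        raise ValueError("means must be non-negative (normalized scale)")
    if eps is None:
        pos = np.concatenate([mean_c[mean_c > 0], mean_j[mean_j > 0]])
        eps = pos.min() if pos.size else 1.0
    both_zero = (mean_c == 0) & (mean_j == 0)
    if both_zero.any():
        warnings.warn("fold change of two zero means set to 1 (no change)")
    up = mean_c >= mean_j
    fc = np.where(
        up,
        mean_c / np.maximum(mean_j, eps),
        -mean_j / np.maximum(mean_c, eps),
    )
    fc = np.where(both_zero, 1.0, fc)
    return fc if fc.size > 1 else float(fc[0])


def analyze_signal(
    raw: SignalMatrix,
    design: GroupDesign,
    fdr: float = 0.05,
    seed: int | None = None,
    k: int = 4,
    restarts: int = 20,
    u_stat: str = "sd",
    pseudo_p: bool = False,
) -> tuple[pd.DataFrame, ClusterModel]:
    """Run the full test on a raw (IP-IN, clamped) signal matrix.

    Pipeline: zero-region filter -> Anscombe -> per-column k-means ->
    U normalization -> observed T -> exhaustive permutation null -> pooled
    p -> BH -> fold change. The result table is in input region order;
    filtered-out regions keep NaN statistics and ``retained = False``.
    """
    missing = [ds for ds in design.dataset_ids if ds not in raw.dataset_ids]
    if missing:
        raise ValueError(f"design names unknown datasets: {missing}")
    keep = filter_regions(raw)
    from .regions import RegionSet

    sub = SignalMatrix(
        regions=RegionSet([r for r, m in zip(raw.regions, keep) if m]),
        dataset_ids=list(raw.dataset_ids),
        values=raw.values[keep],
        stage="raw",
    )
    norm, model = preprocess(sub, k=k, restarts=restarts, seed=seed, u_stat=u_stat)
    mean_j, mean_c, s2_j, s2_c, t_obs = observed_statistics(norm, model, design)
    groupings = enumerate_null_groupings(design)
    t_null = null_statistics(norm, model, groupings, design.n_j, design.n_c)
    p = pooled_pvalues(t_obs, t_null, pseudo=pseudo_p)
    p_adj = bh_adjust(p)
    pos = norm.values[norm.values > 0]
    eps = float(pos.min()) if pos.size else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc = np.atleast_1d(fold_change(mean_c, mean_j, eps=eps))

    q = raw.q
    full = {
        name: np.full(q, np.nan)
        for name in ("mean_J", "mean_C", "sigma2_J", "sigma2_C", "T_obs", "p", "p_adj", "FC")
    }
    for name, vec in zip(
        ("mean_J", "mean_C", "sigma2_J", "sigma2_C", "T_obs", "p", "p_adj", "FC"),
        (mean_j, mean_c, s2_j, s2_c, t_obs, p, p_adj, fc),
    ):
        full[name][keep] = vec

    letters = norm.label_names()
    clusters = np.full(q, "", dtype=object)
    clusters[keep] = [",".join(row) for row in letters]
    df = pd.DataFrame(
        {
            "region_id": raw.regions.ids,
            "chrom": [r.chrom for r in raw.regions],
            "start": [r.start for r in raw.regions],
            "end": [r.end for r in raw.regions],
            "retained": keep,
            **full,
            "clusters": clusters,
        }
    )
    df["direction"] = np.where(df["FC"] >= 1, "up", "down")
    df.loc[~keep, "direction"] = ""
    df["significant"] = keep & (df["p_adj"].to_numpy() < fdr)
    return df, model


def run_db_analysis(
    ct,
    design: GroupDesign,
    fdr: float = 0.05,
    seed: int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, ClusterModel]:
    """End-to-end analysis from a :class:`~cssq.quantify.CountTable`.

    Subtracts input from IP (clamped at zero) and hands off to
    :func:`analyze_signal`; see there for the stages and result columns.
    """
    from .quantify import subtract_background

    raw = subtract_background(ct)
    return analyze_signal(raw, design, fdr=fdr, seed=seed, **kwargs)
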