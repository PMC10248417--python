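"""Variance-stabilizing transform, per-dataset clustering and normalization.

The signal model: background-subtracted counts ``X = IP - IN`` are mapped by
the Anscombe transform ``X^A = 2*sqrt(X + 3/8)`` to an approximately
variance-stabilized continuous scale, where each dataset's values are treated
as a finite Gaussian mixture. The mixture parameters are estimated by 1-D
k-means (k = 4, best of 20 random restarts), giving four signal tiers
named L (low), M (medium), H (high), S (super) in ascending mean order.
An estimated maximum ``U = mean_S + 3*SD_S`` — a three-sigma upper bound of
the top mixture component — rescales each dataset to a common [~0, 1] range:
``X* = X^A / U``. Cluster variances feed the differential-binding test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .regions import RegionSet

#: Cluster tier names in ascending mean order.
CLUSTER_NAMES = ("L", "M", "H", "S")

#: Anscombe transform of zero, the smallest attainable transformed value.
ANSCOMBE_AT_ZERO = 2.0 * np.sqrt(3.0 / 8.0)

_STAGES = ("raw", "anscombe", "normalized")


def anscombe_transform(x):
    """Anscombe variance-stabilizing transform, ``2*sqrt(x + 3/8)``.

    Defined for x >= 0 (negative signals must have been clamped upstream);
    strictly increasing, so column-wise ranks are preserved.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("anscombe_transform requires non-negative input")
    out = 2.0 * np.sqrt(x + 0.375)
    return out if out.ndim else float(out)


def inverse_anscombe(a):
    """Inverse of :func:`anscombe_transform`: ``(a/2)**2 - 3/8``, floored at 0.

    Values below ``2*sqrt(3/8)`` (the image of 0) are clamped to 0.
    """
    a = np.asarray(a, dtype=float)
    out = np.maximum((a / 2.0) ** 2 - 0.375, 0.0)
    return out if out.ndim else float(out)


@dataclass
class ClusterModelEntry:
    """Fitted four-tier 1-D mixture for one dataset (Anscombe scale).

    Arrays are ordered L, M, H, S (ascending cluster mean). ``variances`` are
    unbiased sample variances (0 for singleton clusters). ``u`` is the
    estimated maximum, mean_S + 3*SD_S.
    """

    dataset_id: str
    means: np.ndarray
    variances: np.ndarray
    sizes: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    u: float | None = None
    k: int = 4
    restarts: int = 20
    seed: int | None = None

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(self.variances)

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "cluster_names": list(CLUSTER_NAMES[: self.k]),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "sizes": self.sizes.tolist(),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "u": self.u,
            "k": self.k,
            "restarts": self.restarts,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModelEntry":
        return cls(
            dataset_id=d["dataset_id"],
            means=np.asarray(d["means"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            sizes=np.asarray(d["sizes"], dtype=int),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            u=d.get("u"),
            k=d.get("k", 4),
            restarts=d.get("restarts", 20),
            seed=d.get("seed"),
        )


@dataclass
class ClusterModel:
    """Per-dataset cluster models, keyed by dataset id."""

    entries: dict[str, ClusterModelEntry] = field(default_factory=dict)

    def __getitem__(self, dataset_id: str) -> ClusterModelEntry:
        return self.entries[dataset_id]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: e.to_dict() for k, e in self.entries.items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ClusterModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: ClusterModelEntry.from_dict(d) for k, d in raw.items()})


@dataclass
class SignalMatrix:
    """Region x dataset signal matrix carried through the transform stages.

    ``stage`` moves only forward: raw -> anscombe -> normalized. From the
    anscombe stage onward ``labels`` holds the per-cell cluster index
    (0..k-1 == L..S; -1 before clustering).
    """

    regions: RegionSet
    dataset_ids: list[str]
    values: np.ndarray
    stage: str = "raw"
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.dataset_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.regions)}, {len(self.dataset_ids)})"
            )
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in ("raw", "anscombe") and np.any(self.values < 0):
            raise ValueError(f"{self.stage}-stage values must be non-negative")

    @property
    def q(self) -> int:
        return len(self.regions)

    def label_names(self) -> np.ndarray | None:
        """Per-cell tier letters (object array), or None before clustering."""
        if self.labels is None:
            return None
        lut = np.array(CLUSTER_NAMES, dtype=object)
        return lut[self.labels]


def cluster_column(
    values: np.ndarray, k: int = 4, restarts: int = 20, seed: int | None = None,
    dataset_id: str = "",
) -> tuple[np.ndarray, ClusterModelEntry]:
    """1-D k-means on one dataset's Anscombe-stage values.

    Lloyd iterations with ``restarts`` random data-point initializations; the
    restart with minimal within-cluster sum of squares wins. Clusters are then
    relabeled in ascending mean order as L, M, H, S so the tier semantics do
    not depend on the arbitrary k-means label order.

    Returns
    -------
    labels : ndarray of int, shape (q,)
        Tier index per point (0=L .. k-1).
    entry : ClusterModelEntry
        Per-cluster mean, unbiased variance, size, min and max (``u`` unset).
    """
    from sklearn.cluster import KMeans

    values = np.asarray(values, dtype=float)
    n_distinct = np.unique(values).size
    if n_distinct < k:
        raise ValueError(
            f"need >= {k} distinct values to form {k} clusters, got {n_distinct}; "
            "use a smaller k"
        )
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=None if seed is None else int(seed) % (2**32 - 1),
    )
    raw_labels = km.fit_predict(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = rank[raw_labels]

    means = np.empty(k)
    variances = np.empty(k)
    sizes = np.empty(k, dtype=int)
    mins = np.empty(k)
    maxs = np.empty(k)
    for c in range(k):
        members = values[labels == c]
        sizes[c] = members.size
        means[c] = members.mean()
        variances[c] = members.var(ddof=1) if members.size > 1 else 0.0
        mins[c] = members.min()
        maxs[c] = members.max()
    return labels, ClusterModelEntry(
        dataset_id=dataset_id, means=means, variances=variances, sizes=sizes,
        mins=mins, maxs=maxs, k=k, restarts=restarts, seed=seed,
    )


def estimate_u(entry: ClusterModelEntry, stat: str = "sd") -> float:
    """Estimated maximum U = mean_S + 3 * SD_S of the top (S) cluster.

    ``stat="var"`` substitutes the variance for the SD (an alternative reading
    of the estimator's definition); the three-sigma SD form is the default.
    """
    if stat not in ("sd", "var"):
        raise ValueError("stat must be 'sd' or 'var'")
    mean_s = float(entry.means[-1])
    spread = float(entry.sds[-1] if stat == "sd" else entry.variances[-1])
    if entry.sizes[-1] <= 1:
        warnings.warn(
            f"{entry.dataset_id or 'dataset'}: singleton S cluster, U = mean_S"
        )
    u = mean_s + 3.0 * spread
    if u <= 0:
        raise ValueError("estimated maximum U must be positive")
    return u


def normalize_matrix(matrix: SignalMatrix, model: ClusterModel) -> SignalMatrix:
    """Divide each column by its dataset's U; cluster labels carry over."""
    if matrix.stage != "anscombe":
        raise ValueError("normalize_matrix expects an anscombe-stage matrix")
    us = np.array([model[ds].u for ds in matrix.dataset_ids], dtype=float)
    if np.any(~np.isfinite(us)) or np.any(us <= 0):
        raise ValueError("every dataset needs a positive U before normalization")
    out = SignalMatrix(
        regions=matrix.regions,
        dataset_ids=list(matrix.dataset_ids),
        values=matrix.values / us,
        stage="normalized",
        labels=None if matrix.labels is None else matrix.labels.copy(),
    )
    return out


def preprocess(
    matrix: SignalMatrix,
    k: int = 4,
    restarts: int = 20,
    seed: int | None = None,
    u_stat: str = "sd",
) -> tuple[SignalMatrix, ClusterModel]:
    """Full transform stage: Anscombe -> per-column k-means -> U normalization.

    Takes a raw-stage (IP - IN, clamped) matrix and returns the normalized
    matrix with per-cell tier labels plus the fitted :class:`ClusterModel`.
    Per-column clustering seeds are derived deterministically from ``seed``.
    """
    if matrix.stage != "raw":
        raise ValueError("preprocess expects a raw-stage matrix")
    ansc = SignalMatrix(
        regions=matrix.regions,
        dataset_ids=list(matrix.dataset_ids),
        values=anscombe_transform(matrix.values),
        stage="anscombe",
    )
    labels = np.empty(ansc.values.shape, dtype=np.int8)
    model = ClusterModel()
    seeds = derive_seeds(seed, len(matrix.dataset_ids))
    for j, ds in enumerate(matrix.dataset_ids):
        col_labels, entry = cluster_column(
            ansc.values[:, j], k=k, restarts=restarts, seed=seeds[j], dataset_id=ds
        )
        entry.u = estimate_u(entry, stat=u_stat)
        labels[:, j] = col_labels
        model.entries[ds] = entry
    ansc.labels = labels
    return normalize_matrix(ansc, model), model


def derive_seeds(seed: int | None, n: int) -> list[int | None]:
    """Derive n independent sub-seeds (< 2**31) from one root seed."""
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n)]
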