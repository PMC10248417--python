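import numpy as np
import pandas as pd
import pytest

import cssq


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded simulated experiment at reduced scale, shared across tests."""
    base = cssq.make_synthetic_base(4000, seed=101)
    cfg = cssq.SimulationConfig(dbi_fraction=0.025, seed=202)
    return cssq.generate_experiment(base, cfg)


@pytest.fixture(scope="session")
def design_2v2():
    return cssq.GroupDesign(("J1", "J2"), ("C1", "C2"))


@pytest.fixture(scope="session")
def analyzed_small(small_experiment, design_2v2):
    raw = cssq.signal_from_frame(small_experiment.counts)
    result, model = cssq.analyze_signal(raw, design_2v2, fdr=0.05, seed=7)
    return result, model


@pytest.fixture()
def tiny_bam(tmp_path):
    """Indexed BAM with a handful of hand-placed reads on chr1/chr2.

    Reads (0-based start, length 50):
      r1 chr1:100, r2 chr1:120, r3 chr1:140  -> inside [100, 200)
      r4 chr1:151                            -> 1 bp overlap with [100, 152)
      r5 chr1:500                            -> outside [100, 200)
      r6 chr2:10
    """
    import pysam

    sam = tmp_path / "tiny.sam"
    header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n@SQ\tSN:chr2\tLN:1000\n"
    reads = [
        ("r1", "chr1", 101),
        ("r2", "chr1", 121),
        ("r3", "chr1", 141),
        ("r4", "chr1", 152),
        ("r5", "chr1", 501),
        ("r6", "chr2", 11),
    ]
    lines = [
        f"{name}\t0\t{chrom}\t{pos}\t60\t50M\t*\t0\t0\t{'A'*50}\t{'I'*50}"
        for name, chrom, pos in reads
    ]
    sam.write_text(header + "\n".join(lines) + "\n")
    bam = tmp_path / "tiny.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return str(bam)


def brute_force_kmeans_1d(values, k):
    """Optimal 1-D k-means by enumeration of contiguous partitions of the
    sorted values (the optimum is always contiguous in 1-D). Returns
    (labels in ascending-mean order, total within-cluster SSQ)."""
    from itertools import combinations

    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    sv = values[order]
    n = len(sv)
    best = (np.inf, None)
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ssq, labels_sorted = 0.0, np.empty(n, dtype=int)
        for c in range(k):
            seg = sv[bounds[c]:bounds[c + 1]]
            ssq += float(((seg - seg.mean()) ** 2).sum())
            labels_sorted[bounds[c]:bounds[c + 1]] = c
        if ssq < best[0]:
            best = (ssq, labels_sorted.copy())
    labels = np.empty(n, dtype=int)
    labels[order] = best[1]
    return labels, best[0]


def bh_stepup_oracle(p):
    """Reference Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def pooled_p_oracle(t_obs, t_null):
    """O(q^2 z) double-loop exceedance count on absolute values."""
    t_obs = np.abs(np.asarray(t_obs, dtype=float))
    t_null = np.abs(np.asarray(t_null, dtype=float))
    q_z = t_null.size
    return np.array(
        [np.sum(t_null > t) / q_z for t in t_obs]
    )


def mann_whitney_auc(scores, flags):
    """AUC as the Mann-Whitney probability with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    pos, neg = scores[flags], scores[~flags]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def enumerate_partitions_oracle(ids, n_j):
    """All distinct two-group partitions by brute force, collapsing J<->C
    mirrors only when the sizes allow a mirror to exist."""
    from itertools import combinations

    ids = tuple(ids)
    n_c = len(ids) - n_j
    seen = set()
    for combo in combinations(ids, n_j):
        j = frozenset(combo)
        c = frozenset(ids) - j
        key = frozenset((j, c)) if n_j == n_c else j
        seen.add(key)
    return seen
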