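"""Scoring of differential-binding calls against simulation ground truth."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def score_calls(called, truth) -> tuple[float, float]:
    """Sensitivity and empirical FDR of a call set against the induced set.

    sensitivity = |called & truth| / |truth|;
    fdr = |called - truth| / |called| (0 when nothing was called).
    """
    called, truth = set(called), set(truth)
    if not truth:
        raise ValueError("truth set is empty: sensitivity undefined")
    tp = len(called & truth)
    sensitivity = tp / len(truth)
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return sensitivity, fdr


def roc_auc(scores, truth_flags) -> tuple[np.ndarray, float]:
    """ROC curve and area for a ranking score against binary truth.

    Thresholds sweep the unique score values (ties grouped into one step);
    the area is the trapezoidal integral, equal to the Mann-Whitney
    probability that a random positive outranks a random negative.

    Returns
    -------
    roc_points : ndarray, shape (t, 2)
        (FPR, TPR) pairs, monotone non-decreasing in both coordinates.
    auc : float
    """
    from sklearn.metrics import auc as _auc, roc_curve

    scores = np.asarray(scores, dtype=float)
    truth_flags = np.asarray(truth_flags, dtype=bool)
    n_pos, n_neg = truth_flags.sum(), (~truth_flags).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative region")
    if np.unique(scores).size == 1:
        warnings.warn("all scores identical: ROC is the diagonal, AUC = 0.5")
        return np.array([[0.0, 0.0], [1.0, 1.0]]), 0.5
    fpr, tpr, _ = roc_curve(truth_flags, scores)
    return np.column_stack([fpr, tpr]), float(_auc(fpr, tpr))


def ranking_score(result: pd.DataFrame) -> np.ndarray:
    """Per-region ranking score for ROC analysis: 1 - p, ties broken by |T|.

    Filtered-out regions score 0 (ranked below every tested region). The
    |T| tie-break is scaled below the p-value resolution so it never reorders
    regions with distinct p.
    """
    p = result["p"].to_numpy(dtype=float)
    t = np.abs(result["T_obs"].to_numpy(dtype=float))
    retained = result["retained"].to_numpy(dtype=bool)
    base = np.where(retained, 1.0 - p, 0.0)
    pos = p[retained & (p > 0)]
    resolution = pos.min() if pos.size else 1.0
    t_finite = np.where(np.isfinite(t), t, np.nanmax(np.where(np.isfinite(t), t, 0)) + 1.0)
    tie = np.where(retained, t_finite / (np.nanmax(t_finite) + 1.0), 0.0)
    return base + 0.5 * resolution * tie


def run_simulation_study(
    n_runs: int = 30,
    q: int = 20_000,
    dbi_fraction: float = 0.025,
    multiplier_mode: object = "variable",
    direction_up_prob: float = 0.5,
    fdr: float = 0.05,
    seed: int | None = None,
) -> list[dict]:
    """Repeat the simulate -> analyze -> score loop over independent seeds.

    Each run generates a fresh synthetic base (q regions), a four-replicate
    experiment with the requested induction, analyzes it end to end and scores
    the calls. Per-run metrics: ``sig_fraction`` (regions called significant);
    and, when anything was induced, ``sensitivity``, ``fdr`` and ``auc``.
    All randomness derives from ``seed``.
    """
    from . import (
        GroupDesign,
        SimulationConfig,
        analyze_signal,
        generate_experiment,
        make_synthetic_base,
        signal_from_frame,
    )

    design = GroupDesign(("J1", "J2"), ("C1", "C2"))
    root = np.random.SeedSequence(seed)
    runs: list[dict] = []
    for run_ss in root.spawn(n_runs):
        s_base, s_exp, s_ana = (int(s) % (2**31) for s in run_ss.generate_state(3))
        base = make_synthetic_base(q, seed=s_base)
        cfg = SimulationConfig(
            dbi_fraction=dbi_fraction,
            multiplier_mode=multiplier_mode,
            direction_up_prob=direction_up_prob,
            seed=s_exp,
        )
        exp = generate_experiment(base, cfg)
        result, _ = analyze_signal(
            signal_from_frame(exp.counts), design, fdr=fdr, seed=s_ana
        )
        metrics = {"sig_fraction": float(result["significant"].mean())}
        flags = exp.truth["induced"].to_numpy(dtype=bool)
        if flags.any():
            called = set(result.loc[result["significant"], "region_id"])
            truth_set = set(exp.truth.index[flags])
            sens, fdr_emp = score_calls(called, truth_set)
            _, auc = roc_auc(ranking_score(result), flags)
            metrics.update(sensitivity=sens, fdr=fdr_emp, auc=auc)
        runs.append(metrics)
    return runs


def aggregate_runs(results: list[dict]) -> dict:
    """Mean and sample SD of each metric across simulation runs."""
    if not results:
        raise ValueError("no runs to aggregate")
    keys = results[0].keys()
    summary: dict = {"n_runs": len(results), "per_run": results}
    for key in keys:
        vals = np.array([r[key] for r in results], dtype=float)
        summary[key] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }
    return summary
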