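# cssq

Quantification and differential-binding (DB) analysis of ChIP-seq signal over
predefined genomic regions, built for the common experimental reality of two
conditions with only a couple of replicates each.

ChIP-seq comparisons are hard because datasets differ wildly in depth and
dynamic range even between replicates, signal is zero-inflated and
multi-modal, and with n = 2 per group per-region sample variances are
worthless. This package addresses all three with a single pipeline:

1. **Signal**: reads overlapping each region are counted for the
   immunoprecipitated (IP) and matched input (IN) tracks, depth-normalized to
   10 million mapped reads, and background-subtracted:
   `X = max(IP − IN, 0)`.
2. **Variance stabilization**: the Anscombe transform
   `X^A = 2·sqrt(X + 3/8)` maps the Poisson-like counts to a continuous scale
   where the data are well approximated by a finite Gaussian mixture.
3. **Mixture parameterization**: per dataset, 1-D k-means (k = 4, best of 20
   random restarts) partitions `X^A` into *low/medium/high/super* tiers
   (L, M, H, S, ascending mean); each tier's mean and variance estimate one
   mixture component.
4. **Estimated-maximum normalization**: `U = x̄_S + 3·s_S` (a three-sigma
   upper bound of the top component) rescales each dataset to a common range:
   `X* = X^A / U`.
5. **Test**: for region *i* under a J-vs-C design, a Welch-type statistic

       T_i = (X̄*_iJ − X̄*_iC) / sqrt(σ²_iJ/n_J + σ²_iC/n_C)

   where σ²_iJ is the average, over the J replicates, of the variance of the
   k-means cluster each observation belongs to in its own dataset (rescaled
   by 1/U²) — the clustering supplies the variance that two replicates
   cannot. The null distribution pools T over all `z = C(n, n_J)/2 − 1`
   alternative regroupings of the replicate columns (for a 2 vs 2 design,
   z = 2) and all q regions; `p_i` is the pooled exceedance fraction of
   `|T_i|`, corrected by Benjamini–Hochberg, with DB called at FDR < 0.05 and
   effect size reported as a signed fold change of normalized group means.

A matched simulator generates four-replicate experiments with a zero-inflated
four-tier signal distribution and known induced DBs (shifts of 2–6 cluster
SDs on the C replicates), and a benchmark module scores calls by sensitivity,
empirical FDR and ROC AUC.

## Worked example

```python
import cssq

base = cssq.make_synthetic_base(q=8_000, seed=11)
cfg = cssq.SimulationConfig(dbi_fraction=0.025, multiplier_mode="variable", seed=12)
exp = cssq.generate_experiment(base, cfg)

design = cssq.GroupDesign(("J1", "J2"), ("C1", "C2"))
result, model = cssq.analyze_signal(
    cssq.signal_from_frame(exp.counts), design, fdr=0.05, seed=13
)
```

Running `python examples/differential_binding.py` (which is exactly this)
prints:

```
simulated 8000 regions x 4 datasets; 200 induced DBs; U_sim = 52.8, 52.4, 57.2, 51.3
retained 6336 regions after the zero filter; 140 significant DBs at FDR 0.05

strongest calls (direction 'up' = C gains signal over J):
  region_id  mean_J  mean_C  T_obs  p_adj    FC direction
region_2746   0.631   0.126   8.27      0 -4.99      down
...
against truth: sensitivity 0.68, empirical FDR 0.04
```

`mean_J`/`mean_C` are normalized group means; `T_obs` is the group difference
in units of its cluster-borrowed standard error; `FC` is the signed ratio of
group means (|FC| ≥ 1, negative = loss in C). Here the pipeline recovers 68%
of the induced DBs while keeping the empirical false discovery rate at 0.04.

Other entry points, one short script each under `examples/`:
`transform_and_normalize.py` (tier model and U factor),
`quantify_from_bam.py` (BED + BAM counting), and
`simulation_benchmark.py` (multi-seed benchmarking). The same capabilities
are exposed as a thin CLI: `cssq quantify | analyze | simulate | benchmark`
(see `cssq --help`).

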