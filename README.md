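# restgraph

Resting-state functional brain-network topology pipeline: from region-of-interest
(ROI) time series to binary small-world graphs across a density sweep, to
group-level and node-level statistical comparison with permutation tests.

The scientific workflow it implements is the classic graph-theoretical analysis
of resting-state fMRI cohorts (e.g. patients vs controls):

1. **Preprocessing** — nuisance regression (intercept, linear drift, motion
   parameters) and an optional zero-phase 0.01–0.08 Hz band-pass filter;
   subjects exceeding 3 mm translation or 3° rotation are screened out.
2. **Connectivity** — Pearson correlation between every pair of regional
   series, Fisher r-to-z transformed and taken in absolute value, giving a
   symmetric non-negative association matrix per subject.
3. **Network construction** — the maximum spanning tree of the association
   matrix is kept as a backbone (guaranteeing connectedness), then the
   strongest remaining connections are added until the graph holds exactly
   `round(cost · N(N−1)/2)` edges. This is repeated over a density (cost)
   sweep of 4%–40% in steps of 2% (19 densities); edge sets are nested.
4. **Graph metrics** — clustering coefficient `C_p`, characteristic path
   length `L_p`, global efficiency `E_glob` and local efficiency `E_loc`,
   globally and per node; small-world ratios `γ = C_p/C_p^rand`,
   `λ = L_p/L_p^rand`, `σ = γ/λ` against degree-preserving,
   connectivity-preserving random nulls (Maslov–Sneppen double edge swaps).
5. **Group statistics** — per-density two-sample Student t tests with
   label-permutation p-values (exhaustive below 20,000 distinct splits,
   Monte-Carlo with the add-one estimator above), nodal alteration-frequency
   profiling over the density sweep, and pairwise subgroup contrasts.

Because no public data release exists for this study design, the package ships
a seeded **synthetic cohort generator**: each group carries a planted
Watts–Strogatz graph, turned into a unit-diagonal positive-definite covariance
(`I + s·A`, minimally eigenvalue-shifted when needed), from which each
subject's T×N series is drawn as independent multivariate-normal volumes plus
white noise. A group with a lower rewiring probability has a more lattice-like
planted topology — higher clustering, longer path length — which is the
direction of the patient/control contrast the analysis stage is meant to
recover.

## Quick start

Run the default two-group synthetic study (33 patient-like vs 20 control-like
subjects, 90 regions, 155 volumes at TR = 2 s) end to end:

```bash
restgraph run --seed 1 --outdir run1
```

This writes, under `run1/`: the cohort as TSV, per-subject and group-mean
connectivity matrices, a tidy `metrics/metrics.csv` table, comparison tables
(`stats/global_comparison.csv`, `stats/nodal_comparison.csv`), the nodal
alteration profile, a plain-text report and a provenance manifest. The same
config and seed reproduce every artifact byte for byte.

Other CLI verbs: `restgraph simulate` (cohort generation only),
`restgraph metrics` (graphs + metrics from existing connectivity CSVs),
`restgraph stats` (group analysis on an existing metric table),
`restgraph validate` (check a file-mode cohort manifest).

## Worked example (library API)

```python
import pandas as pd
from restgraph import (
    DensityGrid, compare_global_metrics, connectivity_matrix,
    density_sweep, metric_table, sample_cohort,
)
from restgraph.synthetic import default_cohort_spec

series, traces, manifest = sample_cohort(default_cohort_spec(seed=1))
grid = DensityGrid()           # 0.04, 0.06, ..., 0.40

tables = []
for ts in series:
    conn = connectivity_matrix(ts)          # |Fisher z| of Pearson r
    graphs = density_sweep(conn, grid)      # 19 nested binary graphs
    tables.append(metric_table(ts.subject_id, graphs, include_nodal=False))
table = pd.concat(tables, ignore_index=True)

cmp = compare_global_metrics(table, manifest[["subject_id", "group"]], grid,
                             n_perm=10_000, seed=0)
print(cmp[cmp.metric == "clustering"][["cost", "t_statistic", "p_parametric"]])
```

At seed 1 this recovers the planted contrast clearly at the fixed 22% density:
patient-like mean clustering 0.273 vs control-like 0.240 (t ≈ +16.5), local
efficiency 0.589 vs 0.561 (t ≈ +13.8), global efficiency 0.6075 vs 0.6083
(t ≈ −6.5), and small-world γ ≈ 1.24 vs 1.10 with λ ≈ 1.00 in both groups.
Clustering and local efficiency differ significantly in the planted direction
at all 19 densities; the path-length/global-efficiency contrast genuinely
fades above ~26% density, where nearly all node pairs are within two hops and
`L_p` becomes an almost deterministic function of density (see
`docs/methods.md`).

## Layout

- `src/restgraph/` — library (`synthetic`, `preprocess`, `connectivity`,
  `construction`, `metrics`, `stats`, `pipeline`, `cli`, …)
- `tests/` — unit, property and acceptance tests (brute-force metric oracles
  live in `tests/conftest.py`)
- `scripts/acceptance.py` — headline-quantity evaluation
- `docs/methods.md` — methods note: model, parameter choices, numerical
  details and known limitations
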