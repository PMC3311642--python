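# Methods note

This note records what `restgraph` computes, the defaults it ships with and
why, and the numerical choices that affect results.

## Synthetic cohort model

Each group is defined by a planted connected Watts–Strogatz graph on the
N = 90 regions: a ring lattice with `lattice_neighbors = 3` neighbours per
side (degree 6) whose edges are rewired with probability `rewire_prob`
(generation is retried, fresh randomness, up to 100 times until connected).
The default study cohort plants `rewire_prob = 0.05` for the 33 patient-like
subjects (lattice-like: high clustering, long paths) and `0.35` for the 20
control-like subjects (more random: lower clustering, shorter paths).

The planted graph A becomes a covariance `Σ = I + s·A` with
`edge_strength s = 0.4`. When `Σ` is not positive definite it is repaired by
the minimal uniform eigenvalue shift and rescaled back to unit diagonal; the
shift preserves the edge/non-edge ordering of entries but lowers the effective
edge correlation, and it differs between topologies (≈0.31 effective strength
for the lattice-like group vs ≈0.24 for the random-like group at the default
parameters). Subject series are T = 155 independent rows of `N(0, Σ)` (no
temporal autocorrelation) plus white measurement noise with `noise_sd = 0.25`,
chosen as modest sensor noise relative to the unit-variance signal of
region-averaged series. Zero-motion traces are attached: the generator does
not emulate head movement.

Seeding uses numpy `SeedSequence` spawn keys — master seed plus (group index,
subject index) — so adding subjects or groups never reshuffles the streams of
earlier subjects. All derived integer seeds are reduced below 2³¹.

## Preprocessing

Nuisance regression removes an intercept, a linear drift and any non-constant
motion-parameter columns by ordinary least squares; rank-deficient designs are
rejected with the offending columns named. The band-pass filter is a
zero-phase (forward–backward) order-2 Butterworth, 0.01–0.08 Hz at the
configured sampling interval; an FFT brick-wall alternative is available.
Verified gains: ≈0.985 at 0.045 Hz in-band, ≈6·10⁻⁴ at 0.2 Hz out-of-band.

**Default band-pass policy.** For file-based (real) data the filter is on by
default. For synthetic cohorts it is off by default (`do_bandpass: null` =
auto): the generator's series are temporally white with no drift or
physiological noise, so the filter has nothing to remove and only cuts the
effective number of independent volumes from ~152 to ~43, roughly doubling the
sampling error of each correlation (0.08 → 0.15) against planted effective
edge strengths of 0.24–0.31. That error mis-ranks edges during thresholding
and injects random shortcuts that destroy the planted path-length contrast.
Either behaviour can be forced via config.

Motion screening follows the mean-relative-displacement style summary
(per-volume differences of the translation/rotation traces, Euclidean norm)
plus per-axis maxima, with strict less-than 3 mm / 3° inclusion rules.

## Connectivity and graph construction

Pearson correlations (`numpy.corrcoef`) are Fisher r-to-z transformed with
|r| clamped at 1 − 10⁻⁷, then taken in absolute value; diagonals are exactly
zero and zero-variance regions raise an error naming the region. Graphs keep
the maximum spanning tree (Kruskal; deterministic lexicographic tie-breaks on
(−weight, i, j)) plus the strongest remaining edges until exactly
`round(cost · N(N−1)/2)` edges (round half up). The whole 19-density sweep is
one edge ranking (tree edges first, then non-tree edges by descending weight),
so edge sets are nested across densities and every graph is connected;
densities too small to hold the tree are rejected.

## Metrics and null models

Clustering uses the triangle count `((A·A)∘A)/2` per node; path length and
efficiencies use unweighted Dijkstra distances (scipy `csgraph`); local
efficiency is the global efficiency of each node's neighbour-induced subgraph.
Degree-preserving nulls are Maslov–Sneppen double edge swaps (10 swaps per
edge) with connectivity enforced by an adaptive commit window: batches of
swaps are reverted if they disconnect the graph, and the attempt budget is
bounded so swap-free graphs (e.g. a triangle) fall through unchanged with a
logged warning. Small-world ratios are γ = C_p/C_p^rand, λ = L_p/L_p^rand,
σ = γ/λ against the ensemble means of 100 nulls.

**Problem-size choice.** Building 100 nulls per subject at all 19 densities is
~2 orders of magnitude more rewiring work than the scientific question needs,
so the run config exposes `smallworld_costs` (default: only the fixed 22%
density) for where the null ensemble and γ/λ/σ are computed. Any cost set can
be requested.

## Group statistics

Per (metric, density): two-sample Student pooled-variance t (Welch optional)
with a two-sided label-permutation p-value for |t| — exhaustive enumeration
when the number of distinct splits is ≤ 20,000, otherwise 10,000 Monte-Carlo
shuffles with the add-one estimator (so p ≥ 1/(n_perm+1)). Within one
(metric, density) family nodal tests share a single stream of label shuffles
across regions, preserving the spatial correlation of the permutation null.
The `significant` flag is `p_parametric < 0.05`; no multiple-comparison
correction is applied by default (Benjamini–Hochberg is available). The nodal
alteration profile counts, per (region, metric), the densities with p < α and
retains pairs altered at strictly more than 10 of the 19 densities. Pairwise
subgroup contrasts reuse the same machinery for each unordered subgroup pair.

## Known limitations

- The generator's series are temporally white; the band-pass interaction
  described above is therefore a property of the simulation, not of the
  pipeline, and the filter defaults off only in synthetic mode.
- The positive-definiteness repair makes effective edge strength depend on the
  planted topology, so the two groups differ slightly in connectivity SNR as
  well as in topology.
- Above ~26% density the thresholded graphs approach diameter 2, so `L_p`
  tends to `2 − cost` — an almost deterministic function of density. Group
  contrasts in path length and global efficiency genuinely vanish there (and
  near-zero between-subject variance can make microscopic differences
  statistically "significant" in either direction). Clustering and local
  efficiency remain discriminative across the full sweep. Density-sweep
  findings for `L_p`/`E_glob` should therefore be read over the low-to-middle
  density range.
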