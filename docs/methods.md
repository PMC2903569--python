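# Methods

`epireg` predicts epigenetically regulated genes — genes whose expression
tracks promoter CpG-island methylation inversely — from two tabular
inputs measured on a shared panel of cell lines: per-CpG methylation
percentages with genomic coordinates, and per-probe-set expression values
with gene symbols and genomic ranges. The protocol has three stages.

## Stage (i): two-step dimensionality reduction

Genome-wide methylation screens produce far too many sites for
per-association permutation testing, so sites are first compressed into
representative profiles.

**Proximity grouping.** Within each chromosome, successive sites whose
positions differ by at most `gap_bp` (default 2,000 bp) are aggregated
into one region; a gap strictly greater than the threshold starts a new
region. The boundary is inclusive: a spacing of exactly 2,000 bp merges.
Distance is measured between successive site positions, not region spans,
so grouping is a single linear scan and idempotent.

**PCA compression.** Methylation profiles (sites × cell lines) are
mean-centered per cell line and projected onto the smallest number of
principal components whose cumulative explained variance reaches
`variance_target` (default 0.99). The PCA is fitted once on the full
matrix rather than per region, because inter-line correlation is a
panel-wide property; per-region PCA on a handful of sites would be badly
conditioned. Components use exact SVD with a deterministic sign
convention (largest-magnitude loading positive).

**K-spectral clustering (KSC) with automatic model selection.** Each
region's site profiles, in component space, are clustered by:

1. Gaussian affinity `A_ij = exp(-||s_i - s_j||^2 / (2 sigma^2))` with
   `A_ii = 0`;
2. symmetric normalization `L = D^(-1/2) A D^(-1/2)` with `D_ii` the
   row sums of `A`;
3. the matrix `X` of eigenvectors for the `k` algebraically largest
   eigenvalues of `L`, row-normalized to unit length to give `Y`;
4. k-means on the rows of `Y`; each site inherits its row's cluster.

The bandwidth `sigma` and cluster count `k` are selected by exhaustive
grid search minimizing the compactness ratio `W/B`, where `W` is the
largest distance from a point to its own cluster center and `B` the
smallest distance between two centers. Compactness is evaluated in the
spectral embedding (rows of `Y` against the k-means centers), the
clustering's native geometry; evaluating it in input space is possible
but mixes two metrics. Coincident centers (`B = 0`) reject the pair;
if every pair is rejected, the region falls back to a single cluster
with a warning. Since no canonical grids exist for this selection,
the defaults are `sigma` on 8 log-spaced values between 0.1x and 10x
the median pairwise distance of the region's points, and
`k ∈ {2, ..., min(8, n-1)}`. Regions with fewer than 3 sites bypass
clustering as one cluster.

Each final cluster is summarized by a representative profile — the
nan-mean of its members' **original** methylation percentages (not PCA
coordinates) — and an anchor: the member site nearest the cluster's
positional centroid.

Determinism: k-means runs 10 seeded restarts (best within-cluster sum of
squares, ties to the lowest restart index); eigenvector signs are fixed
by forcing the largest-magnitude entry positive; per-region seeds derive
from the run seed.

## Stage (ii): methylation-expression association

A representative (its anchor) is associated with every expression probe
set on the same chromosome whose range, extended symmetrically by
`window_bp` (default 20,000 bp) on both sides, contains the anchor
position; both boundaries are inclusive. The window absorbs the
positional uncertainty of a CpG island relative to its gene; strand is
ignored because the window is symmetric. Genes with multiple probe sets
yield multiple associations, and one representative can match several
probe sets. Coordinates are 1-based with inclusive ranges throughout;
the BED-dialect reader converts on input. The sweep implementation is
checked against an all-pairs oracle in the tests.

## Stage (iii): sigmoid regression and permutation ranking

Expression values are first de-logged (`log_base` defaults to 2, the
expression-array convention) and min-max normalized to [0, 100] using the
global minimum and maximum over all probe sets and cell lines jointly, so
both modalities share a percentage scale.

Each association's expression profile `E` is regressed on its methylation
profile `M` with the three-parameter monotone-decreasing logistic

    E_fit(M) = a / (1 + exp(b (M - c))),
    a ∈ [0, 200],  b ∈ [1e-8, 50],  c ∈ [-50, 150],

chosen because the target relation is hypermethylation with
down-regulation; the nonnegativity of `b` enforces the decreasing
direction, and the `1e-8` floor (numerically indistinguishable from a
constant curve over the 0–100 range) keeps fitted values off the exact
constant boundary so permutation statistics remain tie-free (see below).
Pairs with a missing value on either side are dropped; fewer than four
pairs skips the association. An exactly constant expression profile is
handled as the explicit degenerate case (`R = 0`).

Fit quality is scored by

    R = SSR / (SSR + SSE),
    SSR = sum((E_fit - mean(E))^2),  SSE = sum((E_fit - E)^2),

which lies in [0, 1], equals 1 exactly at a perfect fit, and 0 for the
degenerate constant fit.

**Optimizer.** The least-squares problem is solved by a projected
Levenberg-Marquardt from eleven deterministic starts: nine canonical ones
(`c` at the 25/50/75th percentiles of `M` crossed with
`b ∈ {0.05, 0.2, 1}`, `a = max(E)`) plus the two best points of a coarse
`(b, c)` grid scan in which `a` is profiled out analytically (the model
is linear in `a` for fixed `b, c`). The grid seeds rescue fits whose
optimum lies far from the canonical starts, which matters for the many
near-null refits of the permutation test. The kernel is jit-compiled
(numba) because a single ranking run refits the curve on the order of
10^5 times; it is validated in the test suite against scipy's bounded
trust-region least squares on random instances and against a dense
(a, b, c) lattice search.

**Permutation p-value.** For each association, the methylation vector is
shuffled `m_perm` times (default 10,000) against the fixed expression
vector and the curve refitted from scratch with the identical procedure;
`p = #{m : R_m >= R_obs} / m_perm` (an add-one variant is available).
Per-association seeds derive from the run seed and a stable hash of the
association id, so results do not depend on iteration order.

*Tie handling.* Under the one-sided constraint, associations with no
decreasing trend at all have a constant-curve optimum whose `R` depends
on the methylation values only through their multiset — it is invariant
under permutation. For such associations the observed and permuted
scores tie exactly, and counting ties as exceedances would place a large
atom of null p-values at 1 (an exhaustive search puts the constant-optimal
fraction near one third of signal-free associations at n = 45). The
package therefore applies the classical randomized-test correction:
strict exceedances count fully, and exact ties (within 1e-9) contribute a
seeded uniform share. This leaves every association with signal
unchanged — perfect fits still print p = 0 — and makes the null p-value
distribution uniform, which the calibration tests verify. The
consequence is that a completely uninformative association receives a
large randomized p-value rather than exactly 1.

**Gene ranking.** Per gene, the association with maximal `R` is kept
(ties: smaller p, then lexicographic association id); genes with
`p < alpha` (default 0.05) are reported sorted by descending `R`. No
multiple-testing correction is applied to the filter; a
Benjamini-Hochberg column is emitted alongside for the reader.

## Synthetic data

The generator emulates the structure the pipeline assumes, at roughly
1/100 the scale of a genome-wide screen so full-pipeline tests run in
seconds to minutes: 45 cell lines (the breast-cancer panel names), 60
genes, ~23 sites per promoter clump, 15% regulated genes, noise standard
deviation 5 percentage points. Sites fall in tight clumps (mean
intra-clump spacing 80 bp; inter-clump gaps at least 45,000 bp, chosen so
a probe set can only ever associate with its own clump). Within a clump,
2-3 sub-groups share latent methylation profiles built from shared
line-correlation factors plus independent noise, clipped to [0, 100].
Regulated genes' expression follows a decreasing logistic of the promoter
sub-group's latent methylation plus noise; null genes' expression is
independent of methylation. Expression is emitted on log2 scale, and two
anchor values pin the global normalized range to exactly [0, 100] so the
pipeline's normalization inverts the emission map — at zero noise every
regulated gene is recoverable with `R = 1` exactly.

What the generator does **not** emulate: probe-level measurement
chemistry and bisulfite-conversion artifacts; genomic covariates (CpG
density, copy-number variation) that confound real methylation-expression
relationships; heavy-tailed or batch-structured noise; overlapping or
nested genes. At the default noise the inter-line correlation is also
weaker than a real panel's, so the panel-wide PCA keeps more components
than a real screen would. Passing tests therefore demonstrate
correctness of the algorithmic chain and statistical calibration under
the stated model, not performance on real arrays.

## Numerical choices and degenerate inputs

- Missing methylation values are NaN: imputed with per-line means for
  PCA/spectral clustering only; representatives use nan-means; curve
  fits use pairwise deletion.
- Isolated points (zero affinity row sum) raise, naming the point;
  an all-rejected parameter grid falls back to one cluster.
- Zero rows in the spectral embedding are left at zero with a warning.
- Table outputs are written with `%.10g` floats; identical configuration
  and seed reproduce byte-identical files.
- Problem sizes in the shipped tests and the acceptance script (panels
  of 30-90 genes, 500-permutation tests, 300-point clustering problems)
  were chosen as the smallest sizes at which the statistical checks have
  meaningful power.

## Known limitations

- The compactness ratio, the sigmoid form, `R`, and the p-value formula
  reconstruct relations whose printed equations are unavailable; each is
  implemented behind a small interface (`compactness`, `fit_curve`,
  `compute_R`, `permutation_pvalue`) so alternate forms can be swapped.
- The `(sigma, k)` grid search refits k-means for every pair and
  dominates stage (i) runtime on large panels.
- Associations inherit probe-set coordinates as given; no transcript
  annotation, strand logic, or TSS inference is attempted.
- p-values are raw; the emitted BH column is advisory only.
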