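# Methods

## The multistep incidence-age model

A disease whose onset requires *n* sequential, independent,
rate-limiting steps with small per-year background risks *u₁ … uₙ* has
incidence i(t) = u·t^(n−1) with u = ∏ uₖ, valid in the regime where no
step is close to saturation. Taking logs gives a straight line of slope
m = n − 1 and intercept c = log u, so n is estimated as round(m + 1)
from an ordinary least-squares fit of log₁₀(incidence) on log₁₀(age).
The slope is invariant to the log base; the intercept is converted to
natural log before computing u = e^c and the per-step geometric mean
μ(u) = u^(1/n).

Model assumptions worth keeping in mind: steps occur in a fixed order at
age-independent rates, mortality from competing causes does not deplete
the at-risk population differentially, and the observed incidence is an
unbiased estimate of the onset rate. None of these hold exactly in old
age, which motivates the truncation rule below.

### Data preparation conventions

- **Representative age of a bin = midpoint.** Studies report incidence
  over age bins; the package takes the bin midpoint as the age of the
  pooled observation. This is the least-biased simple choice when the
  within-bin trend is near-linear on the log scale.
- **Pooling.** All bins of all studies of one stratum enter the fit as
  separate points (no pre-averaging), preserving sample size. The
  harmonized-average path exists separately for the matrix analyses.
- **Zero-incidence bins** are dropped before the log transform.
- **Truncation at 80 years.** Bins with midpoint ≥ 80 years are dropped,
  but only if at least 4 points remain afterwards; otherwise no
  truncation is applied. Late-age incidence estimates are distorted by
  survivor depletion and under-ascertainment; the 4-point floor keeps
  sparse strata fittable.
- **Rounding** of m + 1 is half-up with a floor of 1, reproducing the
  conventional mappings 4.8 → 6 and 4.6 → 6.

### The linearity gate

Not every disease follows a multistep law — multiple sclerosis is the
standard counterexample, with a unimodal incidence peaking in early
adulthood. The package makes the inclusion decision explicit: a stratum
"follows the multistep model" iff its log-log fit has R² ≥ 0.8 **and** a
positive slope (both configurable). Gated-out strata are excluded from
step allocation and from the steps-vs-range regression but stay in the
harmonized matrix and the embeddings, and are drawn as reference leaves
beside the genealogy tree.

## Stratum naming

Labels ending in lowercase `f`/`m` are the female/male strata of a
disease; all-uppercase labels are the pool of both sexes (ADf, ADm, AD).
The registry filter drops a pooled dataset when the same study also
contributes both sex-annotated counterparts (double counting), plus an
explicit, configurable exclusion list of study IDs.

## Harmonization and the incidence matrix

Each study's (midpoint, incidence) trajectory is modelled with a natural
cubic spline (second derivative zero at the boundary knots; linear
interpolation when only 2 bins exist) and evaluated on a common age
grid, by default integer ages 30–79. Values are **never extrapolated**
outside a study's observed midpoint range — cells are marked missing
instead, because cubic splines diverge quickly outside their support.
Negative spline excursions (possible between oscillating knots) are
clipped to 0. Per stratum, study trajectories are averaged at each
covered grid age, giving the d × a matrix I with I(i, j) = mean
incidence of stratum i at age j, plus a per-cell coverage count.

## Embeddings

Profiles (per-dataset by default; per-stratum rows of I via config) are
log₁₀-transformed, restricted to complete-case columns (ages covered by
every profile with strictly positive values), column-centered and
decomposed by SVD (PCA). Centering without unit-variance scaling is
deliberate: the amplitude differences between disease tiers are signal,
not nuisance. UMAP runs on the same log profiles with defaults
n_neighbors = 5, min_dist = 0.3 and a fixed seed; all parameters are
recorded in the embedding object.

## Age ranges and years per step

The onset age range of a stratum is the interval from the start of its
first nonzero-incidence bin to the end of its last one, unioned over
studies, after the same ≥ 80-year truncation rule used in the fit (edge
semantics by default; midpoint semantics available). Years per step =
range width / n. The steps-vs-range analysis regresses the (integer,
post-rounding) step count on the range width over gate-passing strata.
Shared-age-range counts partition the overall age axis into bins
(default width 2 years, anchored at the overall minimum); a stratum
counts toward a bin only if its range covers the whole bin.

## The genealogy tree

Sharing of steps between diseases is constrained by two parsimony
criteria: **ordinal preservation** (step k of one disease can only be
identified with step k of another, so a disease with n steps can share
ordinals 1..n only) and **shared-step maximization** (among admissible
schemes, maximize the total number of (disease, ordinal) sharing
incidences). The output must be a single trunk with branch-offs, so the
sharing sets along ordinals are required to be nested.

Under nestedness, a sharing scheme is fully determined by the set C of
co-sharing diseases: the set sharing ordinal k is S_k = {d ∈ C : n_d ≥
k}, automatically a decreasing chain, and a member's common steps equal
min(n_d, K) where K is the deepest ordinal still shared by two diseases.
`allocate_steps` therefore searches exactly over the pairwise-compatible
candidate sets (the ordinal-1 columns of the sharing matrix) rather than
greedily picking the largest subset ordinal by ordinal — the greedy can
be trapped by a large clique of short diseases when compatibility
constraints exist, while the exact search is cheap at these instance
sizes (≤ 16 diseases). With complete compatibility the two coincide. An
independent brute-force enumerator over all subsets serves as the test
oracle on small instances.

Which diseases are *biologically* allowed to share steps is not
derivable from incidence data alone; the package exposes it as an
injectable pairwise compatibility predicate, complete by default (so the
maximal nested tree is returned unless the caller supplies domain
constraints). Ties between equally good sharing sets are broken by
preferring the set containing the larger step counts, then
lexicographically — an arbitrary but deterministic rule. "Promoter"
bookkeeping attributes each shared ordinal once, to the first disease in
label order of its sharing set.

The extended tree places a branch point at every distinct common-step
count; the trunk width there is the arithmetic mean of the years/step of
the diseases branching off. Tier bands: stem < 3 steps, trunk-level 5–7,
crown > 7; counts of 3–4 fall between the published bands and are
labelled unclassified. In sex-split mode, male branches render on the
left and female on the right.

## The synthetic-data generator

The generator emulates a multi-study incidence collection: per stratum a
true step count n, a background risk u (parameterized for convenience by
the incidence at a reference age), a designed onset age range tiled by
age bins, multiplicative log-normal noise on incidence (keeping values
positive and making the log-log error additive Gaussian — chosen to
match the model being fitted, not inferred from real data), several
independent studies per stratum, and per-study bin-scheme jitter (edges
shifted by up to 2 years) to exercise the spline harmonization. The
non-monotone control uses a Gamma-density-like curve
i(t) = i_peak·(t/t_peak)^a·exp(a(1 − t/t_peak)) with t_peak = 30 years
and sharpness a = 12, emulating an early-adult incidence peak with
vanishingly rare late-life onset.

The default panel holds ten multistep strata spanning the three tiers —
step counts {2, 6, 6, 6, 6, 8, 9, 11, 12, 13} — with onset ranges
designed inversely to the step counts (width 65 years for the 2-step
stratum down to ~22–27 years for the crown strata), all overlapping on
ages 60–78, and reference incidences at age 70 set to realistic
magnitudes (0.6 per 100,000 person-years for the HD-like stratum up to
800 for the AD-like one). Default noise sigma is 0.1 (≈ 10% incidence
error) with 3 studies per stratum. These defaults were fixed at design
time from real-world incidence magnitudes.

What the generator does **not** emulate: registry-specific sample sizes
and their sampling error (noise is homoscedastic on the log scale),
cohort and period effects, diagnostic-criteria drift between studies,
competing mortality, and correlated errors within a study. Passing tests
therefore demonstrate that the pipeline recovers the designed structure
under idealized power-law data with moderate noise — not that real
collections satisfy the multistep model.

## Numerical choices and degenerate inputs

- OLS via `scipy.stats.linregress`; a two-point fit has R² = 1 by
  construction; zero age-variance raises a fit-infeasible error.
- Spline interpolation via `scipy.interpolate.CubicSpline`
  (`bc_type="natural"`); knot reproduction is exact to arithmetic
  precision.
- A stratum whose fitted slope is ≤ −1 (no valid step count) is assigned
  n = 1 for bookkeeping; it necessarily fails the linearity gate.
- CSV floats are read with pandas' round-trip parser so write→read is
  lossless; all tables carry the config hash that produced them, and the
  pipeline is byte-deterministic for a fixed config.
- Problem sizes in the shipped studies (200 replicates per recovery
  condition, 100 control replicates, 50 random allocation instances,
  3 studies × 11 strata in the default panel) keep every stage
  well-resolved while the full suite runs in well under a minute.

## Known limitations

- Step counts carry no confidence intervals; the rounding step makes the
  estimate discrete and its uncertainty non-Gaussian.
- The compatibility constraints that would restrict step sharing between
  specific real diseases are unknown; the default complete predicate
  yields the maximal nested tree, an upper bound on sharing.
- The pooled-points fitting convention (vs. fitting each study and
  combining estimates) is a design choice; with heterogeneous study
  sizes it weights studies by their bin counts.
- Incidence is treated as noisy but unbiased; no competing-risk or
  ascertainment correction beyond the 80-year truncation.
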