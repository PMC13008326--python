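# Methods

This note records the models, numerical conventions and design choices
behind `angiotop`, in the package's own words.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Simulators

All three models run in `[0, L]²` (default `L = 1`, dimensionless) with a
tumour along `y = L`.  VEGF is a static nondimensional field `c(x, y) ∈
[0, 1]`, non-decreasing in `y`; two initial profiles are built in (`linear`:
`c = y/L`; `exponential`: `c = exp(−k(L − y)/L)`, default `k = 3`).
Fibronectin (AC only) starts at `1 − 0.4 y/L` and is produced/degraded at
EC-occupied sites (`f ← f + dt(0.05 − 0.1 f)`, clipped to `[0, 1]`);
it can be frozen with `fibronectin_dynamic=False`.  Tips are seeded evenly
along the bottom edge (default 5), ages zero.  Side and bottom walls
reflect; the top edge absorbs (the tip has reached the tumour).

**AC.**  Tips live on the `R × R` lattice (spacing `h = L/(R−1)`).  Per step
the five moves (stay, ±x, ±y) get weights

    w_stay = s0,   w_dir = max(0, D + χ(c)·Δc/h + ρ·Δf/h),

with `Δc`, `Δf` the concentration differences to the target site, defaults
`D = s0 = 1`, and `χ(c) = χ/(1 + αc)` with `α = 0` (constant sensitivity) by
default.  Weights are clamped at zero (strong adverse gradients cannot
produce negative probabilities), off-lattice moves get weight zero, and the
vector is normalized — so the probabilities always form a simplex, moves up
the VEGF (fibronectin) gradient beat the opposite move whenever `χ > 0`
(`ρ > 0`), and a tip with all weights zero stays put.  This realizes the
standard master-equation discretization of diffusion + chemotaxis +
haptotaxis at the contract level; every coefficient is exposed in
`SimulatorSettings` rather than hard-coded.

**SL.**  Off-lattice Euler–Maruyama step of the Ornstein–Uhlenbeck velocity

    w ← w + dt(−β w + κ ∇c) + σ √dt ξ,   ξ ~ N(0, I₂),

default drag `β = 1`, initial velocity `(0, 0.1)`; position advances by
`w·dt` (default `dt = 0.05`, 300 steps).

**PS.**  Constant speed per tip (default `1.25 L / (T·dt)`, i.e. a straight
run would slightly overshoot the domain height), headings restricted to
multiples of `φ̂ = π/6` measured from vertical.  Turn probabilities

    τ± = (Dr·dt/2) · exp(−d_c (a(θ ± φ̂) − a(θ)) / φ̂),

where `a(·)` is the angular distance to the local VEGF-gradient direction;
`d_c = 0` gives symmetric turning, `d_c > 0` favours the turn that
re-orients the tip towards the tumour, and the scheme is valid only while
`Dr·dt·cosh(d_c) ≤ 1` (violations raise a configuration error advising a
smaller `dt`; the default prior keeps `Dr ≤ 0.25` so the whole prior support
is valid at `dt = 1`).  Reflections map the discrete heading set onto
itself because `π` is a multiple of `φ̂`.

**Branching.**  A tip is eligible when `age > a_br` **and** `c > c_br`
(strict conjunction; the gate, not the rate, is inferred).  Eligible tips
fire with probability 1 per step by default (configurable Bernoulli rate),
capped at `max_tips` simultaneous tips (512; desk configurations use 128).
Both parent and daughter ages reset to zero — a symmetric choice; daughters
get mirrored velocity (SL) or heading (PS) and a fresh trail lineage.

**Anastomosis.**  The trail is rasterized as it is laid (cell size `L/R`,
the same grid used downstream).  A tip that enters a cell already laid by a
*different* lineage fuses there and deactivates; the cell the tip starts a
step in is exempt, so newborn daughters can leave the parent trail.  The
one-cell fusion radius matches the downstream rasterization resolution.
Note that the raster can contain loops no fusion event created (two trails
passing within one cell of each other close a cycle by adjacency), so
recorded anastomosis counts are diagnostics, not the Betti-1 of the network;
loop counting is done by homology.

**Randomness.**  One `numpy` generator per simulation, seeded from the
`(seed,)` seed sequence; draws occur in a fixed per-step order (movement for
all active tips, then branching), making runs bit-reproducible.  Derived
seeds (training sets, replicates, SMC) come from named `SeedSequence`
streams of a master seed and stay below 2³¹.

## Occupancy grids and spatial statistics

Trail geometry is projected onto an `R × R` raster (default: the AC lattice
resolution, making AC rasterization the identity).  Polyline segments use
supercover line drawing — every cell whose closed square the segment
touches — so consecutive points occupy 4-connected chains; exact corner
crossings include all four incident cells; boundary points follow a
half-open floor-cell convention.  The 18 spatially-averaged statistics
(mean, SD, min, max, range, 10/25/75/90th percentiles of occupied-cell-centre
x and y) are computed over the *deduplicated* occupied cells, not raw trail
points weighted by revisits — the grid overlay is what makes on- and
off-lattice models comparable.  Percentiles interpolate linearly between
order statistics; the SD is the population value.

## Extended persistent homology

The cubical complex has one vertex per occupied cell, an edge per 4-adjacent
occupied pair and a square per fully occupied 2×2 block; vertex heights are
cell-centre `y` (vertical sweep, from the edge far from the tumour) or `x`
(horizontal), extended to faces by the maximum (lower star).  Extended
persistence is computed by reducing the boundary matrix of the cone over the
complex: ascending cells ordered by `(max vertex value, dim)`, then a coned
copy of each cell ordered by `(−min vertex value, dim)`; columns are GF(2)
bitmasks (Python integers), reduced by the standard algorithm.  Pair
classification: ascending/ascending → ordinary (feature dim = creator dim);
ascending/coned → extended (dim 0 → extended⁺ with birth ≤ death, dim 1 →
extended⁻ with birth ≥ death); coned/coned → relative (feature dim =
creator dim + 1, birth > death).  Zero-persistence ordinary and relative
pairs are discarded; only dims 0 and 1 are reported (the planar raster has
no higher homology).  Every pair is finite by construction and the diagram
container asserts it.  The extended⁺ count equals Betti-0 and the extended⁻
count Betti-1 of the full complex — the test suite verifies both against
flood-fill and Euler-characteristic oracles, and the ordinary class against
an independently coded plain reduction.

## Vectorization

Each of the 8 strata (2 directions × {ordinary 0, relative 1, extended⁺ 0,
extended⁻ 1}) yields:

* a **persistence image**: Gaussian bumps at `(birth, |death − birth|)`,
  weight linear in persistence (zero on the diagonal), bandwidth `L/20`,
  on a 10×10 pixel grid over the *fixed* box `[0, L]²`.  Fixing the box to
  the domain extent (rather than a training-data bounding box) keeps a
  simulation's features independent of whatever training set it later
  joins, at the cost of occasional clipping for short-lived features.
* **persistence statistics**: mean, SD, median, IQR and 10/25/75/90th
  percentiles of the births, deaths, midpoints and lifespans, plus the
  persistent entropy of normalized lifespans (33 numbers).

Empty strata map to zero blocks, so every simulation gives 1082 features
(18 spatial + 8 × (100 + 33) topological) in a fixed column order; columns
are named (`sx_mean` … `t_h_ext1_entropy`) and carry type/direction
metadata used by the selection summaries.

## Step 1 — feature selection

One `RandomForestRegressor` (500 trees by default; 200 at desk scale) per
(model, parameter); importance is mean impurity decrease, normalized to sum
one, ties broken lexicographically by feature name for determinism;
out-of-bag R² is reported as a diagnostic.  The `ns = 100` statistics per
model are collected round-robin across the four parameter rankings,
skipping duplicates and continuing down each list, so the per-parameter
shares are as equal as the overlap allows and the selection is
deterministic given the rankings.

## Step 2 — ABC-SMC

The distance scales each selected statistic by its max-abs value over the
training table (zero-scale statistics are dropped with a warning), then
averages the Euclidean distance over the observed replicates — replicates
are averaged at the *distance* level, not the feature level.  The SMC
sampler: generation 1 draws from the prior at tolerance `ε₁` (default ∞);
each later tolerance is the `q`-quantile (default 0.5) of the previous
generation's accepted distances, forced strictly decreasing; proposals
resample the previous population by weight and perturb component-wise with
Gaussian kernels of variance twice the weighted empirical variance;
proposals outside the prior are rejected before simulating; weights are
prior density over the kernel mixture, normalized.  The run stops at the
generation limit or when acceptance falls below a floor (1.5–2%), returning
the completed generations with a status.

The posterior is the weighted final population; `posterior_density()` fits
a weighted Gaussian KDE.  **HPD membership** uses the particle-quantile
rule — a point is inside the 95% region if its density is at least the
weighted 5th percentile of the particle densities — with a leave-one-out
correction: each particle's own kernel bump (`≈ w_i K(0)`) is subtracted
before taking the quantile.  Without the correction the threshold is
systematically too high at small particle counts in several dimensions
(the self-contribution is the same order as the density itself) and the
region under-covers.

## Step 3 — model choice

Features enter *unscaled*.  Only statistics in the intersection of the
three models' selected sets are used; an empty intersection raises an error
telling the user to enlarge `ns`.  A `RandomForestClassifier`
(`oob_score=True`) provides per-record out-of-bag predictions; a
`RandomForestRegressor` is fitted to the 0/1 OOB misclassification
indicators on the pooled three-model table; predictions are clamped to
`[0, 1]` and the reported posterior is `1 − predicted error`.  Observed
test-cases with replicates are classified replicate by replicate; the
majority model and the mean posterior over its supporting replicates are
reported alongside the per-replicate detail.

## Synthetic test-cases and study design

Observed data are synthetic: `r = 10` replicate simulations at known
parameters.  Two test-cases per model span a strongly chemotactic,
densely branching regime and a weakly guided, sparse regime; the exact
values live in `angiotop.experiments.TESTCASE_PARAMS` and are package
choices.  Prior ranges are editable placeholders spanning each model's
qualitative regimes (and, for PS, the validity region of the turning
scheme).

Desk-scale defaults — used by the test suite and the acceptance script —
are n = 300 training simulations per model, 200 SMC particles, 5
generations, a 33×33 grid and 200–300 timesteps; `PipelineConfig
.full_scale()` restores the full-study size (n = 10,000, 51×51).  At desk
scale the three-class forest retains an irreducible OOB error near 20%
that does not fall appreciably with more training simulations (up to
n = 600), more trees (500) or a finer raster (41×41): low-noise SL trails
genuinely resemble PS trails, and the sparse, weakly branching regime of
every model carries little model-discriminating topology.  Model recovery
on the six test-cases is consequently 4–6 of 6 depending on the seed, with
the errors concentrated in the low-noise SL and sparse PS cases; the
densely branching cases are identified reliably and with high estimated
posterior probability.

## What the generator does and does not emulate

The simulators produce static final-timestep networks: trails are laid once
and never remodelled, VEGF does not evolve, there is no blood flow, oxygen
transport, vessel pruning or phenotype switching, and the domain is 2-D.
Passing tests therefore demonstrate that the pipeline recovers parameters
and model identities *for data generated by these model classes*; they say
nothing about fit to experimental angiogenesis images, where the
appropriate filtrations, noise models and replicate structure would differ.

## Known limitations

* The cone-construction reduction is O(n³) worst case; fine for desk-scale
  rasters (≤ 10⁴ cells), not tuned for dense high-resolution grids.
* Persistence-image bounds clip features of rasters whose extents exceed
  the domain box (cannot happen for in-domain data).
* The adaptive tolerance schedule can stall when the replicate-averaged
  distance hits its intrinsic noise floor; posteriors then remain
  prior-broad in weakly identified directions (the branching age `a_br` at
  desk scale is the clearest example).
* Model-choice majority votes over replicates break ties by class frequency
  order; with `r = 10` ties are rare but possible.
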