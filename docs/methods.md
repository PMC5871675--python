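# Methods

This note documents the models, conventions and design choices behind the
package: what is simulated, how the estimators are defined, and what the
tests do and do not demonstrate.

## The estimation chain

**Fractionator sectioning.** An organ of height `H` is sectioned
exhaustively at thickness `t` into `floor(H/t)` slabs; a trailing remnant
thinner than `t` is discarded and logged. A target of `ns` section pairs
gives the integer sampling interval `si = floor(floor(H/t)/ns)` and section
sampling fraction `sf = 1/si` (floor is used because it guarantees at least
`ns` pairs before boundary loss; only the exact-division case has a
canonical answer). The random start `R` is uniform on `1..si`; pairs sit at
`R + k·si` with the consecutive section as look-up, and a pair whose
look-up would exceed the series is dropped and logged, so a draw yields
`ns − 1`, `ns` or `ns + 1` pairs.

**Tiles and weights.** Each pair's cross section is tessellated by the
unbiased counting frame (default 200 × 200 µm); partial edge tiles are
dropped rather than clipped so the frame area `a(fra)` stays constant. The
image-analysis weighting step is emulated by an explicit stochastic stain
model (below); weights are integer pixel counts so that exhaustive
enumeration oracles are exact.

**PPS sampling.** All tiles form one supersection with total weight `Z`.
The smooth fractionator sorts tiles by `(weight, pair, y, x)` and folds odd
ranks into an ascending limb and even ranks (reversed) into a descending
limb — a unimodal, deterministic arrangement. Sampling draws `n` lines at
`u + k·T_z`, `T_z = Z/n`, `u ~ Uniform(0, T_z]`, on the cumulative weight
axis; a line in the half-open interval `(c_{i−1}, c_i]` samples tile `i`
with per-line probability `p_i = z_i/T_z`. Three conventions matter:

- `T_z = Z/n`, the interval length of the systematic sample on the weight
  axis. (A sentence in the source literature describes `T_z` as the sum of
  all pixel values; that reading contradicts the worked probability
  `17/343 = 0.0496` and the construction itself, and is treated as an
  erratum.)
- Half-open cumulative intervals make boundary lines hit exactly one tile
  and make zero-weight tiles (empty intervals) unsampleable.
- A tile with `z_i > T_z` can be hit by several lines; each line carries
  one multiplicity and contributes one `x_i/p_i` term to the total
  (Hansen–Hurwitz-style handling of multiplicities), which keeps the
  enumeration identity exact for any weight vector.

The three repetitions are mutually independent draws from the same
arrangement (a tile may recur across repetitions); production uses a
continuous `u`, while the tests enumerate integer starts for exact oracles.

**Estimation.** `X_r = Σ mult·x_i/p_i` per repetition;
`N̂ = mean(X)/(2·sf·tile_fraction)/units_per_animal`;
`CE = SEM(X₁..X₃)/mean(X)` with the sample SD (n−1). The factor 2
compensates bidirectional disector counting; `units_per_animal` is a plain
divisor for pooled anatomical units (e.g. 3 vertebrae per animal). Group
mean CE is the root mean square of per-animal CEs (variances add);
`CV_ani = sqrt(max(CV_obs² − CE², 0))` with a clamp flag for the degenerate
case. The classical baseline uses `CE = 1/√count` applied to the *raw*
bidirectional event count (the convention of the published pilot tables),
while its estimate halves the count before dividing by the sampling
fraction.

## The synthetic tissue model

The simulator emulates the situation the estimator targets: a ~3 × 3 × 3 mm
organ (default cross section 3200 × 3200 µm ≈ 10⁷ µm², chosen as a multiple
of the frame so the tessellation covers the cross section exactly),
sectioned at 6 µm, holding ~50 cells — sparse and inhomogeneously
clustered.

- **Clustering** is Neyman–Scott: Poisson parents (mean 8), isotropic
  Gaussian offspring (σ = 150 µm), with parent intensity elevated by a
  configurable factor (default 4) in the two end zones (15% of the height
  each), mimicking populations concentrated near the endplates. The
  clustering strength has no published value; the factor is a free
  parameter chosen to produce visible between-section inhomogeneity.
- **Counting geometry.** The nucleus (8 µm sphere) is the unique counting
  feature. All intervals are half-open and 0-based. Presence in a slab =
  sphere–interval intersection; the forward direction of pair `(k, k+1)`
  counts nuclei with top in `(kt, (k+1)t]`, the backward direction nuclei
  with bottom in `[(k+1)t, (k+2)t)`. Every top/bottom therefore lies in
  exactly one interval and the 2-D frame rule (half-open on the centroid)
  assigns every profile to exactly one tile — the conservation property the
  oracle tests rely on. Cell placement keeps the whole nucleus inside the
  organ height so no top or bottom escapes into a nonexistent slab;
  mononucleated cells only.
- **Stain model.** A non-false-negative in-slab profile contributes
  `1 + Poisson(m − 1)` pixels (default `m = 50`; optionally gamma-Poisson
  overdispersed). The strictly positive draw means that with
  `false_negative_rate = 0` every countable cell carries weight
  (`x_i > 0 ⇒ z_i > 0`), making Horvitz–Thompson estimation exactly
  unbiased in the simulator; missed detection is modelled solely and
  explicitly by `false_negative_rate`, which is the one mechanism that can
  introduce bias (as it does on real slides). Background adds
  `Poisson(0.05)` nonspecific pixels per tile; with probability
  `artifact_rate` a tile receives a blob of `1 + Poisson(500)` pixels —
  "high weight / low count", which degrades precision but not unbiasedness.
- **Raster path.** Tile weights can also be realised as binary masks whose
  positive-pixel count equals the tabulated weight for the same seed (both
  paths consume one random stream); masks round-trip losslessly through
  PNG. This mirrors the real workflow, where the weight *is* a pixel
  count.

What the simulator does **not** model: real stain colour distributions and
deconvolution, section deformation/alignment error, tissue loss, optically
thick sections, polynucleated cells, and non-rectangular organ geometry
(the cross section is constant because it enters only through tile counts).
Passing tests therefore validate the sampling and estimation mathematics
under controlled conditions, not the image-analysis front end.

## Non-useable tiles

Real samples contain tiles whose artifacts prevent counting. The canonical
handling is not available in the source text, so two clearly labelled
substitute policies are implemented: `exclude_rescale` (default) drops
unusable hits and scales the repetition total by `n/(n − n_unusable)`;
`impute_ratio` replaces the count by `z_i × (Σx/Σz)` over the repetition's
usable hits. If every hit is unusable, estimation fails loudly.

## Numerical and degenerate-input choices

- Zero-count CE, zero-mean CV, zero-signal supersections (`Z = 0`) and
  all-zero repetition totals raise typed errors rather than returning
  infinities; the CLI maps configuration errors to exit 1 and runtime
  failures to exit 2.
- Floating-point roundoff on the cumulative axis is clamped so the last
  sampling line cannot fall past the final positive-weight tile.
- Reported values are rounded only at the presentation layer (summaries,
  JSON written for reports); all computation is full precision.
- Tile subsampling (`subsample_tiles`) realises the nearest fraction
  `1/round(1/f)` systematically and returns the fraction actually used;
  fewer than 10,000 remaining tiles triggers a sparse-population warning.

## Validation design and problem sizes

The statistical test battery runs on the default study conditions (50-cell
endplate-clustered organ, sf = 1/6 as in a small-bone pilot, 200 µm frame,
3 × 60 or 3 × 22 tiles):

- **Exact oracles.** With integer weights and `n | Z`, the HT total
  averaged over all `T_z` integer starts equals the true count to machine
  precision (every integer line position occurs exactly once across
  starts); the analogous enumeration over all fractionator starts `R`
  recovers ground truth exactly. Random instances are kept ≤ 50 tiles so
  the enumeration is itself trivially verifiable.
- **Monte-Carlo unbiasedness.** 500 simulated animals (fixed organ; fresh
  R, stain noise and tile draws) put the mean estimate within 3 standard
  errors of truth. 500 replicates keep the standard error near 1% while
  running in seconds.
- **CE validity.** The tripartite CE estimates the sampling CV of the
  estimator (the mean of the three repetition totals) for a *fixed*
  supersection; 300 refits of one supersection compare the empirical CV of
  `mean(X)` with the RMS of reported CEs (agreement within 20%). The CE
  deliberately excludes between-section and stain-redraw variance.
- **Efficiency.** 200 paired replicates on the sparse organ compare the
  proportionator CE (3 × 22 tiles) with the uniform baseline given the
  same 66-tile budget; an undefined baseline CE (zero count — the usual
  outcome at sparseness ≫ 50) counts as a proportionator win only when the
  proportionator CE is itself defined.

## Known limitations

- The tripartite CE reflects tile-sampling precision only; between-animal
  comparisons should use the PROBE decomposition, not the CE alone.
- `false_negative_rate > 0` biases the estimate downward by design; the
  simulator quantifies, but does not correct, this.
- The smooth arrangement is guaranteed not to *increase* variance relative
  to a random arrangement only empirically (tested on enumeration
  instances); no general proof is attempted here.
- Extremely heavy single tiles (`z_i` comparable to `Z`) are handled via
  multiplicities, a case the classical presentation leaves open; the
  enumeration identity still holds exactly.
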