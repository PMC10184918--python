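# Methods

This note records the models behind `trajsim`, the defaults and why they are
set where they are, the numerical choices that affect results, and what the
synthetic generators do and do not emulate.

## Trajectories, couplings and the measure definitions

A trajectory is an ordered sequence of n ≥ 1 elements, each a finite 3-D
location, optionally timestamped; comparisons are by element order, not by
timestamp (except the LCSS time threshold δ, which counts index offsets).
All measures consume pairwise element distances through a `MetricSpec`, so
one implementation serves Euclidean coordinates and geographic tracks.

- **HD** — `max(max_p min_q d, max_q min_p d)` on the two element sets.
  Computed from the full pairwise matrix (works for any metric); the test
  suite cross-checks it against `scipy.spatial.distance.directed_hausdorff`.
- **DFD** — minimum over monotone couplings of the maximum pair distance,
  by the standard recurrence `c(i,j) = max(d(i,j), min(c(i−1,j), c(i,j−1),
  c(i−1,j−1)))`. The default path keeps a two-row rolling table (memory
  O(min(n, m))); requesting a witness coupling switches to the full table
  and backtracks, preferring the diagonal predecessor, then the
  i-predecessor — tie-breaking affects only the witness, never the value.
- **DWFD** — bottleneck (minimax node cost) path on the n×m free-space grid
  from (0,0) to (n−1,m−1). Steps are *king moves*: each index changes by at
  most 1 per step in either direction. Diagonal steps make every monotone
  coupling a valid path, which is what guarantees DWFD ≤ DFD; restricting
  to 4-neighbour moves would break that bound (a diagonal coupling step
  would have to pay an intermediate node). Implemented as Dijkstra with
  minimax relaxation on a hand-rolled binary heap (numba); validated
  against an independent oracle that binary-searches the sorted node costs
  and checks connectivity by connected-component labelling.
- **DTW** — minimum over monotone couplings of the **sum** of unsquared
  pair distances; no window by default (an optional Sakoe–Chiba band
  exists but defaults off). Unsquared distances keep the value in the
  units of the data and preserve the uniform-scaling property.
- **LCSS** — longest common *subsequence* under `d < ε` and `|i−j| ≤ δ`
  (δ = ∞ by default; tracks have one element per day, so δ counts days).
  The reported value is the normalized dissimilarity `1 − count/min(n,m)`
  so that "larger = more different" matches every other measure; the raw
  count is always retained. A contiguous variant (longest common run) is
  available via `contiguous=True` for users who want substring semantics.
- **DDM** — time-averaged intra-structure pairwise distance matrices
  `D_A`, `D_B`; per-site values are column means of |D_A − D_B|. Absolute
  values are the default because signed column means can cancel equal and
  opposite displacements; `signed=True` restores the signed mean.
  Intra-structure distances are rigid-motion invariant, so DDM profiles
  skip superposition.
- **WD** — sum over the three axes of the exact 1-D 1-Wasserstein distance
  between the empirical coordinate samples (CDF-difference integral via
  `scipy.stats.wasserstein_distance`; no binning).
- **KLD** — per-axis `Σ p ln(p/q)` in nats on histograms that share bin
  edges spanning the union of both trajectories' ranges (KLD is undefined
  on mismatched support). Each axis gets `bins` equal-width, closed-left
  bins with the final bin closed (numpy convention), default 100. A
  pseudocount (default 1e-10) is added to every bin and masses are
  renormalized, so empty bins never produce infinities. KLD is asymmetric
  in its arguments; `symmetrize=True` returns KL(p‖q) + KL(q‖p). The three
  axis divergences are summed.

Axis-wise reduction (WD, KLD) deliberately ignores cross-axis correlation;
joint optimal transport is out of scope.

## Structure pipeline

Multi-model PDB is the native structure format, read through mdtraj (any
other mdtraj-loadable format can be converted upstream). The default atom
selection is `name CA`: one reference point per residue. Profiles carry PDB
residue numbers, not positional indices, so gapped numbering survives.

Superposition is the Kabsch algorithm via SVD with the usual
determinant-sign fix, so the returned rotation is always proper — a mirror
image fits with det +1 and a non-zero RMSD rather than an improper
reflection. Before profiling, both ensembles are fitted frame-by-frame onto
frame 0 of the first ensemble (all-site fit). Two caveats are worth
knowing:

- The fit minimizes *overall* RMSD, so a genuine localized conformational
  change bleeds slightly into other residues' values. On inputs that are
  already expressed in one common frame (e.g. the synthetic generator's
  output), `superpose=False` gives the exact closed-form values.
- RMSF (`sqrt(mean_t ‖x(t) − mean_t x‖²)`) is only meaningful after global
  motion has been removed; it requires at least two frames.

## Track pipeline

Daily fixes are averaged to one point per day; longitudes average
circularly, so fixes straddling the antimeridian average to ±180°, not 0°.
A track model holds per-day mean (lon, lat) and per-day normal standard
errors, declared in km or degrees (km convert at 1° = πR/180 ≈ 111.2 km,
longitude scaled by 1/cos φ). Sampling draws per-day independent normal
deviates (longitude wrapped mod 360, latitude clipped to ±90°) and embeds
the track on a sphere of radius 6371 km, where chord distance approximates
great-circle distance at continental scales; this keeps every measure's 3-D
code path uniform. The data never state which Earth model a geolocator
analysis should use, so the haversine metric is exposed as an option.

The comparison design for K individuals and n samples:

- between individuals: all K(K−1)/2 unordered pairs, sample s of one vs
  sample s of the other — K(K−1)/2 · n comparisons (with K = 8,
  n = 1000: 28 pairs, 28,000 comparisons). Matching sample indices is the
  only design that reproduces those counts; all-vs-all would square them.
- within an individual: n disjoint random pairs drawn from that
  individual's own 2n samples — K · n comparisons (8,000). The pairing
  permutation is seeded; disjointness keeps the noise values independent.

Histograms of the two kinds share bin edges per measure; within
("noise") histograms are density-normalized so their magnitudes are
comparable with the between-individual histograms (peak-height matching
would be an alternative; unit area is the default because it is
parameter-free). For cross-measure displays each measure's pairwise values
are scaled by their maximum, with the Γ = 0.5 level marking "half as
dissimilar as the most dissimilar pair".

## Synthetic generators

`gen_protein_pair` — residues sit on a persistent random chain with fixed
3.8 Å spacing (the Cα–Cα distance) and vibrate as tethered mean-reverting
walks: `x(t+1) = x(t) + θ(anchor − x(t)) + N(0, σ²I)`, started at the
stationary distribution (per-axis sd σ/√(θ(2−θ))), so there is no burn-in
transient and θ = 1 gives i.i.d. frames. The second ensemble's anchors are
displaced by a shift vector inside one residue block. Defaults — 100
residues, 200 frames, σ = 0.3 Å, θ = 0.5, block 40–50 (0-based), shift
(1.5, 0, 0) Å = 5σ — define the package's reference scenario: a localized
change five times the noise scale, which every measure should localize.
Mean reversion (rather than free Brownian motion) keeps vibrating residues
bounded, which is what makes the LCSS ε-sensitivity reproducible. The
generator does not attempt physical realism: no bonded neighbours moving
cooperatively, no solvent, no secondary structure — so passing tests show
that measures localize a displacement against tether noise, not that they
understand protein energetics.

`gen_track_cohort` — a fixed Alaska→East-Africa base route (five waypoints,
crossing the antimeridian) interpolated to D daily positions; each
individual adds a smooth low-frequency offset vanishing at the endpoints
(shared breeding/wintering grounds) with RMS magnitude set by
`route_spread_km`, optionally a stopover plateau of repeated locations, and
constant per-day sds of `noise_sd_km`. Defaults — 8 individuals, 90 days,
500 km spread, 50 km daily error — give a cohort whose between-individual
differences clearly exceed the noise floor, the regime in which the
within/between separation property is testable. Real geolocator error is
not constant (it inflates near the equinoxes and the equator, to ~400 km in
latitude) and real birds vary their schedules; the generator models neither,
so the pipeline's equinox behaviour is untested here by design.

Both generators are pure functions of their spec: the same seed yields
bit-identical output (independent `SeedSequence` streams for anchors and
each ensemble/individual).

## Numerical and testing choices

- DP kernels are numba-jitted and operate on a precomputed distance
  matrix; results are bit-identical for 1 and k workers because
  parallelism only distributes independent units (residues, pairs) and
  reduces them in a fixed order.
- Oracles are kept algorithmically disjoint from the implementations:
  exhaustive lattice-path enumeration for DFD/DTW, subsequence-pair
  enumeration for LCSS, threshold search + component labelling for DWFD,
  scipy for HD/Kabsch. Exact (not approximate) agreement is asserted on
  small random inputs.
- Binned KLD needs samples ≫ bins to settle; with short trajectories the
  estimate is dominated by sampling noise and the pseudocount. The
  profile-noise comparison (bottleneck profiles fluctuate more than KLD)
  is therefore asserted in the long-trajectory regime (1000 frames, 10
  bins). Degenerate histogram ranges (constant axis) are widened by ±0.5
  like `numpy.histogram`.
- The empty-range LCSS dissimilarity, zero-noise track sampling, single
  frame ensembles and single-element trajectories are all defined and
  tested; all-zero inputs to max-scaling raise, since the scaling is
  undefined.
- Test and acceptance problem sizes (e.g. 20 generator seeds for block
  recovery, 10 cohorts × 100 samples for noise separation, 1000 random
  pairs for the inequality chain) were chosen as the smallest runs that
  exercise the stated properties with comfortable statistical margin.

## Known limitations

- Continuous (polyline) Fréchet distance, edit-distance measures (EDR/ERP)
  and joint multivariate optimal transport are not implemented.
- No trajectory smoothing or filtering beyond daily averaging; no map
  projections; no MD functionality (force fields, chemistry).
- The benchmark timing of the measures is hardware-dependent and carries no
  guarantees; an informal sense of relative cost is: WD and HD are
  cheapest, the DP measures scale as n·m, DWFD adds a log factor, DDM
  scales with R²·T.
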