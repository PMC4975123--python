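# Methods

This note documents the models, algorithms, conventions and numerical
choices behind `relief_districts`, in the order the pipeline runs them.

## Setting

A pictorial relief is the depth impression a viewer forms when looking into
a picture.  It is operationalised here as a scalar depth value per vertex of
a coarse triangulation of a region of interest in the picture plane.  Two
psychophysical tasks probe it:

* **2-point comparison**: for a pair of marked vertices, the participant
  indicates which appears nearer.  A complete session judges every one of
  the V(V−1)/2 unordered pairs exactly once (57 vertices → 1,596 pairs at
  the original stimulus scale).
* **gauge figure**: the participant adjusts an overlaid ellipse until it
  looks like a circle painted on the surface, yielding a local slant/tilt —
  equivalently a depth-gradient sample (p, q) — at a face barycenter.

Vertex coordinates are normalised so the picture width is 1; depths are in
arbitrary "depth units" with **larger z = nearer to the observer**, so the
"closest" vertex of the 2-point task is the z-maximum.

## Consensus depth order and the number of merit

For a complete set of pairwise judgements the consensus order is obtained by
counting how often each vertex was judged nearer (a win count), then densely
ranking vertices by descending count: tied counts share a rank, the next
rank is one higher, and the number of *levels* is the number of distinct
counts the observer resolved.

Internal consistency is summarised by a *number of merit* defined like
Kendall's tau: with C judgements that agree with the strict consensus order
and D that contradict it, merit = (C − D)/N where N is the total number of
judged pairs.  Pairs tied in the consensus contribute to neither C nor D but
remain in N (a tau-a convention).  The tie treatment is a design choice; a
tau-b style denominator would rescale but never reorder sessions.

Two properties of this statistic are worth knowing:

* **The count order is a heuristic, not a guaranteed optimum.**  Maximising
  C − D over orderings is the (NP-hard) linear ordering problem; on heavily
  cyclic data a different ranking can beat the count order (a cyclic triple
  has merit 0 against its all-tied count order but 1/3 against any strict
  order).  On near-transitive data — the regime of interest — the best
  strict completion of the count order attains the global optimum; the test
  suite verifies this exhaustively for 5 vertices with planted inversions.
* **Self-scored merit has a positive small-sample bias.**  Because the
  consensus is fitted to the very judgements it is scored on, a pure
  coin-flipping observer does not score 0 but about +0.14 at 64 vertices.
  The binomial null (mean merit ≈ 0) holds against an independent true
  order, and the test suite checks it in that form.  Empirical merits from
  mostly-consistent observers sit far above this bias floor.

*Discordant pairs* (also called confusions) are the judged pairs that
strictly contradict the consensus; consensus-tied pairs are never
discordant.  Depth orders from different sessions or tasks are compared
with tie-corrected Kendall tau-b (`scipy.stats.kendalltau`).

## Confusion-metric segmentation

The working hypothesis is that depth comparisons are reliable within a
bulge (hill) of the relief and unreliable across bulges.  The segmentation
stage therefore builds a dissimilarity that mixes picture geometry with an
all-or-none error metric:

    d(A, B) = |AB|              if the pair was not confused
    d(A, B) = |AB| + diameter   if it was

where the diameter is the largest vertex separation of the triangulation.
A single confusion thus dominates any picture-plane proximity.  The matrix
is symmetric with zero diagonal but can violate the triangle inequality, so
clustering uses **average-linkage agglomerative clustering on the raw
dissimilarities** (no coordinate embedding).  The number of clusters is
chosen by maximising the mean silhouette width (computed on the same
dissimilarities) over k ∈ [2, 10], ties toward smaller k; a maximum
silhouette below 0.25 flags the partition as low-confidence.  Cluster
labels are renumbered by ascending mean x coordinate for stable reporting.
Sessions are clustered separately; no consensus partition is forced.

Partitions are compared with the plain Rand index (fraction of vertex pairs
grouped together in both or separated in both; `sklearn.metrics.rand_score`,
cross-checked against a pair-enumeration oracle in the tests).  Segmentation
quality is quantified by the **inter/intra confusion ratio**: the
probability that an inter-cluster pair is confused divided by the same
probability for intra-cluster pairs.  A zero intra rate with a positive
inter rate reports +inf; no confusions at all reports NaN (undefined).
Cluster contiguity is checked as connectivity of the induced subgraph of
the mesh edge graph.

## Gauge-figure surface integration

Slant σ ∈ [0, π/2) and tilt τ convert to a gradient as
(p, q) = tan σ · (cos τ, sin τ), tilt measured counterclockwise from the
picture x-axis toward increasing depth — the standard convention in the
gauge-figure literature.

A field of attitude samples need not be integrable (most gradient-like
fields are not the gradient of any surface).  The relief is recovered as
the vertex field z minimising

    Σ_faces  area_f · ‖∇z|_f − g_f‖²

where ∇z|_f is the gradient of the linear interpolant of z over face f.
The minimiser is unique up to an additive constant when the sampled faces
are edge-connected (checked; disconnected inputs are an error naming the
components); the constant is fixed by gauging the solution to zero mean
over the involved vertices.  The sparse normal equations with the zero-mean
constraint appended are solved directly (`scipy.sparse.linalg.spsolve`);
robustness was preferred over speed since systems stay below a few thousand
vertices.  Vertices on no sampled face are pinned at 0.

The integrability diagnostic is the normalised residual

    residual = sqrt( Σ area‖∇z* − g‖² / max(Σ area‖g‖², 1e-30) )

which is 0 for perfectly consistent samples and ≈1 for a pure curl field
(the floor avoids 0/0 for flat fields, which report residual 0).  Exact
round trips recover a field from its own face gradients to machine
precision; a field made exactly curl by projecting out its integrable part
yields residual 1 to 1e-6.

For tau comparisons against 2-point orders, reconstructed depths are ranked
strictly with exact ties broken by vertex index (larger index nearer), the
same tie-break used everywhere else in the package.

## Hill/dale geography

The geography of a relief in Maxwell's sense is extracted combinatorially:

* **Classification.**  Each interior vertex is classified by the cyclic
  sign pattern of its one-ring (neighbors higher/lower in the tie-broken
  order): no sign change → peak (all lower) or pit (all higher); two
  changes → regular; 2m changes → saddle of multiplicity m−1 (monkey
  saddles log a notice).  The one-ring order is derived from the face fan,
  so classification is valid even when the 2D coordinates are a projection
  of a closed surface.  Boundary vertices are tested for the peak/pit
  condition against all their neighbors but are never counted as saddles —
  at an occluding contour the sector structure is geometrically ill-posed —
  and are reported separately.  (Testing against *all* neighbors, rather
  than interior neighbors only, keeps basin roots identical to the set of
  vertices with no higher neighbor, which the district invariants require.)
* **Districts.**  From every vertex, steepest ascent repeatedly steps along
  the edge with the largest value difference per unit length toward a
  strictly higher neighbor; the local maximum reached is the vertex's hill
  label.  Exact value ties are broken by vertex index (simulation of
  simplicity), so the walk always terminates.  Dale labels are computed by
  running the *same* ascent routine on −z, which makes the inversion
  duality — the hills of −z are exactly the dales of z — hold by
  construction, ties included.  (No value-based tie-break can be made
  simultaneously consistent under negation, so duality is obtained
  structurally rather than by a clever comparator.)  Plateaus are resolved
  by the index tie-break rather than plateau merging; a documented
  limitation for heavily quantised fields.
* **Feature paths.**  From each saddle, one steepest-ascent path per upper
  sector is traced to a peak (a ridge) and one steepest-descent path per
  lower sector to a pit or to the boundary (a water course / rut).  Simple
  saddles emit two of each.  Ridges bound the dales; courses bound the
  hills.

On a closed test surface the counts satisfy the Euler relation
peaks − saddles (with multiplicity) + pits = 2; on bounded regions the
boundary absorbs flow and the count is reported, not asserted.

## Synthetic study conditions

The human data are not deposited, so the generators define the conditions
every stage is exercised under:

* **Mesh**: a regular nx×ny grid with each cell split along one diagonal;
  the default 8×8 (64 vertices, 2,016 pairs) matches the ~57-vertex scale
  of the original triangulation.
* **Relief**: a sum of Gaussian bumps, zero-mean gauged.  Gaussian bumps
  give analytic, radially monotone hills — the ovoid bulges the part/whole
  account is about.  The canonical four-bump layout places equal bumps
  (amplitude 1, width 0.12) at the quarter points of the unit square,
  producing exactly four hill districts.  The symmetric layout has exact
  depth ties between mirror vertices; tests that need a strict generic
  order use unequal amplitudes instead.
* **Observer**: district-dependent error.  In the default *flip* mode the
  truthful nearer/farther answer is inverted with probability ε_within =
  0.05 when both vertices share a hill district and ε_between = 0.25
  otherwise.  The rates are a planted inter/intra ratio of 5 at the
  per-pair level; after consensus fitting and clustering, the measured
  session-level ratio comes out near 2–3, the regime the empirical ratios
  (≈2) occupy.  A *logistic* mode draws each response with probability
  1/(1+exp(−Δz/σ)), σ chosen by the same-district rule — more
  psychophysically faithful but not needed for the unit-level properties.
  Randomness is a single `numpy` Generator stream keyed by (seed, observer
  label, session label) via CRC32, so multi-session experiments are
  bit-reproducible.
* **Attitudes**: true face gradients plus isotropic Gaussian noise plus an
  optional curl component — the 90°-rotated gradient of an independent
  random smooth field, rescaled to the area-weighted power of the true
  gradients (unit power for flat fields) and multiplied by `curl_frac`.
  The rotated-gradient construction is only approximately curl on a
  discrete mesh (the exact curl part is obtained by projection, as in the
  residual tests), but the reconstruction residual is strictly increasing
  in `curl_frac`, which is the property the diagnostic needs.

What the generators do *not* emulate: response times, lapses, learning or
order effects, anisotropic or distance-dependent confusion probabilities,
and the actual sculpture-photograph relief.  Passing tests therefore show
that the pipeline recovers the structure it assumes (district-structured
errors over a bump relief), not that human data obey that structure.

## Problem sizes and reproducibility

Simulation-backed checks use 64-vertex grids (2,016 pairs per session),
20 independent sessions for median statistics, and an order-42-vertex
icosphere for the closed-surface Euler check — small enough that the whole
suite runs in seconds while pair counts stay at the original stimulus
scale.  `scripts/acceptance.py --seed S --out f.json` regenerates every
reported quantity from scratch; all randomness derives from the single
seed, and rerunning with the same seed reproduces the JSON byte for byte.

## Known limitations

* The merit tie convention (tau-a) is a reconstruction; only orderings of
  sessions, not absolute merit values, are comparable across conventions.
* Silhouette-based k selection is reproducible but not the only defensible
  rule; on data without cluster structure it still returns a k, flagged
  low-confidence.
* Steepest-descent districts are resolved at vertex resolution: district
  boundaries are one-vertex bands, and sub-edge feature localisation or
  persistence-based pruning of minor ridges/ruts is out of scope.
* The area-weighted least-squares integrator assumes homogeneous, isotropic
  sample noise; it does not model slant-dependent setting error.
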