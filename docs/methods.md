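# Methods

`routexpose` implements a route-based environmental-exposure analysis of
travel-mode choice: commuting flows are routed over a street network, each
itinerary's exposure to ordinal road-noise classes and built-environment
context is accounted on a hexagonal grid, a rebalanced random forest
classifies each commuter's mode (car, bicycle, walk), and the fitted model
is interpreted through Gini importance and multiclass partial dependence.
This note documents the models, the defaults and why they are what they
are, and what the synthetic study conditions do and do not demonstrate.

## Spatial unit: the hexagonal grid

The study area is tessellated with congruent, pointy-top regular hexagons of
25 ha (250 000 m²; edge s = √(2A/(3√3)) ≈ 310.2 m), a configurable value.
Per cell the pipeline accumulates clipped building area (m²), clipped street
length (m) and per-category POI counts; all three are conserved under
gridding (a feature spanning k cells contributes each clipped part to its
own cell). Noise-class polygons are reduced to one ordinal class per cell
by majority area; an exact areal tie breaks toward the louder class — the
conservative exposure estimate. A point lying exactly on a shared cell edge
is counted once, for the lowest cell id; a line segment collinear with a
shared edge is likewise attributed to the lower cell id. These tie rules
are arbitrary but deterministic and conservation-preserving.

All coordinates are planar meters in a local engineering CRS; geographic
coordinates are out of scope because every quantity of interest is a metric
density or length.

Two built-in noise schemes are provided, mirroring common strategic-mapping
products: a six-class 16-hour scheme (`london6`: <55, 55–60, 60–65, 65–70,
70–75, >75 dB) and a five-class 18-hour scheme (`brisbane5`: <58, 58–63,
63–68, 68–73, >73 dB). Printed class labels of the six-class product leave
a 54.9/55.0 gap; dB being continuous, the boundary is treated as 55.0
exactly. Schemes are opaque ordered class lists to the rest of the
pipeline, so they interchange cleanly; the averaging-window difference
between the two products is not modelled.

## Routing

Streets become an undirected graph with one node per distinct endpoint
(snapped at 1e-6 m) and per-edge allowed-mode sets derived from street
class. Itineraries minimise *distance* on the mode-filtered subgraph —
trip features downstream are distance-based and per-mode speeds are out of
scope — with straight access/egress connectors from the OD points to their
nearest mode-accessible nodes included in the total. Equal-length ties
break toward the lexicographically smallest node-id sequence, making
itineraries reproducible. Flows with no feasible route are dropped and
counted in the run report. This single-criterion router deliberately
stands in for a full multimodal engine; it is sufficient for validating
the exposure-accounting method, not for realistic travel-time work.

By default every street class admits all three modes (arterials carry
sidewalks). Restrictive rule sets are supported; note that banning
pedestrians from arterials forces detours that inflate walking's routed
distance well beyond its origin–destination distance, which materially
changes the distance–mode relationship in generated data.

## Trip features

For each trip: total routed distance (m); the *unweighted* means of
building area, street length and per-category POI count over the distinct
cells crossed (the closest literal reading of averaging "over the cells
intersected by the itinerary"; a length-weighted variant would be the
natural sensitivity check); and the noise exposure share — the fraction of
the traversed length spent in cells of each ordinal class. Shares are
normalised by the sum of per-cell traversed lengths rather than the stored
total distance, so every share vector lies exactly on the probability
simplex (the two denominators agree to the geometric clipping tolerance,
about 1e-9 relative). A zero-distance trip takes share 1 in its origin
cell's class. Trips crossing a single cell necessarily have binary shares
— the geometric reason very short (walked) trips pile up at exposure
shares of 0 or 1. Flows are finally expanded to one row per commuter, the
unit the classifier sees.

## Synthetic city and flows

The generator is a deliberately simple, fully seeded stand-in for census
OD data and strategic noise maps; none of its choices are calibrated to a
real city.

* **Streets** form a jittered crossing lattice (default 17 lines, 3 of
  them arterial), noded at every intersection as the router requires.
* **Noise** is a partition of the bounding box into buffer rings around
  the arterials (radii 60/140/260/420/650 m), loudest innermost, quietest
  class outside — so noise class decays monotonically with distance from
  the nearest arterial, reproducing the road-traffic origin of strategic
  noise maps at desk scale.
* **Buildings** (900) are centre-weighted rectangles; **POIs** (360) sit
  in 8 Gaussian clusters with a retail-heavy category mix over six
  categories (educational, recreational, medical, public services,
  retail, others).
* **Flows** draw origins near buildings and destinations near the centre;
  the commuter count per flow is shifted-geometric with mean 15, so both
  suppressed and retained flows occur under the census privacy rule that
  removes flows under 10 commuters. From 2 000 flows this leaves roughly
  1 000 flows and ~26 000 individuals after expansion.

Mode labels come from a multinomial-logit utility model with softmax
temperature T:

U_m = α_m + β_m·d + γ_m·B + δ_m·P + ε_m·N

with d the *rectilinear* OD distance (km), B and P z-scores of building
area and POI count within 250 m of the origin, and N the mean noise class
along the straight OD corridor rescaled to [0, 1]. Rectilinear rather than
Euclidean distance is used because on the lattice street fabric the routed
distance essentially *is* the rectilinear distance; a Euclidean utility
would smear the planted distance–mode boundary by the 1.0–1.41 route
factor and blur the very signal the recovery analysis checks. Mode
sampling uses one uniform draw per flow against the cumulative softmax in
fixed (car, bicycle, walk) order, with all random inputs drawn before any
utility is evaluated — so hardening a coefficient with the same seed can
only move flows out of (never into) the walk interval, a monotonicity the
tests exploit.

### Recovery defaults and what they demonstrate

The default coefficients plant a strongly distance-dominated regime:
walking is penalised at −5.0 per km (boundary ≈ 1.4 rectilinear km),
cycling at −2.45 (to ≈ 1.7 km), driving at −0.05; building density, POI
access and noise proximity carry small effects of the expected signs
(active modes favoured by density and amenities, the car by noisy
corridors); T = 0.25 makes the boundaries sharp. These values were chosen
so that the planted structure is unambiguous at desk scale — a fitted
forest should rank distance first, its walk-class distance PDP should fall
and then flatten, shuffled labels should return accuracy to chance — and
they are fixed study conditions, not fitted quantities. What passing
recovery shows is that the *pipeline machinery* (routing, exposure
accounting, rebalancing, training, interpretation) transmits a known
behavioural signal without distortion. It does not show that any real
city's mode choices behave this way: real data are noisier, class
boundaries are soft, socio-demographics are absent here, and the
synthetic city has none of the spatial heterogeneity of a real one.

## Classifier

* **Correlation pruning.** Features with pairwise |Pearson r| > 0.8 are
  removed; when a pair conflicts, the feature with the larger mean
  absolute correlation to the others is dropped (ties drop the later
  column). A keep-list (default: the retail, educational, recreational
  and medical POI means) is exempt from the constraint and never dropped,
  mirroring the practice of retaining an interpretable POI subset even
  though POI types are mutually correlated. Constant columns are excluded
  with a warning (their correlation is undefined).
* **Rebalancing.** Near-miss undersampling on a z-scored copy of the
  training partition brings every class down to the minority count. The
  default `keep-closest` variant retains the majority points with the
  smallest mean distance to their 3 nearest minority points (the standard
  near-miss selection); `remove-closest`, which deletes those points
  instead, is available as an alternative reading of the method. Only the
  training partition is rebalanced; the test partition keeps the original
  class distribution, and evaluation is reported on both the original and
  a near-miss-rebalanced test subset.
* **Forest.** 500 trees by default, bootstrap resampling, `max_features`
  candidate features per split (default √p; tunable by 3-fold
  cross-validated grid search with ties preferring fewer trees, then fewer
  features), remaining settings at library defaults (unlimited depth,
  minimum split size 2, Gini impurity). The out-of-bag score is recorded.
  Note that because expansion duplicates rows, OOB and held-out accuracy
  are both optimistic on expanded tables: duplicates of a test row sit in
  the training partition. This is a property of the individual-level
  design itself, and is why the permutation control below matters.
* **Vote fractions.** The per-class score is the fraction of trees voting
  for the class. Exact argmax ties — common in leaves whose label mix is
  balanced — are broken by a seeded random preference (one per tree), as
  in the classical forest implementations; a deterministic tie-break
  systematically inflates one class's votes and measurably biases the
  permutation control.

## Interpretation

**Gini importance** is the mean-decrease-impurity importance normalised to
sum 1, ranked with ties broken by feature name.

**Partial dependence** is computed on the log-of-votes scale. For a probe
point x with smoothed vote fractions p_j(x) (p = (v + ε)/(1 + Kε),
ε = 1/(2·n_trees), keeping logs finite when a class gets zero votes), two
variants are available:

* `centered` (default): f_k = log p_k − (1/K) Σ_j log p_j — the standard
  multiclass logit; the per-class values sum to zero at every probe point.
* `printed`: f_k = log p_k − Σ_j log p_j — the same expression without the
  1/K factor, as it is sometimes printed; it rescales and shifts the
  curves but does not change their shape.

Under the standard sign convention a positive f_k means class k is more
likely at that probe point than the geometric-mean class. The evaluation
grid is 50 even steps between the feature's 1st and 99th percentiles, and
every other feature is held at its column mean. Held-at-means probes are
cheap and match the stated methodology, but the probe row need not lie on
the data manifold (the mean of a set of simplex-valued share vectors is a
valid point of the simplex, but the joint mean context may be atypical),
and curves inherit a ±1-vote quantisation jitter: with 500 trees the
smallest vote step is 0.002, which on the log scale is visible wherever a
class's vote fraction is small. A data-averaged PDP would be smoother but
is a different estimand and is not implemented.

## Permutation control

The label-permutation null refits the full forest on the rebalanced
training set with shuffled labels and measures accuracy on the rebalanced
test subset, averaged over 3 independent shuffles. Two details are
deliberate: (i) the rebalanced test subset puts chance at exactly 1/3 and
keeps the evaluation inside the training support — on the raw, car-heavy
test distribution the null's behaviour in the unsupported long-distance
region is a winner-takes-all artefact with draw-to-draw swings of several
points; (ii) averaging over shuffles reduces the Monte-Carlo error of the
control itself, which is dominated by the block structure that row
duplication induces.

## Pipeline and reproducibility

Six stages (generate → grid → route → exposure → train → interpret) read
and write plain artifacts (GeoJSON layers, CSV/Parquet tables, JSON
reports) in one output directory; each stage is independently re-runnable
and a missing upstream artifact raises a dependency error naming the stage
to run first. A single global seed deterministically derives per-stage
seeds (SeedSequence over a CRC of the stage name), so identical configs
produce byte-identical outputs; stage events are logged as JSON lines.

Default problem sizes — 5 km × 5 km city, 2 000 flows, ~26 000 expanded
individuals, 500 trees — were chosen so a complete run takes well under a
minute on one CPU while every class keeps thousands of training rows after
rebalancing.

## Known limitations

* The router is single-criterion (distance) and unimodal per trip; no
  transit, turn restrictions, congestion or elevation.
* The generator has no socio-demographics, no temporal structure, and its
  noise surface is a buffer construction, not a propagation model.
* Means over crossed cells are unweighted; a length-weighted reading of
  the same features is plausible and would change feature values for long
  trips.
* Row expansion duplicates feature vectors, so all headline accuracies are
  optimistic relative to a flow-level split; the permutation control, not
  the raw accuracy, is the evidence that the model learns structure.
* Held-at-means PDP probes are off-manifold by construction; interpret
  curve *shapes*, not absolute levels, and expect ±1-vote jitter where a
  class's vote fraction is small.
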