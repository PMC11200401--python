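# Methods

## Scope and model

`flysin` quantifies group-level social behaviour of *Drosophila* from
tracker output.  A recording of one arena yields a per-frame table of fly
positions, headings and body lengths.  From it the pipeline derives:

1. **Activity** — per-fly total path length (mm) and average velocity
   (path length / observed duration, mm/s).
2. **Interaction events** — a directed pair (i, j) is *engaged* at a frame
   when the centre distance is within `distance_bl` (default 2.5) body
   lengths of the focal fly and the focal fly's facing angle to the other
   (angle between its heading vector and the vector to the other fly, in
   [0°, 180°]) is below `max_angle_deg` (default 160°).  Maximal engaged
   runs of at least `min_duration_s` (default 0.6 s) become events.
3. **SIN snapshots** — per minute of recording, a graph over all flies
   whose directed edges carry two weights: event count and total event
   duration (s).  Events are atomic and belong to the minute of their
   onset frame.
4. **Measure battery** — edges, degree, density, in/out strength (count
   and duration), global efficiency, degree heterogeneity, degree
   assortativity, transitivity, clustering, betweenness, closeness and
   modularity, with unweighted / count-weighted / duration-weighted
   variants where meaningful.
5. **Aggregation and comparison** — snapshot → video → group means;
   two-group unpaired t-tests on per-video values; interaction-location
   heatmaps and an outer-annulus (thigmotaxis) fraction.

## Conventions and numerical choices

* **Coordinates** are body-centre positions in mm with the arena centre at
  the origin; headings in degrees counter-clockwise from +x, normalised to
  [0, 360).  Frames are 0-based; the time of frame *f* is *f/fps* s.
* **Symmetric detection (default).**  The engagement predicate is
  symmetrised (a pair is engaged when either direction satisfies both
  criteria) and every event registers in both directions with identical
  frames, making in- and out-strength identical by construction — the
  behaviour expected of an interaction registered once per pair.  A pure
  directed mode (`symmetric=False`) is available.
* **Proximity threshold** uses the focal fly's own mean tracked body
  length, so the test can be asymmetric for unequal flies.  The facing
  criterion is applied to the focal fly only; whether both flies' angles
  should be tested jointly is ambiguous in the literature, and the
  single-sided reading is the one the tracker feature set supports
  directly.
* **Minimum duration** is `ceil(min_duration_s * fps)` frames, inclusive at
  the boundary by default (36 frames at 60 fps qualifies); a strict mode is
  available since a one-frame distinction is below tracker noise.
* **Undirected merged view.**  Topological measures are computed on the
  undirected graph in which reciprocal directed edges collapse to one link
  with summed weights; strengths use the directed view.  Weighted
  shortest-path measures use edge length 1/weight (a stronger tie is a
  shorter distance); weighted efficiency can therefore exceed 1.
* **Heterogeneity** is the coefficient of variation (population SD / mean)
  of the degree distribution, 0 for an edgeless snapshot.
* **Assortativity** (Pearson correlation of degrees across edge endpoints)
  is undefined on degree-regular or near-empty snapshots; such values are
  flagged NaN and excluded from aggregation with the exclusion counted.
* **Closeness** uses the Wasserman–Faust per-component correction because
  minute-resolution snapshots routinely contain isolates; isolates score 0.
* **Weighted clustering** is the geometric-mean (Onnela) form with weights
  normalised by the maximum edge weight.
* **Modularity** is the Q of the partition found by Louvain on the
  undirected view, seeded for determinism; an edgeless snapshot reports
  Q = 0 with a log note.
* **t-tests** are computed on per-video values (the video is the unit of
  replication), Student's pooled-variance variant by default with Welch as
  an option.  A summary-statistic variant (t from means and dispersions
  alone, Welch–Satterthwaite df) supports recomputing published t values.
  Dispersions are reported both as SD (ddof = 1) and SEM, because published
  group dispersions in this assay are sometimes labelled SD while being
  numerically consistent only with SEMs; reporting both keeps either
  reading checkable.  No multiple-testing correction is applied; the number
  of tests is reported.
* **Heatmaps** bin event onset midpoints (not every engaged frame, to avoid
  duration-weighted double counting) on a 50×50 grid over the arena square
  by default; bins whose centres fall outside the circle are masked.  The
  thigmotaxis statistic is the share of event positions in the outer 20%
  of the radius, reported next to the uniform-area baseline
  1 − 0.8² = 0.36.

One spec-level caveat: enlarging the distance or angle threshold can merge
two qualifying engagement runs into one, so the *number* of events is not
monotone under relaxation — only the total event-covered duration is.
Count monotonicity holds for the minimum-duration threshold.  The property
tests assert exactly these corrected forms.

## The synthetic fly-group generator

No public trajectory data exist for the motivating two-strain experiment,
so `synthetic_flies` generates groups with the statistical structure the
analysis assumes.  Dynamics are a discrete-time correlated random walk in
a circular arena (radius 65 mm):

* per step a moving fly turns by Gaussian noise (`heading_noise_sd`), plus
  a wall-attraction term steering radially outward while in the inner 70%
  of the arena (gain ∝ `wall_bias`), plus a social term steering toward the
  nearest free fly within `social_radius` (gain ∝ `social_strength`);
* speed is redrawn every step from N(`mean_speed`, `speed_sd`), clipped at
  0, and zeroed during pauses (geometric duration, entry probability
  `pause_prob` per step);
* the boundary is a billiard wall: a step that would exit the arena is
  reflected at the rim, preserving step length, so per-frame displacement
  never exceeds the drawn step;
* **engagement holds** generate interactions: when a free fly has a free
  neighbour within `social_radius`, with per-step probability
  `social_strength` the pair stops, walks into body contact, faces each
  other, and dwells for a shared geometric time with mean
  `interaction_hold_s`, then both turn away and resume walking.
  `social_strength` is thus both turning bias and interaction propensity;
  `interaction_hold_s` sets interaction duration.
* Two refractory mechanisms keep the contact structure realistic: a per-fly
  lockout after each hold (max(1 s, 1×`interaction_hold_s`)), and a 30 s
  per-pair lockout that forces partner turnover.  Without the pair lockout
  flies re-engage the same neighbour indefinitely and the per-minute graphs
  fragment into small cliques, which inverts the betweenness contrast
  between sparse and dense networks.

One RNG stream per group, seeded explicitly; a fixed seed reproduces the
trajectory table bit-for-bit.  Replicate experiments use consecutive seeds.

### Genotype presets

`active_social` (fast, fairly straight walking, many brief engagements) and
`hypoactive_asocial` (slower, more tortuous, frequent pauses, fewer but
~14× longer engagements, slightly stronger wall preference) encode the
qualitative phenotype contrast of a normally active strain versus a
hypoactive, socially altered one.  The preset magnitudes are design
choices: no quantitative locomotion parameters are published for either
strain, so values were fixed once such that the full pipeline recovers the
directional group phenotype — lower activity, edges, degree, density,
efficiency and closeness, and higher duration-strength, heterogeneity,
betweenness and modularity in the hypoactive group — on scaled-down
recordings, while respecting the qualitative orderings (active: higher
speed and social propensity, lower pause probability and hold duration).

### What the generator does and does not emulate

It reproduces: activity differences, boundary preference, tunable
interaction propensity and duration, and the resulting sparse-vs-dense
network contrast.  It does not model courtship, aggression, sex
differences, stop-bout rhythm, collision avoidance or body-shape contact
geometry, and its per-minute networks are sparser (density ~0.15–0.30,
degree ~4–9) than real crowded-arena recordings (density ~0.27–0.40,
degree ~16–23).  Passing directional tests on this generator therefore
shows that the pipeline measures and orders such phenotypes correctly, not
that the simulator is a quantitative model of fly behaviour.

## Problem sizes used in validation

The test suite and the acceptance script use scaled-down experiments
chosen as representative of the full design: 15 replicate groups per
genotype, 30 flies per group, 2 minutes at 30 fps (the full study design is
15 minutes at 60 fps).  Graph-measure oracles run on 200 random graphs of
up to 8 nodes with power-of-two weights (so shortest-path sums are exact in
floating point and tie handling is unambiguous); the event detector is
checked against an exhaustive frame-scan on 1,000 random pair trajectories
of up to 600 frames, including exact boundary cases at the minimum duration
and at 2.5 body lengths.

## Known limitations

* The detector assumes identity-stable tracks; identity swaps upstream
  masquerade as teleports and are only indirectly visible through the
  validation report (gaps, out-of-arena points).
* Facing angles use body-centre headings; wing or leg contact without
  facing is not captured by the angle criterion.
* Minute snapshots treat events as atomic at their onset minute; an event
  straddling a minute boundary contributes its whole duration to the onset
  minute.
* Summary-statistic t-tests inherit the rounding of published summaries;
  agreement within a few percent is the expected resolution.
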