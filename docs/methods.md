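# Methods

This note documents the models, conventions and design choices behind
`zlap`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and angle conventions

Images use pixel coordinates with the origin at the top-left, x rightward,
y downward, 0-based. All well-centric kinematics (location flags, body-axis
angle, clockwise orientation) first converts to a y-up frame centered on the
well (`x_c = x − cx`, `y_c = cy − y`); this conversion happens exactly once,
when the feature table is built. Angles are degrees on the half-open
interval (−180°, 180°]; the wrap maps −180° to +180°. The signed turn is the
shortest wrapped difference of consecutive body-axis angles, so turns over a
closed angular path sum to a multiple of 360°.

The body axis points from the yolk to the midpoint of the two eyes. The eyes
sit rostral to the yolk in larval zebrafish, so this vector approximates the
facing direction; no published formula fixes this axis, and it is the one
interpretive choice in the orientation measures. "Clockwise" is defined with
respect to circulation around the well center: the heading has a clockwise
tangential component iff cross(r, h) < 0 with r the center-to-larva vector
in y-up coordinates. Within 5 px of the center the tangent direction is
numerically meaningless and the flag is null.

## Per-frame thresholds (set a priori)

| quantity | threshold | rationale |
|---|---|---|
| frame validity | min body-part likelihood ≥ 0.5 | predictions below 0.5 are unreliable; the exclusion is strict `< 0.5` |
| moved | displacement > 3 px / 6 s | separates drift and pose jitter from swims |
| scoot / burst | (3, 20] / (20, ∞) px | short swims vs long/fast swims |
| edge | radial distance > 0.5 × radius | thigmotaxis annulus (outer 50 % of the radius) |
| OMR eligibility | ≥ 5 % of valid frames moved in the period | an immobile larva cannot express an optomotor response |
| whole-recording exclusion | < 1 % of valid frames moved | dead/paralyzed larvae |

Boundary conventions are strict at both cut points (3.0 px is not a move;
20.0 px is a scoot). The well midline counts as the lower half (strict
`y_c > 0` for "up").

## The 25 behavioral parameters

Percent measures use *valid* frames as the denominator — invalid poses are
excluded before behavior is computed, so a larva hidden for half a period is
judged on the frames where it was seen. An "absolute edge" variant over all
frames is emitted alongside (`Ed-1h-abs`, `Ed-V-abs`) for users who prefer
the unconditional rate. Because scoot and burst partition moved frames and
share the denominator, `Sc + Bu = activity` holds exactly per period set.

Optomotor (R, G, B, FR) and orientation (Or-*) measures subtract the first
(down-moving lines) period of each color/speed block from the second
(up-moving); which member of a pair moves up is a property of the stimulus
schedule and therefore configurable. The combined RGB / Or-RGB is the mean
of the per-block differences over blocks where the larva was OMR-eligible in
both periods (null only when every block is gated); the pair-mean form keeps
the combined measure on the same scale as the single-color ones.

Habituation is the first-minus-second 5-minute activity difference within
the 1-s-interval sound period, so a *decline* in responding is a *positive*
Hab. Turn-1h is the mean signed turn and Tabs-1h the mean absolute turn over
valid frame transitions in periods 1–6; means (not sums) keep both
duration-invariant.

## Group statistics

Group summaries are null-aware: a larva whose OMR measure is gated to null
reduces that parameter's n only. Standardization subtracts the DMSO vehicle
mean per parameter, leaving deltas in percentage points (degrees for turn
measures); the vehicle row is zero by construction. Welch's
unequal-variance t-test (two-sided, Welch–Satterthwaite degrees of freedom)
compares each treatment to the vehicle larvae — suited to the unequal group
sizes and variances typical of these screens — with Bonferroni tiers at
0.05/0.01/0.001 over the 190 screened compounds. Two-sidedness is the
conservative choice; sidedness is not prescribed by the assay.

## Screen analytics

PCA is centered but unscaled: all 25 measures live on comparable
percentage-point scales and receive equal weight (a scaling toggle exists).
Missing matrix cells are imputed as 0 — the DMSO-like neutral value — and
logged. K-means runs on the smallest number of leading principal axes
reaching 85 % cumulative explained variance, with 25 restarts and a fixed
seed; the cluster count is chosen by the average silhouette width over
k = 2…10. Hierarchical clustering uses Euclidean distances with Ward's
minimum-variance linkage on the raw 25-parameter space (Ward linkage is a
hierarchical-clustering concept; it does not apply to K-means, which uses
the PCA axes instead). The "CsA-type" cluster is whichever cluster contains
all reference compounds (CsA, FK506); if they split, the result is null
with a warning rather than a guess.

## Well detection

Detection runs a circular Hough transform over Canny edges (`scikit-image`),
scanning radii between the runtime bounds (defaults 65–85 px around the
nominal 75-px well radius) in 2-px steps, then greedily keeps
accumulator-ranked candidates subject to a pairwise Euclidean center
distance ≥ 150 px, capped at `floor(area / min_dist²)` detections. Edge and
accumulator thresholds are exposed as keyword arguments; the defaults were
chosen on the synthetic renders. Grid identities come from 1-D clustering of
center coordinates with a gap threshold of half the median nearest-neighbor
distance — robust to center jitter well below half the 160-px pitch without
assuming an exact pitch. Ellipse fitting, illumination correction and
plate-type auto-detection are out of scope.

## The synthetic larva

The generator is a discrete-time stochastic walker at the 6-s frame cadence,
not a biomechanical model. Per frame: move with probability `p_move`,
augmented during sound periods by a startle (20-s pulses) or excitability
(1-s pulses) increment that decays exponentially within the period at the
habituation rate; draw the step length from the scoot (uniform 4–18 px) or
burst (uniform 22–60 px) distribution — strictly inside the 3/20-px class
boundaries so classification of true steps is unambiguous; update the
heading by von-Mises persistence noise (κ = 4) plus a constant turn bias;
during line periods, capture the heading toward the line direction with
probability `omr_gain`; reflect at the well wall (larvae cannot leave
wells). Poses place the eye midpoint 9 px rostral of the yolk with 6-px eye
separation, add Gaussian jitter (σ = 0.5 px), and drop body-part likelihoods
below the validity threshold at rate 2 %.

The pose jitter σ is 0.5 px rather than the nominal few-px accuracy of real
pose estimators for a quantitative reason: the displacement of a stationary
point under i.i.d. jitter of σ per frame is Rayleigh with scale σ√2, so σ = 1
would mislabel ~10 % of stationary frames as moves (P(d > 3) = e^−2.25),
while σ = 0.5 keeps the false-move rate near e^−9 ≈ 10⁻⁴. With constant
`p_move` and no stimulus terms, expected baseline activity is therefore
100 × `p_move` to good accuracy, which the tests verify within 3 SEM on
48-larva groups.

Phenotype presets encode the screen's reference pharmacology: the
calcineurin-inhibitor preset is hyperactive (p_move 0.30 vs 0.15),
hyperexcitable (gain 0.50 vs 0.30), barely habituates (rate 0.002 vs 0.03)
and mostly ignores the lines (omr_gain 0.05 vs 0.25); the proINDY preset is
the near-opposite (0.06 / 0.10 / 0.05 / 0.70). Rescue combinations
(CsA+proINDY, FK506+proINDY) are assigned the CsA-like phenotype, mirroring
the observation that the combination does not revert the profile. Simulated
screens default to the reference study's group structure — 190 library
compounds at 48 larvae each and 844 DMSO vehicle larvae — with the library
split 70 % control-like, 15 % CsA-like, 15 % opposite.

What the generator does **not** emulate: bout-level swim kinematics, tail
dynamics, inter-larva variability in baseline parameters, illumination
artifacts, occlusions, or position-correlated pose failure. Passing
recovery tests therefore demonstrates that the pipeline's arithmetic and
clustering recover phenotypes whose statistical structure matches its
assumptions — not that the thresholds are optimal for any particular real
imaging rig.

## Problem sizes used in tests and the acceptance script

The output-contract check runs one full-size experiment (384 wells × 1800
frames → 691,200 × 33). The repeated-screen checks (cluster-count selection
and CsA-cluster precision/recall, 20 seeds) keep the 190-compound library
but use 8 larvae per group and 96 vehicle controls; at that size
compound-level means are separated by many standard errors, so recovery is
tested at a fraction of the full simulation cost. The per-frame oracle
checks use 1,000 random poses; Welch's test is checked against an
independent implementation on 1,000 random group pairs at 10⁻¹⁰.

## Known limitations

* The 33-column order is this package's canonical order; the original
  analysis tool's column order is not published.
* The heading axis (yolk → eye midpoint) and the circulation-based
  "clockwise" flag are interpretations, flagged as such above.
* Statistical tests pool larvae across repeat experiments; clutch-level
  random effects and FDR-style corrections are out of scope.
* Period 18 (post-stimulus) enters no behavioral parameter; it is carried
  through the feature table for completeness.
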