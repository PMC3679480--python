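# Methods

This note documents the models, parameter choices and numerical decisions
behind `larvatrack`, and what the synthetic-fixture experiments do and do
not demonstrate.

## Calibration and units

Every threshold is stored in physical units (mm, mm², ms, degrees) in
`CalibrationConfig` and converted to pixels/frames at the use site.  The
defaults describe the reference recording setup: 66 µm pixels, 337 Hz,
2.2 cm wells, 5–7 dpf larvae.  Key values and their roles:

| parameter | default | role |
|---|---|---|
| `core_area_min/max_mm2` | 0.0871 / 0.8712 | eroded-core area gate (20–200 px² at default calibration — the mm² bounds are exactly round pixel counts, so area gating is resolution-consistent) |
| `tail_length_min/max_mm` | 1.32 / 3.96 | tail-validity gate; out-of-range frames carry the previous tail |
| `contact_area_mm2` | 1.9 | full-body area above which two larvae are considered touching |
| `contact_line_vs_threshold_mm` | 1.32 | core distance selecting line vs. intensity separation |
| `move_angle_delta_deg` | 1.15 | bend-angle deviation from the 10-frame surrounding mean that marks an active frame |
| `merge_gap_ms` | 14.8 | events closer than this merge (≈ 5 frames at 337 Hz) |
| `min_displacement_mm`, `min_angle_range_deg` | 0.099, 2.86 | false-positive rejection |
| `candidate_ratio_soft/hard` | 0.20 / 0.25 | tail-tip candidate symmetry bounds |
| `binarize_threshold` | 25 | fixed absolute difference on the 0–255 scale; a fixed level (not Otsu) is deterministic and appropriate for controlled illumination |
| `erosion_iterations` | 2 | 3×3 square element; kept fixed rather than scaled with resolution |
| `median_filter_frames` | 5 | ≈ 15 ms: removes single-frame tail glitches without blunting 25 Hz oscillations |
| `min_eroded_pixel_change` | 3 | eroded-mask change required during a genuine movement |

## Tracking model and conventions

Coordinates are (x right, y down), 0-based, centroids at pixel centres;
angles from +x, in [0, 2π).  "Larva's left" corresponds to positive signed
bend angles.

*Background* is the per-pixel maximum over frames: moving dark objects
vanish under a max projection, so each background pixel must be
larva-free in at least one frame — the reason the fixture schedules keep
larvae moving.

*Heading* is the principal axis of the eroded core's central second
moments.  The 180° ambiguity is resolved by the third central moment along
the axis: the head+bladder end is denser, so the skew points toward the
thin trunk side and the heading is taken opposite to it; when the skew is
weak (|skew| < 0.1 in σ units) continuity with the previous frame decides.
Isotropic components return the previous heading flagged invalid.

*Identities* use constant-velocity prediction from the last two frames and
greedy nearest-candidate matching in increasing distance order (ties to the
lower larva id).  Frame 0 seeds labels in candidate order; frame 1 assumes
zero velocity.  Two larvae predicting the same nearest candidate raise a
collision, resolved by repeated erosion of the shared blob's region of
interest (≥ 2 components of ≥ 4 px², cap 10 iterations).

## Tail tip, midline and bend angle

The body contour is traced by marching squares at the 0.5 level of the
component mask (an ordered border-following, equivalent in role to
classical contour tracing on the binary image).  After rotating contour
coordinates so the head axis is vertical with the head up, reference point
A1 is the contour point nearest the head centre and A2 the point nearest
A1's mirror across the head axis.  Candidates are the contour points of
extremal x and y among points caudal to A1/A2; each candidate's contour-arc
distances d₁, d₂ to A1 and A2 must satisfy |d₁−d₂|/(d₁+d₂) ≤ 0.25 (the
max-y candidate already at ≤ 0.20, a soft pre-filter on the most common
winner).  Among survivors the tip minimizes the scalar product of the
travel-direction tangents just before and after the point — +1 on a smooth
arc, −1 at a perfect cusp — i.e. the sharpest contour turn.  The tangent
step is 4 contour points, comparable to the rendered tip width.

The *head centre* ("boundary of head and trunk") is operationalized as the
eroded-core centroid shifted tailward along the heading by one head radius,
r = √(core area / π); no closed formula exists for it, and this definition
is shared by the tracker and the fixture ground truth so the two are
commensurable.

The *midline* splits the contour at the tip and at the two near-head
points (A1's flank and the closest point on the opposite flank, found by
excluding a 15% contour-index neighbourhood of A1), resamples both arcs to
equal counts, averages them, fits a smoothing spline (residual ≈ 0.5 px per
point) and resamples 10 equally arc-spaced points from head centre to tip.
Tail length is the spline arc length; frames outside [1.32, 3.96] mm carry
the previous tail, flagged invalid.  The *bend angle* is the signed angle
between the reversed heading axis and the head-centre→tip vector, in
(−180°, 180°].  Invalid frames are filled with the previous valid value and
a 5-frame median filter is applied before bout detection (the 1.15° test
therefore runs on the cleaned trace).

Midline arc length is checked for invariance under rigid rotations of the
input frame; on a pixel grid only quarter-turns are rigid, so the test uses
`rot90`.  Re-rendering the same larva at diagonal headings changes the
rasterized length by a few percent — a property of rasterization, not of
the midline estimator (the measured-vs-truth error stays small at every
heading).

## Contact separation

Line separation searches 36 cut angles × 1-px offsets along the inter-core
axis, erasing pixels within 0.75 px of the line, and keeps the cut
maximizing the summed areas of the two head-bearing components (ties: fewer
erased pixels).  Intensity separation raises the binarization threshold in
steps of 5 (cap 250) until two components, each at least core-sized and
containing one head centre, emerge; requiring core-sized components
prevents a few residual dark pixels from being accepted as a "body".
When neither succeeds the frame is unresolved and tails carry over.
Head-centre containment is judged with a 1-px neighbourhood because the
head centre is subpixel while components are pixel sets, and the optimal
cut may pass through the head-centre pixel itself.

## Bout detection

Active frames satisfy |α(t) − mean(α over the ten surrounding frames)| >
1.15°, the surrounding mean being 5 frames before + 5 after, excluding the
current frame, truncated at trace boundaries.  Maximal active runs merge
when their gap is under 14.8 ms; merging is idempotent.  A merged run
becomes an event only if the straight-line core displacement start→end
exceeds 0.099 mm, the in-event bend-angle range exceeds 2.86°, and (when
eroded masks are available) the eroded-mask pixel change between some
consecutive frame pair reaches the configured minimum.  Compound maneuvers
without intermediate stabilization remain a single event by construction
(they form one active run).

## Kinematics

Oscillations are counted as bend-angle extrema above 5° divided by two
(one oscillation = one left + one right half-beat); TBF = oscillations /
duration.  Heading is unwrapped before the range computation and re-zeroed
at onset.  Distance is the path length of the core (sum of per-frame
steps), matching "distance traveled" rather than net displacement; speed =
distance / duration, so speed × duration reproduces distance exactly.

Curvature fits each midline with a cubic spline parameterized by
normalized arc length and evaluates |x′y″ − y′x″| / (x′² + y′²)^{3/2} on a
fixed grid of 25 arc positions, converted to 1/mm.  The formula is
invariant under regular reparameterization, rigid motions (verified to
1e−12 relative) and covariant under scaling.  Circular-arc oracles at radii
5–50 px reproduce 1/r to ≈ 0.1%.

## Categorization

Per movement, four series are aligned to the peak of the first bend (first
|α| extremum above 2°): |α| on [0, 178] ms in 12 ms bins (15 bins),
instantaneous frequency on [0, 104] ms in 7 ms bins (14), cumulative |α|
(running mean from t = 0) on [0, 178] ms in 12 ms bins (14), and speed on
[0, 240] ms in 24 ms bins (10) — 53 raw components total; the stated
windows and widths admit several roundings and this 15+14+14+10 split is
the one that reaches exactly 53.  Instantaneous frequency is 1/(2 ×
half-period) between successive signed extrema (extremum times refined to
sub-frame precision by parabolic interpolation), held piecewise-constant.
Series are spline-interpolated onto bin centres; events shorter than a
window are padded by last-value extrapolation and flagged rather than
dropped, so every movement is classifiable.

The 53 components are z-scored (the choice to standardize before the PCA
is the package's own; unstandardized components would let the
large-amplitude bins dominate), reduced to the first 14 principal
components, and the z-scored total duration is appended.  Two linear SVMs
(C = 1) run in sequence: S vs. {T, E}, then T vs. E; a vector exactly on
the stage-1 boundary goes to stage 2.  Amplitude-type features use |α|, so
classification is invariant to mirroring the larva.  The model serializes
to portable JSON (scaler, PCA basis, separator coefficients).

## Transition-index analysis

I(B₁→B₂) = p(second = B₂ | first = B₁) / p(B₂) with the marginal taken
over all movements of the partition (not per window), so
Σ_B₂ I(B₁→B₂)·p(B₂) = 1 for every B₁ with outgoing pairs.  Same-larva
pairs are consecutive movements of one larva; different-larva pairs are
consecutive movements in the well-wide time ordering restricted to
distinct larvae.  The windowed form assigns pairs to (Δt onset, Δ
onset-distance) cells — by default every ordered pair inside the time
horizon, with a `pairing="successor"` mode restricted to sequential pairs
(in which a single all-spanning cell reproduces the plain index exactly).
Cells with fewer than 20 pairs are masked; ratios of small counts are
unstable.

The permutation test shuffles labels across movements, keeping identities,
times and positions fixed (50 permutations), and recomputes the maximal
windowed index.  The observed value is compared with a two-sample t-test
in which the observed side has a single value: pooled variance comes
entirely from the permutation sample, SE = s·√(1 + 1/n), n−1 degrees of
freedom.  An exceedance-count p-value (1 + #{null ≥ obs}) / (n + 1) is
reported alongside as a distribution-free check; with 50 permutations its
floor is 1/51 ≈ 0.02, so detections below p = 0.01 rest on the t-test, as
in the windowed-enrichment validation.

## Synthetic fixtures: what they emulate and what they don't

The renderer draws, on a bright well (intensity 230) over a darker
surround, larvae composed of a rigid head assembly (8 × 5.5 px ellipse +
4 px-radius swim-bladder disk 9 px caudal, intensity 60) and a 40 px tail
whose thickness tapers 1.8→0.8 px and whose intensity ramps 60→140 toward
the tip, stamped along an integrated-curvature midline; Gaussian pixel
noise (σ = 2) is added last.  The paler tail tip mirrors real images,
where the thin caudal fin transmits more light — it is what makes
intensity-based contact separation meaningful.  Tail bending distributes a
total tangent turn ψ along the tail with a caudally concentrated weight
(∝ s²) for slow swims and a uniform weight for turns and escapes, matching
the qualitative curvature distributions of the three maneuver classes; the
scripted bend amplitude maps to ψ through the profile's small-angle gain,
and ground truth always records the realized geometry.

Maneuver archetypes (defaults): S — 20° amplitude, 25 Hz, 200 ms,
10 mm/s, ≈ 0 heading change, caudal bending; T — 55°, 12 Hz, 160 ms,
8 mm/s, 60° heading change; E — 65°, 35 Hz, 250 ms, 28 mm/s, large heading
change.  These sit inside the ranges reported for group recordings of 5–7
dpf larvae (mean TBF ≈ 24 Hz, bout duration ≈ 190 ms, distance ≈ 2.5 mm,
speed ≈ 13 mm/s) while keeping the classes separable by amplitude and
alternation frequency — turns and escapes differ chiefly by the frequency
of left-right alternation.  Trace-only fixtures use a Tukey envelope
(taper 0.2) around an enveloped sinusoid plus Gaussian noise.

Ground-truth core positions are the centroids of the twice-eroded,
noise-free rendering of each larva alone — i.e. what an ideal tracker
would measure on clean pixels — and the ground-truth head centre and bend
angle use the same definitions as the tracker.  This makes tracker-vs-truth
errors attributable to noise and discretization rather than to definition
mismatches.

Limitations: no refraction, shadows, vignetting or illumination drift; no
z-overlap (the experimental design it mimics keeps water shallow for the
same reason); no 3-larva pileups; rigid head (no eye/jaw movement); class
archetypes are cleaner than real behavior.  Passing the synthetic
benchmarks therefore demonstrates correctness of the algorithms under the
stated imaging model, not performance on degraded real-world footage; the
held-out classifier accuracy bar (≥ 90%) is intentionally stricter than
what is achievable on ambiguous real maneuvers.

## Validation experiment sizes

The benchmark suite (also run by `scripts/acceptance.py`) uses: 10 000
i.i.d. movements (marginals 0.35/0.48/0.16 for S/T/E, normalized) for the
null; 1000 frames × 7 larvae for tracking fidelity; 22 scripted crossings
(angles 30–180°, lateral offsets 0–10 px) for contact resolution; 20
traces × 10 planted events at 0.3° noise for detection; radii 5–50 px for
the curvature oracle; 300 training + 150 held-out movements for the
classifier; a 20 000-movement Markov chain with P(E|E) = 3·π_E for the
planted enrichment.  These sizes give stable rates (binomial SE ≤ ~1.5
points on each) with a full run in a few minutes.
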