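# Methods

`icbkit` implements the quantitative analyses used to characterise
dopamine-agonist-induced impulsive-compulsive behaviour in rats —
open-field and elevated-plus-maze motion metrics, compulsive-checking
scoring, behavioural-state bout analysis, rat Iowa Gambling Task (rIGT)
choice curves, and spatial mapping of striatal pS6⁺ cell distributions —
together with seeded synthetic-data generators that stand in for the
raw recordings.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do
not establish.

## Trajectory metrics

A trajectory is a uniformly sampled planar track (s, cm, arena-centred,
y up).  Speed is estimated by central differences and median-smoothed
over 0.5 s; "time mobile" is the total duration with smoothed speed at
or above 2 cm/s, and "maximal speed" is the peak of a 0.5 s
moving-average speed.  These smoothing and threshold defaults are
declared package choices (commercial tracking software does not publish
its internals); all are configurable.  Total distance is the sum of raw
Euclidean step lengths, reported in metres.

Arena geometry: the open field is an 80 × 80 cm square whose inner zone
is the centred square containing 80% of the floor area (side
80·√0.8 ≈ 71.6 cm); the plus maze has two open and two wall-enclosed
arms of 50.8 × 10.2 cm around a 10.2 cm centre square.  An arm entry is
counted when the tracked point moves from the centre into an arm and
stays at least 0.5 s (the body-part rule of the original scoring is
unreported; the centroid-dwell rule is ours).  The open-arm entry
fraction is flagged undefined — never reported as zero — when no arm
entry occurred.  Region tests are half-open toward the lower zone index
so boundary samples are assigned deterministically.

## Compulsive checking

The 140 × 140 cm platform is covered by a 5 × 5 grid of 35 cm zones
whose outer ring extends 17.5 cm past the platform edge (25 zones).
Stops are maximal intervals of smoothed speed below 1 cm/s lasting more
than 1 s (the duration criterion is standard for this assay; the speed
threshold is our declared default), assigned to the zone of the stop's
time-weighted centroid.  Home bases are the one or two non-adjacent
(8-neighbour) zones with the largest total stop duration; a second base
is admitted only when it accumulates at least half of the first base's
stop time (the "one or two" rule gives no threshold; 0.5 is ours and is
configurable).  Ties break toward the lower zone index.

Visits are zone entries of the tracked point, with re-entries into the
same zone within 1 s merged to suppress boundary jitter.  Over the
scoring window (the full 45 min for baseline-like animals; the last
30 min for hyperlocomotive ones, discarding the transient suppression
phase of D2/3 agonists) the five checking parameters are:

* frequency — number of visits to home-base zones;
* observed/expected ratio — (home-base visits ÷ number of home bases)
  ÷ (total zone visits ÷ 25).  The per-zone expectation controls for
  overall locomotion: a zone-indifferent visitor scores 1 regardless of
  how much it moves.  Variants of this normalisation exist in the
  literature; the per-home-base versus per-zone form used here is an
  explicit interpretation, stated prominently because downstream
  numbers depend on it;
* mean visit time at the home bases;
* mean return time — from home-base exit to the next home-base entry;
* stops between checks — mean number of stops strictly between
  consecutive home-base visits.

With fewer than two home-base visits the return-based quantities are
flagged undefined.  When two home bases exist, visits to either count
as checks and the frequency is summed over both (the alternative,
per-base reporting, is recoverable from the visit sequence).

## Behavioural states

Event logs list non-overlapping bouts of one of six states (locomoting,
rearing, grooming, head bobbing, sniffing up, sniffing down) within a
50 s scoring span per observation window; unannotated spans stay
unscored.  Summaries: total time per state averaged over windows; mean
bout duration pooled over windows for the four states present in every
experimental group (locomoting, rearing, sniffing up, sniffing down),
with zero-bout states reported missing rather than 0; and the switch
rate — label changes between consecutive scored events divided by the
number of distinct common states present in that window, averaged over
windows.  A gap does not break the event sequence by default
(configurable), and the denominator uses the states present in that
window, not the global repertoire.  The switch rate is invariant to
uniform time dilation.

## rIGT

The standard four-arm schedule: the advantageous arm pays 1 pellet with
probability 0.8 (quinine otherwise), the disadvantageous arm 3 pellets
with probability 0.1 (quinine otherwise), two arms are empty.  Expected
payoffs are therefore 8 and 3 pellets per 10 choices, and the chance
levels for empty and advantageous choice fractions are 0.5 and 0.25.
Win probabilities are realised as i.i.d. Bernoulli draws per trial; a
deck mode with an exact 8-of-10 quota is available as a toggle for the
literal reading of the printed schedule.  A complete protocol is 120
trials in 10 sessions of 12; fractions are reported per 12-trial block
(incomplete final blocks use their actual count), and block 10 is the
final-performance score.  Any flagged trial (failure to leave the start
box, no choice, eating quinine, strong quinine-specific responses)
excludes the whole animal; an audit table records reasons.  Completed
choices on quinine trials still count in the fraction denominators.

## Spatial mapping

Each hemisection carries cell coordinates (µm), a traced outline
polygon, an optional lesion (denervated-area) polygon, and metadata.
Lesion extent is the percentage of outline area outside the lesion
polygon; densities are point-in-polygon counts per mm², averaged
bilaterally over the three rostrocaudal levels per animal.

Right hemispheres are mirrored into the left frame (an involution).
Every outline is then registered to a reference by a similarity
transform (rotation, isometric scale, translation).  The original
workflow did this manually; here the fit is automated for
reproducibility: a closed-form initialisation from centroids, √area
scale and the principal axis (180° ambiguity resolved by residual),
refined by Nelder–Mead on the symmetric mean nearest-neighbour distance
between 200-point boundary resamplings.  If refinement fails to improve
the initialisation, the closed form is used and a warning raised.  The
reference outline is the angular mean of aligned section outlines (not
an atlas registration), which is well defined for star-shaped
hemisection traces.

Aligned cells are binned into a 75 × 75 histogram of 80 × 80 µm pixels
(5625 per section) whose window centres the reference bounding box;
bins are half-open, cells off the grid are counted separately, and
histogram mass plus the off-grid count always equals the cell count.
Group difference maps subtract mean count maps inside the striatum mask
(bins whose centre falls inside the reference outline).  Pixelwise
group comparison uses two-sided Mann–Whitney tests per in-mask,
non-degenerate bin — exact enumeration when the smaller group has ≤ 8
maps and the bin has no ties, tie-corrected normal approximation with
continuity correction otherwise; all-tied bins report p = 1 — followed
by Benjamini–Hochberg control at α = 0.01 over the tested bins only
(the test universe is a declared choice).

## PCA covariance patterns

Flattened maps are stacked into a section × pixel matrix (one row per
hemisection-level; left and right contribute separate rows).  PCA is
computed by SVD of the column-mean-centred matrix — no variance
scaling, since all pixels share units and scaling would inflate the
empty margins; whether the original analysis centred is unreported, so
centring is a declared interpretation.  Components are unit-norm and
ordered by explained variance; the coefficient of a section on a
component is the projection of its centred row, and the full-rank
reconstruction is exact to numerical precision.  Because PCA signs are
arbitrary, components are sign-fixed (largest-|loading| pixel positive,
or against supplied reference patterns), with coefficients flipped
consistently.  Three components are reported by default; the full
spectrum is retained.  Expression analysis averages coefficients within
animal (sections are repeated measures) and submits each component to
the treatment × lesion ANOVA with the pooling rule below.

## Statistics

The inferential primitives are implemented from first principles and
validated against independent oracles in the test suite:

* two-factor ANOVA with interaction, Type-III sums of squares under
  sum-to-zero contrasts (well defined for unbalanced cells; the SS type
  of the original software is unreported).  Perfectly fitted
  (zero-residual) data report F = 0, p = 1 rather than 0/0;
* Tukey–Kramer pairwise contrasts from the studentized range, with an
  explicit pooling branch: treatment contrasts pool across lesion
  groups when neither the lesion effect nor the interaction is
  significant, and are computed within lesion level otherwise;
* Kruskal–Wallis with tie correction and Dunn's z post hoc
  (Bonferroni by default, BH optional);
* Mann–Whitney U, exact (dynamic-programming null distribution of U)
  for min(n) ≤ 8 without ties, tie-corrected normal approximation with
  continuity correction otherwise;
* Benjamini–Hochberg step-up cutoff and rejection mask, plus monotone
  q-values.

## Synthetic data

The generators are first-class, tested code; all draw from
`numpy.random.default_rng(seed)` and are byte-reproducible after
serialisation.

**Trajectories** follow a correlated random walk: mobile/immobile
phases from a two-state renewal process (immobile dwell exponential,
mean 4 s by default; the mobile hazard set to give the requested
mobility fraction), von Mises turning (κ = 4) and gamma step speeds
(mean 12 cm/s, CV 0.5 while mobile) at 5 Hz.  Home-base attraction
produces a checking cycle: after each stop the walk runs an undirected
excursion for an exponential time (mean 8 s, shortened by a factor
1 + a/2 at attraction a — preoccupation shortens trips), then a homing
drift of weight a/(a+1) steers the heading to the nearest home-zone
centre, where an elevated stopping hazard ends the trip.  Stronger
attraction therefore monotonically raises checking frequency and the
observed/expected ratio and lowers return time and stops between
checks; the response saturates above a ≈ 5, where the cycle time is
dominated by the dwell itself, so sweeps probing the trend use levels
within the responsive range (0.5–6).  With a = 0 the walk is spatially
unbiased.  Walls reflect; on the plus maze proposals are projected onto
the cross.

**State logs** are semi-Markov: exponential bout durations per state
and a row-stochastic transition matrix; self-transitions extend the
running bout, so realised bout means equal `bout_mean` exactly when the
diagonal is zero.  The last bout of each window is truncated so events
tile the 50 s span.

**Choice sequences** come from a delta-rule agent, Q ← Q + α(r − Q),
with softmax choice (inverse temperature β) and quinine encoded as
−0.5 pellet-equivalents — the simplest agent whose curves qualitatively
reproduce task acquisition; β = 0 yields exact 1/4 arm probabilities.

**Sections** are inhomogeneous Poisson point patterns over a
striatum-shaped template outline (smooth 64-vertex closed curve,
~12.8 mm²).  The intensity is a base level (cells/mm²) modulated by
three smooth basis fields — a dorsolateral gradient, a focal lesion
hotspot, and a centro-medial-versus-dorsolateral shift — each
RMS-normalised over the template interior so weights are comparable;
negative local intensity is clipped at zero.  Sections get smooth
vertex jitter, a random similarity placement for the alignment stage to
undo, and mirrored right-hemisphere copies.  For pattern-recovery
studies a map-level cohort generator plants the Gram–Schmidt
orthonormalised versions of the same fields with Gaussian coefficients
on top of Poisson noise; its planted-variance:noise ratio for a pattern
is defined as the total variance that pattern contributes across the
map divided by the summed per-pixel Poisson variance.  Recovery runs
use distinct ratios (16:8:4) so the eigenvalues separate and each
component can be matched to its planted pattern.

**What the synthetic data do not show.**  The generators reproduce the
statistical structure the analyses assume — not rat behaviour.  Group
presets in the bundled study ("R2.5-like" hyperlocomotive, strongly
checking, poorly learning; "LD24-like" grooming-heavy baseline; etc.)
are illustrative regimes matching only the direction of reported drug
effects; they are not fits to any animal's data, and passing tests on
them demonstrates correctness of the measurement code, not biological
claims.  Real tracking data carry missing samples, identity swaps and
reflection artefacts that the generators do not emulate.

## Pipeline and problem sizes

`make_synthetic_study` writes a complete eight-cell study (default 3
animals per cell, 10 min open field, 45 min checking, 5 min plus maze
at 5 Hz, 3 windows of state logs, 120 rIGT trials for the lesioned
cohort, 6 hemisections per animal) and its manifest;
`run_pipeline` emits one results directory per figure analogue.  All
randomness is spawned from the single manifest seed and every table is
written with a fixed `%.6g` float format, so reruns are byte-identical.
Alignment refinement is off by default in the pipeline (the closed-form
fit is near-exact for the jittered synthetic outlines) and available
via `--refine`.  These sizes were chosen so the complete study runs in
well under a minute per stage on one core; all of them scale up through
parameters.

## Known limitations

* Repeated-measures/mixed-effects inference on block curves is out of
  scope; the package exports the block-level summaries such models
  consume.
* The EPM entry rule uses the tracked centroid only.
* The reference outline is a template mean, not an atlas registration,
  so maps are comparable within a study but not anchored to stereotaxic
  space.
* Exact Mann–Whitney enumeration is limited to min(n) ≤ 8 without ties;
  count data at realistic bin occupancies essentially always fall back
  to the tie-corrected approximation.
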