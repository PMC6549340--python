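# Methods

This note documents the models and procedures `combiscreen` implements,
the parameter choices that matter, what the synthetic data generator
does and does not emulate, and the numerical conventions adopted where
the design was genuinely open.

## Exhaustive combination designs

An exhaustive experiment over a panel of $N_d$ drugs at one fixed
concentration each evaluates every subset of size $1..c$; the treated
well count is $N_w(N_d,c)=\sum_{i=1}^{c}\binom{N_d}{i}$. Multiple
concentrations per drug are out of scope by definition — the design
unit is the subset, not the dose.

Feasibility on a 384-well plate requires
$N_w + U_{\min} \le 384$ with $U_{\min} = 40$ untreated wells; an
infeasible design is answered with the minimum number of plates over
which a balanced split of the conditions fits, never with an error.
When space allows, the layout carries 53 untreated wells (the floor is
40; 53 is the default target and configurable); all remaining wells are
blanks, which the end-point assay needs for background correction.

Each replicate plate draws one uniform permutation of (conditions +
untreated wells) over the plate, seeded as `seed + replicate_id`, so
replicates are independent but individually reproducible. Randomizing
positions across replicates turns spatially correlated noise (edge
effects, gradients) into approximately independent noise terms that
averaging can suppress. Whether untreated wells should additionally be
spread spatially (e.g. one per quadrant) is an open design question;
uniform randomization is used. An optional flag excludes edge wells;
default off.

The destination CSV (one row per compound transfer:
`plate_id, destination_well, compound, final_concentration, unit`;
marker rows for untreated/blank wells) is this package's own schema —
chosen to round-trip losslessly — not a vendor format.

## Foreground segmentation and temporal readouts

Phase-contrast backgrounds dominate sub-confluent frames, so the global
background level $\mu_b$ is estimated as the median intensity. The
pixel population is split at $\mu_b$ and Otsu's threshold is applied
independently to each side, giving a background interval
$[\mathrm{lo},\mathrm{hi}]$; pixels outside it are foreground. Cells in
phase contrast are both darker (bodies) and brighter (halos) than the
background, which is why a two-sided interval rather than a single
threshold is needed. Degenerate cases: a constant frame yields the
interval $[v,v]$ with a warning; a side with fewer than two distinct
intensities contributes its extreme value, i.e. no foreground on that
side.

The interval method assumes the background forms a narrow dominant
mode, as delivered by a camera quantizing to integer grey levels. On a
wide continuous unimodal intensity distribution with no foreground at
all, Otsu has no valley to find and the interval cuts into the
background tails; frames in a real screen always contain cells, so this
matters mainly for synthetic edge cases (see limitations).

Per well, confluence is the foreground area fraction (invariant to crop
size, unlike a pixel count) and its change is
$\Delta C(t_i) = (c(t_i) - c(t_0))/c(t_0)$, zero at the first recorded
frame. Morphology is summarized by hierarchical pixel histograms
(PHHC): at pyramid level $\ell = 0..L-1$ the frame is downsampled by
$\mathrm{scale}^\ell$ (local averaging; nearest-neighbor for the mask)
and the foreground intensities are histogrammed into $n_{\mathrm{bins}}$
fixed-range bins; the concatenation is $h$. Defaults $L=3$,
scale $=2$, $n_{\mathrm{bins}}=16$ (48-dimensional $h$), all
configurable; the histogram range must be held fixed across a plate so
$h$ vectors are comparable between wells. The morphology change is
$\Delta M(t_i) = \lVert h(t_i)-h(t_0)\rVert_1 / \lVert h(t_0)\rVert_1$
(the norms are L1), again zero at $t_0$, which normalizes away seeding
differences between wells. Time is indexed from the first recorded
frame; in a typical screen that is 4 h post-treatment with 17 frames at
4 h intervals.

Per-frame computations are independent (a pure map); all reductions
are order-invariant, so parallel or permuted processing yields
identical profiles.

## Matched-filter object counting

Detection of apoptotic-like (rounded, halo-bearing) cells uses a linear
matched filter. Under Gaussian noise with covariance $C$ the optimal
coefficients are $w = C^{-1}(s-b)$; with $C=I$ (isolated objects on
unstructured background) this is $w = s - b$, where $s$ is a
user-selected prototype patch (~33×32 px in practice) and $b$ a scalar
background level broadcast over the patch (the per-frame median, or a
training-set mean — the choice of a scalar is this package's, made
because no patch-shaped background estimator is defined for single
prototypes). The response $y(p) = \sum w \odot r_p$ is evaluated at
every fully contained patch position (no padding); responses are raw —
unnormalized — so the detection threshold $\tau$ is in response units
and must be tuned per prototype.

Counting algorithms:

* **Taboo-based** — repeatedly accept the largest remaining response if
  it reaches $\tau$, record the detection, and mask ("taboo") the full
  patch footprint centered on it. Even patch dimensions round the
  center toward the top-left. Detections are therefore separated by at
  least the footprint in one axis.
* **Position-based** — binarize $y \ge \tau$; find maximal contiguous
  column intervals containing any supra-threshold pixel, then within
  each, maximal contiguous row intervals; the count is the sum of
  row-interval counts over column intervals. This two-pass reading is
  cross-checked in the tests against a connected-component oracle; it
  can merge objects whose row and column projections both overlap.

The per-frame count is the mean of the two, and a well's count vector
is the per-time-point mean count.

The threshold is tuned by supervised learning on annotated images
(observed counts from visual inspection). The loss is the mean absolute
difference between observed and predicted counts. Optimization is an
interval search: 11 starting points at the deciles of the pooled
supra-background response values, then 20 golden-section refinement
iterations on the bracketing interval, ties resolved toward the larger
threshold (fewer detections). This search runs inside k-fold
cross-validation (default 4 folds, repeated 2 times with reshuffled
partitions): each partition yields an optimum $\tau_j^\*$ and its
leave-out loss. If the median leave-out loss exceeds 5 counts, tuning
aborts with a recommendation to annotate more images; otherwise
$\tau^\* = \mathrm{median}_j\,\tau_j^\*$. At least 8 training images,
each containing both object-like and background regions, are
recommended. The loss is piecewise constant in $\tau$, so golden-section
refinement converges to a plateau rather than a point; any plateau value
is equivalent under the loss, and the tie rule picks its upper end.

## Plate quality control

**Intra-plate.** At the earliest frame (ideally pre-effect) all wells
should look alike. Pairwise relative L1 distances between first-frame
PHHC vectors ($\lVert h_i - h_j\rVert_1$ normalized by the mean of the
two masses; 0 for identical shapes, 2 for disjoint support) give each
well a median distance to the rest; wells above
$\mathrm{median} + 3\,\mathrm{MAD}$ of those medians are excluded from
every downstream step. Because the MAD collapses on a homogeneous
plate and would then flag ordinary extremes, the cutoff has an absolute
floor of 0.5 (a quarter of the histogram mass displaced); both the MAD
factor and the floor are configurable. Excluded wells never enter
inter-plate QC or merging.

**Inter-plate.** The variability of a condition across replicate growth
curves is the area between them,
$V_w = \sum_t (\Delta C^{\max}_w(t) - \Delta C^{\min}_w(t))$, with the
max/min taken per time point. Its null distribution is built by
resampling: draw one untreated well per plate with replacement, compute
$V$, repeat $N = 10000$ times (configurable). Conditions with
$V_w$ strictly above the 95th percentile $\tau_{95}$ of the null are
outliers and are not merged; by construction the false-alarm
probability on well-behaved conditions is $100 - 95 = 5\%$. Both $N$
and the percentile are user parameters. Exclusion granularity is the
whole condition (its wells across all plates), since $V_w$ is defined
across replicates; rescuing a condition by dropping a single deviant
replicate is not attempted.

The accuracy of the 5% calibration depends on how well the finite
untreated pool pins the tail of the null: with ~50 untreated wells per
plate the per-experiment false-alarm rate scatters a few percentage
points around the nominal level, converging as the pool grows (the
acceptance script uses 8000 untreated wells per plate, where the rate
is unbiased to within Monte-Carlo error). This is a property of any
plug-in percentile threshold, not of the implementation.

Replicate merging reports the per-time mean and standard deviation over
surviving replicates plus how many contributed; a condition with no
surviving replicate is dropped, not an error.

## Survival index and Bliss synergy

The end-point survival index is
$S = (f - \tilde f_{blank}) / (\tilde f_{control} - \tilde f_{blank})$
with medians over blank and untreated wells. $S$ is deliberately not
clamped: growth-stimulated wells can exceed 1 and are carried through
with an out-of-range flag, since the $[0,1]$ range is only guaranteed
for growth-inhibiting treatments.

For a combination of $n$ drugs, Bliss independence predicts survival
$\prod_{i} S(c_i)$, and $B = \prod_i S(c_i) - S(\mathbf c_n)$ measures
synergy ($B>0$) or antagonism ($B<0$), in $[-1,1]$ for inputs in
$[0,1]$. $B$ is ambiguous across (expected, observed) pairs, so the
scaled index $B_S = B\,(1-\min\{\text{expected},\text{observed}\})$ is
reported alongside: it suppresses synergy claimed at high observed
survival and antagonism claimed at high expected survival, preserves
the sign, and never exceeds $|B|$ (equality only when the suppressing
term is 0).

Significance uses replicate resampling (the construction is this
package's own): a percentile bootstrap over replicates gives a CI on
$B_S$, and the two-sided p-value is the fraction of a null ensemble —
observed combination survival replaced by the product of independently
resampled single-drug replicate draws, i.e. exact Bliss independence
with replicate noise — whose $|B_S|$ reaches the observed one (with the
standard +1 correction). Across a family of scored combinations,
Benjamini–Hochberg FDR is reported next to raw p-values.

## Response mining

Each condition's four readouts over $n$ time points — $\Delta C$,
$\Delta M$, object counts, and the end-point viability expanded to a
constant $n$-vector — are each divided by their own standard deviation
(a zero-std block passes through unscaled, which is the constant
viability block's normal path) and concatenated into one profile of
length $N = 4n$ (68 for a 17-frame screen). Profiles entering mining
are replicate-merged and QC-passed.

Clustering is top-down multilevel K-means++ (Lloyd iterations, best of
$R = 10$ seeded initializations per K, SSE
$\hat E_{K} = \min_r \sum_k \sum_i \lVert x_{k,i} - c_k\rVert^2$). K is
scanned over $\{1..10\}$ and selected as the smallest K whose relative
SSE drop $\Delta\hat E_{K-1\to K} = (\hat E_K - \hat E_{K-1})/\hat E_{K-1}\cdot 100$
beats −20%; if none does, the level stays unsplit, and a perfect fit
(SSE 0) stops the scan. The literal "smallest K" reading is adopted
(the alternative, "largest K still dropping 20%", cannot be excluded
from the rule's wording alone); for well-separated structure the K=1→2
transition almost always qualifies, so the rule usually yields K=2 per
level and the recursion supplies finer structure. Recursion proceeds
into each cluster until K*=1, fewer than `min_size` (default 8)
members, or `max_depth` (default 2) levels. In the profile dimensions
used here a single isotropic cloud never drops 20% per split, so
homogeneous data stays in one leaf. All of $R$, the K range, the drop
percentage and the recursion limits are configurable, and every
initialization derives from the master seed.

Each node reports its centroid (the group's prototypical response
profile) and its **non-redundant representative set**: iteratively take
the lowest-order remaining combination (lexicographic tie-break), keep
it, and discard every remaining combination containing it. The result
is exactly the subset-minimal members (a minimal antichain), is
independent of input order, and is the device that turns "this group
contains 100 combinations" into "everything in this group contains
drug X".

## Synthetic data generator

The generator emulates, with full ground truth: textured integer-grey
backgrounds (Gaussian noise, default sd 0.75 around level 100);
cell-like foreground as a centered disk of bright/dark texture
(±45 around the background) whose area follows an exponential growth
schedule (untreated cells roughly triple their area over the
recording, starting at 8% confluence); morphology drift as a gradual
shift of the dark/bright mixture; apoptotic-like objects as bright
elliptical rings with darker cores planted at known positions on a
linear count ramp, kept off the cell region (detached dying cells) and
pairwise separated beyond the template diagonal; end-point
fluorescence proportional to terminal viability between blank (500)
and control (30000) levels with multiplicative log-normal noise
(sd 0.03); and replicate plates sharing effect models while re-drawing
all noise.

Treatment effects are four-parameter models (growth inhibition,
morphology drift, apoptotic count, terminal viability). A combination
inherits the elementwise maximum of its members' effects (minimum for
viability, via the kill fraction) unless an explicit boost is
configured — deliberately creating the "one drug explains the group"
structure the subset search must detect, and making inherited effects
Bliss-independent so synthetic synergy tables center on $B=0$.

Fixture frames default to 128×128 px (tests use 64–96 px), much
smaller than a real microscope field; the analysis is size-agnostic
and small frames keep the suite fast. What the generator does *not*
emulate: optics (PSF, phase halo physics), illumination drift, focus
failures, cell migration and division events, debris, or spatially
correlated plate effects. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise models, not
robustness to every real-microscopy artifact.

## Numerical conventions

* Well names are letter row (A–P) + zero-padded 1-based column (A01).
* RNG: NumPy `default_rng`; one master seed per run, per-replicate
  streams as `seed + replicate_id`, cascaded seeds for K-means inits.
* Inter-plate QC uses strict inequality: $V_w = \tau_{95}$ passes.
* The bootstrap p-value uses the $(\#\{|B_S^{null}| \ge |B_S|\}+1)/(N+1)$
  estimator, never exactly zero.
* Even-dimensioned filter patches center toward the top-left; response
  maps index patch corners internally and detections are reported at
  patch centers in frame coordinates.
* Division guards: $\Delta C$ requires $c(t_0) > 0$; $\Delta M$
  requires $\lVert h(t_0)\rVert_1 > 0$; the survival index requires
  distinct blank/control medians; each failure names the offending
  well rather than propagating NaNs.

## Known limitations

* The double-Otsu interval over-segments cell-free frames whose
  background noise is wide and continuous; it is calibrated for
  quantized, narrow background modes (see segmentation section).
* The position-based counter can merge objects whose row and column
  projections both overlap; the taboo counter cannot separate objects
  closer than the patch footprint. Counts are reliable in the
  separation regime the tests quantify.
* The intra-plate cutoff (MAD rule + floor) and the synergy resampling
  scheme are this package's own constructions for steps whose original
  definitions are not public; both are flagged configurable.
* Mining uses Euclidean distance on standardized profiles; responses
  differing mainly by a time lag are not aligned (no warping), and
  alternative clusterers (agglomerative, GMM) are not provided.
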