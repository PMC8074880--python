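# Methods

This note records the models, numerical choices and open design decisions
behind `squamorph`, and what the synthetic-data tests do and do not show
about real fossil data.

## Temporal scaffolding

All binning runs against an ordered stage table (oldest first) with numeric
age bounds in Ma. The shipped default covers the 14 stages
Kimmeridgian–Maastrichtian with ages from the ICS 2020 chronostratigraphic
chart; the ages are configuration (a CSV or the packaged YAML can be
overridden), because downstream statistics depend only on stage *order* —
numeric ages matter solely for midpoint plotting positions, computed as
(base of first-appearance stage + top of last-appearance stage)/2.

Range-through sampling treats a genus as present in every stage between its
first and last appearance inclusive. Bin schemes group contiguous stages;
three are shipped: stage-level (the 14 stages), epoch-level
(Kimmeridgian–Tithonian = Late Jurassic; Berriasian–Albian = Early
Cretaceous; Cenomanian–Maastrichtian = Late Cretaceous), and the multi-stage
scheme used for size contrasts (Aptian–Albian, Cenomanian–Turonian,
Campanian). The size-test scheme deliberately does not cover every stage;
`assign_to_bins(..., partial=True)` skips uncovered presences for such
schemes, while covering schemes treat an uncovered stage as a configuration
error.

## Dental composition

The counting unit is the genus–morphotype pair: a heterodont genus
increments every morphotype it carries, and proportions are taken over total
occurrences in the bin, not genera. The eight-code morphotype vocabulary is
configuration, not code — the eighth category in particular is a
placeholder (`other-specialised`) that users may rename. Bray–Curtis
dissimilarity is computed on proportional compositions by default (making
the matrix invariant to per-bin sampling intensity) with an absolute-count
mode available; bins with zero occurrences are an explicit error, never a
silent zero or NaN. Marine-taxon exclusion is a filter applied before
counting.

## Jaw-size disparity

Analyses default to log₁₀(length in mm); a raw-mm flag exists because the
choice of scale for mean contrasts is genuinely open — log scale was chosen
for consistency with how the size series is plotted and because jaw lengths
span over two orders of magnitude (≈10 mm to ≈1700 mm). Within-bin
disparity is the univariate range (max − min) and the sample SD (n − 1
denominator; reported absent, not zero, for singleton bins).

The permutation test pools two bins, reshuffles membership at the original
group sizes, and recomputes the disparity difference; the default is 1000
iterations with the finite-sample estimator p = (1 + b)/(1 + N), two-sided
on |difference|. An exhaustive mode enumerates all C(n, n_A) splits and
returns the exact count-based proportion; it is the oracle regime for small
pooled n and the target the sampled p converges to. Welch (unequal-variance,
Welch–Satterthwaite df) and Student (pooled variance, df = n_A + n_B − 2)
*t*-tests cover mean contrasts.

## Shape morphospace

Landmark data are 33 ordered 2-D points (7 fixed landmarks, then 26
semilandmarks along the jaw outline), read and written in the TPS dialect
(LM=, ID=, IMAGE=, SCALE= records; SCALE applied multiplicatively).
Left-side configurations are mirrored by x-negation before superimposition
(coordinate convention: lateral view, anterior right, dorsal up).

GPA: translate centroids to the origin, scale to unit centroid size, rotate
each configuration onto the running consensus using the proper-rotation
Kabsch solution (reflections are never introduced), update the consensus,
and iterate until the consensus RMS change falls below 1e-10 or 100
iterations. Because GPA fixes shapes only up to one global rotation, the
aligned sample is put in a canonical frame afterwards (consensus principal
axis along x, the largest-|x| landmark positive, proper rotations only);
this makes the output invariant under arbitrary rigid motions and positive
scalings of the inputs, which is also how the alignment is tested.
Semilandmarks are treated as fixed points by default, since sliding is an
open methodological choice for these data; an optional mode slides them
along the local curve tangent towards the consensus for sensitivity
analysis. No tangent-space projection is applied before PCA; for the small
shape variances involved the curvature effect is negligible (see the PCA
rank-1 note below).

PCA is an SVD of the mean-centred flattened coordinates. All axes with
eigenvalue above 1e-12 are retained by default; each axis' sign is fixed so
its largest-magnitude loading is positive, making runs comparable. A purely
rank-1 family of aligned coordinates loads on PC1 exactly; shapes built by
deforming a template *before* size normalisation lie on a slightly curved
manifold, so through the full GPA path a single deformation mode yields
PC1 ≈ 99.999%, not 100% — both behaviours are tested.

## Disparity, resampling and NPMANOVA

Sum of variances uses all supplied morphospace axes (n − 1 denominator);
hull volume uses PC1–PC3 via Qhull. Degenerate hulls (< 4 points, coplanar
sets) raise an explicit error rather than returning 0, so tiny bins are
handled consciously; the n = 5 Late Jurassic bin is right at the edge and
bootstrap iterates that degenerate are dropped (with a failure-rate guard at
50%).

Bootstrap CIs are percentile intervals from 500 with-replacement resamples
at the original n — the percentile method was chosen because the CI method
behind "95% error bars" is otherwise unspecified and it is the dispRity
default practice. Rarefaction subsamples *without* replacement to the target
n (default: match the Early Cretaceous n = 13) and reports the mean of
iterates with a percentile CI; a with-replacement variant is available
behind a flag because the phrase "rarefaction … incorporating bootstrapping"
admits both readings.

NPMANOVA is the Anderson pseudo-F computed from Euclidean distances on all
retained PC axes (equivalent to distances on the Procrustes-aligned
coordinates): F = (SS_among/(a − 1))/(SS_within/(N − a)), with SS terms
derived from pairwise squared distances. Significance is by label
permutation, 999 by default, p = (1 + #{F ≥ F_obs})/(1 + n_perm); an
exhaustive two-group mode enumerates all label assignments. The
implementation is cross-checked in the tests against scikit-bio's
independent PERMANOVA.

The snake "morphotype" augmentation computes the coordinate-wise mean
aligned shape of the designated Late Cretaceous snakes, projects it through
the fitted morphospace (projection of a mean is the mean of projections, a
tested identity), and adds it as exactly one pseudo-member of each target
early bin.

## Synthetic data: what it emulates and what it does not

Generator defaults are the study conditions: 220 genera with dental
assignments across the 14 stages, 116 jaw-length records, and shape samples
of 5/13/74 for Late Jurassic / Early Cretaceous / Late Cretaceous (the
groups are disjoint here, so the total is 92 configurations; in real data a
taxon can span epochs). The composition regime switches at the Cenomanian:
early vector concentrated on conical teeth (0.75/0.15/0.10 over the first
three codes), late vector spread over all eight; heterodonty probability
0.15. Sizes are lognormal per habitat — terrestrial location 1.5 log₁₀ mm
(≈32 mm), SD 0.35; marine location 2.4 (≈250 mm, mosasauroid grade), SD
0.45, present only from the Cenomanian, 35% of post-onset records. These
values were chosen once as field-realistic magnitudes for the documented
patterns (conical-dominated early faunas; a marine radiation spanning
~100 mm–1.7 m jaws).

Shapes are a hand-authored 33-point template mandible (long low dentary,
raised coronoid process, posterior articular; shipped as data) plus three
smooth unit-norm deformation modes (elongation, coronoid height,
robusticity) with per-epoch offsets and spreads — Late Cretaceous spreads
are largest, encoding the late morphospace expansion — plus isotropic
landmark noise (SD 0.004 of unit jaw length), hidden behind random rigid
motions, scalings in [0.2, 5] and random side flips. Six Late Cretaceous
taxa are labelled snakes and displaced towards a morphospace extreme.

What passing tests show: the pipeline's statistics are correctly computed
(exact oracles), correctly calibrated under the null, and powerful enough to
recover injected effects of the stated size. What they do not show: anything
about preservation bias, taxonomic practice, correlated characters or
phylogenetic structure in real fossil data — the generator draws taxa
independently and has no phylogenetic signal by design.

Because marine taxa enter the synthetic size series throughout the Late
Cretaceous (not only in a Cenomanian burst) and range-through terrestrial
taxa dilute the Cenomanian–Turonian bin, the significance of the synthetic
Welch contrast between Aptian–Albian and Cenomanian–Turonian varies by seed;
the tests therefore assert the computational identities and the direction of
the injected effect, while the controlled power property (SD ratio 3,
n = 20 per bin, rejection rate > 0.8) is verified in a direct simulation.

## Problem sizes and determinism

Null-calibration simulations use 500 replicates with 199 internal
permutation iterations per replicate, so that p ≤ 0.05 has exact null
probability 10/200 = 0.05 under the (1 + b)/(1 + N) estimator; analysis
defaults remain 1000 permutation iterations, 500 bootstrap iterations and
999 NPMANOVA permutations. Power simulations use 200 replicates; the
hull-ordering recovery check uses 100 full pipeline replicates. All
resampling functions take an explicit seed, record it in their result
objects, and are bit-reproducible given (seed, iteration count). The CLI
writes a manifest (command, parameters, config hash) with every run.

## Known limitations

- 2-D landmarks only; no image processing or automatic landmarking.
- No phylogenetically corrected disparity or evolutionary-rate modelling.
- Semilandmark sliding implements only the simple tangent-projection
  criterion, as a sensitivity mode rather than a default.
- The exhaustive NPMANOVA mode supports two groups only.
- Occurrence data are local CSVs; no database querying.
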