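# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `taumap` pipeline in the order the method runs.

## Particle tables and units

Particle metadata is exchanged as RELION-style STAR files (read/written
with `gemmi`), accepting both the legacy single-block layout and the
RELION 3.1+ optics-table layout and always emitting the latter.  All
coordinates are converted to Angstroms at read time using the pixel size
from the optics table (or an explicit override); every downstream
computation is unit-uniform in Å.  The default pixel size for synthetic
data is 0.822 Å/px, the effective pixel size of a Gatan K3 detector at
the magnification used for this kind of data collection, and the default
micrograph field is the corresponding physical K3 extent,
5760 × 4092 px → 4734.7 × 3363.6 Å.  Euler angles are carried in degrees
and canonicalized (rot, psi ∈ (−180, 180], tilt ∈ [0, 180]) so every
orientation has a unique triplet; STAR X/Y coordinates are taken as-is
(pair distances are origin-invariant, so no axis flip is applied).

## Pair mapping

Within each micrograph the two particle populations are matched by
greedy global minimum-distance selection: all A–B cross pairs are sorted
by distance and swept, skipping particles already used — equivalent to
iteratively picking the closest remaining pair and removing both.
Distance ties are broken lexically by particle id so results are
deterministic.  Without a distance cutoff each micrograph yields
min(nA, nB) pairs.  The test suite checks the sorted-sweep
implementation against a literal iterative-argmin oracle on random
instances up to 8+8 particles.

Distance histograms default to 8 Å bins on [0, 600) Å (half-open,
left-closed); the mode is the center of the maximum-count bin, lower bin
on ties.  8 Å resolves a ~168 Å peak with thousands of pairs without
overbinning.

The null model redraws every particle's XY position uniformly over the
micrograph field, exactly preserving per-micrograph particle counts, and
reruns the same pairing; several replicates are accumulated.  The
enrichment report rescales the null to the observed total count and
calls a peak where the observed/null ratio exceeds a factor (default 2)
over at least 2 consecutive bins; empty-null bins with observed counts
get a +inf sentinel.

A note on identifiability: at realistic particle densities
(~20 pairs per K3 field) the probability that some *other* particle lies
closer than a particle's true 168 Å partner is of order 10%, so no
matching algorithm can recover the exact pairing for every particle.
This mislabeling leaves the distance and orientation *modes* — the
quantities the method reports — essentially unchanged, which is why the
tests assert exact ground-truth recovery only in a sparse regime
(2 pairs/micrograph) and assert mode recovery at study density.

## Relative orientations

The Euler convention is RELION's intrinsic ZYZ: R(α, β, γ) =
R<sub>z</sub>(γ) R<sub>y</sub>(β) R<sub>z</sub>(α) with (α, β, γ) =
(rot, tilt, psi).  The conversion is written out explicitly and
cross-checked in tests against `scipy.spatial.transform.Rotation`
(extrinsic `zyz` with the same angle order) and by round-trip to 1e−9.
At gimbal degeneracy (|sin β| < 1e−6) only α ± γ is defined; the
convention here is γ = 0 with α absorbing the full in-plane angle, and
such triplets are flagged degenerate (they still round-trip exactly as
rotations).

For each pair, R<sub>r</sub> = R<sub>B</sub> R<sub>A</sub><sup>−1</sup>
is converted back to a triplet Δαβγ.  Pairs are filtered to
inter-particle distance < 200 Å (the co-localized complexes) before
population analysis.  The joint mode is the maximum-count cell center of
a wrapped 3D histogram with 10° bins (Δα, Δγ circular over (−180, 180],
Δβ over [0, 180]); circular binning keeps modes near ±180° from
splitting.  A histogram mode was chosen over kernel density on SO(3)
because it is deterministic and matches scatter-plot-level analysis.
Per-angle circular standard deviations summarize the spread.

## Synthetic particle fields

Per micrograph, each planted pair places the τB particle uniformly in
the field, draws a uniform in-plane direction and a separation
~ N(168 Å, 10 Å), and puts τA at that offset (positions are redrawn
until both fall inside the field — a slight edge-effect deviation from
uniformity that is negligible at 168 Å versus a ~4000 Å field).  τB
orientations are uniform on SO(3) (normalized random quaternions); τA is
set to R<sub>r</sub><sup>−1</sup> R<sub>B</sub> for the planted
R<sub>r</sub> = (15°, 128°, −103°) and then perturbed by a rotation
about a uniform random axis with angle ~ N(0, 15°) — a simple isotropic
noise model; the 15° width is a modeling choice, not a measured value.
Unpaired background particles (default 10 per type per micrograph) have
uniform positions and orientations, and each planted particle is
observed with a configurable detection probability (default 1).

## Dwell and trace simulation

Dwell durations are drawn from a one- or two-component exponential
mixture.  With a camera frame time set (default 0.2 s, the 200 ms
exposure of the emulated instrument), durations are rounded *up* to
whole frames — so every observed dwell spans at least one frame, which
is exactly a left truncation at one frame plus discretization.  Setting
`frame_time=None` yields continuous durations, used when the estimand is
the continuous mixture itself.  Dwells exceeding an optional censor time
are cut there and flagged right-censored.  The generating component of
every dwell is recorded as ground truth.

Traces alternate unbound intervals (exponential waiting at the binding
rate) with bound dwells from the mixture; within a bound dwell the FRET
efficiency E switches between configured states as a Markov chain, each
segment's E drawn from the state's Gaussian.  A constant total intensity
is split as donor = (1−E), acceptor = E; unbound frames emit full donor
and zero acceptor; a single-step donor bleach at an exponential time
zeroes both channels; Gaussian read noise (default sd 0.02 of total) is
added throughout.  The simulator deliberately omits detector-physics
detail (shot noise, blinking, acceptor bleaching, baseline drift), so
passing recovery tests demonstrate correctness of the estimators under
the stated model, not robustness to every real-data pathology.

## Dwell extraction

Bound dwells are segmented from the acceptor channel before the bleach
frame: optional moving-average smoothing (default window 1), then a
threshold at the unbound baseline + 4 noise standard deviations.  The
noise sd is estimated from median absolute successive differences
(1.4826·MAD/√2), which is insensitive to the bound/unbound level
structure; the baseline is the mean of the lowest signal cluster (all
values within 5σ of the 1st percentile), which stays correct even for
traces that are bound most of the time, where a plain low-quantile
estimate would land inside the bound population.  Contiguous
above-threshold runs become dwells (run length × frame time); runs
touching the trace end or bleach frame are right-censored.  Traces
without a detectable single-step bleach of the total intensity can be
rejected (flagged) in batch extraction.  On synthetic traces with ground
truth, ≥95% of dwells of at least 3 frames are recovered within ±1
frame (measured 98% at the default settings).

## Exponential mixture fitting

Fitting is maximum likelihood on raw dwell durations (not binned
histograms): for one component the MLE is closed form — total observed
time divided by the number of uncensored dwells, which handles
right-censoring exactly.  With a left-truncation time t₀ set, durations
are shifted by t₀ first; by memorylessness this is the exact conditional
MLE, and reported mixture weights then refer to the observed
(post-truncation) population.  Note the truncation correction addresses
*unobservable short dwells*, not frame discretization: on
ceiling-quantized data it overcorrects by about half a frame, which is
immaterial for lifetimes ≫ one frame.

The two-component fit runs EM with censored dwells contributing survival
terms (E-step uses densities/survival functions; M-step imputes a
censored dwell's residual life as the current component mean).  The
observed-data log-likelihood is asserted non-decreasing every iteration.
Ten deterministic restarts initialize the two lifetimes from
progressively wider quantile pairs of the uncensored durations
(q ∈ [0.05, 0.45] and [0.55, 0.95], divided by ln 2) with equal weights;
convergence is relative log-likelihood change < 1e−10, max 2000
iterations; lifetimes are reported ascending.  Fits whose two lifetimes
collapse within 1e−3 relative separation are reported as effective
single exponentials.  Model selection is by BIC (1 parameter for k=1, 3
for k=2); the selection rule is a package choice since penalized
likelihood is reproducible.  Parameter uncertainty is by nonparametric
bootstrap (resampling dwells), a defined substitute for
repeat-experiment standard deviations that cannot be reproduced from a
single synthetic dataset; medians carry percentile-bootstrap intervals
(default 1000 resamples, seeded).

FRET efficiencies are computed per frame as
E = (A − bg_A − x·(D − bg_D)) / (γ·(D − bg_D) + A − bg_A − x·(D − bg_D))
with neutral defaults (bg = 0, crosstalk x = 0, γ = 1) reducing to
A/(A+D); zero-total frames yield NaN.  Efficiency distributions are
fitted with `sklearn.mixture.GaussianMixture` (seeded, 5 initializations),
components sorted by mean, values outside [0, 1] clipped with a warning.

## Promoter motif analysis

Gene-internal coordinates are 1-based with no position 0 (−1 abuts +1);
internal storage is 0-based with explicit converters.  The packaged
tRNA-His fixtures carry the printed 85-bp (−9..+76) and 120-bp (−44..+76)
non-template sequences with A-box +8..+18 (`TAGTATAGTGG`) and B-box
+51..+61 (`GGTTCGATTCT`); the registers were derived by string search
from the printed sequences and are re-asserted at load time.  The full
120-bp wild-type and mutated-A-box variants are reconstructed from the
printed −44..+20 fragments plus the shared +21..+76 tail.

Motif scanning is exact wildcard matching of `TNGNNNANNNG` (N = any
base) on the non-template strand — a strict-correspondence filter makes
p-value scoring redundant, though a log-odds score against the genomic
background (A/C/G/T = 0.325/0.176/0.175/0.324) is attached per match.
The expected background match rate per window is therefore
p(T)·p(G)·p(A)·p(G) ≈ 3.2e−3, verified empirically.  The upstream
pseudo-box filter keeps matches entirely upstream of the A-box whose gap
(nucleotides strictly between match end and A-box start) is < 30 nt;
the gap definition is configurable since match-start conventions also
appear in the literature, and the tRNA-His pseudo-A-box (gap 6 nt)
passes under either.  Reverse-strand scanning is off by default (all
reference motifs are given on the non-template strand) and available as
a both-strand flag at the scan level by scanning the complement
externally.  Linker length is the count of nucleotides strictly between
A-box end and B-box start (32 for tRNA-His); linker histograms flag
lengths outside the literature range 31–93 bp; GC content uses
Biopython's `gc_fraction`.

Synthetic gene sets instantiate the consensus (N positions drawn from
the background), sample linker lengths from a distribution sharply
peaked at 32 bp (P(31)=0.05, P(32)=0.45, geometric-like tail to 93 bp —
the real distribution's shape beyond "32 is by far the most common,
range 31–93" is not quantified, so this is a package choice), and plant
upstream pseudo-boxes with probability 0.05 at gaps of 0–18 nt so every
planted box survives the <30 nt filter.  Generated sequences are i.i.d.
in the background regions; real genomes are not, so empirical
false-positive rates on real data will deviate from the analytic rate.

## Problem sizes and determinism

Default study-condition sizes: 100 micrographs × 20 pairs (+10+10
background), 10⁴ dwells for mixture fits, 10⁵ for medians, 300–500 genes
for motif statistics.  These sizes give sub-minute runtimes while
keeping Monte-Carlo error well inside the asserted tolerances.  All
generators and estimators take explicit seeds; every reported number is
reproducible bit-for-bit given the seed.

## Known limitations

- Pair mapping is 2D (micrograph XY only); defocus-direction separation
  is invisible, exactly as in the emulated experiment.
- The orientation-population mode is a binned estimate; its resolution
  is the bin width (10°), and no symmetry handling is applied.
- The EM mixture fitter targets k ≤ 2; more components would need
  generalized initialization and identifiability checks.
- Trace idealization is threshold-based, not a hidden-Markov model;
  FRET states shorter than ~2 frames blur into neighbors.
- The gene generator does not model tRNA secondary structure or real
  isotype composition; GC-by-isotype summaries on synthetic data are
  placeholders for the real grouping.
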