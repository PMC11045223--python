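# Methods

This note documents the models, conventions and numerical choices behind
`eomsc`, and what the synthetic validation does and does not establish
about real data.

## Image quantification

All quantification runs on 2D maximum-intensity projections of the
``(z, channel, y, x)`` stacks; no 3D analysis is offered, matching the
projected-image workflow the pipeline reproduces. Coordinates are reported
as ``(y, x)`` in µm from the top-left pixel centre; pixel size is isotropic
in y and x (default 0.5 µm/px in the generators — confocal acquisition
settings are configurable, not inferred).

**Thresholding.** Default segmentation is Otsu per projected channel, with
fixed thresholds exposed for reproducibility (the original manual ImageJ
thresholds behind such analyses are typically unrecoverable). Plain Otsu
fails on channels whose foreground is a tiny pixel fraction: the optimal
split falls inside the background noise. `binarize` therefore re-applies
Otsu to the tentative foreground while the threshold lies in the lowest
quarter of the intensity range (at most 4 passes). The guard compares
``(threshold − min) / (max − min)``, so it is invariant to positive affine
intensity maps; it assumes the true foreground is brighter than roughly a
quarter of the dynamic range, which holds for immunofluorescence signal
over camera noise but would mis-segment genuinely low-contrast images —
use a fixed threshold there.

**NMJ scoring.** BTX patches are 8-connected components (the ImageJ
particle-analysis default) above a minimum area (default 20 µm², rejecting
speckle). Coverage = |SYP ∧ BTX| / |BTX| on binarized masks. Category
bounds follow the >60 % / 30–60 % / <30 % definition with the 30–60 % band
taken as the closed interval [0.30, 0.60], so both boundary values are
"partial". Only single en-plaque-like patches are modelled; en-grappe
clusters are out of scope. The NF channel is accepted but unused for
scoring.

**Peri-NMJ satellite cells.** Nuclei are DAPI components ≥ 5 µm²; a
nucleus is Pax7⁺ when more than a configurable fraction (default 0.5) of
its DAPI pixels exceed the Pax7 threshold — the DAPI mask filters
non-nuclear staining. A cell is counted for an NMJ when its nuclear
centroid lies strictly within 37.5 µm of the NMJ centroid (centroid rule,
not any-pixel overlap; whether boundary-intersecting nuclei were counted
in the original procedure is unstated, so the unambiguous rule was
chosen). Discs in the generator never overlap, so counts are unambiguous.

**Culture metrics.** Pax7/Ki67 positivity uses the same nuclear-fraction
rule; the fusion index tests the nuclear centroid against the binarized
MHC mask. Myotube instances are connected components of the MHC mask —
touching myotubes merge, an accepted limitation. "Contact" between a
myotube and the neurite mask means ≥ 1 shared pixel (zero-overlap myotubes
are excluded from the innervation denominator). A patch qualifies for the
innervation ratio when strictly larger than 10 µm² and assigned (by
maximal overlap) to a contacting myotube; it is innervated when it
overlaps the neurite mask by ≥ 1 pixel. Ratios are per image; the image is
the unit of analysis.

**Neurite lengths.** The neurite mask is skeletonized; skeleton pixels
form an 8-connected graph with edge weights of 1 or √2 pixel pitches. For
each connected neurite with pixels on both sides of the vertical
compartment boundary, the reported length is the longest Dijkstra distance
from a boundary-adjacent entry pixel to any tip, walked only through the
myotube side — lengths start at the boundary crossing, not inside the
microgrooves. Accuracy is ± one pixel pitch for straight paths and ± two
for cornered paths.

## Synthetic scenes

Scenes are rendered hard-edged: each structure is a binary occupancy mask
times a 200-intensity amplitude, placed on one random z-slice, with
optional Gaussian noise added to every voxel. Hard edges (rather than
blurred ones) keep the binarized geometry identical to the planted
geometry, which is what makes exact noise-free ground-truth recovery a
meaningful invariant; a `blur_sigma` parameter is available for robustness
experiments but defaults to 0. SYP coverage is planted as a contiguous
lowest-x sweep of the BTX patch's pixels — partial occupancy, not
salt-and-pepper — so the planted coverage is exact up to one-pixel
quantization. Placement uses rejection sampling (cap 1000 tries): NMJ
centroids ≥ 75 µm apart (disjoint discs), nuclei separated enough that
DAPI components never merge. Distractor nuclei alternate Pax7⁻ anywhere
and Pax7⁺ strictly outside every disc. All randomness flows from the
spec's single seed; the noise stream is drawn from an offset of the same
seed so geometry is unchanged by turning noise on.

What the scenes do **not** emulate: realistic PSFs, uneven illumination,
autofluorescence, overlapping nuclei, en-grappe NMJ morphology, or
myotube branching. Passing the recovery tests therefore shows the
measurement logic is correct, not that segmentation is robust to every
real-microscopy artifact.

## Count simulation

Counts are NB(mean = library-scaled baseline × 2^(effect × indicator),
Var = μ + αμ²); α = 0 degenerates to Poisson. Baselines are log-normal
(log2 mean 5, sd 1.5 — a realistic bulk RNA-seq abundance spread);
expected library size 2 × 10⁶ by default, chosen so per-gene means are in
the hundreds as in downsampled bulk data. Planted signature roles map to
design indicators (activation ↔ growth medium, differentiation ↔
differentiation medium, eom_up/quiescence ↔ EOM origin, nabu_up ↔ NaBu
treatment); planted |log2FC| must be ≥ 0.4 so planted genes are
recoverable at the downstream calling threshold, and planted sets must be
disjoint. Library scaling introduces a small composition shift when many
genes are planted in one direction; the median-of-ratios normalization in
the group test absorbs it as long as most genes are null.

## Differential expression

The sample-level test is the Audic–Claverie posterior-predictive test —
the canonical Poisson-based two-library comparison. Given x reads in
library A, the count in library B follows a negative binomial with size
x+1 and success probability N_A/(N_A+N_B); two-sided p doubles the smaller
tail (observation included in both tails), capped at 1. The test
conditions on the first library's count, so swapping the two counts is
only asymptotically symmetric; the implementation is exact against
term-by-term enumeration of the tail sums.

The group-level test is a deliberately transparent NB Wald test:
median-of-ratios size factors; pooled method-of-moments dispersion per
gene (within-group ``(s² − μ·mean(1/s_f))/μ²`` averaged over the two
groups, clipped at 0 and floored at 10⁻⁸); log2FC =
log2((μ_A + 0.5)/(μ_B + 0.5)) with the 0.5 pseudo-mean bounding fold
changes of zero-count groups and keeping the statistic antisymmetric under
contrast reversal; delta-method standard error of the log-mean difference.
The Wald statistic is referred to a t distribution with n_A + n_B − 2
degrees of freedom: at the few-replicate group sizes this test targets,
the normal limit is anticonservative, and the t reference puts the
empirical type-I error at the nominal level in the null simulations the
acceptance script reruns. No dispersion shrinkage and no independent
filtering are applied, so DEG counts from shrinkage-based tools are
reproduced only approximately — published intersection counts derived
from such tools are treated as method-sensitive references, not targets.
Multiple testing is Benjamini–Hochberg throughout (the named "FDR" and
"Qvalue" thresholds: 0.001 sample-level, 0.05 group-level).

## Signatures

Gene symbols match case-insensitively (mouse symbol case variants are
common), preserving first-seen casing. Shared-DEG analysis intersects by
gene identity first and classifies direction second: a gene must pass the
thresholds in every list to enter the intersection, and is "up-in-focal"
or "down-in-focal" only when its sign is consistent across all lists;
mixed-sign genes stay in the intersection unclassified. Whether the
original two-step counts enforced direction at the intersection stage is
unstated; this convention reproduces the identity-then-direction
narrative. The quiescence extension is the fixed 18-marker list; the
published 507-gene quiescence list is user-supplied and never bundled
(third-party data). Subgroup tags (SC markers, Notch, pluripotency) are
the fixed lists given with the original profile figure.

## qPCR

Technical replicates are averaged on the Ct scale before dCt (standard
real-time-PCR practice; replicate handling is otherwise unstated).
Amplification efficiency is fixed at 2 (perfect doubling), which the ΔΔCt
formulation presumes. ΔΔCt is normalized to the mean dCt of the reference
group, so the geometric mean of reference-group RQs is exactly 1.

## Statistics

Group comparisons use Welch (unequal-variance) t-tests — the pooled/Welch
choice is unstated in the workflows this mirrors, and Welch is the safer
default — with no post-hoc multiple-comparison correction on bracketed
pairwise tests. One-way ANOVA is classical. The transcriptome overview
takes log2(TPM+1), keeps the 2000 highest-variance genes by default, and
runs full-SVD PCA plus average-linkage hierarchical clustering on
correlation distance, all deterministic.

## Problem sizes

The test suite and acceptance script use 25–50 scenes of 512×512 px with
3 NMJs each, 10⁴-gene null matrices at 6 vs 6 samples, 2000-gene planted
matrices over 10–20 seeds, and 400–600-gene signature simulations — sizes
at which every recovery and calibration property is measured stably while
the whole validation completes in well under a minute per arm.

## Known limitations

- Segmentation robustness is validated only against the idealized scene
  model; real whole-mount stacks need threshold tuning.
- Touching myotubes and overlapping nuclei merge into single instances.
- The group DEG test trades the efficiency of shrinkage estimators for
  transparency; at very small counts its moment dispersion is noisy.
- The Poisson library test is asymmetric in its two libraries by
  construction (it conditions on the first count).
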