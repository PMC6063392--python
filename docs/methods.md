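# Methods

## Scope and model

`atlassel` implements image-based atlas pre-selection for multi-atlas
brain segmentation and a desk-scale harness to measure what each
selection criterion buys. The full production problem involves deformable
registration (atlas → target) and statistical label fusion; here all
volumes live on one shared voxel grid and label propagation is replaced
by a simple stochastic model of residual registration error (below). The
pre-selection contribution — the ranking criteria and the evaluation
design — is agnostic to the fusion back-end, which is why a voting
back-end suffices for studying it.

## Similarity criteria

* **Dice** of two label regions: `2|A∩B| / (|A|+|B|)`. Empty-vs-empty
  is defined as 1.0 (both raters agree the structure is absent) and
  logged; empty-vs-nonempty is 0.0. This convention is configurable at
  the evaluation layer, where absent-in-truth structures are excluded
  from means instead.
* **4L**: the unweighted arithmetic mean of the four per-tissue Dice
  values (CSF space, gray matter, white matter, ventricles) between two
  coarse maps. The combination rule for the four Dices is a genuine
  design freedom; the unweighted mean treats tissues equally regardless
  of size, which preserves the ventricle signal that motivates the
  criterion. A union-mask mode (one Dice over the union of the four
  labels) is provided for comparison.
* **LV**: Dice of the ventricle label alone.
* **NMI**: `(H(A)+H(B)) / H(A,B)` over equal-width intensity
  histograms, range [1, 2] (2 = identical, 1 = independent). Marginal
  and joint histograms share the same per-volume bin edges so the
  self-similarity identity `NMI(A,A) = 2` holds exactly. Entropies are
  in bits; the ratio is base-invariant. The histogram bin count matters
  and is exposed: default `n_bins = 64`, standard practice in
  intensity-based registration. By default NMI uses the whole grid
  (whole-head information, including extracranial tissue); a
  mask-restricted variant is available via the `mask` parameter.

Ranking sorts by descending score with ties broken by ascending atlas
id, so results are independent of library order. When the target is
itself a library member it is excluded first (leave-one-out). Subset
sizes default to {5, 10, 15, 20, 25}; sizes exceeding the pool saturate
with a warning.

## Atlas-free coarse segmentation

Pre-selection needs the target's coarse tissue map before any atlas is
registered. The estimator: (1) head/air threshold — the lowest cut of a
4-class multi-Otsu (a plain 2-class Otsu can land between CSF and GM
when air dominates the histogram; the multi-class variant is used
whenever the histogram supports it, with binary Otsu as fallback);
(2) largest 6-connected above-threshold component, morphologically
closed, as the brain mask; (3) seeded k-means (k = 3) on in-mask
intensities, classes assigned CSF < GM < WM by ascending cluster mean
(T1-like contrast; a `contrast="t2"` flag reverses the order);
(4) CSF-class connected components that do not touch the mask boundary
are ventricles, the rest is surrounding CSF. Voxels get exactly one hard
label; partial-volume modelling is out of scope. Skull-base and skin
labels are never emitted by this estimator — when a pipeline already has
a full coarse map (the recommended path), it should be passed to the
ranking step directly.

## Phantoms: what they emulate and what they do not

A phantom is a nested-shell head: WM core, cortical GM rind, lateral +
third ventricle ellipsoids inside the WM, hippocampal ellipsoids
infero-laterally, a CSF shell, a dark skull gap, a skin shell, and a
skull-base blob of brain-like intensity. Intensities are per-tissue
class means (air 5, CSF 35, GM 90, WM 140, skull base 70, skin 120;
arbitrary units with T1-like ordering) times a separable quadratic bias
field `1 + a·q(x,y,z)`, `q` normalized to [−1, 1] (default amplitude
a = 0.05, a typical mild coil inhomogeneity), plus Gaussian noise
(default sd 2.5, i.e. 5 % of the GM–WM gap — a good-quality MPRAGE
regime). Default grid: 48×56×48 voxels at 2 mm isotropic, sized so a
library generates in under a second and a full sweep in tens of seconds.

A library varies anatomy along one controlled, *selectable* axis —
ventricle scale, evenly spaced over [0.7, 1.3] (not sampled, so
selection-recovery experiments have a unique known answer), emulating
ventricular enlargement with age/atrophy — plus idiosyncratic, *not
selectable* variation: cortical thickness jitter (uniform ±1 mm) and
per-structure center jitter for ventricles and hippocampi (Gaussian,
sd 1 mm per axis, clipped at 2 sd to preserve the interiority
invariant). The idiosyncratic component is essential: it is what makes a
target imperfectly representable by any one atlas and gives fusion
something to average.

Phantoms do not emulate cortical folding, lesions, partial-volume
voxels, multi-site intensity differences, or skull-stripping failure
modes. Passing tests therefore demonstrate the correctness and the
relative behaviour of the selection machinery under controlled anatomy,
not absolute accuracy on clinical data.

The fine inventory is a ~12-structure proxy of a full parcellation. The
packaged hierarchy table maps it into the packaged Level A/B/C ROI lists
(4 + 26 + 33 = 63 names), so the level-wise evaluation paths run exactly
as they would with a full ontology; structures absent from the phantom
(e.g. amygdala) exercise the absent-in-truth exclusion path. Users with
real parcellations supply their own TSV. One ROI spelling
(`Hippocampu_R`) circulating in published tables is normalized to
`Hippocampus_R` on load, with a note; both spellings are accepted.

## Fusion and the residual-registration model

`fuse_labels` is a voxelwise plurality vote — unit votes (majority) or
per-atlas weights (by default the selection scores, a cheap analogue of
likelihood-weighted fusion). Ties go to the lowest label id, making the
result independent of atlas order.

The sweep harness (`run_sweep`) models residual registration error:
each atlas's label map is translated by a seeded random integer-voxel
shift (Gaussian, sd 2 mm per axis — a typical residual after good
deformable registration — rounded and clipped at 2 voxels), drawn once
per (target, atlas) pair. These independent errors are the mechanism by
which fusing more atlases improves accuracy; with perfectly aligned
identical-grid phantoms (set `propagation_jitter_mm=0`) voting has no
noise to cancel and subset growth only pulls the consensus toward the
library mean.

This is also the package's main known limitation, measured and worth
stating plainly: shift noise does not shrink the *anatomical* mismatch
of dissimilar atlases the way true deformable registration does. In
sweeps on 20-phantom libraries the mean Level-C Dice for the score-based
criteria peaks at small-to-moderate subset sizes and declines by ~0.01
as the subset approaches the whole library, while the random baseline
rises monotonically. The superiority ordering (4L/LV above MI and
random, largest at small k) is robust; the monotone-growth-in-k trend
is only fully reproduced for the random baseline.

## Evaluation design

Per structure, Dice after aggregating both segmentation and truth to a
level; structures empty in truth are excluded from means (scoring them 0
would conflate "not annotated" with "missed"). Summaries per (method,
k, level); poor-outcome ratio = fraction of structure Dice values
< 0.7 per (method, k) — tail-sensitive where means are not; paired t
tests (two-sided) between methods on per-target mean Dice, with
zero-variance differences flagged rather than propagated as NaN.

Experiments in the test suite and the acceptance script use 20-phantom
libraries with 5 centrally located leave-one-out targets (indices
5–13), so the library brackets each target's anatomy on both sides, and
average over 5 library seeds where a stochastic claim is made. These
sizes keep a full run in the low minutes on one CPU while leaving the
Monte-Carlo error of the reported means well below the effect sizes of
interest.

## Numerical and degenerate-input choices

* Grid compatibility is exact (shape, spacing, origin to 1e-6); mixed
  grids are a hard error, never resampled silently.
* Label values within 1e-6 of an integer are rounded on read; anything
  else is an error, as are non-finite intensities.
* Constant volumes: entropy of a constant region is 0; NMI of a
  constant volume is undefined (degenerate joint histogram) and raises.
* k-means is seeded and restarts (`n_init=10`); with the phantom's
  well-separated class means the partition is exact in the noiseless
  limit.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`-derived child generators, so every
  library, sweep, and CLI run is bit-reproducible from its metadata.
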