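# Methods

## Model

An 8-bit image is modeled as two populations of gray values (background
and foreground) whose histogram is bimodal. For a candidate threshold
*t* the histogram splits into a lower mode (levels ≤ *t*) and an upper
mode (levels > *t*). The cross-entropy objective

n(t) = − Σ_{i≤t} i·h(i)·log μ₁(t) − Σ_{i>t} i·h(i)·log μ₂(t)

measures how well the two mode summaries μ₁, μ₂ reconstruct the image;
the optimal threshold minimizes it. The natural logarithm is used:
any base rescales n(t) by a positive constant and cannot move the
argmin.

All mean and objective computation happens on a shifted level scale
i = g + 1 ∈ [1, 256] (g the stored gray value). This makes log μ,
geometric/harmonic means, and negative-order power means well defined
without epsilon guards; thresholds are reported back on the 0–255
scale, and a pixel is foreground when its gray value strictly exceeds
the reported threshold (invertible by flag, since clinical foregrounds
may be darker than their background).

## Mean estimators

Each mode is treated as the sorted multiset of its pixels. Estimators
are evaluated by histogram weighting — level i enters with multiplicity
h(i) — which is identical to expanding the pixel list but costs O(L).
The independent expanded-list evaluation exists only in the test suite,
as the oracle.

Parameters: contra-harmonic order Q (real; Q = 0 reduces to the
classical mean, Q = −1 to the harmonic mean; positive Q discounts low
outliers, negative Q high outliers) and the alpha-trim per-tail count
d/2 (integer pixels). Trimming is symmetric; when a mode holds fewer
than d + 1 pixels the untrimmed classical mean is used instead, so a
full 255-candidate scan never aborts near the histogram tails (the
alternative — marking the candidate invalid — would silently remove
most of the scan range for d/2 = 55 on small modes).

A mode slice is trimmed to its occupied span before evaluation. This
leaves the pixel multiset unchanged but makes every estimate
independent of how far the slice extends into empty bins; consequently
n(t) is *bitwise* constant as t crosses a zero-count gap, and the
plateau tie-break below behaves reproducibly.

## Threshold search

The scan is exhaustive over all splits that leave both modes
non-empty. Candidates where a mean is undefined (empty mode after an
estimator's precondition fails) or non-positive receive a +∞ sentinel
rather than aborting. At flat minima the smallest t is returned: on
well-separated modes the objective is exactly constant across the
empty inter-mode gap (every gap threshold yields identical partial
sums and means), so the reported t\* is the *left edge* of the gap,
not its center. This is deterministic and mask-equivalent to any other
plateau point on the data that produced the plateau, but callers
comparing t\* against a mixture midpoint should expect the left-edge
bias of roughly the upper tail extent of the lower mode.

The per-candidate recomputation is O(L) per split, O(L²) per
configuration — about a millisecond per configuration, so no
incremental prefix-sum optimization is needed. Sweeping many
configurations is embarrassingly parallel; `sweep(..., workers=n)`
uses threads and guarantees order-independent, worker-count-invariant
results.

## Configuration tables

The 32 heterogeneous pairs and 21 homogeneous baselines are fixed
enumerations (ids 1–32 and 0–20; id 0 is classical/classical, the
original MCET). The heterogeneity rule: the two approaches differ,
except contra-harmonic on both sides with sign-opposed orders
(positive for the lower mode, where pepper lives; negative for the
upper mode, where salt lives). Arbitrary Q and d/2 remain available
through the single-configuration API and the CLI's `--mu1/--mu2`.

## Evaluation

Unsupervised scores, all in [0, 1]:

- **Image uniformity**: 1 − (σ₁² + σ₂²)/Z, Z = (Imax − Imin)²/2 over
  the whole image; population variances of the two threshold regions.
  A constant image (Z = 0) scores 1. Clipped to [0, 1].
- **Region contrast**: |μ₁ − μ₂| / (μ₁ + μ₂). The means here are the
  *arithmetic* means of the two threshold regions of the image (on the
  shifted scale), not the filtered means that produced the threshold:
  an evaluation measure must be a function of the segmentation, so two
  configurations landing on the same threshold receive the same score.
  Passing the filtered means instead lets extreme estimators (e.g.
  contra-harmonic Q = −3, whose lower-mode mean collapses toward 1
  under pepper) inflate the score without changing the mask.
- **Inter-region disparity**: per mask region, interior contrast CI =
  mean over region pixels of the maximum normalized contrast
  |I(s) − I(t)|/255 to 8-neighbors inside the region (pixels with no
  in-region neighbor contribute 0), exterior contrast CE = the same
  maximum over neighbors *outside* the region, averaged over border
  pixels (region pixels with ≥ 1 in-image neighbor outside). Region
  score: 1 − CI/CE if 0 < CI < CE; CE if CI = 0; else 0. The two
  region scores are combined by area weighting. The 8-connected 3×3
  window and the area weighting are this package's choices; border
  status ignores the canvas edge.

Supervised scores (given a ground-truth mask): Jaccard TP/(TP+FP+FN),
F-score 2PR/(P+R) (with both-empty → 1, no-TP-with-error → 0), and
accuracy (TP+TN)/total. Absent ground truth, the average covers the
three unsupervised scores only.

Best-threshold selection scores every configuration's result and takes
the maximal unweighted average; ties break on smallest configuration
id, then smallest threshold. A result whose metrics violate a
precondition (e.g. a threshold leaving one region empty, which the
scan itself never produces) is logged and scored 0 rather than
aborting the sweep.

## Synthetic phantoms

`PhantomSpec` defaults: 96×96 canvas, centered foreground disk sized
to half the area (equal class priors), μ_bg = 60, μ_fg = 190,
σ = 10, no impulse noise, seed 0. Gaussian noise is applied first
(rounded, clipped to [0, 255]); salt and pepper then overwrite
disjoint uniformly-chosen pixel sets of exactly round(density·N)
pixels each, so the histogram's tail masses are exact. Placement is
uniform over the whole canvas — both regions are contaminated, which
is the regime heterogeneous estimation targets.

What the phantom does *not* emulate: spatially correlated noise,
intensity inhomogeneity (MRI bias fields), fuzzy boundaries,
illumination gradients, hair and ruler artifacts of dermoscopy.
Passing tests on phantoms therefore demonstrate correctness of the
estimators, the scan and the metrics under the stated noise model —
not clinical segmentation accuracy.

Two phantom-scale observations matter when reading the test results:

- With modes 13σ apart, the inter-mode gap is empty at n ≈ 10⁴ pixels
  and *any* threshold in it reproduces the mask exactly (Jaccard 1);
  the reported threshold sits at the gap's left edge per the
  tie-break, about 25 levels below the mixture midpoint (the
  continuous-model interior optimum (μ₂−μ₁)/ln(μ₂/μ₁) ≈ 114 is never
  isolated because the finite-sample gap carries no mass).
- For the same reason, under impulse noise every estimator family's
  best configuration typically lands in the same gap and the family
  comparison degenerates to equality: the average score is capped by
  the impulse pixels themselves, which no threshold classifies
  correctly. Family orderings become strict only when the modes
  overlap enough for estimator choice to move the argmin off the
  plateau.

## Numerical choices

- float64 throughout; geometric means in log space.
- Alpha-trim tail sums via cumulative counts (no pixel expansion).
- +∞ sentinel for invalid candidates; the scan fails only if *no*
  candidate is valid or the histogram has a single occupied level.
- Smallest-t tie-break at exactly equal objective values; the
  occupied-span trimming above is what makes plateau values exactly
  equal rather than equal-up-to-summation-order.

## Limitations

- Single threshold (bilevel) only; no multi-level extension.
- Histogram-domain only: the estimators are not spatial filters, and
  no denoising of the image itself is performed.
- The evaluation suite's disparity measure is O(pixels) per
  configuration and dominates sweep cost on large images.
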