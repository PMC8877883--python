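"""Segmentation quality measures and best-threshold selection.

Three unsupervised measures score a binarization against the gray image
itself (no annotation needed):

* image uniformity — 1 minus the summed within-region variances,
  normalized by Z = (Imax - Imin)^2 / 2 over the whole image;
* region contrast — |mu1 - mu2| / (mu1 + mu2), the normalized
  separation of the two mode means;
* inter-region disparity — compares interior contrast (local gradients
  inside a region) against exterior contrast (gradients across the
  region border), per region, combined by area weighting.

Three supervised measures compare the predicted mask with a ground
truth: Jaccard index, F-score (Dice) and pixel accuracy. All six lie
in [0, 1], higher is better. The best threshold across a sweep of
configurations is the one maximizing the unweighted mean of the
available scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import MetricError
from .histogram_io import BinaryMask, GrayImage, apply_threshold
from .mcet import ThresholdResult

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "image_uniformity",
    "region_contrast",
    "inter_region_disparity",
    "confusion",
    "jaccard",
    "fscore",
    "accuracy",
    "average_score",
    "evaluate_result",
    "select_best_threshold",
]

logger = logging.getLogger(__name__)

# Offsets of the 8-connected neighborhood W(s).
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion table of a predicted vs ground-truth mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvaluationReport:
    """Scores for one thresholding result.

    Supervised fields are None when no ground truth was supplied;
    ``average`` is the unweighted mean of the present scores. The
    uniformity diagnostics (region variances, normalizer Z, intensity
    extrema) are retained for inspection.
    """

    config_id: int
    family: str
    t_star: int
    iu: float
    rc: float
    disparity: float
    jaccard: Optional[float]
    fscore: Optional[float]
    accuracy: Optional[float]
    average: float
    sigma1_sq: float = float("nan")
    sigma2_sq: float = float("nan")
    z: float = float("nan")
    i_max: int = 0
    i_min: int = 0
    error: Optional[str] = None


def image_uniformity(img: GrayImage, t: int) -> float:
    """Levine-Nazif style uniformity of the two threshold regions.

    Returns 1 - (var(region<=t) + var(region>t)) / Z with
    Z = (Imax - Imin)^2 / 2 over the whole image, clipped to [0, 1].
    A constant image (Z = 0) is perfectly uniform by convention.
    """
    px = img.pixels.astype(np.float64)
    i_max, i_min = float(px.max()), float(px.min())
    z = (i_max - i_min) ** 2 / 2.0
    if z == 0.0:
        return 1.0
    low = px[img.pixels <= t]
    high = px[img.pixels > t]
    if low.size == 0 or high.size == 0:
        raise MetricError(f"threshold {t} leaves an empty region")
    score = 1.0 - (float(low.var()) + float(high.var())) / z
    return float(np.clip(score, 0.0, 1.0))


def region_contrast(mu1: float, mu2: float) -> float:
    """Normalized separation |mu1 - mu2| / (mu1 + mu2) of the two mode
    means; 0 when the means coincide (or are both zero), 1 when one
    region's mean vanishes."""
    if mu1 < 0 or mu2 < 0:
        raise MetricError("region means must be non-negative")
    if mu1 + mu2 == 0:
        return 0.0
    return float(np.clip(abs(mu1 - mu2) / (mu1 + mu2), 0.0, 1.0))


def _uniformity_parts(img: GrayImage, t: int) -> Tuple[float, float, float, int, int]:
    """(sigma1^2, sigma2^2, Z, Imax, Imin) backing image_uniformity."""
    px = img.pixels.astype(np.float64)
    i_max, i_min = int(img.pixels.max()), int(img.pixels.min())
    z = (i_max - i_min) ** 2 / 2.0
    low = px[img.pixels <= t]
    high = px[img.pixels > t]
    s1 = float(low.var()) if low.size else 0.0
    s2 = float(high.var()) if high.size else 0.0
    return s1, s2, z, i_max, i_min


def _shifted_pairs(arr: np.ndarray):
    """Yield (valid, neighbor_view, center_view) for each of the 8
    neighbor offsets; views are the overlapping in-bounds windows."""
    h, w = arr.shape
    for dy, dx in _NEIGHBOR_OFFSETS:
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ysn = slice(max(-dy, 0), h + min(-dy, 0))
        xsn = slice(max(-dx, 0), w + min(-dx, 0))
        yield (ys, xs), (ysn, xsn)


def inter_region_disparity(img: GrayImage, mask: BinaryMask) -> float:
    """Interior/exterior contrast disparity of the two mask regions.

    For region R with area A and border F (pixels of R with at least
    one 8-neighbor outside R):

    * interior contrast CI = (1/A) * sum over region pixels of the
      maximum contrast c(s, t) = |I(s) - I(t)| / 255 to 8-neighbors
      inside R (pixels with no in-region neighbor contribute 0);
    * exterior contrast CE = (1/|F|) * sum over border pixels of the
      maximum contrast to 8-neighbors outside R.

    Per-region score: 1 - CI/CE when 0 < CI < CE; CE when CI = 0;
    0 otherwise. The result is the area-weighted mean over both
    regions, in [0, 1] (1 = crisp boundary, flat interiors).
    """
    if img.pixels.shape != mask.labels.shape:
        raise MetricError("image and mask shapes differ")
    labels = mask.labels
    if labels.min() == labels.max():
        raise MetricError("mask has a single region; disparity undefined")

    px = img.pixels.astype(np.float64)
    h, w = px.shape
    scores, areas = [], []
    for region_value in (0, 1):
        in_region = labels == region_value
        area = int(in_region.sum())

        max_in = np.zeros((h, w))
        max_out = np.zeros((h, w))
        has_out = np.zeros((h, w), dtype=bool)
        for (ys, xs), (ysn, xsn) in _shifted_pairs(px):
            contrast = np.abs(px[ys, xs] - px[ysn, xsn]) / 255.0
            nbr_in = in_region[ysn, xsn]
            view_in = max_in[ys, xs]  # slice views: in-place max accumulates
            np.maximum(view_in, np.where(nbr_in, contrast, 0.0), out=view_in)
            view_out = max_out[ys, xs]
            np.maximum(view_out, np.where(nbr_in, 0.0, contrast), out=view_out)
            has_out[ys, xs] |= ~nbr_in

        border = in_region & has_out
        n_border = int(border.sum())
        if n_border == 0:
            raise MetricError("region has no border pixels")
        ci = float(max_in[in_region].sum()) / area
        ce = float(max_out[border].sum()) / n_border
        if ci == 0.0:
            score = ce
        elif ci < ce:
            score = 1.0 - ci / ce
        else:
            score = 0.0
        scores.append(score)
        areas.append(area)

    total = float(sum(areas))
    combined = sum(s * a for s, a in zip(scores, areas)) / total
    return float(np.clip(combined, 0.0, 1.0))


def confusion(pred: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between predicted and ground-truth masks."""
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("mask shapes differ")
    p = pred.labels.astype(bool)
    g = gt.labels.astype(bool)
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()),
        tn=int((~p & ~g).sum()),
    )


def jaccard(c: ConfusionCounts) -> float:
    """Intersection-over-union TP / (TP + FP + FN); 1 when both masks
    are empty."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def fscore(c: ConfusionCounts) -> float:
    """Dice / F1 score 2PR / (P + R); 1 when both masks are empty, 0
    when there are no true positives but some disagreement."""
    if c.tp == 0:
        return 1.0 if c.fp + c.fn == 0 else 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 2.0 * precision * recall / (precision + recall)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of pixels labeled identically in both masks."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.total


def average_score(scores: Sequence[Optional[float]]) -> float:
    """Unweighted mean of the scores that are present (not None)."""
    present = [s for s in scores if s is not None]
    if not present:
        raise ValueError("no scores present")
    return float(sum(present)) / len(present)


def evaluate_result(
    img: GrayImage,
    result: ThresholdResult,
    gt: Optional[BinaryMask] = None,
    *,
    invert: bool = False,
) -> EvaluationReport:
    """Score one thresholding result against the image (and optional
    ground truth). Metric precondition failures are logged and yield a
    zero-average report rather than aborting a sweep."""
    cid = result.config.config_id
    family = result.config.family
    try:
        mask = apply_threshold(img, result.t_star, invert=invert)
        iu = image_uniformity(img, result.t_star)
        s1, s2, z, i_max, i_min = _uniformity_parts(img, result.t_star)
        # Region contrast scores the segmentation itself, so it uses the
        # plain arithmetic means of the two threshold regions (shifted
        # scale, consistent with the threshold search), not the filtered
        # means that produced t*: two configs landing on the same t*
        # must receive the same score.
        px = img.pixels.astype(np.float64)
        mu1_img = float(px[img.pixels <= result.t_star].mean()) + 1.0
        mu2_img = float(px[img.pixels > result.t_star].mean()) + 1.0
        rc = region_contrast(mu1_img, mu2_img)
        disp = inter_region_disparity(img, mask)
        jac = fsc = acc = None
        if gt is not None:
            counts = confusion(mask, gt)
            jac, fsc, acc = jaccard(counts), fscore(counts), accuracy(counts)
        avg = average_score([iu, rc, disp, jac, fsc, acc])
        return EvaluationReport(
            config_id=cid, family=family, t_star=result.t_star,
            iu=iu, rc=rc, disparity=disp,
            jaccard=jac, fscore=fsc, accuracy=acc, average=avg,
            sigma1_sq=s1, sigma2_sq=s2, z=z, i_max=i_max, i_min=i_min,
        )
    except MetricError as exc:
        logger.warning("config %s (t*=%d) could not be scored: %s", cid, result.t_star, exc)
        return EvaluationReport(
            config_id=cid, family=family, t_star=result.t_star,
            iu=0.0, rc=0.0, disparity=0.0,
            jaccard=None, fscore=None, accuracy=None, average=0.0,
            error=str(exc),
        )


def select_best_threshold(
    img: GrayImage,
    results: Sequence[ThresholdResult],
    gt: Optional[BinaryMask] = None,
    *,
    invert: bool = False,
) -> Tuple[ThresholdResult, List[EvaluationReport]]:
    """Score every result and return the one maximizing the average.

    Ties break on smallest config_id, then smallest t*. Returns the
    winning result and the full per-result report list (in input
    order)."""
    if not results:
        raise ValueError("results must be non-empty")
    reports = [evaluate_result(img, r, gt, invert=invert) for r in results]
    order = sorted(
        range(len(results)),
        key=lambda k: (-reports[k].average, reports[k].config_id, reports[k].t_star),
    )
    return results[order[0]], reports
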