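"""Order-statistic mean estimators over histogram modes.

A candidate threshold splits the histogram into two modes: the lower
mode (levels ``[1..t]`` on the shifted internal scale) and the upper
mode (``[t+1..256]``). Each mode is treated as the sorted multiset of
its pixels, and one of five mean estimators summarizes it:

* classical (arithmetic) mean — the original MCET choice;
* geometric mean — smoothing comparable to the arithmetic mean;
* harmonic mean — suppresses salt (high) outliers, not pepper;
* contra-harmonic mean of order Q — positive Q suppresses pepper
  (low) outliers, negative Q suppresses salt;
* alpha-trimmed mean — drops the d/2 smallest and d/2 largest pixels
  before averaging, robust to mixed impulse noise.

Every estimator is computed by histogram weighting (level ``i`` occurs
``counts[i]`` times), which is mathematically identical to expanding
the mode into a per-pixel vector but costs O(L) instead of O(n_pixels).
The expanded-list brute force serves as the test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UndefinedMeanError
from .histogram_io import Histogram, N_LEVELS

__all__ = [
    "ModeRegion",
    "EstimatorSpec",
    "classical_mean",
    "geometric_mean",
    "harmonic_mean",
    "contraharmonic_mean",
    "alphatrim_mean",
]


@dataclass(frozen=True)
class ModeRegion:
    """A contiguous histogram slice viewed as a sorted pixel multiset.

    ``lo`` and ``hi`` are inclusive bounds on the internal shifted scale
    (``i = gray + 1``, so 1 <= lo <= hi <= 256); ``counts[k]`` is the
    pixel count at level ``lo + k``.
    """

    lo: int
    hi: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= self.lo <= self.hi <= N_LEVELS:
            raise ValueError(f"invalid mode bounds [{self.lo}, {self.hi}]")
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (self.hi - self.lo + 1,):
            raise ValueError("counts length must equal hi - lo + 1")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_histogram(cls, hist: Histogram, lo: int, hi: int) -> "ModeRegion":
        """Slice ``hist`` between internal levels ``lo`` and ``hi``
        inclusive, trimmed to the occupied span. Trimming leaves the
        pixel multiset unchanged but makes every mean computation
        independent of how far the slice extends into empty bins, so
        the objective is exactly constant across zero-count gaps (flat
        plateaus tie-break reproducibly)."""
        window = hist.counts[lo - 1 : hi]
        nz = np.flatnonzero(window)
        if nz.size:
            return cls(lo + int(nz[0]), lo + int(nz[-1]), window[nz[0] : nz[-1] + 1])
        return cls(lo, hi, window)

    @property
    def levels(self) -> np.ndarray:
        """Internal level values carried by this slice."""
        return np.arange(self.lo, self.hi + 1, dtype=np.float64)

    @property
    def length(self) -> int:
        """Total pixel count in the mode."""
        return int(self.counts.sum())


def _require_nonempty(region: ModeRegion) -> None:
    if region.length == 0:
        raise UndefinedMeanError("mean of an empty mode is undefined")


def classical_mean(region: ModeRegion) -> float:
    """Arithmetic mean of the mode's pixels."""
    _require_nonempty(region)
    return float(region.levels @ region.counts) / region.length


def geometric_mean(region: ModeRegion) -> float:
    """Geometric mean, computed in log space to avoid overflow."""
    _require_nonempty(region)
    log_sum = float(np.log(region.levels) @ region.counts)
    return math.exp(log_sum / region.length)


def harmonic_mean(region: ModeRegion) -> float:
    """Harmonic mean; pulls toward the smallest occupied levels."""
    _require_nonempty(region)
    recip_sum = float((region.counts / region.levels).sum())
    return region.length / recip_sum


def contraharmonic_mean(region: ModeRegion, q: float) -> float:
    """Contra-harmonic (power) mean of order ``q``.

    Defined as sum(i^(q+1) * counts[i]) / sum(i^q * counts[i]). Reduces
    to the classical mean at q = 0 and to the harmonic mean at q = -1.
    Levels are >= 1 on the internal scale, so negative orders are
    always defined.
    """
    _require_nonempty(region)
    lv = region.levels
    denom = float(np.power(lv, q) @ region.counts)
    if denom == 0.0 or not math.isfinite(denom):
        raise UndefinedMeanError(f"contra-harmonic denominator degenerate (Q={q})")
    num = float(np.power(lv, q + 1.0) @ region.counts)
    return num / denom


def alphatrim_mean(region: ModeRegion, d_half: int) -> float:
    """Mean after trimming ``d_half`` pixels from each tail.

    Operates on the expanded sorted multiset: the ``d_half`` smallest
    and ``d_half`` largest pixels are discarded and the remainder
    averaged (denominator ``length - 2*d_half``). When the mode holds
    too few pixels to trim (``length <= 2*d_half``) the untrimmed
    classical mean is returned so a full threshold scan never aborts
    near the histogram tails.
    """
    if d_half < 0:
        raise ValueError("d_half must be non-negative")
    _require_nonempty(region)
    n = region.length
    if n <= 2 * d_half:
        return classical_mean(region)
    total = float(region.levels @ region.counts)
    low = _tail_sum(region.counts, region.lo, d_half, from_top=False)
    high = _tail_sum(region.counts, region.lo, d_half, from_top=True)
    return (total - low - high) / (n - 2 * d_half)


def _tail_sum(counts: np.ndarray, lo: int, k: int, *, from_top: bool) -> float:
    """Sum of the k smallest (or largest) pixels of the multiset,
    without materializing it: walk whole bins, then take a partial bin."""
    if k == 0:
        return 0.0
    if from_top:
        counts = counts[::-1]
    levels = np.arange(len(counts), dtype=np.float64)
    if from_top:
        levels = (lo + len(counts) - 1) - levels
    else:
        levels = lo + levels
    csum = np.cumsum(counts)
    j = int(np.searchsorted(csum, k, side="left"))
    full = float(levels[:j] @ counts[:j])
    prev = float(csum[j - 1]) if j > 0 else 0.0
    return full + (k - prev) * float(levels[j])


_APPROACHES = ("classical", "geometric", "harmonic", "c-harmonic", "alpha-trim")


@dataclass(frozen=True)
class EstimatorSpec:
    """One mean-filter approach plus its parameter.

    ``q`` is the contra-harmonic order (required iff approach is
    ``"c-harmonic"``); ``d_half`` is the per-tail trim count, the
    filter's d/2 (required iff approach is ``"alpha-trim"``).
    """

    approach: str
    q: Optional[float] = None
    d_half: Optional[int] = None

    def __post_init__(self) -> None:
        if self.approach not in _APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if (self.approach == "c-harmonic") != (self.q is not None):
            raise ValueError("q is required iff approach is 'c-harmonic'")
        if (self.approach == "alpha-trim") != (self.d_half is not None):
            raise ValueError("d_half is required iff approach is 'alpha-trim'")
        if self.d_half is not None and self.d_half < 0:
            raise ValueError("d_half must be non-negative")

    def evaluate(self, region: ModeRegion) -> float:
        """Apply this estimator to a mode; raises UndefinedMeanError on
        empty modes."""
        if self.approach == "classical":
            return classical_mean(region)
        if self.approach == "geometric":
            return geometric_mean(region)
        if self.approach == "harmonic":
            return harmonic_mean(region)
        if self.approach == "c-harmonic":
            return contraharmonic_mean(region, self.q)  # type: ignore[arg-type]
        return alphatrim_mean(region, self.d_half)  # type: ignore[arg-type]

    def __str__(self) -> str:
        if self.approach == "c-harmonic":
            return f"c-harmonic:{self.q:+g}"
        if self.approach == "alpha-trim":
            return f"alpha-trim:{self.d_half}"
        return self.approach

    @classmethod
    def parse(cls, text: str) -> "EstimatorSpec":
        """Parse the serialized form, e.g. ``"c-harmonic:+0.5"``,
        ``"alpha-trim:55"``, ``"classical"``."""
        name, _, param = text.strip().partition(":")
        name = name.strip().lower()
        if name == "c-harmonic":
            if not param:
                raise ValueError("c-harmonic requires an order, e.g. 'c-harmonic:-1.5'")
            return cls("c-harmonic", q=float(param))
        if name == "alpha-trim":
            if not param:
                raise ValueError("alpha-trim requires a trim count, e.g. 'alpha-trim:55'")
            return cls("alpha-trim", d_half=int(param))
        if param:
            raise ValueError(f"{name!r} takes no parameter")
        return cls(name)
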