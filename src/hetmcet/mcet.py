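"""Minimum cross entropy thresholding with heterogeneous mean estimators.

The MCET objective for a candidate threshold ``t`` (internal shifted
scale, levels in [1, L] with L = 256) is

    n(t) = - sum_{i=1..t} i * h(i) * log(mu1(t))
           - sum_{i=t+1..L} i * h(i) * log(mu2(t))

and the optimal threshold minimizes n(t). In the original formulation
both region means mu1, mu2 are classical (arithmetic) means of the two
histogram modes. Here each mean may instead be estimated by any of the
five order-statistic filters in :mod:`hetmcet.mean_filters`; using a
*different* filter per mode ("heterogeneous" estimation) lets one mode
shed pepper noise while the other sheds salt noise, which a single
homogeneous filter cannot do.

The enumeration tables reproduce the standard test-case grids: 32
heterogeneous pairs (every ordered pair of distinct approaches from
{classical, geometric, harmonic, contra-harmonic, alpha-trim d/2=55},
with contra-harmonic allowed on both sides provided the orders are
sign-opposed: Q in {+0.5, +1.5} for the lower mode against Q in
{-0.5, -1.5} for the upper), and the 21 homogeneous baselines
(one filter for both modes, over a grid of Q and d/2 values).
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, UndefinedMeanError
from .histogram_io import Histogram, N_LEVELS
from .mean_filters import EstimatorSpec, ModeRegion

__all__ = [
    "MCETConfig",
    "ThresholdResult",
    "cross_entropy_objective",
    "find_threshold",
    "classical_config",
    "enumerate_heterogeneous_configs",
    "enumerate_homogeneous_configs",
    "sweep",
]

_CLASSICAL = EstimatorSpec("classical")
_GEOMETRIC = EstimatorSpec("geometric")
_HARMONIC = EstimatorSpec("harmonic")
_ALPHA55 = EstimatorSpec("alpha-trim", d_half=55)


def _ch(q: float) -> EstimatorSpec:
    return EstimatorSpec("c-harmonic", q=q)


@dataclass(frozen=True)
class MCETConfig:
    """A thresholding configuration: one estimator per histogram mode.

    ``config_id`` indexes the enumeration table the config came from
    (0 = classical/classical, the original MCET); ``family`` records
    which table ("heterogeneous", "homogeneous", or "custom").
    """

    mu1_spec: EstimatorSpec
    mu2_spec: EstimatorSpec
    config_id: int = 0
    family: str = "custom"

    @property
    def label(self) -> str:
        return f"{self.mu1_spec}/{self.mu2_spec}"


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of one MCET scan.

    ``t_star`` is reported on the external 0-255 gray scale; pixels
    strictly above it belong to the upper mode. ``mu1``/``mu2`` are the
    mode means at the optimum on the internal shifted scale.
    ``objective_curve[k]`` is n(t) for the internal split t = k + 1
    (+inf marks invalid candidates).
    """

    t_star: int
    mu1: float
    mu2: float
    objective: float
    objective_curve: np.ndarray = field(repr=False)
    config: MCETConfig = field(default_factory=lambda: classical_config())


def cross_entropy_objective(hist: Histogram, t: int, mu1: float, mu2: float) -> float:
    """Evaluate n(t) for one candidate split with given mode means.

    ``t`` is the internal split level: the lower mode is [1..t], the
    upper mode [t+1..256]. Natural logarithm; any base only rescales
    n(t) by a positive constant and cannot move the argmin. Non-positive
    means mark an invalid candidate and return +inf.
    """
    if not 1 <= t <= N_LEVELS - 1:
        raise ValueError(f"internal split {t} outside [1, {N_LEVELS - 1}]")
    if mu1 <= 0 or mu2 <= 0 or not (math.isfinite(mu1) and math.isfinite(mu2)):
        return math.inf
    levels = np.arange(1, N_LEVELS + 1, dtype=np.float64)
    weighted = levels * hist.counts
    s_low = float(weighted[:t].sum())
    s_high = float(weighted[t:].sum())
    return -s_low * math.log(mu1) - s_high * math.log(mu2)


def find_threshold(hist: Histogram, config: Optional[MCETConfig] = None) -> ThresholdResult:
    """Exhaustive MCET scan over all 255 candidate splits.

    For each internal split t in [1, 255] with both modes non-empty,
    estimate mu1 over [1..t] with ``config.mu1_spec`` and mu2 over
    [t+1..256] with ``config.mu2_spec``, then evaluate n(t). Candidates
    with an empty mode or an undefined mean get a +inf sentinel. The
    smallest minimizer wins (deterministic tie-break at flat minima).
    """
    if config is None:
        config = classical_config()
    occupied = hist.occupied_levels
    if occupied.size < 2:
        lvl = int(occupied[0]) if occupied.size else None
        raise DegenerateInputError(
            f"histogram has fewer than two occupied levels (level={lvl}); "
            "bilevel thresholding is undefined"
        )

    levels = np.arange(1, N_LEVELS + 1, dtype=np.float64)
    weighted = levels * hist.counts
    cum_weighted = np.cumsum(weighted)
    cum_counts = np.cumsum(hist.counts)
    total_weighted = float(cum_weighted[-1])
    total_count = int(cum_counts[-1])

    curve = np.full(N_LEVELS - 1, math.inf)
    means = np.full((N_LEVELS - 1, 2), math.nan)
    for t in range(1, N_LEVELS):
        n_low = int(cum_counts[t - 1])
        if n_low == 0 or n_low == total_count:
            continue
        region_a = ModeRegion.from_histogram(hist, 1, t)
        region_b = ModeRegion.from_histogram(hist, t + 1, N_LEVELS)
        try:
            mu1 = config.mu1_spec.evaluate(region_a)
            mu2 = config.mu2_spec.evaluate(region_b)
        except UndefinedMeanError:
            continue
        if mu1 <= 0 or mu2 <= 0 or not (math.isfinite(mu1) and math.isfinite(mu2)):
            continue
        s_low = float(cum_weighted[t - 1])
        curve[t - 1] = -s_low * math.log(mu1) - (total_weighted - s_low) * math.log(mu2)
        means[t - 1] = (mu1, mu2)

    best = int(np.argmin(curve))  # argmin returns the first (smallest t) minimizer
    if not math.isfinite(curve[best]):
        raise DegenerateInputError("no valid candidate threshold")
    return ThresholdResult(
        t_star=best,  # internal split best+1 -> gray scale (best+1) - 1
        mu1=float(means[best, 0]),
        mu2=float(means[best, 1]),
        objective=float(curve[best]),
        objective_curve=curve,
        config=config,
    )


def classical_config() -> MCETConfig:
    """Row 0: classical mean for both modes — the original MCET."""
    return MCETConfig(_CLASSICAL, _CLASSICAL, config_id=0, family="homogeneous")


# Ordered (mu1, mu2) pairs of the 32-row heterogeneous table. The lower
# mode may use contra-harmonic with positive Q only, the upper mode with
# negative Q only (positive orders suppress pepper, negative suppress salt).
_HETEROGENEOUS_PAIRS: List[tuple] = [
    (_CLASSICAL, _GEOMETRIC),
    (_CLASSICAL, _HARMONIC),
    (_CLASSICAL, _ch(-1.5)),
    (_CLASSICAL, _ch(-0.5)),
    (_CLASSICAL, _ALPHA55),
    (_GEOMETRIC, _CLASSICAL),
    (_GEOMETRIC, _HARMONIC),
    (_GEOMETRIC, _ch(-1.5)),
    (_GEOMETRIC, _ch(-0.5)),
    (_GEOMETRIC, _ALPHA55),
    (_HARMONIC, _CLASSICAL),
    (_HARMONIC, _GEOMETRIC),
    (_HARMONIC, _ch(-1.5)),
    (_HARMONIC, _ch(-0.5)),
    (_HARMONIC, _ALPHA55),
    (_ch(+1.5), _CLASSICAL),
    (_ch(+1.5), _GEOMETRIC),
    (_ch(+1.5), _HARMONIC),
    (_ch(+1.5), _ch(-1.5)),
    (_ch(+1.5), _ch(-0.5)),
    (_ch(+1.5), _ALPHA55),
    (_ch(+0.5), _CLASSICAL),
    (_ch(+0.5), _GEOMETRIC),
    (_ch(+0.5), _HARMONIC),
    (_ch(+0.5), _ch(-1.5)),
    (_ch(+0.5), _ch(-0.5)),
    (_ch(+0.5), _ALPHA55),
    (_ALPHA55, _CLASSICAL),
    (_ALPHA55, _GEOMETRIC),
    (_ALPHA55, _HARMONIC),
    (_ALPHA55, _ch(-1.5)),
    (_ALPHA55, _ch(-0.5)),
]

# Homogeneous baseline grid: one estimator for both modes.
_HOMOGENEOUS_SPECS: List[EstimatorSpec] = [
    _CLASSICAL,
    _HARMONIC,
    _GEOMETRIC,
    _ch(-3.0),
    _ch(-1.5),
    _ch(-0.5),
    _ch(+0.5),
    _ch(+1.5),
] + [EstimatorSpec("alpha-trim", d_half=d) for d in
     (10, 20, 30, 40, 50, 55, 60, 65, 70, 80, 90, 100, 110)]


def enumerate_heterogeneous_configs() -> List[MCETConfig]:
    """The 32 heterogeneous configurations, ids 1-32 in table order."""
    return [
        MCETConfig(m1, m2, config_id=i, family="heterogeneous")
        for i, (m1, m2) in enumerate(_HETEROGENEOUS_PAIRS, start=1)
    ]


def enumerate_homogeneous_configs() -> List[MCETConfig]:
    """The 21 homogeneous configurations, ids 0-20; id 0 is the
    classical/classical original MCET."""
    return [
        MCETConfig(spec, spec, config_id=i, family="homogeneous")
        for i, spec in enumerate(_HOMOGENEOUS_SPECS)
    ]


def sweep(
    hist: Histogram,
    configs: Sequence[MCETConfig],
    workers: int = 1,
) -> List[ThresholdResult]:
    """Run :func:`find_threshold` for every config.

    Results are returned in config order and are identical for any
    ``workers`` value (the scan is deterministic; threads only
    parallelize independent configs).
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    if workers <= 1 or len(configs) == 1:
        return [find_threshold(hist, c) for c in configs]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(lambda c: find_threshold(hist, c), configs))
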