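"""Independent brute-force reference implementations used as test oracles.

Everything here works on the *expanded* pixel multiset (level i repeated
count[i] times) with straight-line formulas, deliberately sharing no
code with the package's histogram-weighted implementations.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np


def expand(levels: np.ndarray, counts: np.ndarray) -> List[int]:
    """Sorted pixel list with level repeated count times."""
    out: List[int] = []
    for lv, c in zip(levels, counts):
        out.extend([int(lv)] * int(c))
    return out


def brute_classical(pixels: List[int]) -> float:
    return sum(pixels) / len(pixels)


def brute_geometric(pixels: List[int]) -> float:
    prod = 1
    for p in pixels:
        prod *= p
    return math.exp(math.log(prod) / len(pixels))


def brute_harmonic(pixels: List[int]) -> float:
    return len(pixels) / sum(1.0 / p for p in pixels)


def brute_contraharmonic(pixels: List[int], q: float) -> float:
    num = sum(p ** (q + 1.0) for p in pixels)
    den = sum(p ** q for p in pixels)
    return num / den


def brute_alphatrim(pixels: List[int], d_half: int) -> float:
    xs = sorted(pixels)
    if len(xs) <= 2 * d_half:
        return sum(xs) / len(xs)
    kept = xs[d_half : len(xs) - d_half]
    return sum(kept) / len(kept)


def brute_mean(pixels: List[int], approach: str,
               q: Optional[float] = None, d_half: Optional[int] = None) -> float:
    if approach == "classical":
        return brute_classical(pixels)
    if approach == "geometric":
        return brute_geometric(pixels)
    if approach == "harmonic":
        return brute_harmonic(pixels)
    if approach == "c-harmonic":
        return brute_contraharmonic(pixels, q)
    if approach == "alpha-trim":
        return brute_alphatrim(pixels, d_half)
    raise ValueError(approach)


SpecTuple = Tuple[str, Optional[float], Optional[int]]


def brute_find_threshold(
    counts256: np.ndarray,
    spec_pairs: List[Tuple[SpecTuple, SpecTuple]],
) -> List[Optional[int]]:
    """Brute-force MCET scan on the internal scale for many estimator
    pairs at once (mean values shared per split). Returns, per pair,
    the smallest minimizing threshold on the 0-255 gray scale."""
    counts256 = np.asarray(counts256, dtype=np.int64)
    levels = np.arange(1, 257)
    unique_specs = sorted({s for pair in spec_pairs for s in pair})

    best_val = [math.inf] * len(spec_pairs)
    best_t: List[Optional[int]] = [None] * len(spec_pairs)
    for t in range(1, 256):
        low = expand(levels[:t], counts256[:t])
        high = expand(levels[t:], counts256[t:])
        if not low or not high:
            continue
        mean_low: Dict[SpecTuple, float] = {}
        mean_high: Dict[SpecTuple, float] = {}
        for spec in unique_specs:
            approach, q, d_half = spec
            mean_low[spec] = brute_mean(low, approach, q, d_half)
            mean_high[spec] = brute_mean(high, approach, q, d_half)
        s_low = sum(p for p in low)   # sum of i over expanded lower mode
        s_high = sum(p for p in high)
        for k, (s1, s2) in enumerate(spec_pairs):
            m1, m2 = mean_low[s1], mean_high[s2]
            if m1 <= 0 or m2 <= 0:
                continue
            val = -s_low * math.log(m1) - s_high * math.log(m2)
            if val < best_val[k]:
                best_val[k] = val
                best_t[k] = t - 1  # internal split t -> gray scale
    return best_t


def brute_objective(counts256: np.ndarray, t: int, mu1: float, mu2: float) -> float:
    """Direct double-sum evaluation of the cross-entropy objective."""
    total = 0.0
    for i in range(1, 257):
        c = int(counts256[i - 1])
        if c == 0:
            continue
        total += -i * c * (math.log(mu1) if i <= t else math.log(mu2))
    return total
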