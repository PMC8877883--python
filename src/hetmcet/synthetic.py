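"""Bimodal phantom images with ground truth and controlled noise.

A phantom is a two-region image — a foreground shape (disk, ellipse or
rectangle) on a uniform background — whose gray values are drawn from
per-region Gaussians and then contaminated with impulse noise: a fixed
fraction of pixels forced to 255 (salt, which lands in the high tail of
the histogram) and another fraction forced to 0 (pepper, the low tail).
This reproduces the canonical hard case for mean-based thresholding: a
bimodal histogram with mass injected at both extremes, which drags the
classical region means toward the tails.

The generator is deterministic for a fixed seed, the ground-truth mask
is exact by construction, and the Bayes midpoint (mu_bg + mu_fg) / 2 of
the equal-variance two-Gaussian mixture serves as the reference optimum
for parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .errors import DegeneratePhantomError
from .histogram_io import BinaryMask, GrayImage

__all__ = ["PhantomSpec", "generate_phantom", "bayes_threshold"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Defaults describe a 96x96 canvas with a centered foreground disk
    covering half the area, background mean 60, foreground mean 190,
    Gaussian noise sigma 10, and no impulse noise. ``radii`` is
    (ry, rx) for ellipse/rectangle half-extents; for a disk a single
    radius. When geometry parameters are omitted, the shape is centered
    and sized for equal foreground/background areas.
    """

    height: int = 96
    width: int = 96
    fg_geometry: str = "disk"
    center: Optional[Tuple[float, float]] = None
    radii: Optional[Tuple[float, float]] = None
    mu_bg: float = 60.0
    mu_fg: float = 190.0
    sigma: float = 10.0
    salt_density: float = 0.0
    pepper_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("canvas must be at least 1x1")
        if self.fg_geometry not in ("disk", "ellipse", "rectangle"):
            raise ValueError(f"unknown geometry {self.fg_geometry!r}")
        if self.mu_bg == self.mu_fg:
            raise ValueError("mu_bg and mu_fg must differ")
        for mu in (self.mu_bg, self.mu_fg):
            if not 0 <= mu <= 255:
                raise ValueError("region means must lie in [0, 255]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (0 <= self.salt_density < 1 and 0 <= self.pepper_density < 1):
            raise ValueError("densities must lie in [0, 1)")
        if self.salt_density + self.pepper_density >= 1:
            raise ValueError("salt + pepper density must be < 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        data = json.loads(text)
        for key in ("center", "radii"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PhantomSpec":
        return cls.from_json(Path(path).read_text())


def _geometry_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.radii is not None:
        ry, rx = spec.radii
    else:
        # Default: foreground covers half the canvas area.
        if spec.fg_geometry == "rectangle":
            ry = h / (2.0 * math.sqrt(2.0))
            rx = w / (2.0 * math.sqrt(2.0))
        else:
            r = math.sqrt(h * w / (2.0 * math.pi))
            ry = rx = r
    if ry <= 0 or rx <= 0:
        raise ValueError("radii must be positive")
    if spec.fg_geometry == "rectangle":
        inside = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= rx)
    else:  # disk or ellipse
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return inside


def generate_phantom(spec: PhantomSpec) -> Tuple[GrayImage, BinaryMask]:
    """Render a phantom and its exact ground-truth mask.

    Gaussian noise is applied first (per-region mean, shared sigma,
    rounded and clipped to [0, 255]); impulse noise then overwrites a
    ``round(density * n_pixels)`` sized, uniformly chosen, disjoint set
    of pixels per tail, so the histogram's masses at 0 and 255 are
    exact. Fixed seed implies bit-identical output.
    """
    inside = _geometry_mask(spec)
    if not inside.any():
        raise DegeneratePhantomError("foreground geometry does not intersect the canvas")
    if inside.all():
        raise DegeneratePhantomError("foreground geometry covers the whole canvas")

    rng = np.random.default_rng(spec.seed)
    means = np.where(inside, spec.mu_fg, spec.mu_bg)
    pixels = rng.normal(means, spec.sigma)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)

    n = pixels.size
    n_salt = int(round(spec.salt_density * n))
    n_pepper = int(round(spec.pepper_density * n))
    if n_salt or n_pepper:
        order = rng.permutation(n)
        flat = pixels.ravel()
        flat[order[:n_salt]] = 255
        flat[order[n_salt : n_salt + n_pepper]] = 0
        pixels = flat.reshape(pixels.shape)

    return GrayImage(pixels), BinaryMask(inside.astype(np.uint8))


def bayes_threshold(spec: PhantomSpec) -> float:
    """Midpoint (mu_bg + mu_fg) / 2 — the equal-variance two-Gaussian
    decision boundary up to the class-prior term. For sigma = 0 any
    value strictly between the two levels is optimal; the midpoint is
    returned in that case too."""
    return (spec.mu_bg + spec.mu_fg) / 2.0
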