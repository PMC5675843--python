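"""Saccade target selection: saliency times inhibition of return.

The next fixation is sampled from the full-resolution saliency map
multiplied by an inhibition-of-return (IOR) mask suppressing the last two
fixation points (Gaussian-shaped notches of width sigma1 = 20 px for the
most recent, sigma2 = 10 px for the one before), restricted to the valid
fixation margin.  With 400 ms fixations this yields an 800 ms IOR window.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixationHistory",
    "ior_mask",
    "target_distribution",
    "sample_fixation",
    "random_saccade_policy",
]


@dataclass
class FixationHistory:
    """The last two fixation points, most recent first."""

    sigma1: float = 20.0
    sigma2: float = 10.0
    points: deque = field(default_factory=lambda: deque(maxlen=2))

    def __post_init__(self):
        if not self.sigma1 > self.sigma2 > 0:
            raise ValueError("need sigma1 > sigma2 > 0")

    def push(self, point: tuple[int, int]) -> None:
        self.points.appendleft((int(point[0]), int(point[1])))


def _notch(shape: tuple[int, int], point: tuple[int, int], sigma: float) -> np.ndarray:
    """1 - exp(-||p - p_k||^2 / (2 sigma^2)): 0 at the point, ->1 far away."""
    h, w = shape
    x0, y0 = point
    yy, xx = np.ogrid[0:h, 0:w]
    d2 = (xx - x0) ** 2 + (yy - y0) ** 2
    return 1.0 - np.exp(-d2 / (2.0 * sigma**2))


def ior_mask(history: FixationHistory, frame_shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel suppression mask in [0, 1]; identically 1 with no history."""
    mask = np.ones(frame_shape)
    sigmas = (history.sigma1, history.sigma2)
    for point, sigma in zip(history.points, sigmas):
        mask *= _notch(frame_shape, point, sigma)
    return mask


def target_distribution(
    saliency_full: np.ndarray,
    ior: np.ndarray,
    margin_mask: np.ndarray,
) -> np.ndarray:
    """Normalised product S * IOR, zero outside the valid fixation margin.

    If the product vanishes everywhere (e.g. a blank saliency map), falls
    back to a uniform distribution over the margin.
    """
    prod = saliency_full * ior * margin_mask
    total = prod.sum()
    if total <= 0:
        prod = margin_mask.astype(np.float64)
        total = prod.sum()
    return prod / total


def sample_fixation(
    distribution: np.ndarray,
    rng: np.random.Generator,
    history: FixationHistory | None = None,
) -> tuple[int, int]:
    """Sample an (x, y) fixation point; pushes it into the history if given."""
    flat = distribution.ravel()
    idx = rng.choice(flat.size, p=flat)
    y, x = np.unravel_index(idx, distribution.shape)
    point = (int(x), int(y))
    if history is not None:
        history.push(point)
    return point


def random_saccade_policy(
    margin_mask: np.ndarray,
    rng: np.random.Generator,
    history: FixationHistory | None = None,
) -> tuple[int, int]:
    """Control condition: a fixation point uniform over the valid margin."""
    dist = margin_mask / margin_mask.sum()
    return sample_fixation(dist, rng, history)
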