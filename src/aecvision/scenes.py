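"""Synthetic binocular scenes and the window-shift model of eye movements.

A scene is a stack of textured fronto-parallel planes at integer pixel
disparities in front of a full-frame background plane.  Eye movements are
emulated in 2-D: a *fixation point* in the left image plus a horizontal
*shift* ``d`` (the vergence state) determine which sub-windows of the stereo
pair each mechanism sees.  The retinal disparity at a fixation is
``d - D(x, y)`` where ``D`` is the scene's ground-truth disparity map; zero
retinal disparity means the left and right foveal windows are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VERGENCE_ACTIONS",
    "SceneConfig",
    "Plane",
    "StereoScene",
    "StereoFrame",
    "FixationState",
    "FixationGeometry",
    "WindowSet",
    "generate_scene",
    "render_stereo",
    "retinal_disparity",
    "apply_vergence_action",
    "laplacian_disparity_pmf",
    "sample_laplacian_disparity",
]

#: The 11 discrete vergence actions (pixel changes of the horizontal shift),
#: symmetric signed powers of two about zero.
VERGENCE_ACTIONS: tuple[int, ...] = (-16, -8, -4, -2, -1, 0, 1, 2, 4, 8, 16)

#: Maximum magnitude of the horizontal shift (and of the disparity support
#: of the truncated-Laplacian disparity distribution).
MAX_SHIFT = 40

# Horizontal padding of plane textures so that shifted lookups (|disparity|
# plus |shift|) never leave the texture support.
_TEX_PAD = 64


# ---------------------------------------------------------------------------
# configuration and scene containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    ``texture`` / ``background_texture`` choose the texture family:
    ``pinknoise`` (broadband 1/f noise), ``gratings`` (oriented sinusoids),
    ``deadleaves`` (overlapping random discs), ``smooth`` (weak low-passed
    noise: low entropy but not degenerate) or ``flat`` (constant intensity,
    a texture-free region).
    """

    width: int = 320
    height: int = 240
    n_planes: int = 5
    disparity_range: tuple[int, int] = (-20, 20)
    texture: str = "pinknoise"
    background_texture: str = "pinknoise"
    background_disparity: int = 0
    min_plane_frac: float = 0.15
    max_plane_frac: float = 0.45


@dataclass(frozen=True)
class Plane:
    """A textured fronto-parallel plane.

    ``texture`` has shape ``(height, width + 2 * pad)``; column ``x`` of the
    left image reads ``texture[:, pad + x]`` so horizontally shifted lookups
    stay inside the support.
    """

    y0: int
    y1: int
    x0: int
    x1: int
    disparity: int
    texture: np.ndarray
    pad: int = _TEX_PAD


@dataclass(frozen=True)
class StereoScene:
    """Planes ordered far to near over a full-frame background."""

    width: int
    height: int
    background: Plane
    planes: tuple[Plane, ...]
    seed: int | None = None

    @property
    def disparity_map(self) -> np.ndarray:
        """Dense ground-truth disparity in left-image coordinates (px)."""
        d = np.full((self.height, self.width), self.background.disparity, dtype=np.int64)
        for p in self.planes:  # later planes are nearer and win
            d[p.y0:p.y1, p.x0:p.x1] = p.disparity
        return d


@dataclass(frozen=True)
class StereoFrame:
    """A rectified grayscale stereo pair with values in [0, 1]."""

    left: np.ndarray
    right: np.ndarray
    seed: int | None = None


@dataclass(frozen=True)
class FixationState:
    """Left-image fixation point plus the vergence shift ``d``.

    The right fixation point is ``(x - shift, y)``.  ``frame`` counts frames
    within the current fixation (0-9); the shift carries over across
    saccades unchanged.
    """

    x: int
    y: int
    shift: int = 0
    frame: int = 0
    index: int = 0


@dataclass(frozen=True)
class WindowSet:
    """Multi-scale binocular windows for vergence (coarse/medium/fine)."""

    coarse: tuple[np.ndarray, np.ndarray]
    medium: tuple[np.ndarray, np.ndarray]
    fine: tuple[np.ndarray, np.ndarray]

    def pairs(self):
        return {"C": self.coarse, "M": self.medium, "F": self.fine}


# ---------------------------------------------------------------------------
# texture synthesis
# ---------------------------------------------------------------------------

def _to_unit(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def _make_texture(family: str, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    if family == "flat":
        return np.full(shape, float(rng.uniform(0.3, 0.7)))
    if family == "smooth":
        # weak, heavily low-passed texture: spans few intensity levels
        # (low entropy) without being degenerate
        noise = rng.standard_normal(shape)
        sm = ndimage.gaussian_filter(noise, 8.0, mode="wrap")
        return 0.5 + 0.04 * (_to_unit(sm) - 0.5) * 2.0
    if family == "pinknoise":
        noise = rng.standard_normal(shape)
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        f = np.hypot(fy, fx)
        f[0, 0] = 1.0
        spec = np.fft.fft2(noise) / f
        return _to_unit(np.fft.ifft2(spec).real)
    if family == "gratings":
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(0.03, 0.15)
        phase = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        return 0.5 + 0.5 * np.sin(
            2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase
        )
    if family == "deadleaves":
        img = np.full(shape, float(rng.uniform(0.2, 0.8)))
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(max(30, h * w // 400)):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = rng.uniform(3, max(4.0, min(h, w) / 6))
            img[(yy - cy) ** 2 + (xx - cx) ** 2 < r * r] = rng.uniform(0, 1)
        return img
    raise ValueError(f"unknown texture family {family!r}")


# ---------------------------------------------------------------------------
# scene generation and rendering
# ---------------------------------------------------------------------------

def generate_scene(
    config: SceneConfig,
    seed: int | np.random.Generator,
    *,
    plane_disparities: Sequence[int] | None = None,
    plane_rects: Sequence[tuple[int, int, int, int]] | None = None,
    geometry: "FixationGeometry | None" = None,
) -> StereoScene:
    """Build a random multi-plane scene with ground-truth disparity.

    Deterministic for a given integer ``seed``.  Plane disparities are drawn
    uniformly over the configured integer range unless given explicitly;
    ``plane_rects`` entries are ``(y0, y1, x0, x1)`` half-open bounds.
    ``geometry``, if given, validates that the frame can host the analysis
    windows.
    """
    if geometry is not None:
        geometry.check_frame(config.width, config.height)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    provenance = None if isinstance(seed, np.random.Generator) else int(seed)
    h, w = config.height, config.width
    tex_shape = (h, w + 2 * _TEX_PAD)

    background = Plane(
        0, h, 0, w, int(config.background_disparity),
        _make_texture(config.background_texture, tex_shape, rng),
    )

    lo, hi = config.disparity_range
    planes: list[Plane] = []
    for i in range(config.n_planes):
        if plane_disparities is not None:
            disp = int(plane_disparities[i])
        else:
            disp = int(rng.integers(lo, hi + 1))
        if not lo <= disp <= hi:
            raise ValueError(
                f"plane disparity {disp} outside configured range [{lo}, {hi}]"
            )
        if plane_rects is not None:
            y0, y1, x0, x1 = plane_rects[i]
        else:
            side = min(w, h)
            ph = int(rng.uniform(config.min_plane_frac, config.max_plane_frac) * side)
            pw = int(rng.uniform(config.min_plane_frac, config.max_plane_frac) * side)
            y0 = int(rng.integers(0, h - ph + 1))
            x0 = int(rng.integers(0, w - pw + 1))
            y1, x1 = y0 + ph, x0 + pw
        planes.append(
            Plane(y0, y1, x0, x1, disp, _make_texture(config.texture, tex_shape, rng))
        )

    return StereoScene(w, h, background, tuple(planes), seed=provenance)


def render_stereo(scene: StereoScene) -> StereoFrame:
    """Render the rectified stereo pair by painting planes far to near.

    The right image shows each plane's texture shifted left by its
    disparity; disoccluded pixels take the texture of whatever farther
    surface is exposed there (ultimately the background).
    """
    h, w = scene.height, scene.width
    left = np.empty((h, w))
    right = np.empty((h, w))
    for p in (scene.background, *scene.planes):
        pad = p.pad
        left[p.y0:p.y1, p.x0:p.x1] = p.texture[p.y0:p.y1, pad + p.x0:pad + p.x1]
        # plane columns [x0, x1) of the left image land on right-image
        # columns [x0 - disparity, x1 - disparity), clipped to the frame
        rx0 = max(p.x0 - p.disparity, 0)
        rx1 = min(p.x1 - p.disparity, w)
        if rx1 > rx0:
            right[p.y0:p.y1, rx0:rx1] = p.texture[
                p.y0:p.y1, pad + rx0 + p.disparity:pad + rx1 + p.disparity
            ]
    return StereoFrame(left, right, seed=scene.seed)


def retinal_disparity(scene: StereoScene, fix: FixationState) -> int:
    """Shift minus scene disparity at the fixation; 0 = windows aligned."""
    if not (0 <= fix.x < scene.width and 0 <= fix.y < scene.height):
        raise ValueError("fixation outside the image")
    return int(fix.shift) - int(scene.disparity_map[fix.y, fix.x])


def apply_vergence_action(
    fix: FixationState, action: int, *, max_shift: int = MAX_SHIFT
) -> FixationState:
    """Apply one discrete vergence command; clamps the shift to +-max_shift."""
    if action not in VERGENCE_ACTIONS:
        raise ValueError(f"action {action} not in vergence action set {VERGENCE_ACTIONS}")
    new_shift = int(np.clip(fix.shift + action, -max_shift, max_shift))
    return replace(fix, shift=new_shift, frame=fix.frame + 1)


# ---------------------------------------------------------------------------
# multi-scale window extraction
# ---------------------------------------------------------------------------

def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Bicubic down-sampling by an integer factor (reflect boundaries)."""
    if factor == 1:
        return img
    return ndimage.zoom(img, 1.0 / factor, order=3, mode="reflect", grid_mode=True)


@dataclass(frozen=True)
class FixationGeometry:
    """Sizes and margins of the analysis windows.

    ``window_base`` is the side of the fine-scale window; the medium and
    coarse vergence windows are 2x and 4x that size, down-sampled back to
    ``window_base`` so all three scales present equally sized inputs.  The
    full-scale profile uses base 55 (windows 220/110/55).
    """

    window_base: int = 55
    max_shift: int = MAX_SHIFT

    @property
    def coarse_size(self) -> int:
        return 4 * self.window_base

    @property
    def medium_size(self) -> int:
        return 2 * self.window_base

    @property
    def min_width(self) -> int:
        return self.coarse_size + 2 * self.max_shift

    @property
    def min_height(self) -> int:
        return self.coarse_size

    def check_frame(self, width: int, height: int) -> None:
        if width < self.min_width or height < self.min_height:
            raise ValueError(
                f"frame {width}x{height} too small for a {self.coarse_size}x"
                f"{self.coarse_size} coarse window with shifts up to "
                f"{self.max_shift}px; need at least {self.min_width}x{self.min_height}"
            )

    def margin_bounds(self, width: int, height: int) -> tuple[int, int, int, int]:
        """Inclusive fixation bounds ``(x_lo, x_hi, y_lo, y_hi)``."""
        half = self.coarse_size // 2
        x_lo = half + self.max_shift
        x_hi = width - (self.coarse_size - half) - self.max_shift
        y_lo = half
        y_hi = height - (self.coarse_size - half)
        if x_lo > x_hi or y_lo > y_hi:
            raise ValueError(
                f"frame {width}x{height} has an empty valid fixation margin"
            )
        return x_lo, x_hi, y_lo, y_hi

    def margin_mask(self, width: int, height: int) -> np.ndarray:
        """Boolean mask of fixation points whose windows always fit."""
        x_lo, x_hi, y_lo, y_hi = self.margin_bounds(width, height)
        mask = np.zeros((height, width), dtype=bool)
        mask[y_lo:y_hi + 1, x_lo:x_hi + 1] = True
        return mask

    def _crop(self, img: np.ndarray, cx: int, cy: int, size: int) -> np.ndarray:
        y0 = cy - size // 2
        x0 = cx - size // 2
        if y0 < 0 or x0 < 0 or y0 + size > img.shape[0] or x0 + size > img.shape[1]:
            raise ValueError(
                f"{size}x{size} window at ({cx}, {cy}) leaves the image"
            )
        return img[y0:y0 + size, x0:x0 + size]

    def extract_vergence_input(self, frame: StereoFrame, fix: FixationState) -> WindowSet:
        """The three binocular windows centred on the two fixation points.

        Left windows are centred at ``(x, y)``, right windows at
        ``(x - shift, y)``; coarse/medium crops are bicubically
        down-sampled by 4/2 so every output is ``window_base`` square.
        """
        rx = fix.x - fix.shift
        out = {}
        for name, size, factor in (
            ("coarse", self.coarse_size, 4),
            ("medium", self.medium_size, 2),
            ("fine", self.window_base, 1),
        ):
            lw = _downsample(self._crop(frame.left, fix.x, fix.y, size), factor)
            rw = _downsample(self._crop(frame.right, rx, fix.y, size), factor)
            out[name] = (lw, rw)
        return WindowSet(**out)

    def extract_saccade_input(
        self, frame: StereoFrame, shift: int
    ) -> tuple[np.ndarray, np.ndarray, int]:
        """Largest aligned binocular pair, down-sampled by 4.

        For shift ``d >= 0`` the left sub-window spans columns ``[d, N)``
        and the right ``[0, N - d)`` (mirrored for ``d < 0``), so pixels at
        the same window coordinates correspond when the scene disparity
        equals ``d``.  Returns ``(left, right, col_offset)`` where
        ``col_offset`` is the left-image column of the windows' first
        column (before down-sampling).
        """
        n = frame.left.shape[1]
        d = int(shift)
        if abs(d) >= n:
            raise ValueError(f"shift {d} exceeds image width {n}")
        if d >= 0:
            lw = frame.left[:, d:]
            rw = frame.right[:, : n - d]
            offset = d
        else:
            lw = frame.left[:, : n + d]
            rw = frame.right[:, -d:]
            offset = 0
        return _downsample(lw, 4), _downsample(rw, 4), offset


# ---------------------------------------------------------------------------
# disparity statistics
# ---------------------------------------------------------------------------

def laplacian_disparity_pmf(spread: float, *, support: int = MAX_SHIFT) -> np.ndarray:
    """Truncated discrete Laplacian P(d) ∝ exp(-|d|/spread), d in [-support, support]."""
    if spread <= 0:
        raise ValueError("spread parameter must be positive")
    d = np.arange(-support, support + 1)
    p = np.exp(-np.abs(d) / spread)
    return p / p.sum()


def sample_laplacian_disparity(
    spread: float,
    rng: np.random.Generator,
    size: int | None = None,
    *,
    support: int = MAX_SHIFT,
):
    """Draw integer disparities from the truncated Laplacian law."""
    pmf = laplacian_disparity_pmf(spread, support=support)
    values = np.arange(-support, support + 1)
    out = rng.choice(values, size=size, p=pmf)
    return int(out) if size is None else out
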