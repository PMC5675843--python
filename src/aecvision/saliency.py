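"""Binocular saliency by self-information maximization (BAIM).

Saliency of a coarse-scale binocular patch is the summed Shannon
self-information, -ln p_n(r_n), of its subspace-feature responses, where
p_n is estimated from a histogram of the n-th response map.  The *global*
variant (GBAIM) builds histograms over every patch of the image, so
salience is fixation-independent; the *local* variant (LBAIM) builds them
over a 31x31 patch neighbourhood of the current fixation, so patches that
look (in texture or depth) unlike the currently fixated region become
salient.  A monocular degenerate mode (right half of each patch zeroed)
serves as the in-repo AIM-style baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gassom import PATCH_SIZE, SubspaceBank, patchify, subspace_responses

__all__ = [
    "ALPHA_FLOOR",
    "LOCAL_CONTEXT",
    "ResponseMaps",
    "coarse_response_maps",
    "normalize_map",
    "build_histogram",
    "self_information",
    "saliency_map",
    "draw_feature_subset",
    "upsample_saliency",
    "embed_full_resolution",
    "correlation_coefficient",
    "subset_cc_curve",
    "fixation_to_patch",
]

#: Probability floor keeping self-information finite (max value -ln(1e-6)).
ALPHA_FLOOR = 1e-6

#: Side of the square patch neighbourhood defining the local (LBAIM) context.
LOCAL_CONTEXT = 31


@dataclass(frozen=True)
class ResponseMaps:
    """Stride-1 response maps of a set of features over a coarse pair.

    ``responses`` is (P, n_features); ``grid`` the (rows, cols) patch grid;
    ``feature_ids`` maps columns back to bank feature indices; ``shape``
    the coarse image size the patches were cut from.
    """

    responses: np.ndarray
    grid: tuple[int, int]
    feature_ids: np.ndarray
    shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.responses.shape[0]


def coarse_response_maps(
    bank: SubspaceBank,
    left: np.ndarray,
    right: np.ndarray,
    *,
    feature_ids: np.ndarray | None = None,
    monocular: bool = False,
) -> ResponseMaps:
    """Responses of (a subset of) features to every stride-1 patch.

    A coarse pair of size M1 x M2 yields (M1-9) x (M2-9) patch positions.
    ``monocular`` zeroes the right half of every patch vector after
    normalisation — the AIM-degenerate baseline.
    """
    if min(left.shape) < PATCH_SIZE:
        raise ValueError(
            f"input {left.shape} smaller than a {PATCH_SIZE}x{PATCH_SIZE} patch"
        )
    x, _, grid = patchify(left, right, stride=1)
    if monocular:
        x = x.copy()
        x[:, x.shape[1] // 2:] = 0.0
    if feature_ids is None:
        feature_ids = np.arange(bank.n_subspaces)
    else:
        feature_ids = np.asarray(feature_ids, dtype=int)
    sub = SubspaceBank(bank.bases[feature_ids], bank.sigma_e, bank.omega)
    resp = subspace_responses(sub, x)
    return ResponseMaps(resp, grid, feature_ids, left.shape)


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Min-max normalisation to [0, 1]; a constant map collapses to 0."""
    lo = values.min()
    hi = values.max()
    if hi - lo <= 0:
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) / (hi - lo)


def _bin_of(norm_values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index on [0, 1]; 1.0 falls in the (closed) top bin."""
    return np.minimum((norm_values * n_bins).astype(int), n_bins - 1)


def build_histogram(
    norm_values: np.ndarray,
    context: np.ndarray | None = None,
    n_bins: int | None = None,
) -> np.ndarray:
    """Empirical bin probabilities of one normalised response map.

    ``context`` is a boolean mask (or index array) of the patches used for
    estimation; default all.  ``n_bins`` defaults to the number of context
    patches (one bin per sample), the printed convention — configurable
    because it yields near-singleton bins.
    """
    values = norm_values if context is None else norm_values[context]
    if values.size == 0:
        raise ValueError("empty context region for histogram estimation")
    k = int(n_bins) if n_bins is not None else int(values.size)
    h = np.bincount(_bin_of(values, k), minlength=k).astype(np.float64)
    return h / h.sum()


def self_information(
    norm_values: np.ndarray, hist: np.ndarray, alpha: float = ALPHA_FLOOR
) -> np.ndarray:
    """Per-patch -ln(alpha + (1 - alpha) * h[bin(r)]), in [0, -ln(alpha)]."""
    p = alpha + (1.0 - alpha) * hist[_bin_of(norm_values, len(hist))]
    return -np.log(p)


def _local_context_mask(
    grid: tuple[int, int], center: tuple[int, int], side: int = LOCAL_CONTEXT
) -> np.ndarray:
    rows, cols = grid
    r, c = center
    half = side // 2
    mask = np.zeros((rows, cols), dtype=bool)
    mask[max(r - half, 0):r + half + 1, max(c - half, 0):c + half + 1] = True
    return mask.ravel()


def fixation_to_patch(
    fix_xy: tuple[int, int], col_offset: int, grid: tuple[int, int]
) -> tuple[int, int]:
    """Map a full-resolution fixation point to the nearest coarse patch index.

    ``col_offset`` is the left-image column where the saccade window
    starts; coarse pixels are 4x4 blocks of it, and patch (i, j) is the
    10x10 patch whose top-left coarse pixel is (i, j).
    """
    x, y = fix_xy
    cr = y / 4.0 - PATCH_SIZE / 2.0
    cc = (x - col_offset) / 4.0 - PATCH_SIZE / 2.0
    r = int(np.clip(round(cr), 0, grid[0] - 1))
    c = int(np.clip(round(cc), 0, grid[1] - 1))
    return r, c


def saliency_map(
    maps: ResponseMaps,
    subset: np.ndarray | None = None,
    *,
    context_center: tuple[int, int] | None = None,
    n_bins: int | None = None,
    alpha: float = ALPHA_FLOOR,
) -> np.ndarray:
    """Coarse saliency map: per-patch sum of feature self-information.

    ``subset`` lists bank feature ids to sum over (default: every feature
    in ``maps``).  ``context_center=None`` gives the global (GBAIM)
    context; a patch-grid (row, col) gives the local 31x31 (LBAIM) context.
    Returns a (rows, cols) array.
    """
    if subset is None:
        cols = np.arange(maps.responses.shape[1])
    else:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("empty feature subset")
        lookup = {fid: i for i, fid in enumerate(maps.feature_ids)}
        try:
            cols = np.array([lookup[f] for f in subset])
        except KeyError as err:
            raise ValueError(f"feature {err.args[0]} not present in response maps")
    context = (
        None
        if context_center is None
        else _local_context_mask(maps.grid, context_center)
    )
    total = np.zeros(maps.n_patches)
    for col in cols:
        norm = normalize_map(maps.responses[:, col])
        hist = build_histogram(norm, context, n_bins)
        total += self_information(norm, hist, alpha)
    return total.reshape(maps.grid)


def draw_feature_subset(
    n_features: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """A duplicate-free random subset of feature indices."""
    return rng.choice(n_features, size=size, replace=False)


def upsample_saliency(coarse_map: np.ndarray, coarse_shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad the patch-grid map to the coarse image size, upsample x4.

    Bicubic interpolation can overshoot below zero; negatives are clamped.
    Output dimensions are 4*M1 x 4*M2 for a coarse image of M1 x M2.
    """
    m1, m2 = coarse_shape
    rows, cols = coarse_map.shape
    padded = np.zeros((m1, m2))
    r0 = (m1 - rows) // 2
    c0 = (m2 - cols) // 2
    padded[r0:r0 + rows, c0:c0 + cols] = coarse_map
    up = ndimage.zoom(padded, 4, order=3, mode="reflect", grid_mode=True)
    return np.maximum(up, 0.0)


def embed_full_resolution(
    upsampled: np.ndarray, frame_shape: tuple[int, int], col_offset: int
) -> np.ndarray:
    """Place the upsampled window map into a zeroed full-frame canvas."""
    h, w = frame_shape
    out = np.zeros((h, w))
    uh = min(upsampled.shape[0], h)
    uw = min(upsampled.shape[1], w - col_offset)
    out[:uh, col_offset:col_offset + uw] = upsampled[:uh, :uw]
    return out


def correlation_coefficient(s1: np.ndarray, s2: np.ndarray) -> float:
    """Pearson correlation between two equally sized saliency maps."""
    a = np.asarray(s1, dtype=np.float64).ravel()
    b = np.asarray(s2, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("saliency maps differ in size")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt((da * da).sum())
    nb = np.sqrt((db * db).sum())
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a constant saliency map")
    return float((da * db).sum() / (na * nb))


def subset_cc_curve(
    maps_list: list[ResponseMaps],
    sizes: list[int],
    reps: int,
    rng: np.random.Generator,
    *,
    n_bins: int | None = None,
) -> dict[int, tuple[float, float]]:
    """Mean +- SEM of the CC between subset and full-feature maps.

    For each requested subset size, random duplicate-free subsets are drawn
    ``reps`` times per response-map stack and compared against the map
    built from all features.
    """
    results: dict[int, list[float]] = {int(s): [] for s in sizes}
    for maps in maps_list:
        n = maps.responses.shape[1]
        full = saliency_map(maps, n_bins=n_bins)
        for size in sizes:
            for _ in range(reps):
                ids = maps.feature_ids[draw_feature_subset(n, int(size), rng)]
                sub = saliency_map(maps, ids, n_bins=n_bins)
                results[int(size)].append(correlation_coefficient(sub, full))
    out = {}
    for size, ccs in results.items():
        arr = np.array(ccs)
        sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        out[size] = (float(arr.mean()), float(sem))
    return out
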