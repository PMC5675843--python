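"""Binocular subspace coding (GASSOM).

Each feature extractor is a two-column orthonormal basis spanning a 2-D
subspace of the 200-dimensional binocular patch space (left and right
10x10 patches, each normalised to zero mean / unit variance, concatenated).
A feature's response is the squared length of the projection of the patch
vector onto its subspace — the analogue of a binocular-energy complex cell.
The bank learns online: each patch is softly assigned to subspaces
(sparsity, with a stickiness bonus for the previous winner: slowness) and
every subspace is rotated toward the patches it is responsible for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PATCH_SIZE",
    "PATCH_DIM",
    "SubspaceBank",
    "init_bank",
    "patchify",
    "subspace_responses",
    "best_subspace_and_error",
    "responsibilities",
    "update_bank",
    "scale_error",
    "average_error",
    "orthonormalize",
]

PATCH_SIZE = 10
PATCH_DIM = 2 * PATCH_SIZE * PATCH_SIZE  # 200

_LOW_CONTRAST_STD = 1e-6


def orthonormalize(bases: np.ndarray) -> np.ndarray:
    """Two-column Gram-Schmidt applied to a stack of (dim, 2) bases.

    Preserves the direction of the first column (unlike a batched QR,
    which may flip signs), which keeps update trajectories continuous.
    """
    b1 = bases[..., 0]
    b2 = bases[..., 1]
    n1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    u1 = b1 / np.maximum(n1, 1e-300)
    v2 = b2 - np.sum(u1 * b2, axis=-1, keepdims=True) * u1
    n2 = np.linalg.norm(v2, axis=-1, keepdims=True)
    u2 = v2 / np.maximum(n2, 1e-300)
    return np.stack([u1, u2], axis=-1)


@dataclass
class SubspaceBank:
    """A set of N two-dimensional subspaces over binocular patch space.

    ``bases`` has shape (N, dim, 2) with orthonormal columns.
    ``prev_winners`` remembers, per patch-grid position, which subspace won
    on the previous frame (the slowness prior); it is None before the first
    frame and after a saccade.
    """

    bases: np.ndarray
    sigma_e: float = 0.2
    omega: float = 0.5
    hard_assign: bool = False
    prev_winners: np.ndarray | None = None

    @property
    def n_subspaces(self) -> int:
        return self.bases.shape[0]

    @property
    def dim(self) -> int:
        return self.bases.shape[1]

    def copy(self) -> "SubspaceBank":
        return SubspaceBank(
            self.bases.copy(), self.sigma_e, self.omega, self.hard_assign,
            None if self.prev_winners is None else self.prev_winners.copy(),
        )

    def reset_stream(self) -> None:
        """Forget the previous winners (call at temporal discontinuities)."""
        self.prev_winners = None

    def adapt(
        self, patches: np.ndarray, active: np.ndarray, lr: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """One online learning step on a frame's patches.

        ``active`` flags patches that may drive updates (low-contrast
        patches are excluded but still scored).  Returns the (pre-update)
        response array (P, N) and the per-patch best-subspace residuals.
        """
        resp = subspace_responses(self, patches)
        winners, errors = best_subspace_and_error(self, patches, responses=resp)
        h = responsibilities(self, resp, self.prev_winners)
        h = h * active[:, None]
        update_bank(self, patches, h, lr)
        self.prev_winners = winners
        return resp, errors


def init_bank(
    n_subspaces: int,
    seed: int | np.random.Generator,
    *,
    dim: int = PATCH_DIM,
    sigma_e: float = 0.2,
    omega: float = 0.5,
    hard_assign: bool = False,
) -> SubspaceBank:
    """Random isotropic initialisation, orthonormalized; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = orthonormalize(rng.standard_normal((n_subspaces, dim, 2)))
    return SubspaceBank(bases, sigma_e=sigma_e, omega=omega, hard_assign=hard_assign)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def _normalize_halves(patches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean / unit-variance per 100-d monocular half.

    Halves with std below 1e-6 are flagged low-contrast and come out as
    (near-)zero vectors instead of amplified noise.
    """
    half = patches.shape[1] // 2
    out = patches.astype(np.float64).copy()
    flat = np.zeros(patches.shape[0], dtype=bool)
    for sl in (slice(0, half), slice(half, None)):
        block = out[:, sl]
        block -= block.mean(axis=1, keepdims=True)
        std = np.sqrt(np.mean(block**2, axis=1))
        flat |= std < _LOW_CONTRAST_STD
        block /= np.maximum(std, _LOW_CONTRAST_STD)[:, None]
    return out, ~flat


def patchify(
    left: np.ndarray, right: np.ndarray, stride: int
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Cut a binocular window pair into normalised 200-d patch vectors.

    Patches are 10x10, taken at the given stride (5 for vergence pooling,
    1 for saliency) on a regular grid; corresponding left/right patches are
    concatenated left-first.  Returns ``(X, active, grid_shape)`` where
    ``X`` is (P, 200), ``active`` flags patches with contrast in both eyes,
    and ``grid_shape`` is the (rows, cols) of the patch grid.
    """
    if left.shape != right.shape:
        raise ValueError("left/right windows differ in size")
    h, w = left.shape
    if h < PATCH_SIZE or w < PATCH_SIZE:
        raise ValueError(f"window {h}x{w} smaller than a {PATCH_SIZE}x{PATCH_SIZE} patch")
    lv = np.lib.stride_tricks.sliding_window_view(left, (PATCH_SIZE, PATCH_SIZE))
    rv = np.lib.stride_tricks.sliding_window_view(right, (PATCH_SIZE, PATCH_SIZE))
    lv = lv[::stride, ::stride]
    rv = rv[::stride, ::stride]
    grid = lv.shape[:2]
    lv = lv.reshape(-1, PATCH_SIZE * PATCH_SIZE)
    rv = rv.reshape(-1, PATCH_SIZE * PATCH_SIZE)
    x, active = _normalize_halves(np.concatenate([lv, rv], axis=1))
    return x, active, grid


# ---------------------------------------------------------------------------
# responses, errors, responsibilities, updates
# ---------------------------------------------------------------------------

def _coefficients(bank: SubspaceBank, patches: np.ndarray) -> np.ndarray:
    """Projection coefficients, shape (P, N, 2)."""
    return np.tensordot(patches, bank.bases, axes=([1], [1]))


def subspace_responses(bank: SubspaceBank, patches: np.ndarray) -> np.ndarray:
    """Squared projection lengths r_n(x) = ||Phi_n^T x||^2, shape (P, N)."""
    patches = np.atleast_2d(patches)
    c = _coefficients(bank, patches)
    return np.einsum("pne,pne->pn", c, c)


def best_subspace_and_error(
    bank: SubspaceBank, patches: np.ndarray, *, responses: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Winning subspace index (ties -> lowest) and its squared residual.

    Under orthonormality the residual is ||x||^2 - r_m(x) >= 0.
    """
    patches = np.atleast_2d(patches)
    if responses is None:
        responses = subspace_responses(bank, patches)
    winners = np.argmax(responses, axis=1)
    energy = np.einsum("pd,pd->p", patches, patches)
    errors = np.maximum(energy - responses[np.arange(len(winners)), winners], 0.0)
    return winners, errors


def scale_error(bank: SubspaceBank, patches: np.ndarray) -> float:
    """Mean best-subspace reconstruction error over a frame's patches."""
    patches = np.atleast_2d(patches)
    if patches.shape[0] == 0:
        raise ValueError("empty patch list")
    _, errors = best_subspace_and_error(bank, patches)
    return float(errors.mean())


def average_error(e_coarse: float, e_medium: float, e_fine: float) -> float:
    """Cross-scale average reconstruction error; its negative is the reward."""
    return (e_coarse + e_medium + e_fine) / 3.0


def responsibilities(
    bank: SubspaceBank,
    responses: np.ndarray,
    prev_winners: np.ndarray | None = None,
) -> np.ndarray:
    """Soft assignment of each patch to subspaces, shape (P, N), rows sum to 1.

    h_n ∝ exp(r_n / (2 sigma_e^2)) * prior, with prior mass ``omega`` on the
    patch's previous winner and (1-omega)/(N-1) elsewhere (uniform when no
    previous winner).  ``hard_assign`` replaces this with one-hot argmax.
    """
    responses = np.atleast_2d(responses)
    p, n = responses.shape
    if bank.hard_assign:
        h = np.zeros((p, n))
        h[np.arange(p), np.argmax(responses, axis=1)] = 1.0
        return h
    log_h = responses / (2.0 * bank.sigma_e**2)
    if prev_winners is not None and n > 1:
        log_prior = np.full((p, n), np.log((1.0 - bank.omega) / (n - 1)))
        log_prior[np.arange(p), prev_winners] = np.log(bank.omega)
        log_h = log_h + log_prior
    log_h -= log_h.max(axis=1, keepdims=True)
    h = np.exp(log_h)
    return h / h.sum(axis=1, keepdims=True)


def update_bank(
    bank: SubspaceBank, patches: np.ndarray, h: np.ndarray, lr: float
) -> SubspaceBank:
    """One rotation step of every subspace toward its responsible patches.

    Delta_Phi_n = sum_j h_nj * resid_jn (x_j^T Phi_n) / (||xhat_jn|| ||x_j||),
    followed by re-orthonormalization.  Patches with zero norm or zero
    projection contribute nothing.  Mutates and returns ``bank``.
    """
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    patches = np.atleast_2d(patches)
    c = _coefficients(bank, patches)  # (P, N, 2)
    cn = np.ascontiguousarray(c.transpose(1, 0, 2))  # (N, P, 2)
    proj = cn @ bank.bases.transpose(0, 2, 1)  # xhat, (N, P, dim)
    resid = patches[None, :, :] - proj
    proj_norm = np.sqrt((cn * cn).sum(axis=-1))  # (N, P)
    x_norm = np.linalg.norm(patches, axis=1)
    denom = proj_norm * x_norm[None, :]
    weight = np.where(denom > 1e-12, h.T / np.maximum(denom, 1e-12), 0.0)
    delta = resid.transpose(0, 2, 1) @ (cn * weight[:, :, None])  # (N, dim, 2)
    bank.bases = orthonormalize(bank.bases + lr * delta)
    return bank
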