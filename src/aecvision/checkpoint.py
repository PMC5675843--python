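"""Checkpoints (HDF5) and image/CSV export."""

from __future__ import annotations

import json

import h5py
import imageio.v3 as iio
import numpy as np

from .gassom import SubspaceBank
from .scenes import StereoFrame, StereoScene
from .simulate import SCALES, ActiveVisionSystem, RunConfig
from .vergence import VergenceLearner, VergencePolicy

__all__ = [
    "save_system",
    "load_system",
    "export_frame_png",
    "load_stereo_png",
    "export_disparity_csv",
    "export_saliency_png",
    "basis_mosaic",
]


def save_system(path, system: ActiveVisionSystem) -> None:
    """Write banks, policy and config to one HDF5 container."""
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in system.config.__dict__.items()}
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(cfg)
        for scale in SCALES:
            g = f.create_group(f"bank_{scale}")
            bank = system.banks[scale]
            g.create_dataset("bases", data=bank.bases)
            g.attrs["sigma_e"] = bank.sigma_e
            g.attrs["omega"] = bank.omega
        p = f.create_group("policy")
        pol = system.learner.policy
        p.create_dataset("theta", data=pol.theta)
        p.create_dataset("v", data=pol.v)
        p.create_dataset("w", data=pol.w)
        p.attrs["b"] = pol.b
        if system.learner.feature_mean is not None:
            p.create_dataset("feature_mean", data=system.learner.feature_mean)
            p.create_dataset("feature_var", data=system.learner.feature_var)


def load_system(path, *, expect_config: RunConfig | None = None) -> ActiveVisionSystem:
    """Rebuild a system from a checkpoint.

    If ``expect_config`` is given and differs from the stored one, raises
    with the list of differing fields.
    """
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg_dict["disparity_range"] = tuple(cfg_dict["disparity_range"])
        config = RunConfig(**cfg_dict)
        if expect_config is not None and (bad := config.diff(expect_config)):
            raise ValueError(f"checkpoint config differs in fields: {bad}")
        banks = {}
        for scale in SCALES:
            g = f[f"bank_{scale}"]
            banks[scale] = SubspaceBank(
                g["bases"][...], float(g.attrs["sigma_e"]), float(g.attrs["omega"])
            )
        p = f["policy"]
        policy = VergencePolicy(
            theta=p["theta"][...], v=p["v"][...], b=float(p.attrs["b"]), w=p["w"][...],
            beta=config.beta, gamma=config.gamma,
            alpha_critic=config.alpha_critic, alpha_actor=config.alpha_actor,
            actor_decay=config.actor_decay,
        )
        fmean = p["feature_mean"][...] if "feature_mean" in p else None
        fvar = p["feature_var"][...] if "feature_var" in p else None
    system = ActiveVisionSystem.fresh(config)
    system.banks = banks
    learner = VergenceLearner(policy, normalize_features=config.normalize_features)
    learner.feature_mean = fmean
    learner.feature_var = fvar
    system.learner = learner
    return system


# ---------------------------------------------------------------------------
# image / CSV export
# ---------------------------------------------------------------------------

def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def export_frame_png(frame: StereoFrame, left_path, right_path) -> None:
    """8-bit grayscale PNGs of the stereo pair."""
    iio.imwrite(left_path, _to_u8(frame.left))
    iio.imwrite(right_path, _to_u8(frame.right))


def load_stereo_png(left_path, right_path) -> StereoFrame:
    """Ingest a user-supplied rectified grayscale pair (no ground truth)."""
    left = np.asarray(iio.imread(left_path), dtype=np.float64)
    right = np.asarray(iio.imread(right_path), dtype=np.float64)
    if left.ndim == 3:
        left = left.mean(axis=2)
    if right.ndim == 3:
        right = right.mean(axis=2)
    if left.shape != right.shape:
        raise ValueError("left and right images differ in size")
    return StereoFrame(left / 255.0, right / 255.0)


def export_disparity_csv(scene: StereoScene, path) -> None:
    np.savetxt(path, scene.disparity_map, fmt="%d", delimiter=",")


def export_saliency_png(saliency: np.ndarray, path) -> None:
    """Linearly rescaled to the full 8-bit range."""
    lo, hi = saliency.min(), saliency.max()
    scaled = (saliency - lo) / (hi - lo) if hi > lo else np.zeros_like(saliency)
    iio.imwrite(path, _to_u8(scaled))


def basis_mosaic(bank: SubspaceBank, *, column: int = 0, patch: int = 10) -> np.ndarray:
    """Tile left-over-right 10x10 halves of one basis column of each subspace."""
    n = bank.n_subspaces
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    tile_h, tile_w = 2 * patch + 1, patch + 1
    out = np.zeros((rows * tile_h, cols * tile_w))
    for i in range(n):
        vec = bank.bases[i, :, column]
        lo, hi = vec.min(), vec.max()
        vec = (vec - lo) / (hi - lo) if hi > lo else vec * 0
        r, c = divmod(i, cols)
        out[r * tile_h:r * tile_h + patch, c * tile_w:c * tile_w + patch] = (
            vec[: patch * patch].reshape(patch, patch)
        )
        out[r * tile_h + patch:r * tile_h + 2 * patch,
            c * tile_w:c * tile_w + patch] = vec[patch * patch:].reshape(patch, patch)
    return out


def write_fixation_log(logs: dict, path) -> None:
    """CSV trace: one row per fixation with start/end retinal disparity."""
    import csv

    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(
            f, fieldnames=["index", "x", "y", "retinal_start", "retinal_end", "shift_end"]
        )
        writer.writeheader()
        for rec in logs["fixations"]:
            writer.writerow(rec)
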