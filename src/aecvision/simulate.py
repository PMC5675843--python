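"""The joint training loop: saccades, fixations, and simultaneous learning.

One simulation step cycles through: sample a saccade target from the
saliency-derived distribution (with inhibition of return), then fixate for
10 frames during which the subspace banks adapt at all three scales, the
vergence policy issues one command per frame, and the actor-critic updates
on every within-fixation transition.  The scene is regenerated every 30
fixations.  The whole pipeline is a pure function of the configuration and
the master seed, which is partitioned into named substreams (scenes, bank
init, action sampling, saccade sampling, feature subsets) so that
different saccade variants can train on identical scene sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import metrics
from . import scenes as sc
from .gassom import (
    PATCH_SIZE,
    SubspaceBank,
    best_subspace_and_error,
    init_bank,
    patchify,
    subspace_responses,
)
from .saccades import FixationHistory, ior_mask, random_saccade_policy, sample_fixation, target_distribution
from .saliency import (
    coarse_response_maps,
    draw_feature_subset,
    embed_full_resolution,
    fixation_to_patch,
    saliency_map,
    subset_cc_curve,
    upsample_saliency,
)
from .vergence import VergenceLearner, init_policy

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ActiveVisionSystem",
    "TrainResult",
    "train",
    "run_frozen",
    "evaluate",
    "compare_policies",
    "stream_rng",
    "SCALES",
]

SCALES = ("C", "M", "F")

VARIANTS = ("random", "gbaim", "lbaim", "aim-mono")

# substream identifiers for the master-seed partition
_STREAMS = {"scenes": 0, "bank": 1, "actions": 2, "saccades": 3, "subsets": 4, "eval": 5}


def stream_rng(master_seed: int, stream: str, index: int | None = None) -> np.random.Generator:
    """A named, reproducible substream of the master seed."""
    key = (_STREAMS[stream],) if index is None else (_STREAMS[stream], index)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass(frozen=True)
class RunConfig:
    """Everything a training run depends on.

    The defaults are the desk-scale profile (320x240 frames, window base
    25, N=64 subspaces) which runs a full joint-training comparison in
    minutes; ``full_scale()`` gives the 640x480 / base-55 / N=324 profile.
    """

    # scene
    width: int = 320
    height: int = 240
    n_planes: int = 5
    disparity_range: tuple[int, int] = (-20, 20)
    texture: str = "pinknoise"
    background_texture: str = "smooth"
    # window geometry
    window_base: int = 25
    max_shift: int = 40
    # perceptual representation
    n_subspaces: int = 64
    learning_rate: float = 0.02
    lr_decay: bool = True
    sigma_e: float = 0.2
    omega: float = 0.5
    # vergence reinforcement learning
    gamma: float = 0.0
    alpha_critic: float = 0.05
    alpha_actor: float = 0.3
    actor_decay: float = 0.002
    beta: float = 1.0
    normalize_features: bool = True
    # saccade control
    variant: str = "lbaim"
    subset_size: int = 25
    saliency_bins: int | None = None
    # protocol
    frames_per_fixation: int = 10
    scene_period: int = 30
    total_fixations: int = 600
    checkpoint_every: int | None = None
    master_seed: int = 0

    @staticmethod
    def full_scale(**overrides) -> "RunConfig":
        base = dict(width=640, height=480, window_base=55, n_subspaces=324)
        base.update(overrides)
        return RunConfig(**base)

    def scene_config(self) -> sc.SceneConfig:
        return sc.SceneConfig(
            width=self.width,
            height=self.height,
            n_planes=self.n_planes,
            disparity_range=self.disparity_range,
            texture=self.texture,
            background_texture=self.background_texture,
        )

    def diff(self, other: "RunConfig") -> list[str]:
        return [
            f.name for f in fields(self)
            if getattr(self, f.name) != getattr(other, f.name)
        ]


@dataclass
class ActiveVisionSystem:
    """The agent: window geometry, three subspace banks, vergence learner."""

    config: RunConfig
    geometry: sc.FixationGeometry
    banks: dict[str, SubspaceBank]
    learner: VergenceLearner

    @staticmethod
    def fresh(config: RunConfig) -> "ActiveVisionSystem":
        geometry = sc.FixationGeometry(config.window_base, config.max_shift)
        geometry.check_frame(config.width, config.height)
        bank_rng = stream_rng(config.master_seed, "bank")
        banks = {
            s: init_bank(
                config.n_subspaces, bank_rng, sigma_e=config.sigma_e, omega=config.omega
            )
            for s in SCALES
        }
        policy = init_policy(
            3 * config.n_subspaces,
            gamma=config.gamma,
            alpha_critic=config.alpha_critic,
            alpha_actor=config.alpha_actor,
            actor_decay=config.actor_decay,
            beta=config.beta,
        )
        learner = VergenceLearner(policy, normalize_features=config.normalize_features)
        return ActiveVisionSystem(config, geometry, banks, learner)

    def copy(self) -> "ActiveVisionSystem":
        system = ActiveVisionSystem(
            self.config, self.geometry, {s: b.copy() for s, b in self.banks.items()},
            VergenceLearner(
                self.learner.policy.copy(),
                normalize_features=self.learner.normalize_features,
                scale_rate=self.learner.scale_rate,
            ),
        )
        if self.learner.feature_mean is not None:
            system.learner.feature_mean = self.learner.feature_mean.copy()
            system.learner.feature_var = self.learner.feature_var.copy()
        return system

    # -- encoding ----------------------------------------------------------

    def encode(self, window_set: sc.WindowSet) -> tuple[np.ndarray, float]:
        """Pooled 3N feature vector and cross-scale mean reconstruction error."""
        pooled = []
        errs = []
        for scale, (left, right) in zip(SCALES, window_set.pairs().values()):
            x, _, _ = patchify(left, right, stride=5)
            resp = subspace_responses(self.banks[scale], x)
            _, e = best_subspace_and_error(self.banks[scale], x, responses=resp)
            pooled.append(resp.mean(axis=0))
            errs.append(float(e.mean()))
        return np.concatenate(pooled), float(np.mean(errs))

    def encode_adapt(self, window_set: sc.WindowSet, lr: float) -> tuple[np.ndarray, float]:
        """Encode and, when lr > 0, run one GASSOM step at every scale."""
        pooled = []
        errs = []
        for scale, (left, right) in zip(SCALES, window_set.pairs().values()):
            x, active, _ = patchify(left, right, stride=5)
            bank = self.banks[scale]
            if lr > 0:
                resp, e = bank.adapt(x, active, lr)
            else:
                resp = subspace_responses(bank, x)
                _, e = best_subspace_and_error(bank, x, responses=resp)
            pooled.append(resp.mean(axis=0))
            errs.append(float(e.mean()))
        return np.concatenate(pooled), float(np.mean(errs))

    # -- saccade targeting -------------------------------------------------

    def saliency_full(
        self,
        frame: sc.StereoFrame,
        shift: int,
        rng: np.random.Generator,
        *,
        variant: str | None = None,
        prev_fix: tuple[int, int] | None = None,
        subset: np.ndarray | None = None,
    ) -> np.ndarray:
        """Full-resolution saliency map of a frame for the given variant."""
        variant = variant or self.config.variant
        left, right, offset = self.geometry.extract_saccade_input(frame, shift)
        bank = self.banks["C"]
        if subset is None:
            size = min(self.config.subset_size, bank.n_subspaces)
            subset = draw_feature_subset(bank.n_subspaces, size, rng)
        maps = coarse_response_maps(
            bank, left, right, feature_ids=subset,
            monocular=(variant == "aim-mono"),
        )
        if variant == "lbaim":
            center_xy = prev_fix if prev_fix is not None else (
                self.config.width // 2, self.config.height // 2
            )
            context = fixation_to_patch(center_xy, offset, maps.grid)
        elif variant in ("gbaim", "aim-mono"):
            context = None
        else:
            raise ValueError(f"unknown saliency variant {variant!r}; options: {VARIANTS}")
        coarse = saliency_map(
            maps, context_center=context, n_bins=self.config.saliency_bins
        )
        up = upsample_saliency(coarse, maps.shape)
        return embed_full_resolution(up, (self.config.height, self.config.width), offset)

    def select_fixation(
        self,
        frame: sc.StereoFrame,
        shift: int,
        history: FixationHistory,
        rng: np.random.Generator,
        *,
        variant: str | None = None,
        prev_fix: tuple[int, int] | None = None,
        subset_rng: np.random.Generator | None = None,
    ) -> tuple[int, int]:
        """Saccade: sample the next fixation point and push it to history."""
        variant = variant or self.config.variant
        margin = self.geometry.margin_mask(self.config.width, self.config.height)
        if variant == "random":
            return random_saccade_policy(margin, rng, history)
        sal = self.saliency_full(
            frame, shift, subset_rng if subset_rng is not None else rng,
            variant=variant, prev_fix=prev_fix,
        )
        shape = (self.config.height, self.config.width)
        dist = target_distribution(sal, ior_mask(history, shape), margin)
        return sample_fixation(dist, rng, history)


@dataclass
class TrainResult:
    system: ActiveVisionSystem
    logs: dict
    checkpoints: list = field(default_factory=list)


def _scene_for(config: RunConfig, scene_index: int) -> sc.StereoScene:
    """Scene ``scene_index`` of the run's scene stream (variant-independent)."""
    return sc.generate_scene(
        config.scene_config(), stream_rng(config.master_seed, "scenes", scene_index)
    )


def train(config: RunConfig, *, system: ActiveVisionSystem | None = None) -> TrainResult:
    """Run the joint learning loop; bit-reproducible per master seed."""
    if system is not None and (bad := system.config.diff(config)):
        raise ValueError(f"resumed system's config differs in fields: {bad}")
    if system is None:
        system = ActiveVisionSystem.fresh(config)
    action_rng = stream_rng(config.master_seed, "actions")
    saccade_rng = stream_rng(config.master_seed, "saccades")
    subset_rng = stream_rng(config.master_seed, "subsets")

    logs: dict = {"e_avg": [], "fixations": [], "scene_indices": []}
    checkpoints: list = []
    history = FixationHistory()
    shift = 0
    total_frames = config.total_fixations * config.frames_per_fixation
    frame_idx = 0
    scene = frame = dmap = None
    prev_fix = None

    for fix_idx in range(config.total_fixations):
        if fix_idx % config.scene_period == 0:
            scene_index = fix_idx // config.scene_period
            scene = _scene_for(config, scene_index)
            frame = sc.render_stereo(scene)
            dmap = scene.disparity_map
            logs["scene_indices"].append(scene_index)

        x, y = system.select_fixation(
            frame, shift, history, saccade_rng,
            prev_fix=prev_fix, subset_rng=subset_rng,
        )
        fix = sc.FixationState(x, y, shift, index=fix_idx)
        for bank in system.banks.values():
            bank.reset_stream()
        system.learner.episode_boundary()
        retinal_start = sc.retinal_disparity(scene, fix)

        for t in range(config.frames_per_fixation):
            if config.lr_decay:
                lr = config.learning_rate * (1.0 - 0.9 * frame_idx / total_frames)
            else:
                lr = config.learning_rate
            ws = system.geometry.extract_vergence_input(frame, fix)
            features, e_avg = system.encode_adapt(ws, lr)
            logs["e_avg"].append(e_avg)
            if t > 0:
                # reward on the fractional-error scale (patch energy is
                # ~2 * patch_size^2 after normalisation), keeping TD
                # magnitudes O(1)
                system.learner.learn(-e_avg / (2.0 * PATCH_SIZE**2), features)
            action = system.learner.act(features, action_rng)
            fix = sc.apply_vergence_action(fix, action, max_shift=config.max_shift)
            frame_idx += 1

        shift = fix.shift
        prev_fix = (x, y)
        logs["fixations"].append({
            "index": fix_idx,
            "x": x,
            "y": y,
            "retinal_start": retinal_start,
            "retinal_end": sc.retinal_disparity(scene, fix),
            "shift_end": shift,
        })
        if config.checkpoint_every and (fix_idx + 1) % config.checkpoint_every == 0:
            checkpoints.append((fix_idx + 1, system.copy()))

    return TrainResult(system, logs, checkpoints)


def run_frozen(
    system: ActiveVisionSystem,
    variant: str,
    n_fixations: int,
    seed: int,
    *,
    scene_seed_offset: int = 10_000,
) -> dict:
    """Behave (saccade + vergence) without any learning; log E_avg per frame.

    Used for the controlled comparison of saccade policies on a fixed
    perceptual representation and vergence policy.  Scenes come from a
    stream disjoint from training via ``scene_seed_offset``.
    """
    config = system.config
    rng = stream_rng(seed, "eval")
    logs: dict = {"e_avg": [], "fixations": []}
    history = FixationHistory()
    shift = 0
    prev_fix = None
    scene = frame = None
    for fix_idx in range(n_fixations):
        if fix_idx % config.scene_period == 0:
            scene = _scene_for(
                replace(config, master_seed=seed),
                scene_seed_offset + fix_idx // config.scene_period,
            )
            frame = sc.render_stereo(scene)
        x, y = system.select_fixation(
            frame, shift, history, rng, variant=variant, prev_fix=prev_fix
        )
        fix = sc.FixationState(x, y, shift, index=fix_idx)
        for t in range(config.frames_per_fixation):
            ws = system.geometry.extract_vergence_input(frame, fix)
            features, e_avg = system.encode(ws)
            logs["e_avg"].append(e_avg)
            pi = system.learner.action_distribution(features)
            action = system.learner.policy.actions[int(rng.choice(len(pi), p=pi))]
            fix = sc.apply_vergence_action(fix, action, max_shift=config.max_shift)
        shift = fix.shift
        prev_fix = (x, y)
        logs["fixations"].append({"index": fix_idx, "x": x, "y": y})
    return logs


def train_representation(
    config: RunConfig,
    spread: float,
    n_fixations: int,
    seed: int,
    *,
    frames_per_fixation: int | None = None,
) -> ActiveVisionSystem:
    """Train the subspace banks alone under controlled disparity statistics.

    At every fixation (uniform over the margin) the shift is set so the
    retinal disparity follows the truncated Laplacian with the given
    spread, isolating the effect of the disparity distribution on the
    learned representation (no vergence policy involved).  Scenes use the
    run's texture family at zero scene disparity so the imposed retinal
    disparity is exact.
    """
    cfg = replace(config, disparity_range=(0, 0), master_seed=seed)
    system = ActiveVisionSystem.fresh(cfg)
    rng = stream_rng(seed, "actions")
    fpf = frames_per_fixation or cfg.frames_per_fixation
    x_lo, x_hi, y_lo, y_hi = system.geometry.margin_bounds(cfg.width, cfg.height)
    total_frames = n_fixations * fpf
    frame_idx = 0
    scene = frame = None
    for fix_idx in range(n_fixations):
        if fix_idx % cfg.scene_period == 0:
            scene = _scene_for(cfg, fix_idx // cfg.scene_period)
            frame = sc.render_stereo(scene)
        x = int(rng.integers(x_lo, x_hi + 1))
        y = int(rng.integers(y_lo, y_hi + 1))
        d = sc.sample_laplacian_disparity(spread, rng)
        shift = int(np.clip(d, -cfg.max_shift, cfg.max_shift))
        fix = sc.FixationState(x, y, shift, index=fix_idx)
        for bank in system.banks.values():
            bank.reset_stream()
        for _ in range(fpf):
            lr = cfg.learning_rate * (1.0 - 0.9 * frame_idx / total_frames) \
                if cfg.lr_decay else cfg.learning_rate
            ws = system.geometry.extract_vergence_input(frame, fix)
            system.encode_adapt(ws, lr)
            frame_idx += 1
    return system


PROTOCOLS = ("rmse", "entropy", "vcurve", "delta-d", "error-decrease", "cc-curve")


def evaluate(system: ActiveVisionSystem, protocol: str, seed: int, **kwargs) -> dict:
    """Run a named evaluation protocol on freshly seeded scenes.

    ``seed`` feeds an evaluation stream disjoint (by stream id) from every
    training stream, so test scenes never coincide with training scenes.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; options: {PROTOCOLS}")
    rng = stream_rng(seed, "eval")
    config = system.config
    report: dict = {"protocol": protocol, "seed": int(seed)}

    if protocol == "rmse":
        report["rmse"] = metrics.policy_rmse(
            system, rng,
            disparities=kwargs.get("disparities", range(-20, 21)),
            reps=kwargs.get("reps", 20),
            iterations=kwargs.get("iterations", 10),
        )
    elif protocol == "entropy":
        scene_list = kwargs.get("scenes") or [
            sc.generate_scene(config.scene_config(), rng)
            for _ in range(kwargs.get("n_scenes", 10))
        ]
        for variant in kwargs.get("variants", ("lbaim", "random")):
            med, sem = metrics.median_fixation_entropy(
                system, variant, scene_list, rng,
                n_fixations=kwargs.get("n_fixations", 10),
            )
            report[f"median_entropy_{variant}"] = med
            report[f"sem_{variant}"] = sem
    elif protocol == "vcurve":
        grid, errors = metrics.reconstruction_error_curve(
            system, rng,
            disparity_grid=kwargs.get("disparity_grid", range(-20, 21, 2)),
            n_scenes=kwargs.get("n_scenes", 20),
        )
        fit = metrics.fit_vcurve(grid, errors)
        report.update({
            "disparities": [int(d) for d in grid],
            "errors": [float(e) for e in errors],
            "slope": fit.slope,
            "fit": {"a": fit.a, "mu": fit.mu, "b": fit.b, "c": fit.c},
        })
    elif protocol == "delta-d":
        scene_list = kwargs.get("scenes") or [
            sc.generate_scene(config.scene_config(), rng)
            for _ in range(kwargs.get("n_scenes", 5))
        ]
        fps = kwargs.get("fixations_per_scene", 10)
        for variant in kwargs.get("variants", ("lbaim", "random")):
            report[f"delta_d_{variant}"] = metrics.expected_disparity_difference(
                system, scene_list, variant, rng, fixations_per_scene=fps
            )
        if "delta_d_random" in report and report["delta_d_random"] > 0:
            for variant in kwargs.get("variants", ("lbaim", "random")):
                report[f"ratio_{variant}"] = (
                    report[f"delta_d_{variant}"] / report["delta_d_random"]
                )
    elif protocol == "error-decrease":
        n_fix = kwargs.get("n_fixations", 100)
        for variant in kwargs.get("variants", ("lbaim", "random")):
            logs = run_frozen(system, variant, n_fix, seed)
            summary = metrics.fixation_error_decrease(
                np.array(logs["e_avg"]),
                frames_per_fixation=config.frames_per_fixation,
                window=kwargs.get("window", 3000),
            )
            report[f"mean_decrease_{variant}"] = summary["mean"]
    elif protocol == "cc-curve":
        scene_list = kwargs.get("scenes") or [
            sc.generate_scene(config.scene_config(), rng)
            for _ in range(kwargs.get("n_scenes", 3))
        ]
        maps_list = []
        for scene in scene_list:
            frame = sc.render_stereo(scene)
            left, right, _ = system.geometry.extract_saccade_input(frame, 0)
            maps_list.append(coarse_response_maps(system.banks["C"], left, right))
        curve = subset_cc_curve(
            maps_list,
            kwargs.get("sizes", [1, 5, 25, min(100, config.n_subspaces), config.n_subspaces]),
            kwargs.get("reps", 3),
            rng,
            n_bins=config.saliency_bins,
        )
        report["cc"] = {str(k): {"mean": v[0], "sem": v[1]} for k, v in curve.items()}
    return report


def compare_policies(
    config: RunConfig,
    variants=("random", "lbaim"),
    n_seeds: int = 3,
    *,
    eval_seed: int = 999,
    rmse_kwargs: dict | None = None,
) -> dict:
    """Train each saccade variant on identical scene streams; compare RMSE.

    Replicate ``k`` of every variant shares master seed ``master_seed + k``
    and therefore the exact same scene sequence; only the saccade targeting
    differs.  Reports initial and final vergence-policy RMSE per run.
    """
    rmse_kwargs = rmse_kwargs or {}
    out: dict = {"variants": {}, "initial": []}
    for k in range(n_seeds):
        seed = config.master_seed + k
        fresh = ActiveVisionSystem.fresh(replace(config, master_seed=seed))
        out["initial"].append(
            metrics.policy_rmse(fresh, stream_rng(eval_seed, "eval", k), **rmse_kwargs)
        )
    for variant in variants:
        runs = []
        for k in range(n_seeds):
            run_cfg = replace(config, variant=variant, master_seed=config.master_seed + k)
            result = train(run_cfg)
            rmse = metrics.policy_rmse(
                result.system, stream_rng(eval_seed, "eval", k), **rmse_kwargs
            )
            runs.append({"master_seed": run_cfg.master_seed, "rmse_final": rmse})
        finals = [r["rmse_final"] for r in runs]
        out["variants"][variant] = {
            "runs": runs,
            "rmse_mean": float(np.mean(finals)),
            "rmse_sd": float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0,
        }
    out["initial_mean"] = float(np.mean(out["initial"]))
    return out
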