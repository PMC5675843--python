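"""Evaluation protocols for the trained active-vision system.

Every protocol here consumes a (possibly frozen) system object exposing
``geometry``, ``banks``, ``learner``, ``encode`` and ``select_fixation``
plus freshly seeded synthetic scenes, and reduces a simulation to one
number or curve: vergence-policy RMSE, fixation-window entropy,
reconstruction error versus retinal disparity (the "V" curve) and its
exponential-notch fit, the expected absolute disparity difference between
successive fixations, and the within-fixation decrease in reconstruction
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import scenes as sc
from .saccades import FixationHistory

__all__ = [
    "VCurveFit",
    "policy_rmse",
    "window_entropy",
    "median_fixation_entropy",
    "reconstruction_error_curve",
    "fit_vcurve",
    "expected_disparity_difference",
    "fixation_error_decrease",
]


# ---------------------------------------------------------------------------
# test-scene helpers
# ---------------------------------------------------------------------------

def _flat_scene(system, rng: np.random.Generator, *, disparity: int = 0) -> sc.StereoScene:
    """A single full-frame textured plane: constant ground-truth disparity."""
    cfg = sc.SceneConfig(
        width=system.config.width,
        height=system.config.height,
        n_planes=0,
        background_texture=system.config.texture,
        background_disparity=disparity,
    )
    return sc.generate_scene(cfg, rng)


def _random_margin_point(system, rng: np.random.Generator) -> tuple[int, int]:
    x_lo, x_hi, y_lo, y_hi = system.geometry.margin_bounds(
        system.config.width, system.config.height
    )
    return int(rng.integers(x_lo, x_hi + 1)), int(rng.integers(y_lo, y_hi + 1))


# ---------------------------------------------------------------------------
# vergence policy quality
# ---------------------------------------------------------------------------

def policy_rmse(
    system,
    seed: int | np.random.Generator,
    *,
    disparities=range(-20, 21),
    reps: int = 100,
    iterations: int = 10,
    action_selector=None,
) -> float:
    """RMS final retinal disparity of the frozen policy, in pixels.

    Single-plane (fronto-parallel) scenes are shown at every initial
    disparity in ``disparities``, ``reps`` textures per disparity; the
    policy runs for ``iterations`` vergence commands and the residual
    retinal disparity is recorded.  ``action_selector(features, retinal,
    rng) -> action px`` overrides the learned policy (used e.g. for the
    analytically ideal policy).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if action_selector is None:
        def action_selector(features, retinal, rng_):
            pi = system.learner.action_distribution(features)
            return system.learner.policy.actions[int(rng_.choice(len(pi), p=pi))]

    sq_sum = 0.0
    count = 0
    for _ in range(reps):
        scene = _flat_scene(system, rng)
        frame = sc.render_stereo(scene)
        x, y = _random_margin_point(system, rng)
        for d0 in disparities:
            fix = sc.FixationState(x, y, shift=int(d0))
            for _ in range(iterations):
                ws = system.geometry.extract_vergence_input(frame, fix)
                features, _ = system.encode(ws)
                action = action_selector(features, fix.shift, rng)
                fix = sc.apply_vergence_action(
                    fix, action, max_shift=system.geometry.max_shift
                )
            sq_sum += float(fix.shift) ** 2  # scene disparity is 0 everywhere
            count += 1
    return float(np.sqrt(sq_sum / count))


def ideal_action_selector(features, retinal, rng):
    """The analytically ideal policy: the step bringing |retinal| closest to 0."""
    steps = np.array(sc.VERGENCE_ACTIONS)
    return int(steps[np.argmin(np.abs(retinal + steps))])


# ---------------------------------------------------------------------------
# fixation entropy
# ---------------------------------------------------------------------------

def window_entropy(window: np.ndarray, *, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram of one window.

    Intensities in [0, 1] are quantised to ``n_bins`` equal-width levels;
    the result lies in [0, log2(n_bins)] and is 0 for a constant window.
    """
    hist, _ = np.histogram(window, bins=n_bins, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def median_fixation_entropy(
    system,
    variant: str,
    scene_list,
    seed: int | np.random.Generator,
    *,
    n_fixations: int = 10,
) -> tuple[float, float]:
    """Median L/R-averaged fine-window entropy at policy-chosen fixations.

    Runs the frozen saccade + vergence system for ``n_fixations`` per scene
    and pools the per-fixation entropies; returns (median, SEM).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entropies = []
    for scene in scene_list:
        frame = sc.render_stereo(scene)
        history = FixationHistory()
        shift = 0
        prev_fix = None
        for _ in range(n_fixations):
            x, y = system.select_fixation(
                frame, shift, history, rng, variant=variant, prev_fix=prev_fix
            )
            fix = sc.FixationState(x, y, shift)
            ws = system.geometry.extract_vergence_input(frame, fix)
            left, right = ws.fine
            entropies.append(0.5 * (window_entropy(left) + window_entropy(right)))
            for _ in range(system.config.frames_per_fixation):
                ws = system.geometry.extract_vergence_input(frame, fix)
                features, _ = system.encode(ws)
                pi = system.learner.action_distribution(features)
                action = system.learner.policy.actions[int(rng.choice(len(pi), p=pi))]
                fix = sc.apply_vergence_action(
                    fix, action, max_shift=system.geometry.max_shift
                )
            shift = fix.shift
            prev_fix = (x, y)
    arr = np.array(entropies)
    sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return float(np.median(arr)), float(sem)


# ---------------------------------------------------------------------------
# reconstruction error vs disparity ("V" curve)
# ---------------------------------------------------------------------------

def reconstruction_error_curve(
    system,
    seed: int | np.random.Generator,
    *,
    disparity_grid=range(-20, 21, 2),
    n_scenes: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean cross-scale reconstruction error as a function of retinal disparity.

    Fronto-parallel test scenes are viewed with the shift set so the
    retinal disparity equals each grid value in turn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.array(list(disparity_grid))
    errors = np.zeros((n_scenes, len(grid)))
    for i in range(n_scenes):
        scene = _flat_scene(system, rng)
        frame = sc.render_stereo(scene)
        x, y = _random_margin_point(system, rng)
        for k, d in enumerate(grid):
            fix = sc.FixationState(x, y, shift=int(d))
            ws = system.geometry.extract_vergence_input(frame, fix)
            _, e_avg = system.encode(ws)
            errors[i, k] = e_avg
    return grid, errors.mean(axis=0)


@dataclass(frozen=True)
class VCurveFit:
    """Fit of f(d) = c - a*exp(-|d - mu| / b); sharpness is the slope a/b."""

    a: float
    mu: float
    b: float
    c: float
    residual: float

    @property
    def slope(self) -> float:
        return self.a / self.b


def fit_vcurve(disparities: np.ndarray, errors: np.ndarray) -> VCurveFit:
    """Nonlinear least-squares fit of the exponential-notch "V" model."""
    d = np.asarray(disparities, dtype=np.float64)
    e = np.asarray(errors, dtype=np.float64)
    if len(d) < 6:
        raise ValueError("need at least 6 grid points to fit the V curve")

    def model(x, a, mu, b, c):
        return c - a * np.exp(-np.abs(x - mu) / b)

    p0 = [float(e.max() - e.min()), float(d[np.argmin(e)]), 5.0, float(e.max())]
    bounds = ([0.0, float(d.min()), 1e-9, -np.inf], [np.inf, float(d.max()), np.inf, np.inf])
    try:
        popt, _ = curve_fit(model, d, e, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"V-curve fit failed to converge: {err}") from err
    resid = float(np.linalg.norm(model(d, *popt) - e))
    return VCurveFit(float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), resid)


# ---------------------------------------------------------------------------
# expected disparity difference between successive fixations
# ---------------------------------------------------------------------------

def expected_disparity_difference(
    system,
    scene_list,
    variant: str,
    seed: int | np.random.Generator,
    *,
    fixations_per_scene: int = 10,
) -> float:
    """Mean expected |disparity(next) - disparity(current)| under a variant.

    Current fixations are drawn uniformly over the valid margin (assumed
    fused: shift = scene disparity there).  The expectation over next
    fixations is computed exactly from the saccade-target distribution
    without IOR; the ``random`` variant uses the uniform distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = system.config.height, system.config.width
    margin = system.geometry.margin_mask(w, h)
    total = 0.0
    count = 0
    for scene in scene_list:
        frame = sc.render_stereo(scene)
        dmap = scene.disparity_map.astype(np.float64)
        for _ in range(fixations_per_scene):
            x, y = _random_margin_point(system, rng)
            d_here = dmap[y, x]
            if variant == "random":
                dist = margin / margin.sum()
            else:
                sal = system.saliency_full(
                    frame, int(d_here), rng, variant=variant, prev_fix=(x, y)
                )
                masked = sal * margin
                if masked.sum() <= 0:
                    dist = margin / margin.sum()
                else:
                    dist = masked / masked.sum()
            total += float((np.abs(dmap - d_here) * dist).sum())
            count += 1
    return total / count


# ---------------------------------------------------------------------------
# within-fixation error decrease
# ---------------------------------------------------------------------------

def fixation_error_decrease(
    e_trace: np.ndarray,
    *,
    frames_per_fixation: int = 10,
    window: int = 3000,
) -> dict:
    """Per-fixation normalized decrease of E_avg and its running average.

    The decrease for one fixation is (E_start - E_end) / E_start; fixations
    with E_start = 0 are excluded but counted.  The running average uses a
    trailing window of ``window`` fixations (shorter at the start).
    """
    e = np.asarray(e_trace, dtype=np.float64)
    n_fix = len(e) // frames_per_fixation
    e = e[: n_fix * frames_per_fixation].reshape(n_fix, frames_per_fixation)
    start = e[:, 0]
    end = e[:, -1]
    valid = start > 0
    decrease = np.zeros(n_fix)
    decrease[valid] = (start[valid] - end[valid]) / start[valid]
    vals = decrease[valid]
    running = np.array([
        vals[max(0, i - window + 1): i + 1].mean() for i in range(len(vals))
    ]) if len(vals) else np.array([])
    return {
        "per_fixation": vals,
        "running_average": running,
        "mean": float(vals.mean()) if len(vals) else float("nan"),
        "excluded": int((~valid).sum()),
    }
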