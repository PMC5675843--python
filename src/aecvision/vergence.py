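"""Vergence control: linear-softmax policy over pooled subspace responses.

The state is the 3N-dimensional vector of per-feature mean responses across
the patch grid at the three scales (coarse, medium, fine — 972-d at the
full-scale N=324 configuration).  An actor maps it through a linear layer
and a softmax (temperature 1) to a distribution over the 11 discrete pixel
vergence actions.  Learning follows a natural actor-critic scheme: a linear
TD(0) critic supplies the TD error, a compatible-feature regression
estimates the natural gradient, and the actor steps along it.  The reward
is the negative cross-scale reconstruction error, so the policy learns to
move the eyes into configurations the subspace code represents well.
Updates happen only within fixations, never across saccades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenes import VERGENCE_ACTIONS

__all__ = [
    "VergencePolicy",
    "VergenceLearner",
    "init_policy",
    "pooled_features",
    "policy_distribution",
    "sample_action",
    "modal_action",
    "reward_from_error",
    "nac_step",
]


def pooled_features(
    resp_coarse: np.ndarray, resp_medium: np.ndarray, resp_fine: np.ndarray
) -> np.ndarray:
    """Concatenate per-feature mean responses, scales ordered C, M, F."""
    pooled = []
    for name, resp in (("coarse", resp_coarse), ("medium", resp_medium), ("fine", resp_fine)):
        if resp is None:
            raise ValueError(f"missing response map for scale {name!r}")
        pooled.append(np.atleast_2d(resp).mean(axis=0))
    return np.concatenate(pooled)


@dataclass
class VergencePolicy:
    """Actor/critic parameters for the discrete vergence task.

    gamma is deliberately small: within a 10-frame fixation the task is
    nearly a contextual bandit, and a short horizon keeps the critic easy.
    """

    theta: np.ndarray                 # (F, n_actions) actor weights
    v: np.ndarray                     # (F,) critic weights
    b: float = 0.0                    # critic bias
    w: np.ndarray = None              # (F, n_actions) natural-gradient weights
    beta: float = 1.0                 # softmax temperature
    gamma: float = 0.3
    alpha_critic: float = 0.01
    alpha_actor: float = 0.005
    actor_decay: float = 0.002        # L2 pull of theta toward the uniform policy
    actions: tuple[int, ...] = VERGENCE_ACTIONS

    def __post_init__(self):
        if self.w is None:
            self.w = np.zeros_like(self.theta)

    @property
    def feature_dim(self) -> int:
        return self.theta.shape[0]

    @property
    def n_actions(self) -> int:
        return self.theta.shape[1]

    def copy(self) -> "VergencePolicy":
        return VergencePolicy(
            self.theta.copy(), self.v.copy(), self.b, self.w.copy(),
            self.beta, self.gamma, self.alpha_critic, self.alpha_actor,
            self.actor_decay, self.actions,
        )


def init_policy(
    feature_dim: int,
    *,
    n_actions: int = len(VERGENCE_ACTIONS),
    gamma: float = 0.3,
    alpha_critic: float = 0.01,
    alpha_actor: float = 0.005,
    actor_decay: float = 0.002,
    beta: float = 1.0,
    actions: tuple[int, ...] = VERGENCE_ACTIONS,
) -> VergencePolicy:
    """Fresh policy: zero weights, i.e. a uniform action distribution."""
    return VergencePolicy(
        theta=np.zeros((feature_dim, n_actions)),
        v=np.zeros(feature_dim),
        gamma=gamma,
        alpha_critic=alpha_critic,
        alpha_actor=alpha_actor,
        actor_decay=actor_decay,
        beta=beta,
        actions=actions,
    )


def policy_distribution(policy: VergencePolicy, features: np.ndarray) -> np.ndarray:
    """Softmax(theta^T r / beta) with max-subtraction for overflow safety."""
    features = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(features)):
        bad = int(np.flatnonzero(~np.isfinite(features))[0])
        raise ValueError(f"non-finite pooled feature at index {bad}")
    z = features @ policy.theta / policy.beta
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def sample_action(pi: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an action index from the policy distribution."""
    return int(rng.choice(len(pi), p=pi))


def modal_action(policy: VergencePolicy, features: np.ndarray) -> int:
    """Greedy action value (px); ties break to the lowest index."""
    pi = policy_distribution(policy, features)
    return policy.actions[int(np.argmax(pi))]


def reward_from_error(e_avg: float) -> float:
    """Instantaneous reward: the negative average reconstruction error."""
    return -float(e_avg)


def nac_step(
    policy: VergencePolicy,
    features: np.ndarray,
    action: int,
    reward: float,
    next_features: np.ndarray,
) -> float:
    """One natural actor-critic update on a within-fixation transition.

    TD(0) critic on V(r) = v.r + b; compatible features
    psi(a, r) = (1_a - pi(r)) outer r; natural-gradient weights ``w``
    regressed toward the TD error along psi; actor stepped by alpha_a * w.
    Returns the TD error.  ``action`` is the action *index*.
    """
    r = np.asarray(features, dtype=np.float64)
    r2 = np.asarray(next_features, dtype=np.float64)
    value = policy.v @ r + policy.b
    next_value = policy.v @ r2 + policy.b
    delta = reward + policy.gamma * next_value - value

    policy.v = policy.v + policy.alpha_critic * delta * r
    policy.b = policy.b + policy.alpha_critic * delta

    pi = policy_distribution(policy, r)
    score = -pi
    score[action] += 1.0
    psi = np.outer(r, score)  # (F, n_actions)
    policy.w = policy.w + policy.alpha_critic * (delta - np.vdot(psi, policy.w)) * psi
    if policy.alpha_actor > 0:
        # the small decay bounds ||theta|| (keeping the softmax away from
        # saturation, i.e. exploration alive) without changing the
        # gradient direction
        policy.theta = (1.0 - policy.actor_decay) * policy.theta \
            + policy.alpha_actor * policy.w
    return float(delta)


class VergenceLearner:
    """Stateful wrapper: feature scaling, pending transitions, boundaries.

    ``act`` records the (scaled) features and chosen action; ``learn``
    consumes them with the next frame's reward and features — calling it
    with nothing pending (e.g. across a saccade) is an error.
    ``episode_boundary`` drops the pending transition so no update ever
    spans a saccade; the weights are untouched.
    """

    def __init__(self, policy: VergencePolicy, *, normalize_features: bool = True,
                 scale_rate: float = 0.01):
        self.policy = policy
        self.normalize_features = normalize_features
        self.scale_rate = scale_rate
        self.feature_mean: np.ndarray | None = None
        self.feature_var: np.ndarray | None = None
        self.n_updates = 0
        self._pending: tuple[np.ndarray, int] | None = None

    # kept for checkpoint compatibility: a scalar summary of the statistics
    @property
    def feature_scale(self):
        return None if self.feature_mean is None else float(self.feature_mean.mean())

    def _prepare(self, features: np.ndarray, *, update_scale: bool) -> np.ndarray:
        """Per-feature running z-score, scaled so ||r|| is O(1).

        Pooled responses are nonnegative with a large common-mode component;
        standardising them keeps the critic's effective step size
        (alpha * ||r||^2) stable independent of the feature dimension.
        """
        r = np.asarray(features, dtype=np.float64)
        if not self.normalize_features:
            return r
        if self.feature_mean is None:
            self.feature_mean = r.copy()
            self.feature_var = np.ones_like(r)
        elif update_scale:
            delta = r - self.feature_mean
            self.feature_mean += self.scale_rate * delta
            self.feature_var += self.scale_rate * (delta**2 - self.feature_var)
        sd = np.sqrt(np.maximum(self.feature_var, 1e-12))
        return (r - self.feature_mean) / (sd * np.sqrt(len(r)))

    def action_distribution(self, features: np.ndarray) -> np.ndarray:
        return policy_distribution(self.policy, self._prepare(features, update_scale=False))

    def act(self, features: np.ndarray, rng: np.random.Generator) -> int:
        """Choose a vergence action (pixel value) and stage the transition.

        A frame with no foveal contrast (all-zero pooled responses, e.g. a
        texture-free surface fills every window) carries no visual state:
        it is staged as invalid and produces no learning.
        """
        valid = bool(np.any(features))
        r = self._prepare(features, update_scale=valid)
        idx = sample_action(policy_distribution(self.policy, r), rng)
        self._pending = (r, idx, valid)
        return self.policy.actions[idx]

    def learn(self, reward: float, next_features: np.ndarray) -> float | None:
        """Update from the staged transition; only valid within a fixation.

        Returns the TD error, or None when either endpoint of the
        transition was a no-signal frame (no update is made).
        """
        if self._pending is None:
            raise RuntimeError(
                "no staged transition: nac updates may not cross a saccade boundary"
            )
        r, idx, valid = self._pending
        self._pending = None
        if not (valid and np.any(next_features)):
            return None
        r2 = self._prepare(next_features, update_scale=False)
        self.n_updates += 1
        return nac_step(self.policy, r, idx, reward, r2)

    def episode_boundary(self) -> None:
        """Clear cross-step learning state at a saccade; weights untouched."""
        self._pending = None
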