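"""The dual-module learner: convolutional encoder Z_w plus relational scalar θ.

The representational module encodes each image of a pair to one scalar; the
difference ΔZ = Z(right) − Z(left) is compared against the relational
expectation θ through the ring-regularized loss

    L(w, θ) = (ΔZ − θ)² + λ (ΔZ² + θ² − r²)²

whose global minima lie where the line ΔZ = θ meets the ring
ΔZ² + θ² = r², i.e. at ±(r/√2, r/√2).  Both w and θ are trained by plain
SGD with a single learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ConvEncoder
from .stimuli import ImagePair

__all__ = ["Hyperparams", "AgentState", "init_agent", "delta_z",
           "pair_loss", "order_decision", "train_on_batch", "batch_images"]


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters (defaults are the reference configuration)."""

    lambda_reg: float = 4.0    # ring-regularization weight λ
    r_sq: float = 0.1          # ring radius squared r²
    learning_rate: float = 0.004
    batch_size: int = 2        # image pairs per batch
    steps_per_batch: int = 20  # SGD steps on each batch

    def __post_init__(self):
        if self.lambda_reg <= 0 or self.r_sq <= 0:
            raise ValueError("lambda_reg and r_sq must be positive")


@dataclass
class AgentState:
    """Trainable state: encoder weights w and the relational scalar θ."""

    encoder: ConvEncoder
    theta: float

    def copy(self) -> "AgentState":
        return AgentState(encoder=self.encoder.copy(), theta=self.theta)

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {k: v for k, v in self.encoder.params.items()}
        np.savez(path, theta=np.float64(self.theta),
                 side=np.int64(self.encoder.side), **arrays)

    @classmethod
    def load(cls, path) -> "AgentState":
        with np.load(path) as data:
            enc = ConvEncoder(side=int(data["side"]))
            enc.params = {k: data[k].copy() for k in data.files
                          if k not in ("theta", "side")}
            return cls(encoder=enc, theta=float(data["theta"]))


def init_agent(seed: int, side: int = 224) -> AgentState:
    """Fresh agent: every weight uniform on ±1/√(fan-in); θ on ±1 (fan-in 1)."""
    rng = np.random.default_rng(seed)
    enc = ConvEncoder(side=side, rng=rng)
    theta = float(rng.uniform(-1.0, 1.0))
    return AgentState(encoder=enc, theta=theta)


def batch_images(pairs: list[ImagePair]) -> np.ndarray:
    """Stack pairs into a (2·n, side, side) batch, left then right per pair."""
    imgs = []
    for p in pairs:
        imgs.append(p.left_image)
        imgs.append(p.right_image)
    return np.stack(imgs)


def delta_z(state: AgentState, pair: ImagePair) -> float:
    """ΔZ = Z(right) − Z(left)."""
    z = state.encoder.forward(batch_images([pair]))
    return float(z[1] - z[0])


def delta_z_many(state: AgentState, pairs: list[ImagePair],
                 chunk: int = 2) -> np.ndarray:
    """ΔZ for many pairs, batched in chunks to bound workspace memory."""
    out = np.empty(len(pairs))
    for i in range(0, len(pairs), chunk):
        z = state.encoder.forward(batch_images(pairs[i:i + chunk]))
        out[i:i + chunk] = z[1::2] - z[0::2]
    return out


def _loss_value(dz: float, theta: float, hyper: Hyperparams) -> float:
    ring = dz * dz + theta * theta - hyper.r_sq
    return (dz - theta) ** 2 + hyper.lambda_reg * ring * ring


def pair_loss(state: AgentState, pair: ImagePair, hyper: Hyperparams) -> float:
    """Ring-regularized loss (ΔZ − θ)² + λ(ΔZ² + θ² − r²)² for one pair."""
    return _loss_value(delta_z(state, pair), state.theta, hyper)


def order_decision(state: AgentState, pair: ImagePair,
                   hyper: Hyperparams) -> bool:
    """True iff the presented order has strictly lower loss than its reverse.

    Ties (a measure-zero event) count as incorrect.
    """
    dz = delta_z(state, pair)
    return _loss_value(dz, state.theta, hyper) < \
        _loss_value(-dz, state.theta, hyper)


def decisions_from_delta_z(dzs: np.ndarray, theta: float,
                           hyper: Hyperparams) -> np.ndarray:
    """Vectorized order decisions given probe ΔZ values."""
    ring = dzs ** 2 + theta ** 2 - hyper.r_sq  # same for both orders
    fwd = (dzs - theta) ** 2 + hyper.lambda_reg * ring ** 2
    rev = (-dzs - theta) ** 2 + hyper.lambda_reg * ring ** 2
    return fwd < rev


def train_on_batch(state: AgentState, pairs: list[ImagePair],
                   hyper: Hyperparams) -> float:
    """Apply `steps_per_batch` SGD steps on one batch of image pairs.

    The batch loss is the mean of the per-pair losses; θ and the encoder
    weights share the single SGD learning rate.  Returns the batch loss
    before the last step.
    """
    imgs = batch_images(pairs)
    n = len(pairs)
    lr = hyper.learning_rate
    lam = hyper.lambda_reg
    loss = np.nan
    for _ in range(hyper.steps_per_batch):
        theta = state.theta
        # one forward to get ΔZ, then analytic loss gradients through ΔZ
        z = state.encoder.forward(imgs)
        dzs = z[1::2] - z[0::2]
        ring = dzs ** 2 + theta ** 2 - hyper.r_sq
        loss = float(np.mean((dzs - theta) ** 2 + lam * ring ** 2))
        g_dz = (2.0 * (dzs - theta) + 4.0 * lam * ring * dzs) / n
        g_theta = float(np.sum(-2.0 * (dzs - theta) + 4.0 * lam * ring * theta) / n)
        dz_vec = np.empty(2 * n)
        dz_vec[0::2] = -g_dz
        dz_vec[1::2] = g_dz
        grads = state.encoder.backward_from_last(dz_vec)
        state.encoder.sgd_step(grads, lr)
        state.theta = theta - lr * g_theta
    return loss
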