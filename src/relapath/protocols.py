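"""Training protocols: initial learning, rule reversal, intermediate steps.

An experiment is a sequence of phases.  Each phase draws a fresh stream of
image pairs under one rule α, consumes them in batches of
``Hyperparams.batch_size`` with ``steps_per_batch`` SGD steps per batch, and
records a checkpoint after every batch.  θ (free to read) is recorded at
every checkpoint; the probe quantities — mean ΔZ and order accuracy over a
held-out 32-pair set drawn from the current phase's rule — are evaluated on
a configurable schedule, because each probe costs 64 encoder passes.
Checkpoints where no probe ran carry NaN in the probe fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dual_module import (AgentState, Hyperparams, decisions_from_delta_z,
                          delta_z_many, init_agent, train_on_batch)
from .stimuli import TaskConfig, make_phase

__all__ = ["ProbeSchedule", "Checkpoint", "Trajectory", "train_phase",
           "run_phases", "run_reversal", "run_intermediate", "stimulus_seed"]

FAILED_LEARNER_ACCURACY = 0.75   # phase-1 accuracy below this flags the agent


@dataclass(frozen=True)
class ProbeSchedule:
    """When to evaluate the 32-pair probe along a phase.

    Probes always run on the first and last batch of a phase; in between
    they run every batch while ``pairs_seen`` (within the phase) is at most
    ``dense_until_pairs`` and every ``every_batches`` batches afterwards.
    """

    dense_until_pairs: int = 48
    every_batches: int = 8

    def active(self, batch_idx: int, n_batches: int, batch_size: int) -> bool:
        if batch_idx == 0 or batch_idx == n_batches - 1:
            return True
        if (batch_idx + 1) * batch_size <= self.dense_until_pairs:
            return True
        return (batch_idx + 1) % self.every_batches == 0


@dataclass
class Checkpoint:
    pairs_seen: int          # cumulative over the whole experiment
    phase: int
    theta: float
    batch_loss: float
    mean_dz: float = np.nan  # probe mean ΔZ (NaN when not probed)
    accuracy: float = np.nan


@dataclass
class Trajectory:
    """Per-agent record of an experiment (one or more phases)."""

    agent_seed: int
    alphas: list[float] = field(default_factory=list)
    checkpoints: list[Checkpoint] = field(default_factory=list)
    phase_boundaries: list[int] = field(default_factory=list)  # pairs_seen at switches
    flagged_failed: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(c) for c in self.checkpoints])
        df["agent_seed"] = self.agent_seed
        return df

    # -- convenience accessors --------------------------------------------

    def phase_end(self, phase: int) -> Checkpoint:
        """Last checkpoint of a phase (probe fields guaranteed present)."""
        cps = [c for c in self.checkpoints if c.phase == phase]
        if not cps:
            raise ValueError(f"no checkpoints for phase {phase}")
        return cps[-1]

    def phase_start(self, phase: int) -> Checkpoint:
        return [c for c in self.checkpoints if c.phase == phase][0]

    @property
    def n_phases(self) -> int:
        return len(self.alphas)


def probe(state: AgentState, test_pairs, hyper: Hyperparams):
    """Mean ΔZ and order accuracy over a held-out probe set."""
    dzs = delta_z_many(state, test_pairs)
    acc = float(np.mean(decisions_from_delta_z(dzs, state.theta, hyper)))
    return float(np.mean(dzs)), acc


def train_phase(state: AgentState, train_pairs, test_pairs,
                hyper: Hyperparams, trajectory: Trajectory, phase: int,
                alpha: float, schedule: ProbeSchedule | None = None) -> None:
    """Train on one phase's pair sequence in order, appending checkpoints.

    A zero-length phase leaves the state untouched.
    """
    schedule = schedule or ProbeSchedule()
    bs = hyper.batch_size
    start = trajectory.checkpoints[-1].pairs_seen if trajectory.checkpoints else 0
    trajectory.alphas.append(alpha)
    if phase > 0:
        trajectory.phase_boundaries.append(start)
    n_batches = len(train_pairs) // bs
    for b in range(n_batches):
        batch = train_pairs[b * bs:(b + 1) * bs]
        loss = train_on_batch(state, batch, hyper)
        cp = Checkpoint(pairs_seen=start + (b + 1) * bs, phase=phase,
                        theta=state.theta, batch_loss=loss)
        if schedule.active(b, n_batches, bs):
            cp.mean_dz, cp.accuracy = probe(state, test_pairs, hyper)
        trajectory.checkpoints.append(cp)


def stimulus_seed(base_seed: int, agent_index: int, phase: int) -> int:
    """Deterministic stimulus seed, independent of the agent-init stream."""
    ss = np.random.SeedSequence([base_seed, agent_index, phase])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_phases(alphas, n_agents: int, hyper: Hyperparams, base_seed: int = 0,
               side: int = 224, predictive_feature: str = "size",
               n_pairs: int = 160, n_test_pairs: int = 32,
               schedule: ProbeSchedule | None = None,
               return_states: bool = False):
    """Train ``n_agents`` fresh agents through the phase sequence ``alphas``.

    Agent i is initialized from seed ``base_seed + i``; each phase uses an
    independent stimulus stream.  Agents whose end-of-phase-1 accuracy is
    below the failed-learner margin are flagged (not dropped).
    """
    out, states = [], []
    for i in range(n_agents):
        state = init_agent(base_seed + i, side=side)
        traj = Trajectory(agent_seed=base_seed + i)
        for ph, alpha in enumerate(alphas):
            cfg = TaskConfig(predictive_feature=predictive_feature,
                             alpha=float(alpha), n_train_pairs=n_pairs,
                             n_test_pairs=n_test_pairs, image_side=side,
                             seed=stimulus_seed(base_seed, i, ph))
            train, test = make_phase(cfg)
            train_phase(state, train, test, hyper, traj, ph, float(alpha),
                        schedule)
            if ph == 0 and traj.checkpoints:
                traj.flagged_failed = \
                    traj.phase_end(0).accuracy < FAILED_LEARNER_ACCURACY
        state.encoder.release_workspaces()
        out.append(traj)
        states.append(state)
    return (out, states) if return_states else out


def run_reversal(alpha_1: float, alpha_2: float, n_agents: int,
                 hyper: Hyperparams, base_seed: int = 0, **kw):
    """Rule reversal +α₁ → −α₂ (160 pairs each by default)."""
    if alpha_1 <= 0 or alpha_2 <= 0:
        raise ValueError("alpha_1 and alpha_2 must be positive")
    return run_phases([alpha_1, -alpha_2], n_agents, hyper, base_seed, **kw)


def run_intermediate(alpha: float, beta: float, n_agents: int,
                     hyper: Hyperparams, base_seed: int = 0, **kw):
    """Three-phase shaping protocol +α → β → −α."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return run_phases([alpha, beta, -alpha], n_agents, hyper, base_seed, **kw)


def trajectories_frame(trajs) -> pd.DataFrame:
    """Tidy long-format table: one row per agent per checkpoint."""
    return pd.concat([t.to_frame() for t in trajs], ignore_index=True)
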