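"""Dynamic routing over a stage's experts.

Each stage holds N parallel expert blocks and a learned routing matrix
W_R (C x N).  Routing scores are the global-average-pooled stage input times
W_R (no bias); a softmax turns them into a per-sample simplex over the
experts.  Every expert processes the input, each expert output is scaled by
its routing weight, and the scaled outputs are concatenated along channels
(soft routing — no expert is skipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import ExpertBlock
from .nn import ConfigurationError, Module, Parameter


class InputError(ValueError):
    """Invalid runtime input (as opposed to a configuration problem)."""


@dataclass
class StageTrace:
    """Routing diagnostics for one forward pass of one stage.

    ``weights`` is the per-sample simplex over experts, shape (N_samples,
    N_experts); rows sum to 1.
    """

    stage_index: int
    weights: np.ndarray

    @property
    def n_experts(self) -> int:
        return self.weights.shape[1]


def compute_routing_scores(stage_input: Tensor, w_r: Tensor) -> Tensor:
    """Unscaled routing scores: GAP(stage_input) @ W_R (no bias term)."""
    if stage_input.shape[1] != w_r.shape[0]:
        raise ConfigurationError(
            f"routing matrix expects {w_r.shape[0]} channels, "
            f"input has {stage_input.shape[1]}"
        )
    pooled = ag.reshape(
        ag.global_avg_pool(stage_input), (stage_input.shape[0], stage_input.shape[1])
    )
    return pooled @ w_r


def routing_softmax(scores: Tensor) -> Tensor:
    """Softmax over the last axis, stabilized by max-subtraction.

    The subtraction of the (detached) per-row maximum leaves the result
    unchanged — softmax is invariant under additive shifts — while keeping
    the exponentials bounded.
    """
    if not np.all(np.isfinite(scores.data)):
        raise InputError("routing scores must be finite")
    shifted = scores - Tensor(scores.data.max(axis=-1, keepdims=True))
    ez = ag.exp(shifted)
    return ez / ag.tsum(ez, axis=-1, keepdims=True)


class Router(Module):
    """Learned linear gating map; weights start near zero (std 0.01) so early
    routing is close to uniform and specialization emerges with training."""

    def __init__(self, channels: int, n_experts: int, rng: np.random.Generator,
                 bias: bool = False):
        super().__init__()
        self.w_r = Parameter(rng.normal(0.0, 0.01, size=(channels, n_experts)))
        self.b_r = Parameter(np.zeros(n_experts)) if bias else None

    def forward(self, stage_input: Tensor) -> Tensor:
        scores = compute_routing_scores(stage_input, self.w_r)
        if self.b_r is not None:
            scores = scores + self.b_r
        return routing_softmax(scores)

    __call__ = forward


class RoutedStage(Module):
    """N experts + router; output channels = N x expert channels."""

    def __init__(self, stage_index: int, experts: list[ExpertBlock],
                 rng: np.random.Generator):
        super().__init__()
        if not experts:
            raise ConfigurationError("a stage needs at least one expert")
        channels = experts[0].cfg.in_channels
        if any(e.cfg.in_channels != channels for e in experts):
            raise ConfigurationError("all experts in a stage must share channels")
        self.stage_index = stage_index
        self.n_experts = len(experts)
        for i, e in enumerate(experts):
            setattr(self, f"expert{i}", e)
        self.experts = experts
        self.router = Router(channels, len(experts), rng)

    def forward(self, stage_input: Tensor) -> tuple[Tensor, StageTrace]:
        weights = self.router(stage_input)  # (B, N)
        B = stage_input.shape[0]
        scaled = []
        for j, expert in enumerate(self.experts):
            wj = ag.reshape(weights[:, j : j + 1], (B, 1, 1, 1))
            scaled.append(expert(stage_input) * wj)
        out = ag.concat(scaled, axis=1)
        trace = StageTrace(self.stage_index, weights.data.copy())
        return out, trace

    __call__ = forward


# -- diagnostics -------------------------------------------------------------


def merge_traces(traces: list[StageTrace]) -> StageTrace:
    """Stack traces from successive batches of the same stage."""
    if not traces:
        raise InputError("no traces to merge")
    idx = traces[0].stage_index
    if any(t.stage_index != idx for t in traces):
        raise InputError("traces come from different stages")
    return StageTrace(idx, np.concatenate([t.weights for t in traces], axis=0))


def expert_utilization(trace: StageTrace) -> np.ndarray:
    """Mean routing weight per expert over all samples; sums to 1."""
    if trace.weights.shape[0] == 0:
        raise InputError("utilization of an empty trace is undefined")
    return trace.weights.mean(axis=0)


def routing_pattern_matrix(trace: StageTrace, n_samples: int = 20) -> np.ndarray:
    """First ``n_samples`` rows of routing weights (for heatmap rendering)."""
    if n_samples > trace.weights.shape[0]:
        raise InputError(
            f"requested {n_samples} samples but trace holds "
            f"{trace.weights.shape[0]}"
        )
    return trace.weights[:n_samples].copy()
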