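"""The full classifier: stem -> three routed expert stages with transitions
-> global context gate -> classifier head, plus two auxiliary heads.

Channel plan (default base 64): the stem emits ``base`` channels; stage s
runs N experts at ``base * 2**(s-1)`` channels, so the weighted concat holds
``N * base * 2**(s-1)`` channels, which the following transition compresses
to ``base * 2**s`` while halving H and W.  After stage 3 a global-context
gate recalibrates the concatenated features and the final head classifies:
adaptive GAP -> flatten -> linear(512) -> ReLU -> dropout(0.5) -> linear.
Auxiliary heads (GAP -> flatten -> linear) sit after the two transitions;
their losses join the final loss during training only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import AttentionMaps, BlockConfig, ExpertBlock, GlobalContext, Stem, Transition
from .nn import ConfigurationError, Dropout, Linear, Module
from .routing import RoutedStage, StageTrace


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``gamma_final`` and ``gamma_aux`` weight the final and auxiliary
    cross-entropy terms in the composite training loss; auxiliary terms are
    dropped at evaluation time.
    """

    num_classes: int
    experts_per_stage: int = 3
    base_channels: int = 64
    num_stages: int = 3
    fc_width: int = 512
    dropout_rate: float = 0.5
    gamma_final: float = 1.0
    gamma_aux: tuple[float, ...] = (0.3, 0.3)
    use_se: bool = True
    use_scab: bool = True
    se_reduction: int = 16
    attn_reduction: int = 16
    bottleneck_channels: int = 32
    conv_groups: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.experts_per_stage < 1:
            raise ConfigurationError("experts_per_stage must be >= 1")
        if self.gamma_final <= 0:
            raise ConfigurationError("final loss weight must be positive")
        if any(g < 0 for g in self.gamma_aux):
            raise ConfigurationError("auxiliary loss weights must be nonnegative")
        if len(self.gamma_aux) != self.num_stages - 1:
            raise ConfigurationError(
                f"expected {self.num_stages - 1} auxiliary weights, "
                f"got {len(self.gamma_aux)}"
            )

    def stage_channels(self, stage: int) -> int:
        """Expert width of stage ``stage`` (1-based)."""
        return self.base_channels * 2 ** (stage - 1)


@dataclass
class ModelOutputs:
    final_logits: Tensor
    aux_logits: list[Tensor]
    stage_traces: list[StageTrace]
    attention: list[list[AttentionMaps | None]] = field(default_factory=list)


class AuxHead(Module):
    """Deep-supervision head: GAP -> flatten -> linear."""

    def __init__(self, channels: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(channels, num_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = ag.reshape(ag.global_avg_pool(x), (x.shape[0], x.shape[1]))
        return self.fc(pooled)

    __call__ = forward


class MoEClassifier(Module):
    """Hierarchical attention-driven mixture-of-experts CNN."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0]
        )
        N = cfg.experts_per_stage

        self.stem = Stem(rng, 3, cfg.base_channels)
        stages: list[RoutedStage] = []
        transitions: list[Transition] = []
        aux_heads: list[AuxHead] = []
        for s in range(1, cfg.num_stages + 1):
            c = cfg.stage_channels(s)
            block_cfg = BlockConfig(
                in_channels=c,
                bottleneck_channels=cfg.bottleneck_channels,
                conv_groups=cfg.conv_groups,
                se_reduction=cfg.se_reduction,
                attn_reduction=cfg.attn_reduction,
                use_se=cfg.use_se,
                use_scab=cfg.use_scab,
            )
            try:
                block_cfg.validate()
            except ConfigurationError as e:
                raise ConfigurationError(f"stage {s}: {e}") from e
            experts = [ExpertBlock(block_cfg, rng) for _ in range(N)]
            stage = RoutedStage(s, experts, rng)
            stages.append(stage)
            setattr(self, f"stage{s}", stage)
            if s < cfg.num_stages:
                tr = Transition(N * c, cfg.stage_channels(s + 1), rng)
                transitions.append(tr)
                setattr(self, f"transition{s}", tr)
                head = AuxHead(cfg.stage_channels(s + 1), cfg.num_classes, rng)
                aux_heads.append(head)
                setattr(self, f"aux_head{s}", head)
        self.stages = stages
        self.transitions = transitions
        self.aux_heads = aux_heads

        final_c = N * cfg.stage_channels(cfg.num_stages)
        self.global_context = GlobalContext(final_c, cfg.se_reduction, rng)
        self.fc1 = Linear(final_c, cfg.fc_width, rng)
        self.dropout = Dropout(cfg.dropout_rate, self._dropout_rng)
        self.fc2 = Linear(cfg.fc_width, cfg.num_classes, rng)

    # -- forward -------------------------------------------------------------
    def forward(self, images: np.ndarray | Tensor) -> ModelOutputs:
        """Run a batch. ``images`` is (N, H, W, 3) in [0, 1] (channels-last,
        as produced by the data pipeline) or an (N, 3, H, W) Tensor."""
        if isinstance(images, Tensor):
            x = images
        else:
            images = np.asarray(images, dtype=np.float64)
            if images.ndim != 4 or images.shape[-1] != 3:
                raise ConfigurationError(
                    f"expected (N, H, W, 3) images, got shape {images.shape}"
                )
            x = Tensor(images.transpose(0, 3, 1, 2))

        x = self.stem(x)
        traces: list[StageTrace] = []
        attention: list[list[AttentionMaps | None]] = []
        aux_logits: list[Tensor] = []
        for s, stage in enumerate(self.stages, start=1):
            x, trace = stage(x)
            traces.append(trace)
            attention.append([e.last_attention for e in stage.experts])
            if s < self.cfg.num_stages:
                x = self.transitions[s - 1](x)
                aux_logits.append(self.aux_heads[s - 1](x))

        x = x * self.global_context(x)
        pooled = ag.reshape(ag.global_avg_pool(x), (x.shape[0], x.shape[1]))
        hidden = self.dropout(ag.relu(self.fc1(pooled)))
        final = self.fc2(hidden)
        return ModelOutputs(final, aux_logits, traces, attention)

    __call__ = forward

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Argmax class indices from the final head, in eval mode."""
        was_training = self.training
        self.eval()
        preds = []
        for i in range(0, len(images), batch_size):
            out = self.forward(images[i : i + batch_size])
            preds.append(out.final_logits.data.argmax(axis=1))
        if was_training:
            self.train()
        return np.concatenate(preds)


def build_model(cfg: ModelConfig) -> MoEClassifier:
    """Construct a model with deterministic, seeded initialization."""
    return MoEClassifier(cfg)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars (conv/linear weights and biases, BN
    scale/shift, routing matrices)."""
    return model.count_parameters()


def total_loss(final_loss: Tensor | float, aux_losses: list[Tensor | float],
               cfg: ModelConfig, training: bool = True) -> Tensor | float:
    """Composite loss: gamma_final * L_final + sum_s gamma_aux[s] * L_aux,s.

    Auxiliary terms contribute during training only; in evaluation the
    composite reduces to the weighted final term.
    """
    cfg.validate()
    if len(aux_losses) != len(cfg.gamma_aux):
        raise ConfigurationError(
            f"expected {len(cfg.gamma_aux)} auxiliary losses, "
            f"got {len(aux_losses)}"
        )
    out = cfg.gamma_final * final_loss
    if training:
        for g, l in zip(cfg.gamma_aux, aux_losses):
            out = out + g * l
    return out
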