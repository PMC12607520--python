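"""Tree-Structured Parzen Estimator for hyperparameter optimization.

TPE is sequential model-based optimization that, instead of modelling the
objective directly, models two densities over configurations: ``l(z)`` fitted
to the best-performing fraction of past trials and ``g(z)`` to the rest.
Candidates are drawn from ``l`` and ranked by the acquisition ratio
``l(z) / (g(z) + eps)``; maximizing this ratio is equivalent to maximizing
expected improvement under the two-density model.

The search space is tree-structured: a parameter may be conditioned on a
categorical parent taking a specific value, in which case it exists (and is
modelled) only in trials where the parent took that value.

Conventions used here (where the procedure leaves room):

* the "good" set has ``max(1, ceil(gamma * n))`` members, ties broken by
  trial index;
* numeric kernels are Gaussians truncated to the domain, one per
  observation, with per-observation bandwidth ``max(nearest-neighbour
  distance, 1% of the domain width)``, blended with a uniform prior
  component of weight ``1 / (k + 1)``;
* categorical densities are Laplace-smoothed frequency tables;
* failed trials are excluded from both densities.

A seeded random-search baseline with the identical trial-record contract is
provided for benchmarking; with ``n_init >= budget`` the TPE loop never
leaves its warm-up phase and reproduces random search exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.stats import norm


class StateError(RuntimeError):
    """Operation called before enough trials exist."""


# -- search space ------------------------------------------------------------


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"low must be < high, got [{self.low}, {self.high}]")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled domains must be positive")


@dataclass(frozen=True)
class Integer:
    low: int
    high: int

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"low must be < high, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __post_init__(self):
        if not self.choices:
            raise ValueError("choice list must be nonempty")


Domain = Real | Integer | Categorical


@dataclass
class SearchSpace:
    """Named parameter domains with optional parent conditions.

    ``conditions[name] = (parent_name, value)`` makes ``name`` active only in
    configurations where ``parent_name`` equals ``value``.
    """

    params: dict[str, Domain]
    conditions: dict[str, tuple[str, Any]] = field(default_factory=dict)

    def __post_init__(self):
        for child, (parent, _) in self.conditions.items():
            if parent not in self.params:
                raise ValueError(f"condition parent {parent!r} not in space")
            if child not in self.params:
                raise ValueError(f"conditional parameter {child!r} not in space")
        self._order = self._topo_order()

    def _topo_order(self) -> list[str]:
        order, seen = [], set()

        def visit(name, chain):
            if name in seen:
                return
            if name in chain:
                raise ValueError("condition graph contains a cycle")
            if name in self.conditions:
                visit(self.conditions[name][0], chain | {name})
            seen.add(name)
            order.append(name)

        for name in self.params:
            visit(name, set())
        return order

    def is_active(self, name: str, config: dict[str, Any]) -> bool:
        if name not in self.conditions:
            return True
        parent, value = self.conditions[name]
        return config.get(parent) == value

    def sample_prior(self, rng: np.random.Generator) -> dict[str, Any]:
        """One configuration from the prior, respecting conditions: uniform
        over each active domain (log-uniform for log-scaled reals)."""
        config: dict[str, Any] = {}
        for name in self._order:
            if not self.is_active(name, config):
                continue
            dom = self.params[name]
            if isinstance(dom, Real):
                if dom.log:
                    config[name] = float(
                        np.exp(rng.uniform(np.log(dom.low), np.log(dom.high)))
                    )
                else:
                    config[name] = float(rng.uniform(dom.low, dom.high))
            elif isinstance(dom, Integer):
                config[name] = int(rng.integers(dom.low, dom.high + 1))
            else:
                config[name] = dom.choices[rng.integers(len(dom.choices))]
        return config


@dataclass
class TrialRecord:
    config: dict[str, Any]
    value: float
    index: int
    failed: bool = False


@dataclass
class TPEConfig:
    gamma: float = 0.25
    n_init: int = 10
    n_candidates: int = 24
    eps: float = 1e-12
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.n_init < 1 or self.n_candidates < 1:
            raise ValueError("n_init and n_candidates must be >= 1")


# -- trial splitting ---------------------------------------------------------


def split_trials(history: list[TrialRecord],
                 gamma: float) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Partition completed trials into (good, bad) by objective value.

    The good set holds the ``max(1, ceil(gamma * n))`` lowest values; ties
    are broken by trial index so the split is deterministic.
    """
    completed = [t for t in history if not t.failed]
    n = len(completed)
    if n < 2:
        raise StateError("need at least 2 completed trials to split; "
                         "run more random trials first")
    k = max(1, math.ceil(gamma * n))
    k = min(k, n - 1)  # keep both sides nonempty
    ranked = sorted(completed, key=lambda t: (t.value, t.index))
    return ranked[:k], ranked[k:]


# -- Parzen densities --------------------------------------------------------


class _NumericDensity:
    """1-D mixture of truncated Gaussians plus a uniform prior component.

    For log-scaled domains the density lives on the log axis.
    """

    def __init__(self, obs: np.ndarray, low: float, high: float,
                 integer: bool = False):
        self.low, self.high = low, high
        self.integer = integer
        self.obs = np.sort(np.asarray(obs, dtype=float))
        k = len(self.obs)
        width = high - low
        if k > 1:
            gaps = np.diff(self.obs)
            nearest = np.minimum(
                np.concatenate([[np.inf], gaps]), np.concatenate([gaps, [np.inf]])
            )
        else:
            nearest = np.full(k, np.inf)
        self.bw = np.maximum(np.minimum(nearest, width), 0.01 * width)
        self.w_uniform = 1.0 / (k + 1)
        self.w_kernel = 1.0 / (k + 1)

    def pdf(self, x: float) -> float:
        dens = self.w_uniform / (self.high - self.low)
        if len(self.obs):
            a = (self.low - self.obs) / self.bw
            b = (self.high - self.obs) / self.bw
            mass = norm.cdf(b) - norm.cdf(a)
            dens += float(
                (self.w_kernel * norm.pdf((x - self.obs) / self.bw)
                 / (self.bw * mass)).sum()
            )
        return dens

    def sample(self, rng: np.random.Generator) -> float:
        k = len(self.obs)
        comp = rng.integers(0, k + 1)
        if comp == k:  # uniform prior component
            return float(rng.uniform(self.low, self.high))
        mu, bw = self.obs[comp], self.bw[comp]
        for _ in range(1000):
            x = rng.normal(mu, bw)
            if self.low <= x <= self.high:
                return float(x)
        return float(np.clip(rng.normal(mu, bw), self.low, self.high))


class _CategoricalDensity:
    def __init__(self, obs: list, choices: tuple, smoothing: float = 1.0):
        counts = np.array([sum(o == c for o in obs) for c in choices], dtype=float)
        self.choices = choices
        self.probs = (counts + smoothing) / (counts.sum() + smoothing * len(choices))

    def pdf(self, x) -> float:
        return float(self.probs[self.choices.index(x)])

    def sample(self, rng: np.random.Generator):
        return self.choices[rng.choice(len(self.choices), p=self.probs)]


class ParzenEstimator:
    """Per-parameter Parzen densities fitted to one side of the split."""

    def __init__(self, configs: list[dict[str, Any]], space: SearchSpace):
        if not configs:
            raise StateError("cannot fit a Parzen estimator to zero configs")
        self.space = space
        self.dens: dict[str, Any] = {}
        for name, dom in space.params.items():
            values = [c[name] for c in configs if name in c]
            if isinstance(dom, Categorical):
                self.dens[name] = _CategoricalDensity(values, dom.choices)
            elif values:
                if isinstance(dom, Real) and dom.log:
                    self.dens[name] = _NumericDensity(
                        np.log(values), np.log(dom.low), np.log(dom.high)
                    )
                elif isinstance(dom, Integer):
                    self.dens[name] = _NumericDensity(
                        values, dom.low - 0.5, dom.high + 0.5, integer=True
                    )
                else:
                    self.dens[name] = _NumericDensity(values, dom.low, dom.high)
            else:
                # conditional parameter never active on this side: prior only
                if isinstance(dom, Real) and dom.log:
                    self.dens[name] = _NumericDensity(
                        np.empty(0), np.log(dom.low), np.log(dom.high)
                    )
                elif isinstance(dom, Integer):
                    self.dens[name] = _NumericDensity(
                        np.empty(0), dom.low - 0.5, dom.high + 0.5, integer=True
                    )
                else:
                    self.dens[name] = _NumericDensity(np.empty(0), dom.low, dom.high)

    def _x(self, name: str, value):
        dom = self.space.params[name]
        if isinstance(dom, Real) and dom.log:
            return np.log(value)
        return value

    def pdf(self, config: dict[str, Any]) -> float:
        """Joint density of the active coordinates (product over parameters)."""
        p = 1.0
        for name, value in config.items():
            p *= self.dens[name].pdf(self._x(name, value))
        return p

    def sample(self, rng: np.random.Generator) -> dict[str, Any]:
        """Draw a configuration, walking parents before conditionals."""
        config: dict[str, Any] = {}
        for name in self.space._order:
            if not self.space.is_active(name, config):
                continue
            dom = self.space.params[name]
            raw = self.dens[name].sample(rng)
            if isinstance(dom, Categorical):
                config[name] = raw
            elif isinstance(dom, Real):
                config[name] = float(np.exp(raw)) if dom.log else float(raw)
            else:
                config[name] = int(np.clip(round(raw), dom.low, dom.high))
        return config


def fit_parzen(configs: list[dict[str, Any]], space: SearchSpace) -> ParzenEstimator:
    return ParzenEstimator(configs, space)


def score_candidate(config: dict[str, Any], good: ParzenEstimator,
                    bad: ParzenEstimator, eps: float = 1e-12) -> float:
    """Acquisition ratio l(z) / (g(z) + eps); higher is more promising."""
    return good.pdf(config) / (bad.pdf(config) + eps)


# -- optimization loops ------------------------------------------------------


def _trial_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def suggest(history: list[TrialRecord], space: SearchSpace,
            cfg: TPEConfig) -> dict[str, Any]:
    """Propose the next configuration given the trial history.

    Warm-up (< ``n_init`` completed trials): a prior sample.  Afterwards:
    split, fit both densities, draw ``n_candidates`` from the good density
    and return the best-scoring one.  Deterministic in (seed, history).
    """
    rng = _trial_rng(cfg.seed, len(history))
    completed = [t for t in history if not t.failed]
    if len(completed) < cfg.n_init or len(completed) < 2:
        return space.sample_prior(rng)
    good, bad = split_trials(history, cfg.gamma)
    l_dens = fit_parzen([t.config for t in good], space)
    g_dens = fit_parzen([t.config for t in bad], space)
    candidates = [l_dens.sample(rng) for _ in range(cfg.n_candidates)]
    scores = [score_candidate(c, l_dens, g_dens, cfg.eps) for c in candidates]
    return candidates[int(np.argmax(scores))]


def _run_loop(objective: Callable[[dict[str, Any]], float], space: SearchSpace,
              cfg: TPEConfig, budget: int, proposer) -> tuple[dict, float, list]:
    if budget < 1:
        raise ValueError("budget must be >= 1")
    history: list[TrialRecord] = []
    best_config, best_value = None, np.inf
    for i in range(budget):
        config = proposer(history)
        try:
            value = float(objective(config))
            failed = not np.isfinite(value)
        except Exception:
            value, failed = np.nan, True
        history.append(TrialRecord(config, value, i, failed))
        if not failed and value < best_value:
            best_config, best_value = config, value
    if best_config is None:
        raise RuntimeError("every trial failed")
    return best_config, best_value, history


def optimize(objective: Callable[[dict[str, Any]], float], space: SearchSpace,
             cfg: TPEConfig, budget: int) -> tuple[dict, float, list[TrialRecord]]:
    """Minimize ``objective`` with TPE; returns (best config, best value,
    full history).  The incumbent is the minimum over evaluated trials, so
    the best value is non-increasing in budget for a fixed seed."""
    return _run_loop(objective, space, cfg, budget,
                     lambda h: suggest(h, space, cfg))


def random_search(objective: Callable[[dict[str, Any]], float], space: SearchSpace,
                  cfg: TPEConfig, budget: int) -> tuple[dict, float, list[TrialRecord]]:
    """Matched-budget baseline: i.i.d. prior samples, same trial bookkeeping
    and per-trial seeding as :func:`optimize`."""
    return _run_loop(
        objective, space, cfg, budget,
        lambda h: space.sample_prior(_trial_rng(cfg.seed, len(h))),
    )


def default_search_space() -> SearchSpace:
    """The shipped tuning space for the classifier: learning rate
    (log-uniform 1e-4..1e-2), batch size {8, 16, 32}, dropout 0.3..0.6 and
    auxiliary-loss weight 0..0.5."""
    return SearchSpace({
        "learning_rate": Real(1e-4, 1e-2, log=True),
        "batch_size": Categorical((8, 16, 32)),
        "dropout_rate": Real(0.3, 0.6),
        "gamma_aux": Real(0.0, 0.5),
    })
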