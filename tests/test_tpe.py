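"""Tree-Structured Parzen Estimator: splitting convention, density fits,
acquisition scoring, determinism, the random-search reduction and benchmark
behaviour on toy objectives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endomoe.tpe import (
    Categorical,
    Integer,
    ParzenEstimator,
    Real,
    SearchSpace,
    StateError,
    TPEConfig,
    TrialRecord,
    default_search_space,
    fit_parzen,
    optimize,
    random_search,
    score_candidate,
    split_trials,
    suggest,
)


def make_history(values):
    return [TrialRecord({"z": 0.5}, v, i) for i, v in enumerate(values)]


class TestSplit:
    def test_quantile_sizes(self):
        good, bad = split_trials(make_history(np.arange(10.0)), 0.25)
        assert len(good) == 3 and len(bad) == 7
        assert max(t.value for t in good) <= min(t.value for t in bad)

    def test_two_trials_minimum_floor(self):
        good, bad = split_trials(make_history([3.0, 1.0]), 0.25)
        assert len(good) == 1 and good[0].value == 1.0
        assert len(bad) == 1 and bad[0].value == 3.0

    def test_ties_broken_by_trial_index(self):
        good, bad = split_trials(make_history([2.0] * 8), 0.25)
        assert [t.index for t in good] == [0, 1]
        assert len(bad) == 6

    def test_partition_properties(self, rng):
        hist = make_history(rng.normal(size=17))
        good, bad = split_trials(hist, 0.3)
        assert len(good) + len(bad) == 17
        assert {t.index for t in good} | {t.index for t in bad} == set(range(17))
        assert good and bad

    def test_too_few_trials(self):
        with pytest.raises(StateError):
            split_trials(make_history([1.0]), 0.25)

    def test_failed_trials_excluded(self):
        hist = make_history([1.0, 2.0, 3.0])
        hist.append(TrialRecord({"z": 0.1}, np.nan, 3, failed=True))
        good, bad = split_trials(hist, 0.5)
        assert all(not t.failed for t in good + bad)
        assert len(good) + len(bad) == 3


class TestParzen:
    SPACE = SearchSpace({"z": Real(0.0, 1.0)})

    def test_single_observation_mode_at_midpoint(self):
        est = fit_parzen([{"z": 0.5}], self.SPACE)
        grid = np.linspace(0.0, 1.0, 101)
        dens = [est.pdf({"z": float(g)}) for g in grid]
        assert grid[int(np.argmax(dens))] == pytest.approx(0.5, abs=0.02)

    def test_density_integrates_to_one(self, rng):
        est = fit_parzen([{"z": float(v)} for v in rng.random(5)], self.SPACE)
        grid = np.linspace(0.0, 1.0, 2001)
        dens = [est.pdf({"z": float(g)}) for g in grid]
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-2)

    def test_categorical_laplace_smoothing(self):
        space = SearchSpace({"c": Categorical(("a", "b"))})
        est = fit_parzen([{"c": "a"}], space)
        assert est.pdf({"c": "a"}) == pytest.approx(2 / 3)
        assert est.pdf({"c": "b"}) == pytest.approx(1 / 3)

    def test_positive_density_everywhere(self, rng):
        space = SearchSpace({
            "lr": Real(1e-4, 1e-1, log=True),
            "n": Integer(1, 10),
            "c": Categorical(("x", "y", "z")),
        })
        est = fit_parzen([space.sample_prior(rng) for _ in range(4)], space)
        for _ in range(50):
            assert est.pdf(space.sample_prior(rng)) > 0

    def test_empty_fit_rejected(self):
        with pytest.raises(StateError):
            fit_parzen([], self.SPACE)


class TestScore:
    def test_equal_densities_score_near_one(self):
        space = SearchSpace({"z": Real(0.0, 1.0)})
        est = fit_parzen([{"z": 0.5}], space)
        assert score_candidate({"z": 0.3}, est, est) == pytest.approx(1.0, rel=1e-6)

    def test_preference_ordering_by_hand(self):
        class Fixed:
            def __init__(self, v):
                self.v = v

            def pdf(self, _):
                return self.v

        s1 = score_candidate({"z": 0}, Fixed(0.4), Fixed(0.1))
        s2 = score_candidate({"z": 0}, Fixed(0.2), Fixed(0.3))
        assert s1 == pytest.approx(4.0, rel=1e-6)
        assert s2 == pytest.approx(0.2 / 0.3, rel=1e-6)
        assert s1 > s2


class TestConditional:
    def make_space(self):
        return SearchSpace(
            {
                "optimizer": Categorical(("adam", "sgd")),
                "momentum": Real(0.0, 1.0),
            },
            conditions={"momentum": ("optimizer", "sgd")},
        )

    def test_inactive_parameters_absent(self, rng):
        space = self.make_space()
        for _ in range(50):
            cfg = space.sample_prior(rng)
            assert ("momentum" in cfg) == (cfg["optimizer"] == "sgd")

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            SearchSpace(
                {"a": Categorical((0, 1)), "b": Categorical((0, 1))},
                conditions={"a": ("b", 0), "b": ("a", 0)},
            )

    def test_conditional_hygiene_through_optimize(self):
        space = self.make_space()

        def objective(cfg):
            return cfg.get("momentum", 0.5)

        _, _, history = optimize(objective, space, TPEConfig(seed=0, n_init=4), 20)
        for t in history:
            assert ("momentum" in t.config) == (t.config["optimizer"] == "sgd")


class TestLoops:
    QUAD_SPACE = SearchSpace({"z": Real(0.0, 1.0)})

    @staticmethod
    def quad(cfg):
        return (cfg["z"] - 0.3) ** 2

    def test_empty_history_prior_sample_in_bounds(self):
        cfg = suggest([], self.QUAD_SPACE, TPEConfig(seed=1))
        assert 0.0 <= cfg["z"] <= 1.0

    def test_suggest_deterministic(self):
        hist = make_history(list(np.linspace(0, 1, 12)))
        for t, v in zip(hist, np.linspace(0.1, 0.9, 12)):
            t.config = {"z": float(v)}
        a = suggest(hist, self.QUAD_SPACE, TPEConfig(seed=5))
        b = suggest(hist, self.QUAD_SPACE, TPEConfig(seed=5))
        assert a == b

    def test_budget_one_returns_single_trial(self):
        best, value, hist = optimize(self.quad, self.QUAD_SPACE,
                                     TPEConfig(seed=2), 1)
        assert len(hist) == 1 and hist[0].config == best

    def test_random_search_reduction(self):
        cfg = TPEConfig(seed=9, n_init=50)
        _, _, h_tpe = optimize(self.quad, self.QUAD_SPACE, cfg, 30)
        _, _, h_rs = random_search(self.quad, self.QUAD_SPACE, cfg, 30)
        assert [t.config for t in h_tpe] == [t.config for t in h_rs]

    def test_optimize_reproducible(self):
        a = optimize(self.quad, self.QUAD_SPACE, TPEConfig(seed=3), 25)
        b = optimize(self.quad, self.QUAD_SPACE, TPEConfig(seed=3), 25)
        assert a[1] == b[1]
        assert [t.config for t in a[2]] == [t.config for t in b[2]]

    def test_incumbent_nonincreasing_in_budget(self):
        cfg = TPEConfig(seed=4)
        _, v30, _ = optimize(self.quad, self.QUAD_SPACE, cfg, 30)
        _, v50, _ = optimize(self.quad, self.QUAD_SPACE, cfg, 50)
        assert v50 <= v30

    def test_failed_objective_excluded(self):
        calls = {"n": 0}

        def flaky(cfg):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return self.quad(cfg)

        best, value, hist = optimize(flaky, self.QUAD_SPACE,
                                     TPEConfig(seed=6, n_init=4), 15)
        assert sum(t.failed for t in hist) == 5
        assert np.isfinite(value)

    def test_suggestions_concentrate_near_optimum(self):
        """After 30 quadratic trials, most TPE proposals land near z=0.3."""
        cfg = TPEConfig(seed=7, n_init=10)
        _, _, hist = optimize(self.quad, self.QUAD_SPACE, cfg, 30)
        hits = 0
        for k in range(20):
            proposal = suggest(hist, self.QUAD_SPACE,
                               TPEConfig(seed=100 + k, n_init=10))
            hits += 0.1 <= proposal["z"] <= 0.5
        assert hits >= 14  # >= 70%

    def test_random_search_visits_all_categories(self):
        space = SearchSpace({"c": Categorical(("a", "b", "c"))})
        seen_all = 0
        for seed in range(20):
            _, _, hist = random_search(lambda cfg: 0.0, space,
                                       TPEConfig(seed=seed), 100)
            cats = {t.config["c"] for t in hist}
            seen_all += cats == {"a", "b", "c"}
        assert seen_all == 20

    def test_tpe_beats_random_on_quadratic(self):
        """Median best |z - 0.3| over 20 seeds: TPE < matched random search
        at budget 60 (n_init 10, 24 candidates/iteration)."""
        tpe_err, rs_err = [], []
        for seed in range(20):
            cfg = TPEConfig(seed=seed, n_init=10, n_candidates=24)
            b_tpe, _, _ = optimize(self.quad, self.QUAD_SPACE, cfg, 60)
            b_rs, _, _ = random_search(self.quad, self.QUAD_SPACE, cfg, 60)
            tpe_err.append(abs(b_tpe["z"] - 0.3))
            rs_err.append(abs(b_rs["z"] - 0.3))
        assert np.median(tpe_err) < np.median(rs_err)

    def test_tpe_not_worse_on_mixed_space(self):
        """Mixed continuous+categorical toy: TPE median final value over 20
        seeds is no worse than random search's."""
        space = SearchSpace({
            "z": Real(0.0, 1.0),
            "c": Categorical(("good", "bad")),
        })

        def objective(cfg):
            return (cfg["z"] - 0.7) ** 2 + (0.0 if cfg["c"] == "good" else 0.5)

        tpe_v, rs_v = [], []
        for seed in range(20):
            cfg = TPEConfig(seed=seed, n_init=10)
            tpe_v.append(optimize(objective, space, cfg, 60)[1])
            rs_v.append(random_search(objective, space, cfg, 60)[1])
        assert np.median(tpe_v) <= np.median(rs_v)


def test_default_search_space_well_formed(rng):
    space = default_search_space()
    cfg = space.sample_prior(rng)
    assert 1e-4 <= cfg["learning_rate"] <= 1e-2
    assert cfg["batch_size"] in (8, 16, 32)
    assert 0.3 <= cfg["dropout_rate"] <= 0.6


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    values=st.lists(st.floats(-100, 100), min_size=2, max_size=40, unique=True),
    gamma=st.floats(0.05, 0.95),
)
def test_split_size_convention_property(values, gamma):
    good, bad = split_trials(make_history(values), gamma)
    expected = min(max(1, math.ceil(gamma * len(values))), len(values) - 1)
    assert len(good) == expected
    assert len(bad) == len(values) - expected
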