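"""Splitting, merging, resampling and the WE driver loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_walker, random_ensemble
from wesample.binning import BinningError, BinScheme
from wesample.config import WEConfig
from wesample.core import (
    Ensemble,
    WERunError,
    merge_walkers,
    resample,
    run_we,
    split_walker,
)
from wesample.fixtures import make_jump_process


class TestSplit:
    def test_half_weight_splits_to_quarters(self):
        w = make_walker(0, 0.5, [1.0])
        kids = split_walker(w, 2, ids=[0, 1])
        assert [k.weight for k in kids] == [0.25, 0.25]
        assert all(k.parent_id == 0 for k in kids)
        assert all(np.array_equal(k.pcoord, w.pcoord) for k in kids)

    def test_split_into_one_is_an_error(self):
        with pytest.raises(ValueError, match="n=1"):
            split_walker(make_walker(0, 1.0, [0.0]), 1)

    def test_sum_is_exact_single_division(self):
        kids = split_walker(make_walker(0, 0.3, [0.0]), 3, ids=[0, 1, 2])
        assert math.fsum(k.weight for k in kids) == pytest.approx(0.3, abs=1e-16)
        assert all(k.weight == 0.3 / 3 for k in kids)

    def test_invalid_weight_cannot_exist(self):
        with pytest.raises(ValueError, match="weight"):
            make_walker(0, 0.0, [0.0])
        with pytest.raises(ValueError, match="weight"):
            make_walker(0, -1.0, [0.0])
        with pytest.raises(ValueError):
            make_walker(0, float("nan"), [0.0])


class TestMerge:
    def test_survivor_carries_summed_weight(self, rng):
        a, b = make_walker(0, 0.25, [1.0]), make_walker(1, 0.25, [2.0])
        s = merge_walkers((a, b), rng)
        assert s.weight == 0.5
        assert s.id in (0, 1)

    def test_equal_weights_any_scale(self, rng):
        for w in (1e-9, 0.125, 0.4):
            s = merge_walkers(
                (make_walker(0, w, [0.0]), make_walker(1, w, [1.0])), rng
            )
            assert s.weight == pytest.approx(2 * w)

    def test_survival_probability_proportional_to_weight(self):
        # weights (0.9, 0.1): the binomial oracle says the heavy walker
        # survives a 0.9 fraction of 10,000 draws, within ~3 sigma
        rng = np.random.default_rng(1234)
        n = 10_000
        heavy = 0
        for _ in range(n):
            s = merge_walkers(
                (make_walker(0, 0.9, [0.0]), make_walker(1, 0.1, [1.0])), rng
            )
            heavy += s.id == 0
        assert abs(heavy / n - 0.9) < 0.01

    def test_equal_weights_select_evenly(self):
        rng = np.random.default_rng(99)
        n = 10_000
        first = sum(
            merge_walkers(
                (make_walker(0, 0.25, [0.0]), make_walker(1, 0.25, [1.0])), rng
            ).id
            == 0
            for _ in range(n)
        )
        assert abs(first / n - 0.5) < 0.015  # 3 sigma


class TestResample:
    def test_single_walker_split_to_target(self, rng):
        scheme = BinScheme([[0, 1, 2, 3]], target_count=2)
        ens = Ensemble([make_walker(0, 0.5, [1.5])])
        out, rep = resample(ens, scheme, rng)
        assert sorted(w.weight for w in out.walkers) == [0.25, 0.25]
        assert rep.n_splits == 1 and rep.n_merges == 0

    def test_three_equal_walkers_merge_to_two(self, rng):
        # three weight-1/4 walkers in one bin with target 2 leave one
        # merged pair (weight 1/2) plus the untouched third (weight 1/4)
        scheme = BinScheme([[0, 1]], target_count=2)
        ens = Ensemble([make_walker(i, 0.25, [0.5]) for i in range(3)])
        out, rep = resample(ens, scheme, rng)
        assert sorted(w.weight for w in out.walkers) == [0.25, 0.5]
        assert rep.n_merges == 1
        assert out.total_weight == pytest.approx(0.75, abs=1e-15)

    def test_at_target_is_a_fixed_point(self, rng):
        scheme = BinScheme([[0, 1, 2]], target_count=2)
        ens = Ensemble(
            [
                make_walker(0, 0.3, [0.5], state="a"),
                make_walker(1, 0.2, [0.5], state="b"),
                make_walker(2, 0.25, [1.5], state="c"),
                make_walker(3, 0.25, [1.5], state="d"),
            ]
        )
        out, rep = resample(ens, scheme, rng)
        assert [(w.id, w.weight, w.state) for w in out.walkers] == [
            (w.id, w.weight, w.state) for w in ens.walkers
        ]
        assert rep.n_splits == rep.n_merges == 0

    def test_out_of_domain_names_walker(self, rng):
        scheme = BinScheme([[0, 1]], target_count=1)
        ens = Ensemble([make_walker(7, 1.0, [5.0])])
        with pytest.raises(BinningError, match="walker 7"):
            resample(ens, scheme, rng)

    def test_empty_bins_stay_empty(self, rng):
        scheme = BinScheme([[0, 1, 2, 3]], target_count=4)
        ens = Ensemble([make_walker(0, 1.0, [0.5])])
        out, _ = resample(ens, scheme, rng)
        assert all(w.pcoord[0] < 1.0 for w in out.walkers)
        assert len(out) == 4

    def test_conservation_and_populations_randomized(self):
        """10^4 randomized resample calls conserve weight to < 1e-12 and
        leave every occupied bin exactly at target."""
        rng = np.random.default_rng(777)
        for trial in range(10_000):
            n = int(rng.integers(1, 25))
            target = int(rng.integers(1, 6))
            ens = random_ensemble(rng, n, domain_high=5.0)
            scheme = BinScheme([np.arange(0.0, 6.0)], target_count=target)
            out, rep = resample(ens, scheme, rng)
            assert abs(out.total_weight - 1.0) < 1e-12
            pops = np.bincount(
                scheme.assign(out.pcoord_array()), minlength=scheme.n_bins
            )
            assert set(pops[pops > 0]) == {target}


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    weights=st.lists(
        st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=12
    ),
    n=st.integers(min_value=2, max_value=7),
)
def test_split_then_merge_conserves_weight(weights, n):
    rng = np.random.default_rng(5)
    w0 = make_walker(0, weights[0], [0.0])
    kids = split_walker(w0, n, ids=list(range(n)))
    assert math.fsum(k.weight for k in kids) == pytest.approx(
        w0.weight, rel=1e-15
    )
    merged = kids[0]
    for k in kids[1:]:
        merged = merge_walkers((merged, k), rng)
    assert merged.weight == pytest.approx(w0.weight, rel=1e-12)


class TestRunWE:
    @pytest.fixture
    def jump2(self):
        return make_jump_process(np.array([[-1.0, 1.0], [0.5, -0.5]]))

    def test_zero_iterations_records_initial_only(self, jump2):
        scheme = BinScheme([[0, 1, 2]], target_count=4)
        cfg = WEConfig(
            tau=0.1, n_iterations=0, initial_states=[jump2.initial_state(0)]
        )
        store = run_we(jump2.engine(), scheme, cfg)
        assert store.n_iterations == 0
        assert len(store.iterations) == 1
        assert store.final().total_weight == pytest.approx(1.0)

    def test_deterministic_given_seed(self, jump2):
        scheme = BinScheme([[0, 1, 2]], target_count=6)
        cfg = WEConfig(
            tau=0.2, n_iterations=25, initial_states=[jump2.initial_state(0)], seed=42
        )
        s1 = run_we(jump2.engine(), scheme, cfg)
        s2 = run_we(jump2.engine(), scheme, cfg)
        for a, b in zip(s1.iterations, s2.iterations):
            assert np.array_equal(a.ids, b.ids)
            assert np.array_equal(a.parent_ids, b.parent_ids)
            assert np.array_equal(a.weights, b.weights)
            assert np.array_equal(a.pcoords, b.pcoords)
            assert np.array_equal(a.bins, b.bins)

    def test_weight_is_one_at_every_boundary(self, jump2):
        scheme = BinScheme([[0, 1, 2]], target_count=8)
        cfg = WEConfig(
            tau=0.25, n_iterations=40, initial_states=[jump2.initial_state(0)], seed=3
        )
        store = run_we(jump2.engine(), scheme, cfg)
        dev = np.abs(store.summary_frame().total_weight.to_numpy() - 1.0)
        assert dev.max() < 1e-12

    def test_lineage_links_resolve_one_iteration_back(self, jump2):
        scheme = BinScheme([[0, 1, 2]], target_count=8)
        cfg = WEConfig(
            tau=0.25, n_iterations=30, initial_states=[jump2.initial_state(0)], seed=9
        )
        store = run_we(jump2.engine(), scheme, cfg)
        for prev, cur in zip(store.iterations, store.iterations[1:]):
            assert set(cur.parent_ids.tolist()) <= set(prev.ids.tolist())

    def test_engine_failure_persists_partial_store(self):
        class FailingEngine:
            time_dependent = False
            calls = 0

            def pcoord(self, state):
                return np.array([0.5])

            def propagate(self, state, tau, rng):
                FailingEngine.calls += 1
                if FailingEngine.calls > 5:
                    raise RuntimeError("boom")
                return state

        scheme = BinScheme([[0, 1]], target_count=2)
        cfg = WEConfig(tau=1.0, n_iterations=50, initial_states=[object()])
        with pytest.raises(WERunError) as ei:
            run_we(FailingEngine(), scheme, cfg)
        assert ei.value.store is not None
        assert ei.value.iteration >= 1
        assert len(ei.value.store.iterations) >= 1
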