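"""Recycling, Hill-relation MFPT and the transition-matrix route."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import make_walker
from wesample.binning import BinScheme
from wesample.core import Ensemble
from wesample.fixtures import make_birth_death
from wesample.steady_state import (
    FluxSeries,
    StateDefinition,
    TransitionEstimate,
    estimate_transition_matrix,
    flux_from_matrix,
    flux_table,
    fpt_distribution,
    hill_mfpt,
    recycle,
    running_average,
    solve_steady_state,
)
from wesample.store import IterationRecord, RunStore


class TestRecycle:
    B = StateDefinition.at_least("B", 10.0)

    @staticmethod
    def sampler(rng):
        return ("init", np.array([0.0]))

    def test_arrival_replaced_with_same_weight(self, rng):
        ens = Ensemble(
            [make_walker(0, 0.99, [3.0]), make_walker(1, 0.01, [12.0])]
        )
        out, w = recycle(ens, self.B, self.sampler, rng)
        assert w == pytest.approx(0.01)
        fresh = [x for x in out.walkers if x.id not in (0,)]
        assert len(out) == 2
        repl = [x for x in out.walkers if x.pcoord[0] == 0.0][0]
        assert repl.weight == pytest.approx(0.01)
        assert repl.parent_id == 1
        assert fresh is not None

    def test_no_arrivals_is_identity(self, rng):
        ens = Ensemble([make_walker(0, 1.0, [3.0])])
        out, w = recycle(ens, self.B, self.sampler, rng)
        assert w == 0.0
        assert out is ens

    def test_many_arrivals_conserve_weight_exactly(self, rng):
        ens = Ensemble(
            [make_walker(i, 1.0 / 8, [11.0 if i % 2 else 1.0]) for i in range(8)]
        )
        before = ens.total_weight
        out, w = recycle(ens, self.B, self.sampler, rng)
        assert out.total_weight == pytest.approx(before, abs=1e-15)
        assert w == pytest.approx(0.5)

    def test_sampler_inside_target_is_ill_posed(self, rng):
        ens = Ensemble([make_walker(0, 1.0, [11.0])])
        bad = lambda rng: ("s", np.array([15.0]))
        with pytest.raises(ValueError, match="ill-posed"):
            recycle(ens, self.B, bad, rng)


class TestHillMFPT:
    def test_constant_flux_reciprocal(self):
        f = FluxSeries(weights=np.full(100, 0.2), tau=1.0)
        est = hill_mfpt(f, burn_in=0.5)
        assert est.mfpt == pytest.approx(5.0)

    def test_running_average_uses_most_recent_half(self):
        f = FluxSeries(weights=np.array([0.0, 0.0, 4e-4, 2e-4]), tau=1.0)
        ra = running_average(f.weights)
        assert ra[-1] == pytest.approx(3e-4)  # mean of the last two entries
        assert ra[0] == 0.0
        # independent naive evaluation
        vals = f.weights
        for t in range(4):
            win = math.ceil((t + 1) / 2)
            assert ra[t] == pytest.approx(np.mean(vals[t + 1 - win : t + 1]))

    def test_tau_scaling(self):
        f = FluxSeries(weights=np.full(50, 0.02), tau=0.1)
        est = hill_mfpt(f)
        assert est.mean_flux == pytest.approx(0.2)
        assert est.mfpt == pytest.approx(5.0)

    def test_all_zero_flux_yields_lower_bound_not_division(self):
        f = FluxSeries(weights=np.zeros(40), tau=0.5)
        est = hill_mfpt(f)
        assert est.no_arrivals
        assert est.mfpt == float("inf")
        assert est.mfpt_lower_bound == pytest.approx(20 * 0.5)

    def test_flux_entries_validated(self):
        with pytest.raises(ValueError):
            FluxSeries(weights=np.array([1.5]), tau=1.0)

    def test_flux_table_columns(self):
        f = FluxSeries(weights=np.array([0.0, 0.1, 0.1, 0.2]), tau=0.5)
        df = flux_table(f)
        assert list(df.columns) == [
            "iteration",
            "time",
            "flux",
            "running_avg_flux",
            "mfpt_estimate",
        ]
        assert df.mfpt_estimate.iloc[0] == np.inf
        assert df.mfpt_estimate.iloc[-1] == pytest.approx(
            1.0 / df.running_avg_flux.iloc[-1]
        )


def _synthetic_store(k_true, n_walkers, n_iters, seed, tau=1.0):
    """RunStore written from a known Markov chain (multinomial draws)."""
    rng = np.random.default_rng(seed)
    n_bins = k_true.shape[0]
    store = RunStore()
    store.meta = {"tau": tau}
    store.scheme_edges = [np.arange(n_bins + 1, dtype=float)]
    bins = rng.integers(0, n_bins, n_walkers)
    ids = np.arange(n_walkers)
    w = np.full(n_walkers, 1.0 / n_walkers)
    for it in range(n_iters + 1):
        store.iterations.append(
            IterationRecord(
                index=it,
                ids=ids.copy(),
                parent_ids=ids.copy(),
                weights=w.copy(),
                pcoords=bins[:, None].astype(float) + 0.5,
                bins=bins.copy(),
            )
        )
        nxt = np.array(
            [rng.choice(n_bins, p=k_true[b]) for b in bins], dtype=np.int64
        )
        bins = nxt
    return store


class TestTransitionMatrix:
    def test_identity_when_weight_stays_put(self):
        k = np.eye(2)
        store = _synthetic_store(k, n_walkers=10, n_iters=5, seed=0)
        est = estimate_transition_matrix(store, BinScheme([[0, 1, 2]]))
        assert np.allclose(est.k[est.observed], np.eye(2)[est.observed])

    def test_rows_sum_to_one(self):
        k = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.25, 0.25, 0.5]])
        store = _synthetic_store(k, 50, 40, seed=1)
        est = estimate_transition_matrix(store, BinScheme([[0, 1, 2, 3]]))
        assert np.allclose(est.k[est.observed].sum(axis=1), 1.0, atol=1e-12)

    def test_recovers_known_chain_within_multinomial_error(self):
        k = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.25, 0.25, 0.5]])
        store = _synthetic_store(k, 200, 60, seed=2)
        scheme = BinScheme([[0, 1, 2, 3]])
        est = estimate_transition_matrix(store, scheme)
        counts = est.weight_flow * 200  # equal weights -> counts
        for i in range(3):
            n_i = counts[i].sum()
            sigma = np.sqrt(k[i] * (1 - k[i]) / n_i)
            assert np.all(np.abs(est.k[i] - k[i]) < 3.5 * sigma + 1e-9)

    def test_broken_lineage_detected(self):
        store = _synthetic_store(np.eye(2), 5, 3, seed=0)
        store.iterations[2].parent_ids = store.iterations[2].parent_ids + 1000
        with pytest.raises(ValueError, match="lineage"):
            estimate_transition_matrix(store, BinScheme([[0, 1, 2]]))


class TestSolveSteadyState:
    @staticmethod
    def _estimate(k):
        k = np.asarray(k, dtype=float)
        return TransitionEstimate(
            k=k,
            weight_flow=k.copy(),
            observed=k.sum(axis=1) > 0,
            tau=1.0,
        )

    def test_symmetric_two_state(self):
        p = solve_steady_state(self._estimate([[0.7, 0.3], [0.3, 0.7]]))
        assert p == pytest.approx([0.5, 0.5])

    def test_matches_dominant_eigenvector(self, rng):
        k = rng.random((5, 5)) + 0.05
        k /= k.sum(axis=1, keepdims=True)
        p = solve_steady_state(self._estimate(k))
        vals, vecs = np.linalg.eig(k.T)
        v = np.real(vecs[:, np.argmax(np.real(vals))])
        v = np.abs(v) / np.abs(v).sum()
        assert np.allclose(p, v, atol=1e-10)

    def test_birth_death_detailed_balance_closed_form(self):
        # tau-step transition matrix of a truncated birth-death chain has
        # the same stationary law as the generator: renormalized Poisson
        fx = make_birth_death(3.0, 1.0, 8)
        k = expm(fx.generator(8) * 0.3)
        p = solve_steady_state(self._estimate(k))
        assert np.allclose(p, fx.stationary_pmf(8), atol=1e-8)

    def test_reducible_matrix_raises_with_blocks(self):
        k = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="reducible"):
            solve_steady_state(self._estimate(k))


class TestFluxFromMatrix:
    def test_no_transitions_into_target_is_zero_with_warning(self):
        est = TestSolveSteadyState._estimate([[1.0, 0.0], [0.5, 0.5]])
        with pytest.warns(UserWarning, match="no bin"):
            assert flux_from_matrix(est, np.array([], dtype=int)) == 0.0

    def test_single_source_single_term(self):
        est = TestSolveSteadyState._estimate([[0.9, 0.1], [1.0, 0.0]])
        got = flux_from_matrix(est, [1], p=np.array([1.0, 0.0]))
        assert got == pytest.approx(0.1)

    def test_state_definition_classifies_bins(self):
        scheme = BinScheme.integer_bins(0, 1)
        est = TestSolveSteadyState._estimate([[0.8, 0.2], [0.9, 0.1]])
        b = StateDefinition.at_least("B", 1.0)
        flux = flux_from_matrix(est, b, scheme=scheme)
        p = solve_steady_state(est)
        assert flux == pytest.approx(p[0] * 0.2)


class TestFPTDistribution:
    @staticmethod
    def _store(fluxes, tau=0.5):
        s = RunStore()
        s.meta = {"tau": tau}
        s.scheme_edges = [np.array([0.0, 1.0])]
        empty = dict(
            ids=np.array([0]),
            parent_ids=np.array([0]),
            weights=np.array([1.0]),
            pcoords=np.zeros((1, 1)),
            bins=np.array([0]),
        )
        s.iterations.append(IterationRecord(index=0, **empty))
        for i, f in enumerate(fluxes, start=1):
            s.iterations.append(IterationRecord(index=i, flux=f, **empty))
        return s

    def test_no_arrivals_anywhere(self):
        d = fpt_distribution([self._store([0, 0, 0]), self._store([0, 0, 0])])
        assert d.no_arrivals
        assert d.total_probability == 0.0
        assert np.all(d.mean_weight == 0)

    def test_total_equals_sum_of_histogram(self):
        runs = [self._store([0.0, 1e-4, 3e-4]), self._store([2e-4, 0.0, 1e-4])]
        d = fpt_distribution(runs)
        assert d.total_probability == pytest.approx(d.mean_weight.sum())
        assert d.n_runs == 2
        assert np.all(np.isfinite(d.se_weight))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="differing"):
            fpt_distribution([self._store([0, 0]), self._store([0, 0, 0])])

    def test_single_run_has_no_error_bars(self):
        d = fpt_distribution([self._store([1e-4, 0.0])])
        assert np.all(np.isnan(d.se_weight))
        assert math.isnan(d.total_se)
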