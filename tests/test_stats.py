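"""Outcome statistics: survival, fixation, agreement, fitness, turnover."""

import numpy as np
import pandas as pd
import pytest

from cryptsim.engine import RunResult
from cryptsim.params import SimulationParams
from cryptsim.stats import (crypt_fitness, incidence, km_cumulative_hazard,
                            mutator_agreement_by_distance,
                            mutator_fixed_fraction, population_time_average,
                            turnover_and_burden_metrics)
from cryptsim.tissue import Tissue


def product_limit_oracle(times, flags):
    """Brute-force product-limit survival at each distinct time.

    Independent of the estimator under test: walks distinct times in
    order, tracking the risk set explicitly.
    """
    times = np.asarray(times, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    out = {}
    s = 1.0
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & flags)
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def _snapshot(statuses, coords=None):
    if coords is None:
        coords = [(i, 0) for i in range(len(statuses))]
    return pd.DataFrame({
        "q": [c[0] for c in coords], "r": [c[1] for c in coords],
        "n_cells": 10, "mutator_fixed": statuses,
    })


class TestKaplanMeier:
    def test_hand_example(self):
        # events at 2 and 5, censored at 3 and 7
        table = km_cumulative_hazard([2, 5, 3, 7], [True, True, False, False])
        by_time = table.set_index("time")
        assert by_time.loc[2.0, "survival"] == pytest.approx(0.75)
        assert by_time.loc[5.0, "survival"] == pytest.approx(0.375)
        assert by_time.loc[5.0, "cumulative_hazard"] == pytest.approx(
            -np.log(0.375), abs=1e-10)
        assert by_time.loc[2.0, "n_at_risk"] == 4
        assert by_time.loc[5.0, "n_at_risk"] == 2

    def test_all_censored_zero_hazard(self):
        table = km_cumulative_hazard([1, 2, 3], [False] * 3)
        assert (table["cumulative_hazard"] == 0).all()
        assert (table["survival"] == 1).all()

    def test_single_subject_event_saturates(self):
        table = km_cumulative_hazard([1.0], [True])
        assert table["survival"].iloc[-1] == 0
        assert np.isinf(table["cumulative_hazard"].iloc[-1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_cumulative_hazard([], [])

    def test_monotone_invariants(self, rng):
        times = rng.integers(1, 8, 30).astype(float)
        flags = rng.random(30) < 0.6
        table = km_cumulative_hazard(times, flags)
        assert (np.diff(table["time"]) > 0).all()
        assert (np.diff(table["survival"]) <= 1e-15).all()
        assert (np.diff(table["cumulative_hazard"]) >= -1e-15).all()
        mask = table["survival"] > 0
        np.testing.assert_allclose(
            table.loc[mask, "cumulative_hazard"],
            -np.log(table.loc[mask, "survival"]), atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(150):
            n = rng.integers(1, 20)
            times = rng.integers(0, 6, n).astype(float)  # heavy ties
            flags = rng.random(n) < rng.random()
            table = km_cumulative_hazard(times, flags)
            oracle = product_limit_oracle(times, flags)
            for _, row in table.iterrows():
                assert row["survival"] == pytest.approx(
                    oracle[row["time"]], abs=1e-12)

    def test_nelson_aalen_option(self):
        table = km_cumulative_hazard([2, 5, 3, 7], [True, True, False, False],
                                     method="nelson-aalen")
        by_time = table.set_index("time")
        # sum of d_i / n_i: 1/4 at t=2, then 1/2 at t=5
        assert by_time.loc[2.0, "cumulative_hazard"] == pytest.approx(0.25)
        assert by_time.loc[5.0, "cumulative_hazard"] == pytest.approx(0.75)


class TestMutatorFixation:
    def test_simple_fraction(self):
        snap = _snapshot([True] * 5 + [False] * 20)
        assert mutator_fixed_fraction(snap) == pytest.approx(0.2)

    def test_no_mutators(self):
        assert mutator_fixed_fraction(_snapshot([False] * 4)) == 0.0

    def test_empty_tissue_is_nan(self):
        assert np.isnan(mutator_fixed_fraction(_snapshot([])))

    def test_pooling_rule(self):
        # equal living-crypt counts: mean of fractions == pooled ratio
        snaps = [_snapshot([True, False, False, False]),
                 _snapshot([True, True, False, False]),
                 _snapshot([True, True, True, False])]
        mean_of_fracs = np.mean([mutator_fixed_fraction(s) for s in snaps])
        pooled = sum(s["mutator_fixed"].sum() for s in snaps) / 12
        assert mean_of_fracs == pytest.approx(pooled)


class TestAgreement:
    def test_all_fixed_full_agreement(self):
        snap = _snapshot([True] * 4, coords=[(0, 0), (1, 0), (2, 0), (0, 1)])
        table = mutator_agreement_by_distance(snap)
        assert (table["agreement"] == 1.0).all()

    def test_three_adjacent_crypts(self):
        snap = _snapshot([True, True, False],
                         coords=[(0, 0), (1, 0), (0, 1)])
        table = mutator_agreement_by_distance(snap).set_index("distance_class")
        assert table.loc[1, "n_pairs"] == 3
        assert table.loc[1, "agreement"] == pytest.approx(1 / 3)

    def test_alternating_line_zero_agreement_at_one(self):
        snap = _snapshot([True, False, True, False],
                         coords=[(0, 0), (1, 0), (2, 0), (3, 0)])
        table = mutator_agreement_by_distance(snap).set_index("distance_class")
        assert table.loc[1, "agreement"] == 0.0
        assert table.loc[2, "agreement"] == 1.0

    def test_translation_invariance(self):
        statuses = [True, False, True, True, False]
        coords = [(0, 0), (1, 0), (2, 1), (0, 2), (1, 2)]
        shifted = [(q + 3, r + 7) for q, r in coords]
        a = mutator_agreement_by_distance(_snapshot(statuses, coords))
        b = mutator_agreement_by_distance(_snapshot(statuses, shifted))
        pd.testing.assert_frame_equal(a, b)

    def test_requires_two_crypts(self):
        with pytest.raises(ValueError):
            mutator_agreement_by_distance(_snapshot([True]))


class TestCryptFitness:
    def test_unmutated_equals_rate_gap(self, params):
        t = Tissue(params)
        fit = crypt_fitness(t.crypts[0], params)
        assert fit == pytest.approx(0.05 - 0.04878, abs=1e-12)

    def test_deleterious_division_burden(self, params):
        t = Tissue(params)
        t.ndd[:t.n_cells_total] = 1
        fit = crypt_fitness(t.crypts[0], params)
        assert fit == pytest.approx(0.05 / 1.01 - 0.04878, abs=1e-12)

    def test_opposing_mutations_cancel(self, params):
        t = Tissue(params)
        t.ndd[:t.n_cells_total] = 1
        t.nbd[:t.n_cells_total] = 1
        fit = crypt_fitness(t.crypts[0], params)
        assert fit == pytest.approx(0.00122, abs=1e-12)

    def test_feedback_excluded(self, params):
        # fitness is genotype-intrinsic: population size must not matter
        t = Tissue(params)
        t.remove_cell(0)  # crypt 0 now below target
        assert crypt_fitness(t.crypts[0], params) == pytest.approx(
            0.00122, abs=1e-12)

    def test_dead_crypt_rejected(self, params):
        t = Tissue(params)
        for i in sorted(t.crypt_cell_indices(0), reverse=True):
            t.remove_cell(i)
        t.mark_extinct((0, 0), 1.0)
        with pytest.raises(ValueError):
            crypt_fitness(t.crypts[0], params)


def _result(**kw):
    p = SimulationParams()
    base = dict(endpoint="censored", endpoint_time=3000.0,
                initiating_cell_was_mutator=None, seed=0, params=p,
                n_symmetric_divisions=100, n_asymmetric_divisions=2000,
                n_losses=100, n_general_mutations=250, n_tsg_hits=50,
                mean_cells_tw=250.0, mean_cells_per_crypt_tw=10.0,
                n_living_crypts_final=25, mutator_fixed_crypts_final=0,
                final_tissue_snapshot=pd.DataFrame(), turnover_log=[])
    base.update(kw)
    return RunResult(**base)


class TestTurnoverMetrics:
    def test_counts_and_lifespan(self):
        log = [("crypt_birth", 100.0, 0, 0, 1, 0, 100.0),
               ("crypt_death", 150.0, 2, 0, None, None, 0.0),
               ("crypt_birth", 200.0, 2, 0, 1, 0, 200.0)]
        m = turnover_and_burden_metrics(_result(turnover_log=log))
        assert m["crypt_births"] == 2
        assert m["crypt_deaths"] == 1
        assert m["mean_crypt_lifespan_days"] == pytest.approx(150.0)

    def test_empty_log(self):
        m = turnover_and_burden_metrics(_result())
        assert m["crypt_births"] == 0 and m["crypt_deaths"] == 0
        assert np.isnan(m["mean_crypt_lifespan_days"])

    def test_rates_per_day(self):
        m = turnover_and_burden_metrics(_result())
        assert m["mutations_per_day"] == pytest.approx(300 / 3000)
        assert m["divisions_per_day"] == pytest.approx(2100 / 3000)

    def test_incidence_helper(self):
        rs = [_result(), _result(endpoint="initiation"),
              _result(endpoint="initiation"), _result(endpoint="tissue_death")]
        assert incidence(rs) == pytest.approx(0.5)


class TestPopulationTimeAverage:
    def test_piecewise_constant_integral(self):
        # population 10 until t=4, then 11 until t=8, then 10
        log = [(4.0, "symmetric_division", 0, 0, 1, 11, "-", 0),
               (8.0, "cell_loss", 0, 0, 2, 10, "-", 0)]
        r = _result(event_log=log,
                    params=SimulationParams(grid_rows=1, grid_cols=1),
                    endpoint_time=10.0)
        avg = population_time_average(r, 2.0, 10.0)
        assert avg == pytest.approx((10 * 2 + 11 * 4 + 10 * 2) / 8)

    def test_requires_event_log(self):
        with pytest.raises(ValueError, match="record_events"):
            population_time_average(_result(), 0, 10)
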