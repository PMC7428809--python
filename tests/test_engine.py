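"""Event scheduling, event application, endpoints, and determinism."""

import numpy as np
import pytest

from cryptsim.engine import (apply_event, cell_rate_arrays, derive_seeds,
                             next_event, run, run_replicates, summary_frame)
from cryptsim.params import SimulationParams
from cryptsim.tissue import Tissue

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def _single_cell_params(**kw):
    """One crypt of one cell with no feedback and no floors."""
    base = dict(grid_rows=1, grid_cols=1, crypt_size=1,
                division_min_time=0.0, loss_min_time=0.0,
                mutation_rate=0.0, tsg_mutation_rate=0.0)
    base.update(kw)
    return SimulationParams(**base)


class TestNextEvent:
    def test_kind_frequencies_proportional_to_rates(self, rng):
        p = _single_cell_params()
        t = Tissue(p)
        total = 0.05 + 1.0 + 0.04878
        n = 30000
        kinds = {"symmetric_division": 0, "asymmetric_division": 0,
                 "cell_loss": 0}
        for _ in range(n):
            kinds[next_event(t, rng).kind] += 1
        for kind, rate in [("symmetric_division", 0.05),
                           ("asymmetric_division", 1.0),
                           ("cell_loss", 0.04878)]:
            q = rate / total
            se = np.sqrt(n * q * (1 - q))
            assert abs(kinds[kind] - n * q) < 4 * se

    def test_equal_cells_selected_equally(self, rng):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=2,
                             mutation_rate=0.0, tsg_mutation_rate=0.0)
        t = Tissue(p)
        n = 20000
        picks = sum(next_event(t, rng).cell_id == 0 for _ in range(n))
        assert abs(picks - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_division_floor_honored(self, rng):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=1,
                             mutation_rate=0.0, tsg_mutation_rate=0.0)
        t = Tissue(p)
        waits = []
        for _ in range(2000):
            ev = next_event(t, rng)
            if ev.kind.endswith("division"):
                waits.append(ev.time - t.current_time)
        assert min(waits) >= p.division_min_time

    def test_dead_tissue_raises(self, rng):
        p = _single_cell_params()
        t = Tissue(p)
        t.remove_cell(0)
        with pytest.raises(ValueError, match="no living"):
            next_event(t, rng)


class TestApplyEvent:
    def test_population_accounting(self, rng):
        p = SimulationParams(grid_rows=2, grid_cols=2, crypt_size=5,
                             mutation_rate=0.0, tsg_mutation_rate=0.0)
        t = Tissue(p)
        for _ in range(400):
            before = t.n_cells_total
            if before == 0:
                break
            ev = next_event(t, rng)
            apply_event(t, ev, rng)
            delta = t.n_cells_total - before
            expected = {"symmetric_division": 1, "cell_loss": -1,
                        "asymmetric_division": 0}[ev.kind]
            assert delta == expected
            assert t.crypt_counts[:].sum() == t.n_cells_total

    def test_stale_event_rejected(self, rng):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=3,
                             mutation_rate=0.0, tsg_mutation_rate=0.0)
        t = Tissue(p)
        ev = next_event(t, rng)
        t.remove_cell(ev.cell_index)
        t.remove_cell(0)
        with pytest.raises(ValueError, match="stale"):
            apply_event(t, ev, rng)

    def test_asymmetric_without_mutation_changes_nothing(self, rng):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=4,
                             mutation_rate=0.0, tsg_mutation_rate=0.0)
        t = Tissue(p)
        while True:
            ev = next_event(t, rng)
            if ev.kind == "asymmetric_division":
                break
        before = t.n_cells_total
        muts = apply_event(t, ev, rng)
        assert muts == [] and t.n_cells_total == before


class TestRun:
    def test_no_mutations_censors_at_horizon(self, quiet_params):
        r = run(quiet_params, 7)
        assert r.endpoint == "censored"
        assert r.endpoint_time == quiet_params.max_days
        assert r.total_mutations == 0

    def test_same_seed_bit_identity(self, quiet_params):
        a = run(quiet_params, 11, record_events=True)
        b = run(quiet_params, 11, record_events=True)
        assert a.event_log == b.event_log
        assert a.summary_row() == b.summary_row()
        assert a.final_tissue_snapshot.equals(b.final_tissue_snapshot)

    def test_event_log_time_monotone(self, quiet_params):
        r = run(quiet_params, 3, record_events=True)
        times = [row[0] for row in r.event_log]
        assert all(t2 >= t1 for t1, t2 in zip(times, times[1:]))

    def test_event_log_population_deltas(self):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=10,
                             mutation_rate=0.0, tsg_mutation_rate=0.0,
                             max_days=300.0)
        r = run(p, 5, record_events=True)
        n = 10
        for row in r.event_log:
            kind, n_after = row[1], row[5]
            n += {"symmetric_division": 1, "cell_loss": -1,
                  "asymmetric_division": 0}[kind]
            assert n_after == n

    def test_single_cell_crypts_have_massive_turnover(self):
        # one-cell crypts die constantly and are refilled by neighbor
        # fission; ten-cell crypts at baseline essentially never die
        p1 = SimulationParams(crypt_size=1, mutation_rate=0.0,
                              tsg_mutation_rate=0.0, max_days=2000.0)
        p10 = p1.replace(crypt_size=10)
        deaths1 = sum(run(p1, s).crypt_deaths for s in range(5))
        deaths10 = sum(run(p10, s).crypt_deaths for s in range(5))
        assert deaths1 > 1000
        assert deaths1 > 100 * (deaths10 + 1)

    def test_forced_initiation_records_mutator_flag(self):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=5,
                             mutation_rate=0.0, tsg_mutation_rate=0.2,
                             tsg_mutation_rate_max=0.2)
        r = run(p, 1)
        assert r.endpoint == "initiation"
        assert r.initiating_cell_was_mutator is False
        assert r.endpoint_time <= p.max_days
        assert r.n_tsg_hits >= 2

    def test_uncontrolled_endpoint_when_enabled(self):
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=10,
                             uncontrolled_threshold=1.0,
                             mutation_rate=0.0, tsg_mutation_rate=0.0)
        r = run(p, 2, enable_uncontrolled_endpoint=True)
        assert r.endpoint == "uncontrolled_proliferation"
        # disabled by default: the same run censors instead
        r2 = run(p.replace(max_days=100.0), 2)
        assert r2.endpoint in ("censored", "tissue_death")

    def test_python_path_matches_kernel_distribution(self):
        # mean population at t=30 d agrees between the two executions
        p = SimulationParams(grid_rows=1, grid_cols=1, crypt_size=5,
                             mutation_rate=0.0, tsg_mutation_rate=0.0,
                             max_days=30.0)
        finals = {}
        for use_kernel in (True, False):
            ns = []
            for s in range(250):
                r = run(p, s, use_kernel=use_kernel)
                snap = r.final_tissue_snapshot
                ns.append(snap["n_cells"].sum() if len(snap) else 0)
            finals[use_kernel] = np.asarray(ns, dtype=float)
        se = np.sqrt(finals[True].var(ddof=1) / 250
                     + finals[False].var(ddof=1) / 250)
        assert abs(finals[True].mean() - finals[False].mean()) < 3.5 * se

    def test_turnover_logged_for_small_crypts(self):
        p = SimulationParams(grid_rows=2, grid_cols=2, crypt_size=2,
                             mutation_rate=0.0, tsg_mutation_rate=0.0,
                             max_days=2000.0)
        r = run(p, 9)
        deaths = [rec for rec in r.turnover_log if rec[0] == "crypt_death"]
        births = [rec for rec in r.turnover_log if rec[0] == "crypt_birth"]
        assert len(deaths) > 0
        # every fission event targeted a previously dead slot
        assert all(rec[4] is not None for rec in births)


class TestReplicates:
    def test_zero_replicates_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            run_replicates(quiet_params, 0, 1)

    def test_reproducible_and_distinct_seeds(self, quiet_params):
        a = run_replicates(quiet_params, 3, 5)
        b = run_replicates(quiet_params, 3, 5)
        assert [r.seed for r in a] == [r.seed for r in b]
        assert len({r.seed for r in a}) == 3
        assert summary_frame(a).equals(summary_frame(b))

    def test_derived_seeds_distinct_and_bounded(self):
        seeds = derive_seeds(123, 500)
        assert len(set(seeds)) == 500
        assert all(0 <= s < 2 ** 31 for s in seeds)

    def test_summary_streaming(self, quiet_params, tmp_path):
        import pandas as pd

        out = tmp_path / "summary.csv"
        results = run_replicates(quiet_params, 2, 4, out_path=out)
        stored = pd.read_csv(out)
        assert len(stored) == 2
        assert list(stored["seed"]) == [r.seed for r in results]
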