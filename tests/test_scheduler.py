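"""Task planning, blocked updates and cross-strategy equivalence."""

import numpy as np
import pytest

from nmfcc import (
    RunConfig,
    SimulatedBackend,
    blocked_update_step,
    generate_planted_data,
    initialize_factors,
    kl_divergence,
    partition_rows,
    plan_tasks,
    run_all,
    update_step,
)
from nmfcc.nmf import RankError
from nmfcc.scheduler import ALL_WORKERS, PartitionError, RunFailure, SynchronizationError

from conftest import random_factors


class TestPlanTasks:
    def test_grid_size_and_task_conservation(self):
        cfg = RunConfig(k_min=2, k_max=4, num_clusterings=7, strategy="kfactor",
                        n_workers=2)
        plan = plan_tasks(cfg, 50, 20)
        assert len(plan.tasks) == 21
        pairs = {(t.k, t.run_index) for t in plan.tasks}
        assert pairs == {(k, r) for k in range(2, 5) for r in range(7)}

    def test_serial_puts_everything_on_worker_zero_in_order(self):
        cfg = RunConfig(k_min=2, k_max=3, num_clusterings=3, strategy="serial")
        plan = plan_tasks(cfg, 10, 10)
        assert all(t.assigned_worker == 0 for t in plan.tasks)
        assert [(t.k, t.run_index) for t in plan.tasks] == [
            (k, r) for k in (2, 3) for r in range(3)
        ]

    def test_kfactor_keeps_each_k_on_one_worker(self):
        cfg = RunConfig(k_min=2, k_max=5, num_clusterings=10,
                        strategy="kfactor", n_workers=4)
        plan = plan_tasks(cfg, 100, 40)
        workers_by_k = {}
        for t in plan.tasks:
            workers_by_k.setdefault(t.k, set()).add(t.assigned_worker)
        assert all(len(ws) == 1 for ws in workers_by_k.values())
        # 4 k values over 4 workers: exactly one k each
        assert sorted(next(iter(ws)) for ws in workers_by_k.values()) == [0, 1, 2, 3]

    def test_kfactor_load_balance_within_one_k(self):
        cfg = RunConfig(k_min=2, k_max=8, num_clusterings=5,
                        strategy="kfactor", n_workers=3)
        plan = plan_tasks(cfg, 100, 40)
        loads = {}
        for t in plan.tasks:
            loads[t.assigned_worker] = loads.get(t.assigned_worker, 0) + 1
        assert max(loads.values()) - min(loads.values()) <= cfg.num_clusterings

    def test_input_matrix_tasks_are_cooperative(self):
        cfg = RunConfig(k_min=2, k_max=3, num_clusterings=2,
                        strategy="input-matrix", n_workers=3)
        plan = plan_tasks(cfg, 30, 12)
        assert all(t.assigned_worker == ALL_WORKERS for t in plan.tasks)

    def test_seeds_follow_the_derivation_rule(self):
        cfg = RunConfig(k_min=2, k_max=3, num_clusterings=2, base_seed=5)
        plan = plan_tasks(cfg, 10, 10)
        assert {(t.k, t.run_index): t.seed for t in plan.tasks} == {
            (2, 0): 20005, (2, 1): 20006, (3, 0): 30005, (3, 1): 30006,
        }

    def test_rank_error_when_k_exceeds_dims(self):
        cfg = RunConfig(k_min=2, k_max=12)
        with pytest.raises(RankError):
            plan_tasks(cfg, 100, 10)


class TestPartitionRows:
    @pytest.mark.parametrize(
        "n, w, sizes",
        [(10, 4, [3, 3, 2, 2]), (7, 1, [7]), (4, 4, [1, 1, 1, 1]),
         (9, 2, [5, 4])],
    )
    def test_balanced_contiguous_cover(self, n, w, sizes):
        blocks = partition_rows(n, w)
        assert [len(b) for b in blocks] == sizes
        flat = [i for b in blocks for i in b]
        assert flat == list(range(n))

    def test_more_workers_than_rows_is_an_error(self):
        with pytest.raises(PartitionError):
            partition_rows(3, 4)


class TestBlockedUpdate:
    def test_single_worker_is_bitwise_identical_to_serial(self):
        rng = np.random.default_rng(0)
        V = rng.random((8, 6)) * 2
        f = random_factors(8, 6, 2, rng)
        serial = update_step(V, f)
        blocked = blocked_update_step(V, f, SimulatedBackend(1))
        assert np.array_equal(blocked.W, serial.W)
        assert np.array_equal(blocked.H, serial.H)

    @pytest.mark.parametrize("n_workers", [2, 3])
    def test_matches_serial_within_reduction_tolerance(self, n_workers):
        rng = np.random.default_rng(1)
        V = rng.random((8, 6)) * 2
        f = random_factors(8, 6, 2, rng)
        serial = update_step(V, f)
        blocked = blocked_update_step(V, f, SimulatedBackend(n_workers))
        np.testing.assert_allclose(blocked.W, serial.W, rtol=1e-6)
        np.testing.assert_allclose(blocked.H, serial.H, rtol=1e-6)

    def test_hundred_iterations_end_to_end_against_serial(self):
        d = generate_planted_data(40, 16, 2, separation=4.0, noise_scale=0.2,
                                  seed=3)
        V = d.matrix.values
        backend = SimulatedBackend(4)
        f_serial = initialize_factors(*V.shape, 2, seed=9)
        f_blocked = initialize_factors(*V.shape, 2, seed=9)
        for _ in range(100):
            f_serial = update_step(V, f_serial)
            f_blocked = blocked_update_step(V, f_blocked, backend)
        d_serial = kl_divergence(V, f_serial)
        d_blocked = kl_divergence(V, f_blocked)
        assert d_blocked == pytest.approx(d_serial, rel=1e-4)

    def test_allreduce_rejects_missing_partials(self):
        backend = SimulatedBackend(3)
        with pytest.raises(SynchronizationError):
            backend.allreduce_sum([np.zeros((2, 2))] * 2)


@pytest.fixture(scope="module")
def dataset():
    return generate_planted_data(60, 18, 3, separation=5.0,
                                 noise_scale=0.3, seed=4)


class TestRunAll:
    def _config(self, strategy, workers=1):
        return RunConfig(k_min=2, k_max=3, num_clusterings=4,
                         max_iterations=300, stop_convergence=5,
                         strategy=strategy, n_workers=workers, base_seed=17)

    def test_serial_and_kfactor_identical(self, dataset):
        res_s, rep_s = run_all(dataset.matrix, self._config("serial"))
        res_k, rep_k = run_all(dataset.matrix, self._config("kfactor", 2))
        for k in (2, 3):
            assert np.array_equal(res_s[k][0].values, res_k[k][0].values)
        assert rep_s.selected_k == rep_k.selected_k

    def test_serial_and_input_matrix_agree(self, dataset):
        res_s, _ = run_all(dataset.matrix, self._config("serial"))
        res_b, _ = run_all(dataset.matrix, self._config("input-matrix", 2))
        for k in (2, 3):
            np.testing.assert_allclose(
                res_b[k][0].values, res_s[k][0].values, atol=1e-6
            )

    def test_report_has_one_record_per_k(self, dataset):
        cfg = RunConfig(k_min=2, k_max=3, num_clusterings=5,
                        max_iterations=200, stop_convergence=5)
        _, report = run_all(dataset.matrix, cfg)
        assert [r.k for r in report.records] == [2, 3]
        assert all(r.n_runs == 5 for r in report.records)

    def test_failed_run_names_the_task(self, dataset):
        cfg = RunConfig(k_min=2, k_max=2, num_clusterings=1)

        def broken_backend_step(*a, **kw):
            raise FloatingPointError("boom")

        import nmfcc.scheduler as sched
        bad = dataset.matrix
        orig = sched.run_nmf
        try:
            sched.run_nmf = broken_backend_step
            with pytest.raises(RunFailure, match=r"k=2, run_index=0"):
                run_all(bad, cfg)
        finally:
            sched.run_nmf = orig
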