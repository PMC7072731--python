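"""Pareto dominance, archive invariants, and MOPSO convergence on a surrogate."""

import numpy as np
import pytest

from ubp_pred.classifier import PARAM_BOUNDS, PARAM_ORDER, HyperParams
from ubp_pred.evaluation import MetricSet
from ubp_pred.tuning import (
    ArchiveEntry,
    ParetoArchive,
    crowding_distances,
    dominates,
    hypervolume_2d,
    mopso_tune,
    search_box,
)


class TestDominates:
    def test_componentwise_better(self):
        assert dominates((0.9, 0.9), (0.8, 0.8))

    def test_incomparable(self):
        assert not dominates((0.9, 0.7), (0.7, 0.9))
        assert not dominates((0.7, 0.9), (0.9, 0.7))

    def test_identical_not_dominating(self):
        assert not dominates((0.5, 0.5), (0.5, 0.5))

    def test_equal_in_one_strict_in_other(self):
        assert dominates((0.5, 0.6), (0.5, 0.5))

    def test_arity_mismatch_is_error(self):
        with pytest.raises(ValueError):
            dominates((0.5,), (0.5, 0.5))


def entry(objectives, position=None):
    pos = np.zeros(8) if position is None else position
    m = MetricSet(objectives[0], objectives[-1], 0, 0, 0, float(np.mean(objectives)))
    return ArchiveEntry(pos, tuple(objectives), m)


class TestArchive:
    def test_dominating_point_replaces(self):
        archive = ParetoArchive()
        archive.insert(entry((0.5, 0.5)))
        archive.insert(entry((0.9, 0.9)))
        assert [e.objectives for e in archive.entries] == [(0.9, 0.9)]

    def test_dominated_point_refused(self):
        archive = ParetoArchive()
        archive.insert(entry((0.9, 0.9)))
        assert not archive.insert(entry((0.5, 0.5)))
        assert len(archive) == 1

    def test_incomparable_point_added(self):
        archive = ParetoArchive()
        archive.insert(entry((0.9, 0.1)))
        archive.insert(entry((0.1, 0.9)))
        assert len(archive) == 2

    def test_nondomination_invariant_random_stream(self):
        rng = np.random.default_rng(0)
        archive = ParetoArchive(capacity=30)
        for _ in range(500):
            archive.insert(entry(tuple(rng.uniform(size=2))))
            objs = [e.objectives for e in archive.entries]
            # brute-force pairwise scan
            for i, a in enumerate(objs):
                for j, b in enumerate(objs):
                    if i != j:
                        assert not dominates(a, b)
        assert len(archive) <= 30

    def test_capacity_pruning_keeps_extremes(self):
        archive = ParetoArchive(capacity=5)
        for x in np.linspace(0, 1, 20):
            archive.insert(entry((float(x), float(1 - x))))
        assert len(archive) == 5
        objs = [e.objectives for e in archive.entries]
        assert (0.0, 1.0) in objs and (1.0, 0.0) in objs

    def test_best_by_mcc(self):
        archive = ParetoArchive()
        archive.insert(entry((0.2, 0.9)))
        archive.insert(entry((0.9, 0.2)))
        best = archive.best_by("sen")
        assert best.objectives == (0.9, 0.2)


class TestCrowdingAndHypervolume:
    def test_boundary_points_infinite(self):
        d = crowding_distances([(0.1, 0.9), (0.5, 0.5), (0.9, 0.1)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert np.isfinite(d[1])

    def test_hypervolume_single_point(self):
        assert hypervolume_2d([(0.5, 0.4)]) == pytest.approx(0.2)

    def test_hypervolume_staircase(self):
        # union of [0,1]x[0,0.5] and [0,0.5]x[0,1] has area 0.75
        assert hypervolume_2d([(1.0, 0.5), (0.5, 1.0)]) == pytest.approx(0.75)

    def test_dominated_point_adds_nothing(self):
        front = [(1.0, 0.5), (0.5, 1.0)]
        assert hypervolume_2d(front + [(0.4, 0.4)]) == hypervolume_2d(front)


def normalized(params: HyperParams) -> np.ndarray:
    low, high = search_box()
    vec = np.array([getattr(params, name) for name in PARAM_ORDER], dtype=float)
    return (vec - low) / (high - low)


def make_surrogate(optimum_normalized: np.ndarray):
    """Two objectives, both 1 - normalized distance to a known interior point."""

    def evaluate(params: HyperParams) -> MetricSet:
        dist = float(np.linalg.norm(normalized(params) - optimum_normalized))
        value = 1.0 - dist / np.sqrt(8)
        return MetricSet(sen=value, spe=value, pre=value, acc=value, f1=value, mcc=value)

    return evaluate


class TestMopso:
    OPTIMUM = np.array([0.3, 0.6, 0.4, 0.7, 0.5, 0.2, 0.8, 0.35])

    def test_surrogate_convergence_within_five_percent(self):
        best, archive, history = mopso_tune(
            make_surrogate(self.OPTIMUM), swarm_size=20, max_iter=50, seed=0
        )
        dist = np.linalg.norm(normalized(best) - self.OPTIMUM)
        assert dist <= 0.05 * np.sqrt(8)

    def test_positions_respect_box(self):
        best, archive, _ = mopso_tune(
            make_surrogate(self.OPTIMUM), swarm_size=10, max_iter=10, seed=1
        )
        low, high = search_box()
        for e in archive.entries:
            clipped = np.clip(e.position, low, high)
            assert np.allclose(e.position, clipped)
        for name, (lo, hi, _) in PARAM_BOUNDS.items():
            assert lo <= getattr(best, name) <= hi

    def test_hypervolume_nondecreasing(self):
        _, _, history = mopso_tune(
            make_surrogate(self.OPTIMUM), swarm_size=10, max_iter=30, seed=2
        )
        hv = [h["hypervolume"] for h in history]
        assert all(b >= a - 1e-12 for a, b in zip(hv, hv[1:]))

    def test_reproducible_for_fixed_seed(self):
        a, _, _ = mopso_tune(make_surrogate(self.OPTIMUM), swarm_size=8, max_iter=10, seed=5)
        b, _, _ = mopso_tune(make_surrogate(self.OPTIMUM), swarm_size=8, max_iter=10, seed=5)
        assert a == b

    def test_swarm_size_particles_created(self):
        calls = []

        def counting(params: HyperParams) -> MetricSet:
            calls.append(params)
            return MetricSet(0.5, 0.5, 0.5, 0.5, 0.5, 0.5)

        mopso_tune(counting, swarm_size=80, max_iter=0, seed=0)
        assert len(calls) == 80

    def test_all_failures_is_error(self):
        def failing(params):
            raise RuntimeError("no evaluation possible")

        with pytest.raises(RuntimeError, match="empty archive"):
            mopso_tune(failing, swarm_size=4, max_iter=2, seed=0)

    def test_single_candidate_archive(self):
        # one evaluation only: archive is exactly that candidate
        seen = []

        def once(params):
            seen.append(params)
            if len(seen) > 1:
                raise RuntimeError("only one evaluation allowed")
            return MetricSet(0.4, 0.6, 0.5, 0.5, 0.5, 0.3)

        best, archive, _ = mopso_tune(once, swarm_size=1, max_iter=0, seed=0)
        assert len(archive) == 1
        assert archive.entries[0].metrics.mcc == 0.3
        assert best == HyperParams.from_vector(archive.entries[0].position)
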