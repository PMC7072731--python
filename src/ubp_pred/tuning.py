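"""Multi-objective particle swarm optimization over the hyperparameter box.

Hyperparameter tuning is cast as multi-objective optimization: each swarm
particle is an 8-dimensional point in the search box of
:data:`ubp_pred.classifier.PARAM_BOUNDS`, evaluated by cross-validated
classification, and an external archive keeps the Pareto-non-dominated
solutions found so far.  Particles move by the standard PSO velocity rule

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(leader - x)

with constriction-style coefficients (w = 0.729, c1 = c2 = 1.494), where
the social leader is drawn from the archive.  Default objectives are
(sensitivity, specificity) — the two complementary error rates of the
confusion matrix — and the final configuration is the archive member with
the highest MCC, the most reliable single selection metric.

Integer-valued parameters (n_estimators, max_depth) move in continuous
space and are rounded only at evaluation time, which avoids degenerate
swarms collapsing onto integer lattices.  Positions are clipped to the box
after every move, with the velocity zeroed on clipped components.  The
production defaults are a swarm of 80 run for 200 iterations; tests and the
bundled examples use desk-scale swarms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ubp_pred.classifier import PARAM_BOUNDS, PARAM_ORDER, HyperParams
from ubp_pred.evaluation import MetricSet

INERTIA = 0.729
COGNITIVE = 1.494
SOCIAL = 1.494

DEFAULT_SWARM_SIZE = 80
DEFAULT_MAX_ITER = 200
DEFAULT_OBJECTIVES = ("sen", "spe")
DEFAULT_ARCHIVE_CAPACITY = 100

# Fractional parameters cannot be 0 for the booster; the search box floors
# them at 0.05 (a subset of their printed [0, 1] interval).
_MIN_FRACTION = 0.05


def search_box() -> tuple[np.ndarray, np.ndarray]:
    """(low, high) bounds of the 8-dim search box in :data:`PARAM_ORDER`."""
    low, high = [], []
    for name in PARAM_ORDER:
        lo, hi, _ = PARAM_BOUNDS[name]
        if name in ("subsample", "colsample_bytree"):
            lo = _MIN_FRACTION
        low.append(lo)
        high.append(hi)
    return np.array(low, dtype=float), np.array(high, dtype=float)


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Strict Pareto dominance on maximized objectives.

    True iff ``a`` is at least as good as ``b`` in every component and
    strictly better in at least one.
    """
    if len(a) != len(b):
        raise ValueError(f"objective arity mismatch: {len(a)} vs {len(b)}")
    at_least = all(x >= y for x, y in zip(a, b))
    strictly = any(x > y for x, y in zip(a, b))
    return at_least and strictly


@dataclass
class ArchiveEntry:
    position: np.ndarray
    objectives: tuple[float, ...]
    metrics: MetricSet


@dataclass
class ParetoArchive:
    """A bounded set of mutually non-dominated solutions.

    Insertion keeps the non-domination invariant: a dominated candidate is
    refused, an accepted candidate evicts every member it dominates, and
    when capacity is exceeded the most crowded member (smallest NSGA-II
    crowding distance in objective space) is pruned first, preserving the
    spread of the front.
    """

    capacity: int = DEFAULT_ARCHIVE_CAPACITY
    entries: list[ArchiveEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def insert(self, entry: ArchiveEntry) -> bool:
        """Insert if non-dominated; returns whether the archive changed."""
        for member in self.entries:
            if dominates(member.objectives, entry.objectives) or (
                member.objectives == entry.objectives
            ):
                return False
        self.entries = [
            m for m in self.entries if not dominates(entry.objectives, m.objectives)
        ]
        self.entries.append(entry)
        if len(self.entries) > self.capacity:
            self._prune()
        return True

    def _prune(self) -> None:
        distances = crowding_distances([e.objectives for e in self.entries])
        most_crowded = int(np.argmin(distances))
        del self.entries[most_crowded]

    def best_by(self, metric: str = "mcc") -> ArchiveEntry:
        if not self.entries:
            raise ValueError("archive is empty")
        return max(self.entries, key=lambda e: getattr(e.metrics, metric))


def crowding_distances(points: list[tuple[float, ...]]) -> np.ndarray:
    """NSGA-II crowding distance of each point within its own set."""
    n = len(points)
    if n == 0:
        return np.array([])
    arr = np.asarray(points, dtype=float)
    dist = np.zeros(n)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        span = arr[order[-1], j] - arr[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        for idx in range(1, n - 1):
            dist[order[idx]] += (arr[order[idx + 1], j] - arr[order[idx - 1], j]) / span
    return dist


def hypervolume_2d(
    points: list[tuple[float, ...]], reference: tuple[float, float] = (0.0, 0.0)
) -> float:
    """Dominated hypervolume (area) of a 2-objective maximized front."""
    pts = [p for p in points if p[0] > reference[0] and p[1] > reference[1]]
    if not pts:
        return 0.0
    pts = sorted(set(pts), key=lambda p: (-p[0], -p[1]))
    area = 0.0
    prev_y = reference[1]
    for x, y in pts:
        if y > prev_y:
            area += (x - reference[0]) * (y - prev_y)
            prev_y = y
    return area


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_objectives: tuple[float, ...]


def mopso_tune(
    evaluator: Callable[[HyperParams], MetricSet],
    swarm_size: int = DEFAULT_SWARM_SIZE,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    objectives: tuple[str, ...] = DEFAULT_OBJECTIVES,
    archive_capacity: int = DEFAULT_ARCHIVE_CAPACITY,
    box: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[HyperParams, ParetoArchive, list[dict]]:
    """Tune the eight XGBoost hyperparameters by MOPSO.

    Parameters
    ----------
    evaluator:
        Maps a :class:`HyperParams` to a :class:`MetricSet` (typically via
        stratified cross-validation on a training matrix).
    swarm_size, max_iter:
        Population size and iteration budget (production defaults 80 x 200).
    objectives:
        Names of the maximized metrics forming the Pareto front.
    box:
        Override of the search box (used by tests with analytic
        surrogates); defaults to :func:`search_box`.

    Returns ``(best, archive, history)`` where ``best`` is the archive
    member with the highest MCC and ``history`` records per-iteration
    archive statistics.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    low, high = search_box() if box is None else box
    dim = len(low)

    def evaluate(position: np.ndarray) -> MetricSet:
        return evaluator(HyperParams.from_vector(np.clip(position, low, high)))

    archive = ParetoArchive(capacity=archive_capacity)
    particles: list[Particle] = []
    n_failures = 0
    for _ in range(swarm_size):
        pos = rng.uniform(low, high)
        try:
            metrics = evaluate(pos)
        except Exception:
            n_failures += 1
            metrics = None
        if metrics is None:
            objs = tuple([-np.inf] * len(objectives))
        else:
            objs = metrics.objective_values(objectives)
            archive.insert(ArchiveEntry(pos.copy(), objs, metrics))
        particles.append(
            Particle(
                position=pos,
                velocity=np.zeros(dim),
                best_position=pos.copy(),
                best_objectives=objs,
            )
        )

    history: list[dict] = []

    def record(iteration: int) -> None:
        fronts = [e.objectives for e in archive.entries]
        entry = {
            "iteration": iteration,
            "archive_size": len(archive),
            "best_mcc": max((e.metrics.mcc for e in archive.entries), default=float("nan")),
        }
        if len(objectives) == 2:
            entry["hypervolume"] = hypervolume_2d(fronts)
        history.append(entry)

    record(0)

    for iteration in range(1, max_iter + 1):
        for particle in particles:
            if archive.entries:
                leader = archive.entries[rng.integers(len(archive.entries))].position
            else:
                leader = particle.best_position
            r1 = rng.uniform(size=dim)
            r2 = rng.uniform(size=dim)
            particle.velocity = (
                INERTIA * particle.velocity
                + COGNITIVE * r1 * (particle.best_position - particle.position)
                + SOCIAL * r2 * (leader - particle.position)
            )
            particle.position = particle.position + particle.velocity
            clipped = (particle.position < low) | (particle.position > high)
            particle.position = np.clip(particle.position, low, high)
            particle.velocity[clipped] = 0.0

            try:
                metrics = evaluate(particle.position)
            except Exception:
                n_failures += 1
                continue
            objs = metrics.objective_values(objectives)
            archive.insert(ArchiveEntry(particle.position.copy(), objs, metrics))
            # Personal best: replace when the new point dominates, or when
            # incomparable with probability 1/2 (keeps exploration moving).
            if particle.best_objectives[0] == -np.inf or dominates(
                objs, particle.best_objectives
            ):
                particle.best_position = particle.position.copy()
                particle.best_objectives = objs
            elif not dominates(particle.best_objectives, objs) and rng.uniform() < 0.5:
                particle.best_position = particle.position.copy()
                particle.best_objectives = objs
        record(iteration)

    if not archive.entries:
        raise RuntimeError(
            f"MOPSO terminated with an empty archive ({n_failures} failed evaluations)"
        )
    best_entry = archive.best_by("mcc")
    best = HyperParams.from_vector(np.clip(best_entry.position, low, high))
    return best, archive, history
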