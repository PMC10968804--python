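"""Particle Swarm Optimization of the wake/N3 thresholds.

Global-best PSO over the 2-D box of (t1, t2), maximizing pooled epoch
accuracy against technician scoring.  The velocity update is

    v <- w * v + c1 * r1 * (p_i - x) + c2 * r2 * (p_g - x),   x <- x + v,

with r1, r2 ~ U(0,1) fresh per particle and dimension each iteration and
the inertia weight w ~ U(0,1) redrawn each iteration (shared across the
swarm).  Defaults: 200 particles, 40 iterations, c1 = c2 = 1.  Velocities
are clamped to a fraction of each dimension's range and positions to the
box; personal and global bests update only on strict improvement, so the
best-fitness history is non-decreasing and ties keep the first find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSeries, Thresholds
from .metrics import map_to_predicted_classes
from .signal_io import Hypnogram
from .staging import stage_night

__all__ = ["PsoConfig", "PsoResult", "fitness_accuracy", "pso_optimize",
           "DEFAULT_BOUNDS"]

#: default search box for (t1, t2); spans the plausible range of the
#: night-normalized features by a wide margin and is fully configurable
DEFAULT_BOUNDS = ((0.0, 1e-4), (0.0, 1e-3))


@dataclass(frozen=True)
class PsoConfig:
    swarm_size: int = 200
    iterations: int = 40
    c1: float = 1.0
    c2: float = 1.0
    #: "random" draws w ~ U(0,1) per iteration; a float fixes it
    inertia: str | float = "random"
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    velocity_clamp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy lo < hi")
        if isinstance(self.inertia, str) and self.inertia != "random":
            raise ValueError("inertia must be 'random' or a float")


@dataclass(frozen=True)
class PsoResult:
    best_position: tuple[float, ...]
    best_fitness: float
    history: tuple[float, ...]
    seed: int

    @property
    def thresholds(self) -> Thresholds:
        t1, t2 = self.best_position
        return Thresholds(t1=t1, t2=t2)


def fitness_accuracy(
    position: tuple[float, float],
    training: list[tuple[FeatureSeries, Hypnogram]],
    tm: float | None = None,
) -> float:
    """Pooled epoch accuracy of staging at (t1, t2) over the training nights.

    Technician 5-class labels are collapsed to {WAKE, N3, OTHER} before
    comparison.  ``tm`` fixes the movement threshold (default: the
    full-night calibration).
    """
    if not training:
        raise ValueError("empty training set")
    t1, t2 = position
    kw = {} if tm is None else {"tm": tm}
    th = Thresholds(t1=float(t1), t2=float(t2), **kw)
    correct = total = 0
    for features, truth in training:
        if features.n_epochs != len(truth):
            raise ValueError(
                f"night has {features.n_epochs} feature epochs but "
                f"{len(truth)} hypnogram epochs"
            )
        pred = stage_night(features, th).labels
        mapped = map_to_predicted_classes(truth).labels
        correct += sum(p == t for p, t in zip(pred, mapped))
        total += len(pred)
    return correct / total


def pso_optimize(fitness, cfg: PsoConfig) -> PsoResult:
    """Maximize ``fitness`` over the box with global-best PSO.

    Reproducible given ``cfg.seed``; raises on non-finite fitness values.
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = np.asarray(cfg.bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    vmax = cfg.velocity_clamp * span
    ndim = bounds.shape[0]

    x = lo + span * rng.uniform(size=(cfg.swarm_size, ndim))
    v = vmax * rng.uniform(-1, 1, size=(cfg.swarm_size, ndim))

    def evaluate(pos: np.ndarray) -> float:
        f = float(fitness(tuple(pos)))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness at position {tuple(pos)}")
        return f

    pbest = x.copy()
    pbest_f = np.array([evaluate(p) for p in x])
    g = int(np.argmax(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    history = []
    for _ in range(cfg.iterations):
        w = rng.uniform() if cfg.inertia == "random" else float(cfg.inertia)
        r1 = rng.uniform(size=(cfg.swarm_size, ndim))
        r2 = rng.uniform(size=(cfg.swarm_size, ndim))
        v = w * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        for i in range(cfg.swarm_size):
            f = evaluate(x[i])
            if f > pbest_f[i]:                      # strict improvement only
                pbest_f[i] = f
                pbest[i] = x[i]
                if f > gbest_f:
                    gbest_f = f
                    gbest = x[i].copy()
        history.append(gbest_f)

    return PsoResult(tuple(gbest), gbest_f, tuple(history), cfg.seed)
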