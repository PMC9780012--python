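"""RBF-kernel soft-margin SVM hyperparameter tuning by particle swarm
optimization tempered with a simulated-annealing acceptance rule (SAPSO).

The classifier is a standard soft-margin SVM with Gaussian kernel
``K(u, v) = exp(-g * ||u - v||^2)``; the penalty C and kernel width g are the
two coordinates of a particle, searched in log2 space over a symmetric box
(default [-10, 10]^2, i.e. C, g in [2^-10, 2^10]).  Fitness is mean
stratified cross-validated accuracy.  The underlying quadratic program is
solved by scikit-learn's SVC (libsvm); this module owns the search, not the
solver.

Plain PSO can stagnate in a local optimum: every particle move is kept
unconditionally, so the swarm's memory only ever reinforces its current
basin.  Here each particle's move is instead gated the way simulated
annealing gates a state change: a move that does not worsen the particle's
personal best is always kept, a worsening one is kept only with probability
``exp(-delta_f / T)`` where ``delta_f = f_personal_best - f_new >= 0`` and T
is a temperature cooled geometrically each iteration.  Rejected moves revert
both position and velocity.  The recorded global best is never gated, so its
fitness trace is non-decreasing.

All randomness flows from a single integer seed; results are bit-for-bit
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ConfigError

__all__ = [
    "SapsoConfig",
    "Particle",
    "SwarmState",
    "OptimResult",
    "cv_fitness",
    "sa_accept",
    "update_particle",
    "anneal",
    "sapso_optimize",
    "grid_search",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SapsoConfig:
    """SAPSO search settings.

    Positions live in (log2 C, log2 g).  ``w_start``/``w_end`` define a
    linearly decaying inertia weight; ``clamp_frac`` limits each velocity
    component to that fraction of the box width.
    """

    swarm_size: int = 20
    n_iter: int = 50
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    clamp_frac: float = 0.2
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-10.0, 10.0), (-10.0, 10.0))
    t0: float = 0.1
    alpha: float = 0.9
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ConfigError("swarm size must be >= 2")
        if self.n_iter < 1:
            raise ConfigError("need at least one iteration")
        if not 0 < self.alpha < 1:
            raise ConfigError("cooling factor alpha must lie in (0, 1)")
        if self.t0 <= 0:
            raise ConfigError("initial temperature must be > 0")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigError("bounds must be finite with lo < hi")
        if not 0 < self.clamp_frac <= 1:
            raise ConfigError("velocity clamp fraction must lie in (0, 1]")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    temperature: float
    iteration: int


@dataclass
class OptimResult:
    """Outcome of a SAPSO run over (log2 C, log2 g)."""

    best_c: float
    best_g: float
    best_fitness: float
    fitness_trace: list[float]  # global best after each iteration
    accepted_moves: int
    rejected_moves: int
    config: SapsoConfig

    @property
    def best_log2(self) -> tuple[float, float]:
        return (float(np.log2(self.best_c)), float(np.log2(self.best_g)))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key,value\n")
            fh.write(f"best_C,{self.best_c:.12g}\n")
            fh.write(f"best_g,{self.best_g:.12g}\n")
            fh.write(f"best_fitness,{self.best_fitness:.12g}\n")
            fh.write(f"accepted_moves,{self.accepted_moves}\n")
            fh.write(f"rejected_moves,{self.rejected_moves}\n")
            for i, v in enumerate(self.fitness_trace):
                fh.write(f"gbest_iter_{i + 1},{v:.12g}\n")


def cv_fitness(x, y, c: float, g: float, folds: int = 5, seed: int = 0) -> float:
    """Mean held-out accuracy of an RBF-SVM over stratified CV folds.

    ``c`` is the soft-margin penalty, ``g`` the kernel coefficient in
    ``exp(-g ||u - v||^2)``.  If a class has fewer members than ``folds``
    the fold count is lowered to keep every training fold two-class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if c <= 0 or g <= 0:
        raise ConfigError(f"C and g must be positive, got C={c}, g={g}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ConfigError("cross-validated fitness needs both classes present")
    min_count = int(counts.min())
    if min_count < folds:
        log.warning("smallest class has %d members; folds lowered from %d", min_count, folds)
        folds = max(2, min_count)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(x, y):
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(x[train], y[train])
        accs.append(float(np.mean(clf.predict(x[test]) == y[test])))
    return float(np.mean(accs))


def sa_accept(delta_f: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: keep a non-worsening move always (``delta_f <= 0``),
    a worsening one with probability ``exp(-delta_f / T)``."""
    if temperature <= 0:
        raise ConfigError(f"temperature must be > 0, got {temperature}")
    if delta_f <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_f / temperature))


def anneal(temperature: float, alpha: float) -> float:
    """Geometric cooling: T' = alpha * T."""
    if temperature <= 0:
        raise ConfigError("temperature must be > 0")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    return alpha * temperature


def _box_arrays(bounds) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    return lo, hi


def update_particle(
    particle: Particle,
    gbest_position: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    bounds,
    clamp_frac: float,
    rng: np.random.Generator,
) -> Particle:
    """Canonical PSO update with velocity clamping and position clipping.

    ``v' = w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``; each velocity
    component is clamped to ``clamp_frac`` of the box width, the new
    position is clipped to the box.
    """
    lo, hi = _box_arrays(bounds)
    vmax = clamp_frac * (hi - lo)
    r1 = rng.random(particle.position.size)
    r2 = rng.random(particle.position.size)
    v = (
        w * particle.velocity
        + c1 * r1 * (particle.best_position - particle.position)
        + c2 * r2 * (np.asarray(gbest_position, dtype=float) - particle.position)
    )
    v = np.clip(v, -vmax, vmax)
    pos = np.clip(particle.position + v, lo, hi)
    return replace(particle, position=pos, velocity=v)


def sapso_optimize(x, y, config: SapsoConfig, objective=None) -> OptimResult:
    """Run the SA-gated particle swarm over (log2 C, log2 g).

    By default the objective is :func:`cv_fitness` on ``(x, y)``; passing
    ``objective`` (a callable on a 2-vector position, to be maximised)
    replaces it, e.g. for benchmarking the optimizer on a test function,
    in which case ``x`` and ``y`` may be None.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = _box_arrays(config.bounds)

    if objective is None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ConfigError("need at least two classes")

        def objective(pos):
            return cv_fitness(x, y, 2.0 ** pos[0], 2.0 ** pos[1], config.cv_folds, config.seed)

    def safe_eval(pos):
        f = float(objective(pos))
        return f

    particles = []
    for _ in range(config.swarm_size):
        pos = rng.uniform(lo, hi)
        vel = rng.uniform(-1, 1, size=lo.size) * config.clamp_frac * (hi - lo)
        fit = safe_eval(pos)
        if not np.isfinite(fit):
            log.warning("non-finite fitness at init; particle re-initialized")
            pos = rng.uniform(lo, hi)
            fit = safe_eval(pos)
        particles.append(Particle(pos, vel, pos.copy(), fit))

    gbest_idx = int(np.argmax([p.best_fitness for p in particles]))
    gbest_pos = particles[gbest_idx].best_position.copy()
    gbest_fit = particles[gbest_idx].best_fitness

    t = config.t0
    trace = []
    accepted = rejected = 0
    for it in range(config.n_iter):
        w = config.w_start + (config.w_end - config.w_start) * (
            it / max(config.n_iter - 1, 1)
        )
        for i, p in enumerate(particles):
            moved = update_particle(p, gbest_pos, w, config.c1, config.c2, config.bounds, config.clamp_frac, rng)
            fit = safe_eval(moved.position)
            if not np.isfinite(fit):
                log.warning("non-finite fitness; particle re-initialized")
                moved = Particle(
                    rng.uniform(lo, hi), np.zeros_like(lo), p.best_position, p.best_fitness
                )
                fit = safe_eval(moved.position)
            delta_f = p.best_fitness - fit  # >0 means the move worsens
            if sa_accept(delta_f, t, rng):
                accepted += 1
                p = moved
                if fit > p.best_fitness:
                    p = replace(p, best_position=moved.position.copy(), best_fitness=fit)
            else:
                rejected += 1  # revert position and velocity
            particles[i] = p
            if p.best_fitness > gbest_fit:
                gbest_fit = p.best_fitness
                gbest_pos = p.best_position.copy()
        trace.append(gbest_fit)
        t = anneal(t, config.alpha)

    return OptimResult(
        best_c=float(2.0 ** gbest_pos[0]),
        best_g=float(2.0 ** gbest_pos[1]),
        best_fitness=gbest_fit,
        fitness_trace=trace,
        accepted_moves=accepted,
        rejected_moves=rejected,
        config=config,
    )


def grid_search(x, y, log2_values, folds: int = 5, seed: int = 0):
    """Dense CV-accuracy surface over the (log2 C, log2 g) lattice.

    Returns ``(surface, best_c, best_g, best_fitness)`` where ``surface``
    has shape ``(len(log2_values), len(log2_values))`` with rows indexing
    log2 C.  Ties resolve to the first lattice point in row-major order.
    """
    log2_values = np.asarray(log2_values, dtype=float)
    surface = np.empty((log2_values.size, log2_values.size))
    for i, lc in enumerate(log2_values):
        for j, lg in enumerate(log2_values):
            surface[i, j] = cv_fitness(x, y, 2.0**lc, 2.0**lg, folds, seed)
    i, j = np.unravel_index(int(np.argmax(surface)), surface.shape)
    return surface, float(2.0 ** log2_values[i]), float(2.0 ** log2_values[j]), float(surface[i, j])
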