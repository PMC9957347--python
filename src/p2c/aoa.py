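"""Archimedes Optimization Algorithm (AOA), a buoyancy-inspired metaheuristic.

Each member of the population is an immersed object carrying a position, a
density, a volume and an acceleration.  Every iteration, densities and
volumes drift a random fraction toward the incumbent best object; a
time-increasing transfer operator

    TF(t) = exp((t - tmax) / tmax)

switches the update from collision-based exploration (TF <= 0.5: the
acceleration is driven by a randomly chosen "material", and positions move
relative to a random object) to best-guided exploitation (TF > 0.5), while a
time-decreasing density factor

    d(t) = exp((tmax - t) / tmax) - t / tmax

damps step sizes from global to local search.  Accelerations are normalized
across the population onto [0.1, 0.9] to act as step percentages.  Position
updates use constants C1 = 2 (exploration) and C2 = 6 (exploitation), a
direction flag F in {-1, +1} drawn from P = 2*rand - C4, and an attraction
target T = C3 * TF (capped at ``t_cap``) toward the best position.

A single seeded RNG stream drives the whole run.  Random draws occur in a
fixed order per iteration: per object (density rand, volume rand); then per
object the acceleration's material index when exploring; then per object the
position-update draws (exploration: random-partner index then one rand per
dimension; exploitation: the P rand then one rand per dimension).  Reference
values (best / random material / random partner) come from a snapshot of the
population at the start of the iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AOAObject", "AOAConfig", "AOAResult",
    "initialize_population", "transfer_operator", "density_factor",
    "update_density_volume", "update_acceleration", "normalize_acceleration",
    "update_position", "optimize", "random_search",
]

_EPS = 1e-12  # stabilizer for a vanishing den*vol denominator


@dataclass
class AOAObject:
    """One population member (an immersed object)."""

    x: np.ndarray
    den: float
    vol: float
    acc: float
    fitness: float = np.inf


@dataclass(frozen=True)
class AOAConfig:
    """Run settings; ``lower``/``upper`` are D-dimensional box bounds."""

    lower: np.ndarray
    upper: np.ndarray
    n_objects: int = 30
    tmax: int = 100
    c1: float = 2.0
    c2: float = 6.0
    c3: float = 2.0
    c4: float = 0.5
    norm_l: float = 0.1
    norm_u: float = 0.9
    t_cap: float = 1.0
    bound_mode: str = "clamp"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lower", np.atleast_1d(np.asarray(self.lower, dtype=np.float64)))
        object.__setattr__(self, "upper", np.atleast_1d(np.asarray(self.upper, dtype=np.float64)))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper bound shapes differ")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")
        if self.n_objects < 2:
            raise ValueError(f"population size must be >= 2, got {self.n_objects}")
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if self.bound_mode not in ("clamp", "reflect"):
            raise ValueError(f"unknown bound_mode {self.bound_mode!r}")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class AOAResult:
    """Best position/fitness plus the per-iteration best-so-far trace."""

    best_x: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def transfer_operator(t: int, tmax: int) -> float:
    """TF = exp((t - tmax)/tmax); strictly increasing, TF(tmax) = 1."""
    if not 0 <= t <= tmax:
        raise ValueError(f"iteration t={t} outside [0, {tmax}]")
    return float(np.exp((t - tmax) / tmax))


def density_factor(t: int, tmax: int) -> float:
    """d = exp((tmax - t)/tmax) - t/tmax; strictly decreasing, d(tmax) = 0."""
    if not 0 <= t <= tmax:
        raise ValueError(f"iteration t={t} outside [0, {tmax}]")
    return float(np.exp((tmax - t) / tmax) - t / tmax)


def initialize_population(cfg: AOAConfig, rng: np.random.Generator,
                          fitness_fn=None) -> list[AOAObject]:
    """Uniformly random positions/accelerations in [l, u], den/vol ~ U(0,1)."""
    span = cfg.upper - cfg.lower
    pop = []
    for _ in range(cfg.n_objects):
        x = cfg.lower + rng.random(cfg.dim) * span
        den = float(rng.random())
        vol = float(rng.random())
        # acceleration carried as a scalar: one draw in the mean bound range
        acc = float(np.mean(cfg.lower) + rng.random() * np.mean(span))
        obj = AOAObject(x=x, den=den, vol=vol, acc=acc)
        if fitness_fn is not None:
            obj.fitness = _safe_fitness(fitness_fn, x)
        pop.append(obj)
    return pop


def update_density_volume(obj: AOAObject, best: AOAObject,
                          rng: np.random.Generator) -> AOAObject:
    """Move den/vol a random fraction toward the best object's values."""
    obj.den = obj.den + float(rng.random()) * (best.den - obj.den)
    obj.vol = obj.vol + float(rng.random()) * (best.vol - obj.vol)
    return obj


_warned_zero_denom = False


def update_acceleration(obj: AOAObject, reference: AOAObject, TF: float,
                        cfg: AOAConfig) -> float:
    """acc = (den_ref + vol_ref * acc_ref) / (den_i * vol_i).

    ``reference`` is a randomly drawn material when TF <= 0.5 (collision /
    exploration) and the best object otherwise (exploitation); the caller
    selects it.  A vanishing denominator gets a tiny stabilizer, logged once.
    """
    global _warned_zero_denom
    denom = obj.den * obj.vol
    if denom == 0.0:
        if not _warned_zero_denom:
            logger.warning("zero den*vol denominator; stabilizing with %g", _EPS)
            _warned_zero_denom = True
        denom = _EPS
    return (reference.den + reference.vol * reference.acc) / denom


def normalize_acceleration(accs, cfg: AOAConfig) -> np.ndarray:
    """Affine map of the population's accelerations onto [norm_l, norm_u].

    The minimum maps to ``norm_l`` (0.1), the maximum to ``norm_u`` (0.9);
    if all values coincide everything maps to the midpoint.
    """
    accs = np.asarray(accs, dtype=np.float64)
    if accs.size < 1:
        raise ValueError("need at least one acceleration value")
    lo, hi = accs.min(), accs.max()
    if hi == lo:
        return np.full(accs.shape, 0.5 * (cfg.norm_l + cfg.norm_u))
    return cfg.norm_l + (cfg.norm_u - cfg.norm_l) * (accs - lo) / (hi - lo)


def _apply_bounds(x: np.ndarray, cfg: AOAConfig) -> np.ndarray:
    if cfg.bound_mode == "clamp":
        return np.clip(x, cfg.lower, cfg.upper)
    span = cfg.upper - cfg.lower
    with np.errstate(invalid="ignore"):
        y = np.where(span > 0, np.abs((x - cfg.lower) % (2 * span)), 0.0)
        y = np.where(y > span, 2 * span - y, y)
    return cfg.lower + y


def update_position(obj: AOAObject, best_or_rand: AOAObject, acc_norm: float,
                    d: float, TF: float, cfg: AOAConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """One position step (exploration when TF <= 0.5, else exploitation)."""
    x = obj.x
    if TF <= 0.5:
        r = rng.random(cfg.dim)
        x_new = x + cfg.c1 * r * acc_norm * d * (best_or_rand.x - x)
    else:
        P = 2.0 * float(rng.random()) - cfg.c4
        F = 1.0 if P <= 0.5 else -1.0
        T = min(cfg.c3 * TF, cfg.t_cap)
        r = rng.random(cfg.dim)
        x_new = x + F * cfg.c2 * r * acc_norm * d * (T * best_or_rand.x - x)
    return _apply_bounds(x_new, cfg)


def _safe_fitness(fn, x: np.ndarray) -> float:
    v = float(fn(x))
    if np.isnan(v):
        logger.warning("fitness returned NaN at %s; treating as +inf", x)
        return np.inf
    return v


def optimize(fitness_fn, cfg: AOAConfig) -> AOAResult:
    """Minimize ``fitness_fn`` over the box [lower, upper].

    Runs ``tmax`` update cycles after the seeded initialization; returns the
    best-so-far solution and a monotone best-fitness history (entry 0 is the
    initial population's best, then one entry per iteration).
    """
    rng = np.random.default_rng(cfg.seed)
    pop = initialize_population(cfg, rng, fitness_fn)
    n_eval = cfg.n_objects
    best_i = int(np.argmin([o.fitness for o in pop]))
    best = replace(pop[best_i], x=pop[best_i].x.copy())
    history = [best.fitness]

    for t in range(1, cfg.tmax + 1):
        TF = transfer_operator(t, cfg.tmax)
        d = density_factor(t, cfg.tmax)
        snapshot = [replace(o, x=o.x.copy()) for o in pop]
        for obj in pop:
            update_density_volume(obj, best, rng)
        accs = []
        for obj in pop:
            if TF <= 0.5:
                ref = snapshot[int(rng.integers(cfg.n_objects))]
            else:
                ref = best
            accs.append(update_acceleration(obj, ref, TF, cfg))
        acc_norm = normalize_acceleration(accs, cfg)
        for i, obj in enumerate(pop):
            obj.acc = float(acc_norm[i])  # normalized value is carried forward
            if TF <= 0.5:
                partner = snapshot[int(rng.integers(cfg.n_objects))]
            else:
                partner = best
            obj.x = update_position(obj, partner, obj.acc, d, TF, cfg, rng)
            obj.fitness = _safe_fitness(fitness_fn, obj.x)
            n_eval += 1
            if obj.fitness < best.fitness:
                best = replace(obj, x=obj.x.copy())
        history.append(best.fitness)

    return AOAResult(best_x=best.x, best_fitness=best.fitness,
                     history=history, n_evaluations=n_eval)


def random_search(fitness_fn, cfg: AOAConfig) -> AOAResult:
    """Uniform random sampling at the same evaluation budget as ``optimize``.

    Baseline for benchmark comparisons: N * (tmax + 1) evaluations.
    """
    rng = np.random.default_rng(cfg.seed)
    budget = cfg.n_objects * (cfg.tmax + 1)
    span = cfg.upper - cfg.lower
    best_x, best_f = None, np.inf
    history = []
    for i in range(budget):
        x = cfg.lower + rng.random(cfg.dim) * span
        f = _safe_fitness(fitness_fn, x)
        if f < best_f:
            best_f, best_x = f, x
        if (i + 1) % cfg.n_objects == 0:
            history.append(best_f)
    return AOAResult(best_x=best_x, best_fitness=best_f,
                     history=history, n_evaluations=budget)
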