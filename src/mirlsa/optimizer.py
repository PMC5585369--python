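"""Binary differential evolution with a Gaussian-process surrogate.

The tuner searches the 35-bit configuration space with a modified binary
differential evolution (MBDE): the classical DE mutation ``x1 + F (x2 - x3)``
is pushed through a sigmoid probability-estimation operator and sampled into
a binary mutant, followed by standard binomial crossover and greedy
replacement.  Because one real fitness evaluation (a full cross-validated
model build) is expensive, an ordinary-kriging surrogate trained on the
archive of real evaluations scores ``mu`` intermediate generations with the
merit function ``f_hat - omega * xi`` (omega < 0 for maximisation rewards
uncertain regions); the population is then re-evaluated with the real
fitness in parallel (generation-based evolution control).  With ``mu = 0``
the surrogate is skipped entirely and the loop degenerates to plain parallel
binary DE (PBDE).
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .encoding import GENOME_LENGTH

__all__ = [
    "OptimizerConfig",
    "OptimizerState",
    "HistoryRow",
    "GPModel",
    "mutant_probability",
    "mbde_mutate",
    "crossover",
    "select",
    "merit",
    "parallel_evaluate",
    "run",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Tuner settings; defaults follow the published parameterisation.

    ``population_size`` (lambda) = 50, ``real_generations`` (t) = 50,
    ``surrogate_generations`` (mu) = 100, ``scale_factor`` F = 0.8,
    ``crossover_rate`` CR = 0.8, ``sigmoid_slope`` b = 6,
    ``merit_weight`` omega = -2 and 35-bit genomes.  ``surrogate_generations
    = 0`` selects plain PBDE.
    """

    population_size: int = 50
    real_generations: int = 50
    surrogate_generations: int = 100
    scale_factor: float = 0.8
    crossover_rate: float = 0.8
    sigmoid_slope: float = 6.0
    merit_weight: float = -2.0
    genome_length: int = GENOME_LENGTH
    worker_count: int = 1
    seed: int = 0
    gp_theta: float = 0.1
    gp_power: float = 1.0
    gp_nugget: float = 1e-8
    gp_optimize_theta: bool = False

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (target + 3 distinct partners)")
        if self.scale_factor < 0:
            raise ValueError("scale_factor F must be non-negative")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate CR must lie in [0, 1]")
        if self.surrogate_generations < 0 or self.real_generations < 0:
            raise ValueError("generation counts must be non-negative")


@dataclass(frozen=True)
class HistoryRow:
    real_eval_count: int
    best: float
    mean: float
    worst: float


@dataclass
class OptimizerState:
    """Final population plus the per-real-generation fitness trajectory."""

    population: np.ndarray
    real_fitness: np.ndarray
    history: list[HistoryRow]
    archive_X: np.ndarray
    archive_y: np.ndarray
    n_real_evals: int
    config: OptimizerConfig

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.real_fitness))

    @property
    def best_genome(self) -> np.ndarray:
        return self.population[self.best_index]

    @property
    def best_fitness(self) -> float:
        return float(self.real_fitness[self.best_index])


# ---------------------------------------------------------------------------
# MBDE operators
# ---------------------------------------------------------------------------

def mutant_probability(x1, x2, x3, F: float, b: float):
    """Per-bit probability of a 1 in the binary mutant.

    ``P = 1 / (1 + exp(-2 b [x1 + F (x2 - x3) - 0.5] / (1 + 2 F)))`` —
    a sigmoid squeeze of the classical DE mutation, centred so that
    ``x1 + F (x2 - x3) = 0.5`` maps to probability 0.5.
    """
    if F < 0:
        raise ValueError("scale factor F must be non-negative")
    if b <= 0:
        raise ValueError("sigmoid slope b must be positive")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    z = x1 + F * (x2 - x3) - 0.5
    return 1.0 / (1.0 + np.exp(-2.0 * b * z / (1.0 + 2.0 * F)))


def mbde_mutate(base, p2, p3, F: float, b: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a binary mutant, each bit independently Bernoulli(P)."""
    p = mutant_probability(base, p2, p3, F, b)
    return (rng.random(p.shape) < p).astype(np.int8)


def crossover(target, mutant, CR: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover with one guaranteed mutant coordinate."""
    target = np.asarray(target, dtype=np.int8)
    mutant = np.asarray(mutant, dtype=np.int8)
    if target.shape != mutant.shape:
        raise ValueError("target and mutant genomes must have equal length")
    take = rng.random(target.shape) <= CR
    take[rng.integers(target.size)] = True
    return np.where(take, mutant, target)


def select(target_fitness: float, trial_fitness: float, target, trial):
    """Greedy maximising replacement; ties keep the target."""
    tf = target_fitness if math.isfinite(target_fitness) else -math.inf
    rf = trial_fitness if math.isfinite(trial_fitness) else -math.inf
    if not math.isfinite(target_fitness) or not math.isfinite(trial_fitness):
        logger.warning("non-finite fitness encountered in selection; treated as -inf")
    return trial if rf > tf else target


def merit(f_hat: float, xi: float, omega: float) -> float:
    """Surrogate merit ``f_hat - omega * xi`` (omega < 0 rewards uncertainty)."""
    if xi < 0:
        raise ValueError("predictive standard deviation xi must be >= 0")
    return float(f_hat) - float(omega) * float(xi)


# ---------------------------------------------------------------------------
# Gaussian-process (ordinary kriging) surrogate
# ---------------------------------------------------------------------------

class GPModel:
    """Ordinary kriging on binary genomes.

    Spatial correlation ``sc(x, x') = exp(-sum_i theta_i |x_i - x'_i|^p_i)``
    with a nugget on the diagonal; the constant mean is estimated by
    generalised least squares.  On the binary grid ``|dx| in {0, 1}`` the
    exponent ``p_i`` is inert; it is kept for completeness.  ``theta`` can be
    tuned by maximising the concentrated log marginal likelihood over a
    bounded grid.
    """

    def __init__(self, theta: float | Sequence[float] = 0.1,
                 power: float | Sequence[float] = 1.0, nugget: float = 1e-8):
        self.theta = theta
        self.power = power
        self.nugget = float(nugget)

    # -- correlation -----------------------------------------------------

    def _corr(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        diff = np.abs(A[:, None, :] - B[None, :, :])
        return np.exp(-(self._theta * diff ** self._power).sum(axis=2))

    def correlation(self, x, y) -> float:
        """sc(x, y) for two single genomes."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        return float(self._corr(x, y)[0, 0])

    # -- fitting ---------------------------------------------------------

    @staticmethod
    def _dedupe(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        seen: dict[bytes, list[float]] = {}
        order: list[bytes] = []
        rows: dict[bytes, np.ndarray] = {}
        for xi, yi in zip(X, y):
            key = np.asarray(xi, dtype=np.int8).tobytes()
            if key not in seen:
                seen[key] = []
                order.append(key)
                rows[key] = xi
            seen[key].append(float(yi))
        Xd = np.array([rows[k] for k in order], dtype=float)
        yd = np.array([np.mean(seen[k]) for k in order])
        return Xd, yd

    def fit(self, X, y, optimize_theta: bool = False) -> "GPModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        X, y = self._dedupe(X, y)
        if len(X) < 2:
            raise ValueError("kriging needs at least 2 distinct archive points")
        d = X.shape[1]
        self._theta = np.broadcast_to(np.asarray(self.theta, dtype=float), (d,)).copy()
        self._power = np.broadcast_to(np.asarray(self.power, dtype=float), (d,)).copy()
        if (self._theta <= 0).any():
            raise ValueError("theta must be positive")
        if ((self._power < 1) | (self._power > 2)).any():
            raise ValueError("power must lie in [1, 2]")
        if optimize_theta:
            best = (-np.inf, self._theta)
            for t in np.geomspace(0.01, 1.0, 10):
                self._theta = np.full(d, t)
                try:
                    ll = self._fit_once(X, y)
                except np.linalg.LinAlgError:
                    continue
                if ll > best[0]:
                    best = (ll, self._theta.copy())
            self._theta = best[1]
        self._fit_once(X, y)
        return self

    def _fit_once(self, X: np.ndarray, y: np.ndarray) -> float:
        n = len(X)
        R = self._corr(X, X) + self.nugget * np.eye(n)
        try:
            cho = scipy.linalg.cho_factor(R, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "correlation matrix is singular; increase the nugget"
            ) from exc
        ones = np.ones(n)
        Ri_y = scipy.linalg.cho_solve(cho, y)
        Ri_1 = scipy.linalg.cho_solve(cho, ones)
        mu = float(ones @ Ri_y / (ones @ Ri_1))
        resid = y - mu
        alpha = scipy.linalg.cho_solve(cho, resid)
        sigma2 = float(resid @ alpha / n)
        self.X_, self.y_ = X, y
        self._cho, self._mu, self._alpha = cho, mu, alpha
        self._Ri_1, self._sigma2 = Ri_1, max(sigma2, 0.0)
        # concentrated log marginal likelihood (up to constants)
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        return -0.5 * (n * np.log(max(sigma2, 1e-300)) + logdet)

    # -- prediction ------------------------------------------------------

    def predict(self, x) -> tuple[float, float]:
        """Kriging mean ``f_hat`` and standard deviation ``xi`` at genome x."""
        if not hasattr(self, "X_"):
            raise RuntimeError("GPModel is not fitted")
        x = np.atleast_2d(np.asarray(x, dtype=float))
        r = self._corr(self.X_, x)[:, 0]
        f_hat = self._mu + r @ self._alpha
        Ri_r = scipy.linalg.cho_solve(self._cho, r)
        ones = np.ones(len(self.X_))
        denom = float(ones @ self._Ri_1)
        s2 = self._sigma2 * (1.0 - r @ Ri_r + (1.0 - ones @ Ri_r) ** 2 / denom)
        return float(f_hat), float(np.sqrt(max(s2, 0.0)))


# ---------------------------------------------------------------------------
# Parallel evaluation
# ---------------------------------------------------------------------------

def parallel_evaluate(
    population: Sequence[np.ndarray],
    fitness_fn: Callable[[np.ndarray], float],
    worker_count: int = 1,
) -> np.ndarray:
    """Evaluate a population, preserving order, with per-genome fault isolation.

    Results are identical for any ``worker_count >= 1`` (master-slave
    contract).  A genome whose evaluation raises, or returns a non-finite
    value, scores ``-inf`` (logged); if every evaluation fails the run aborts.
    """
    if worker_count < 1:
        raise ValueError("worker_count must be >= 1")

    def safe(genome):
        try:
            value = float(fitness_fn(genome))
        except Exception:
            logger.exception("fitness evaluation failed; scoring -inf")
            return -math.inf
        if not math.isfinite(value):
            logger.warning("non-finite fitness %r; scoring -inf", value)
            return -math.inf
        return value

    if worker_count == 1:
        values = [safe(g) for g in population]
    else:
        with ThreadPoolExecutor(max_workers=worker_count) as pool:
            values = list(pool.map(safe, population))
    values = np.asarray(values, dtype=float)
    if len(values) and np.isneginf(values).all():
        raise RuntimeError("every fitness evaluation failed")
    return values


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _partners(rng: np.random.Generator, lam: int, i: int) -> tuple[int, int, int]:
    candidates = np.delete(np.arange(lam), i)
    i1, i2, i3 = rng.choice(candidates, size=3, replace=False)
    return int(i1), int(i2), int(i3)


def _de_generation(
    pop: np.ndarray, cfg: OptimizerConfig, rng: np.random.Generator
) -> np.ndarray:
    """One synchronous round of MBDE mutation + crossover (no selection)."""
    lam = len(pop)
    trials = np.empty_like(pop)
    for i in range(lam):
        i1, i2, i3 = _partners(rng, lam, i)
        mutant = mbde_mutate(
            pop[i1], pop[i2], pop[i3], cfg.scale_factor, cfg.sigmoid_slope, rng
        )
        trials[i] = crossover(pop[i], mutant, cfg.crossover_rate, rng)
    return trials


def run(fitness_fn: Callable[[np.ndarray], float], config: OptimizerConfig) -> OptimizerState:
    """Run PGPABDE (or PBDE when ``surrogate_generations == 0``).

    Loop: random initial population, real-evaluated in parallel; then for
    each real generation fit the kriging model on the archive, evolve the
    population ``mu`` surrogate generations scored by the merit function
    (one plain DE round when ``mu = 0``), real-evaluate the result in
    parallel, and apply greedy replacement against the incumbents using real
    fitness.  Total real evaluations: ``lambda * (t + 1)``.  Fully
    reproducible from the seed for any worker count.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lam, n = cfg.population_size, cfg.genome_length

    pop = rng.integers(0, 2, size=(lam, n), dtype=np.int8)
    fitness = parallel_evaluate(pop, fitness_fn, cfg.worker_count)
    archive_X = [g.copy() for g in pop]
    archive_y = list(fitness)
    finite = fitness[np.isfinite(fitness)]
    history = [HistoryRow(lam, float(fitness.max()), float(finite.mean()), float(fitness.min()))]

    for _ in range(cfg.real_generations):
        if cfg.surrogate_generations > 0:
            gp = GPModel(cfg.gp_theta, cfg.gp_power, cfg.gp_nugget).fit(
                archive_X, archive_y, optimize_theta=cfg.gp_optimize_theta
            )
            work = pop.copy()
            scores = np.array(
                [merit(*gp.predict(g), cfg.merit_weight) for g in work]
            )
            for _ in range(cfg.surrogate_generations):
                trials = _de_generation(work, cfg, rng)
                trial_scores = np.array(
                    [merit(*gp.predict(g), cfg.merit_weight) for g in trials]
                )
                better = trial_scores > scores
                work[better] = trials[better]
                scores[better] = trial_scores[better]
        else:
            work = _de_generation(pop, cfg, rng)

        new_fitness = parallel_evaluate(work, fitness_fn, cfg.worker_count)
        archive_X.extend(g.copy() for g in work)
        archive_y.extend(new_fitness)
        improved = new_fitness > fitness
        pop[improved] = work[improved]
        fitness[improved] = new_fitness[improved]
        finite = fitness[np.isfinite(fitness)]
        history.append(
            HistoryRow(
                len(archive_y),
                float(fitness.max()),
                float(finite.mean()) if len(finite) else -math.inf,
                float(fitness.min()),
            )
        )

    return OptimizerState(
        population=pop,
        real_fitness=fitness,
        history=history,
        archive_X=np.array(archive_X),
        archive_y=np.array(archive_y),
        n_real_evals=len(archive_y),
        config=cfg,
    )
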