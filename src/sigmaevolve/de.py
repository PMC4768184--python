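"""Differential-evolution engine for abstract transcription-factor vectors.

A transcription factor is a vector of expression levels in [0, 1], one per
gene.  A population of ``NP`` such vectors is evolved towards a fixed target
vector with the classic DE/rand/1/bin scheme: for every population member a
trial vector is built from three mutually distinct other members as

    trial_j = x[r1, j] + F * (x[r2, j] - x[r3, j])

applied per coordinate with probability ``CR`` (one coordinate is always
taken from the mutant so the trial never equals its parent by construction),
and the trial replaces the parent whenever it is at least as close to the
target.  Closeness is the *quality index* (QI): the mean absolute per-gene
distance between a candidate and the target, i.e. the error expressed as a
fraction of the [0, 1] expression range.

Runs stop on success (best QI below a threshold, default 0.1% of the
expression range), on stagnation (best QI improved by less than a minimum
amount over a trailing window of generations), or on a generation cap.

Random-number consumption order
-------------------------------
Reproducibility down to the individual draw matters here because the engine
is checked against an independent loop-based reference.  Per generation the
engine consumes, in this order, from a single :class:`numpy.random.Generator`:

1. ``rng.random((NP, NP))`` — row-wise argsort gives, for each member, a
   random permutation of the population from which r1, r2, r3 are the first
   three indices distinct from the member itself;
2. ``rng.integers(0, d, size=NP)`` — the forced crossover coordinate;
3. ``rng.random((NP, d))`` — the per-coordinate crossover uniforms.

Initialisation consumes one ``rng.random((NP, d))`` call.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DEConfig",
    "Trajectory",
    "quality_index",
    "mutate",
    "select",
    "run_de",
]


@dataclass
class DEConfig:
    """Parameters of a differential-evolution run.

    Attributes
    ----------
    pop_size : int
        Population size NP; at least 4 (mutation needs three donors distinct
        from the base member).  For the default CR=0.4 and F=0.1, rand/1/bin
        contracts population variance faster than selection can exploit it
        whenever NP < (2-CR)/(2 F^2) = 80, and such populations collapse
        prematurely far above the success threshold; the default 100 sits
        comfortably above that critical size, making subproblems of up to a
        few hundred genes reliably solvable while whole genomes of >= 500
        genes still stagnate — the regime the strategy comparison probes.
    cr : float
        Crossover probability CR in [0, 1].
    f : float
        Differential weight F in [0, 2].  ``f=0`` degrades mutation to pure
        copying of a random member, a useful robustness control.
    qi_success_threshold : float
        A run succeeds when the best QI drops strictly below this value.
        The default 0.001 is 0.1% of the expression range.
    stagnation_window : int
        Trailing window, in generations, over which progress is required.
    stagnation_min_decrease : float
        Minimum decrease of the best QI over the trailing window; a run that
        improves less is stopped as stagnated.
    max_generations : int
        Hard cap on the number of generations.
    rng_seed : int
        Seed used when no explicit generator is supplied.
    """

    pop_size: int = 100
    cr: float = 0.4
    f: float = 0.1
    qi_success_threshold: float = 0.001
    stagnation_window: int = 1000
    stagnation_min_decrease: float = 1e-6
    max_generations: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError(f"pop_size must be >= 4, got {self.pop_size}")
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError(f"cr must be in [0, 1], got {self.cr}")
        if not 0.0 <= self.f <= 2.0:
            raise ValueError(f"f must be in [0, 2], got {self.f}")
        if self.qi_success_threshold <= 0:
            raise ValueError("qi_success_threshold must be positive")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be >= 1")
        if self.stagnation_min_decrease < 0:
            raise ValueError("stagnation_min_decrease must be >= 0")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")


@dataclass
class Trajectory:
    """Per-run record of a DE optimisation.

    ``best_qi_per_generation[g]`` is the best QI after generation ``g``
    (entry 0 is the initial population), and is non-increasing by greedy
    selection.  ``evaluations`` counts gene-coordinate distance evaluations,
    a hardware-independent cost proxy.  ``monitored_qi_per_generation``
    tracks the QI restricted to a monitored gene subset (a regulon) for the
    population member that is currently best genome-wide; it need not be
    monotone.
    """

    best_qi_per_generation: list[float] = field(default_factory=list)
    generations_run: int = 0
    evaluations: int = 0
    success: bool = False
    stop_reason: str = "max_generations"
    cpu_seconds: float = 0.0
    monitored_qi_per_generation: Optional[list[float]] = None

    def validate(self) -> None:
        qi = np.asarray(self.best_qi_per_generation)
        if np.any(np.diff(qi) > 1e-15):
            raise AssertionError("best QI series must be non-increasing")


def _as_vector(x: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def quality_index(
    candidate: np.ndarray,
    target: np.ndarray,
    monitored_indices: Optional[np.ndarray] = None,
) -> float:
    """Mean absolute per-gene distance between candidate and target.

    ``monitored_indices`` restricts the mean to a gene subset (e.g. the
    regulon of the transcription factor of interest); the default is all
    genes.
    """
    cand = _as_vector(candidate, "candidate")
    tgt = _as_vector(target, "target")
    if cand.shape != tgt.shape:
        raise ValueError("candidate and target must have equal length")
    if monitored_indices is not None:
        idx = np.asarray(monitored_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("monitored index set must be non-empty")
        if idx.min() < 0 or idx.max() >= cand.size:
            raise ValueError("monitored indices out of range")
        cand = cand[idx]
        tgt = tgt[idx]
    return float(np.mean(np.abs(cand - tgt)))


def _donor_indices(order: np.ndarray, i: int) -> tuple[int, int, int]:
    # first three entries of the random permutation that are not i
    picked = [int(j) for j in order[:4] if j != i][:3]
    return picked[0], picked[1], picked[2]


def mutate(
    population: np.ndarray,
    base_index: int,
    f: float,
    cr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Build one binomial-crossover trial vector for ``population[base_index]``.

    Draws r1, r2, r3 mutually distinct and distinct from the base member,
    applies ``x[r1] + f*(x[r2]-x[r3])`` per coordinate with probability
    ``cr`` (one coordinate forced), clips to [0, 1], and keeps the parent's
    value elsewhere.
    """
    pop = np.asarray(population, dtype=float)
    n, d = pop.shape
    if n < 4:
        raise ValueError("population must have at least 4 members")
    others = [j for j in range(n) if j != base_index]
    r1, r2, r3 = rng.choice(others, size=3, replace=False)
    mutant = np.clip(pop[r1] + f * (pop[r2] - pop[r3]), 0.0, 1.0)
    jrand = int(rng.integers(0, d))
    mask = rng.random(d) < cr
    mask[jrand] = True
    return np.where(mask, mutant, pop[base_index])


def select(parent: np.ndarray, trial: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Greedy selection: whichever of parent/trial is closer to the target.

    Ties are resolved in favour of the trial (standard DE convention), which
    lets the population drift across plateaus.
    """
    if quality_index(trial, target) <= quality_index(parent, target):
        return trial
    return parent


def run_de(
    target: np.ndarray,
    active_indices: Optional[np.ndarray],
    config: DEConfig,
    rng: Optional[np.random.Generator] = None,
    monitored_indices: Optional[np.ndarray] = None,
) -> tuple[Trajectory, np.ndarray]:
    """Evolve a population towards ``target`` restricted to ``active_indices``.

    Parameters
    ----------
    target : array
        Full-genome target vector with entries in [0, 1].
    active_indices : array of int or None
        Gene indices the optimiser operates on (``None`` = all genes).
        Candidates are vectors over this index set only.
    config : DEConfig
    rng : numpy Generator, optional
        Source of randomness; defaults to ``default_rng(config.rng_seed)``.
    monitored_indices : array of int, optional
        Subset of ``active_indices`` (as positions in the full genome) whose
        QI is additionally recorded each generation for the genome-wide best
        member.

    Returns
    -------
    (Trajectory, best_vector)
        ``best_vector`` has the length of ``active_indices`` and is the
        closest candidate found.
    """
    target = _as_vector(target, "target")
    if active_indices is None:
        active = np.arange(target.size)
    else:
        active = np.asarray(active_indices, dtype=int)
    if active.size < 1:
        raise ValueError("active index set must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    tgt = target[active]
    d = active.size
    npop = config.pop_size

    mon_pos: Optional[np.ndarray] = None
    mon_weight = 0
    if monitored_indices is not None:
        mon = np.asarray(monitored_indices, dtype=int)
        pos_of = {int(g): k for k, g in enumerate(active)}
        mon_pos = np.asarray([pos_of[int(g)] for g in mon if int(g) in pos_of], dtype=int)
        mon_weight = mon_pos.size

    t0 = time.perf_counter()
    pop = rng.random((npop, d))
    fit = np.mean(np.abs(pop - tgt), axis=1)
    evals = npop * d

    best_hist = [float(fit.min())]
    mon_hist: Optional[list[float]] = None
    if mon_pos is not None:
        mon_hist = []
        if mon_pos.size:
            b = int(fit.argmin())
            mon_hist.append(float(np.mean(np.abs(pop[b, mon_pos] - tgt[mon_pos]))))

    stop_reason = "max_generations"
    gen = 0
    while True:
        if best_hist[-1] < config.qi_success_threshold:
            stop_reason = "success"
            break
        if gen >= config.stagnation_window and (
            best_hist[gen - config.stagnation_window] - best_hist[gen]
            < config.stagnation_min_decrease
        ):
            stop_reason = "stagnation"
            break
        if gen >= config.max_generations:
            stop_reason = "max_generations"
            break

        order = np.argsort(rng.random((npop, npop)), axis=1)
        jrand = rng.integers(0, d, size=npop)
        umat = rng.random((npop, d))

        rows = np.arange(npop)
        # first three permutation entries distinct from the row index
        not_self = order != rows[:, None]
        first3 = order[not_self].reshape(npop, npop - 1)[:, :3]
        r1, r2, r3 = first3[:, 0], first3[:, 1], first3[:, 2]

        mutant = np.clip(pop[r1] + config.f * (pop[r2] - pop[r3]), 0.0, 1.0)
        mask = umat < config.cr
        mask[rows, jrand] = True
        trial = np.where(mask, mutant, pop)

        tfit = np.mean(np.abs(trial - tgt), axis=1)
        evals += npop * d
        accept = tfit <= fit
        pop[accept] = trial[accept]
        fit[accept] = tfit[accept]

        gen += 1
        best_hist.append(float(fit.min()))
        if mon_hist is not None and mon_pos is not None and mon_pos.size:
            b = int(fit.argmin())
            mon_hist.append(float(np.mean(np.abs(pop[b, mon_pos] - tgt[mon_pos]))))

    traj = Trajectory(
        best_qi_per_generation=best_hist,
        generations_run=gen,
        evaluations=evals,
        success=best_hist[-1] < config.qi_success_threshold,
        stop_reason=stop_reason,
        cpu_seconds=time.perf_counter() - t0,
        monitored_qi_per_generation=mon_hist,
    )
    traj.validate()
    best = pop[int(fit.argmin())].copy()
    return traj, best
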