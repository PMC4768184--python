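"""Independent, deliberately naive oracles used only by the test suite.

The DE reference below re-implements the engine's documented algorithm with
explicit Python loops over members and coordinates, consuming the random
stream through the same documented sequence of generator calls, so a run
with the same seed must reproduce the vectorized engine's trajectory
exactly.  The enumeration oracles compute exact null distributions for the
2x2 and rank-sum tests by brute force.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from sigmaevolve.de import DEConfig, Trajectory


def reference_run_de(target, active_indices, config: DEConfig, rng) -> Trajectory:
    """Loop-based DE/rand/1/bin sharing the engine's RNG stream."""
    target = np.asarray(target, dtype=float)
    active = (np.arange(target.size) if active_indices is None
              else np.asarray(active_indices, dtype=int))
    tgt = [float(target[i]) for i in active]
    d = len(tgt)
    npop = config.pop_size

    pop = [list(row) for row in rng.random((npop, d))]

    def qi(vec):
        return sum(abs(vec[j] - tgt[j]) for j in range(d)) / d

    fit = [qi(m) for m in pop]
    evals = npop * d
    best_hist = [min(fit)]

    gen = 0
    stop_reason = "max_generations"
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

        trials = []
        for i in range(npop):
            donors = [int(j) for j in order[i] if int(j) != i][:3]
            r1, r2, r3 = donors
            trial = []
            for j in range(d):
                if umat[i, j] < config.cr or j == int(jrand[i]):
                    v = pop[r1][j] + config.f * (pop[r2][j] - pop[r3][j])
                    v = min(1.0, max(0.0, v))
                else:
                    v = pop[i][j]
                trial.append(v)
            trials.append(trial)

        for i in range(npop):
            tf = qi(trials[i])
            evals += d
            if tf <= fit[i]:
                pop[i] = trials[i]
                fit[i] = tf

        gen += 1
        best_hist.append(min(fit))

    return Trajectory(
        best_qi_per_generation=best_hist,
        generations_run=gen,
        evaluations=evals,
        success=best_hist[-1] < config.qi_success_threshold,
        stop_reason=stop_reason,
    )


def fisher_oracle_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        # P(table with top-left x | margins), hypergeometric
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


def rank_sum_oracle(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p via exhaustive enumeration of group assignments."""
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free data assumed
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2

    us = []
    for idx in combinations(range(n1 + n2), n1):
        rs = sum(i + 1 for i in idx)
        us.append(rs - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs + 1e-9)
    sf = np.mean(us >= u_obs - 1e-9)
    if alternative == "greater":
        return float(sf)
    if alternative == "less":
        return float(cdf)
    return float(min(1.0, 2 * min(cdf, sf)))


def holm_oracle(p_values):
    """Definitional step-down Holm adjustment."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adj[i] = min(1.0, running)
    return adj
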