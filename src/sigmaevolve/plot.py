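"""Basic plots: per-block convergence heat maps and QI trajectories.

matplotlib is imported lazily so the simulation stack works without a
plotting backend installed.
"""

from __future__ import annotations

import numpy as np

from .strategies import RunResult

__all__ = ["plot_block_heatmap", "plot_qi_series"]


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install sigmaevolve[plot])") from exc
    return plt


def plot_qi_series(run_result: RunResult, ax=None):
    """Best QI (and monitored QI, if tracked) against generation."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    qi = run_result.trajectory.best_qi_per_generation
    ax.semilogy(np.arange(len(qi)), qi, label="best QI")
    if run_result.monitored_trajectory:
        ax.semilogy(
            np.arange(len(run_result.monitored_trajectory)),
            run_result.monitored_trajectory,
            label="monitored (regulon) QI",
        )
    ax.set_xlabel("generation")
    ax.set_ylabel("quality index")
    ax.legend()
    return ax


def plot_block_heatmap(run_result: RunResult, ax=None):
    """Generations x blocks heat map of best QI, the per-block view of a run.

    For a genome-strategy run there is a single row.  After a block stops,
    its final QI is carried forward so rows are comparable in length.
    """
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    trajs = run_result.block_trajectories or [run_result.trajectory]
    n_gen = max(len(t.best_qi_per_generation) for t in trajs)
    grid = np.vstack([
        np.concatenate([
            t.best_qi_per_generation,
            np.full(n_gen - len(t.best_qi_per_generation),
                    t.best_qi_per_generation[-1]),
        ])
        for t in trajs
    ])
    im = ax.imshow(grid, aspect="auto", interpolation="nearest", cmap="viridis_r")
    ax.set_xlabel("generation")
    ax.set_ylabel("sigma-factor block" if len(trajs) > 1 else "whole genome")
    plt.colorbar(im, ax=ax, label="best QI")
    return ax
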