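"""Variance-acquisition Bayesian experiment design.

Proposes the next round's dose set from a fitted dose-response model by
greedy sequential maximization of the posterior epistemic variance on a
1 uM dose grid: pick the grid point of maximal variance, excise its
``min_separation`` neighborhood, repeat.  Ties break toward the lower dose
and the output is sorted ascending, so proposals are deterministic given
the model and request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp import GPDoseResponse

__all__ = ["AcquisitionRequest", "propose_doses"]


@dataclass(frozen=True)
class AcquisitionRequest:
    """How many doses to propose, over which domain, how far apart."""

    n_points: int = 5
    domain: tuple[float, float] = (0.0, 500.0)
    grid_step: float = 1.0
    min_separation: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.min_separation < self.grid_step:
            raise ValueError("min_separation must be >= grid_step")
        if self.domain[1] <= self.domain[0]:
            raise ValueError("domain must be increasing")


def propose_doses(model: GPDoseResponse, request: AcquisitionRequest | None = None,
                  return_grid: bool = False):
    """Greedy variance-acquisition proposals on the dose grid.

    Returns a sorted list of grid-aligned doses; with ``return_grid=True``
    also returns a DataFrame (dose, variance, selected) for audit.
    """
    request = request or AcquisitionRequest()
    lo, hi = request.domain
    if hi - lo < request.n_points * request.min_separation:
        raise ValueError("domain narrower than n_points * min_separation")
    grid = np.arange(lo, hi + 0.5 * request.grid_step, request.grid_step)
    _, sd = model.predict(grid, return_std=True)
    variance = sd ** 2
    admissible = np.ones(grid.size, dtype=bool)
    chosen: list[float] = []
    for _ in range(request.n_points):
        if not admissible.any():
            raise ValueError("admissible grid exhausted before n_points selected")
        idx_pool = np.flatnonzero(admissible)
        best = idx_pool[np.argmax(variance[idx_pool])]  # argmax -> first max -> lower dose
        chosen.append(float(grid[best]))
        admissible &= np.abs(grid - grid[best]) >= request.min_separation
    doses = sorted(chosen)
    if return_grid:
        audit = pd.DataFrame(dict(dose=grid, variance=variance,
                                  selected=np.isin(grid, doses)))
        return doses, audit
    return doses
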