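"""Heritable diapause-exit trait: mean day, phenotypic variance, inheritance.

The single trait has two properties: the mean day-of-year of diapause exit
(grid days 50, 60, ..., 200 — sixteen values, matching the 10-day exit grid
of the trajectory store) and the phenotypic-variance standard deviation SDPV
(0, 10, 20, 30 or 40 days).  An individual's realized exit day is drawn once
at the egg stage from a Gaussian centred on the inherited mean, rounded to
the nearest 10-day grid setting and clamped to the grid range; traits are
inherited unchanged (no mutation).
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import norm

EXIT_GRID: tuple[int, ...] = tuple(range(50, 201, 10))   # 16 values
SDPV_GRID: tuple[int, ...] = (0, 10, 20, 30, 40)


class TraitPair(NamedTuple):
    """(exit-date mean, phenotypic-variance SD), both in days."""

    exit_mean: int
    sdpv: int


def trait_grid(
    exit_means: Sequence[int] = EXIT_GRID, sdpvs: Sequence[int] = SDPV_GRID
) -> list[TraitPair]:
    """All trait combinations, lexicographically ordered (16 x 5 = 80)."""
    return [TraitPair(m, s) for m in exit_means for s in sdpvs]


def round_to_step(x: float, step: int = 10) -> int:
    """Round to the nearest multiple of ``step``, ties half away from zero."""
    return int(math.copysign(math.floor(abs(x) / step + 0.5), x)) * step


def realize_exit_day(
    trait: TraitPair,
    rng: np.random.Generator,
    grid: Sequence[int] = EXIT_GRID,
) -> int:
    """Draw the realized diapause-exit day for one individual.

    With SDPV = 0 the inherited mean is returned exactly; otherwise a
    Gaussian deviation is added, the result rounded to the nearest grid
    setting (10-day spacing by default) and clamped to the grid range, so
    the realized day always has a stored trajectory.
    """
    if trait.sdpv == 0:
        return int(trait.exit_mean)
    step = grid[1] - grid[0] if len(grid) > 1 else 10
    x = trait.exit_mean + rng.normal(0.0, trait.sdpv)
    return int(np.clip(round_to_step(x, step), grid[0], grid[-1]))


def exit_day_distribution(
    trait: TraitPair, grid: Sequence[int] = EXIT_GRID
) -> np.ndarray:
    """Exact probability of each grid exit day under ``realize_exit_day``.

    Interior grid day e receives the Gaussian mass of (e - step/2, e + step/2);
    the edge days additionally absorb the clamped tails.  Used by the
    selection engine to draw realized exit days for whole cohorts at once
    (multinomially — exactly the law of independent per-individual draws).
    """
    grid = np.asarray(grid)
    probs = np.zeros(len(grid))
    if trait.sdpv == 0:
        idx = int(np.argmin(np.abs(grid - trait.exit_mean)))
        if grid[idx] != trait.exit_mean:
            raise ValueError(f"exit_mean {trait.exit_mean} not on grid")
        probs[idx] = 1.0
        return probs
    step = grid[1] - grid[0] if len(grid) > 1 else 10
    half = step / 2.0
    upper = norm.cdf(grid + half, loc=trait.exit_mean, scale=trait.sdpv)
    lower = norm.cdf(grid - half, loc=trait.exit_mean, scale=trait.sdpv)
    probs = upper - lower
    probs[0] = upper[0]          # everything below rounds/clamps to the first day
    probs[-1] = 1.0 - lower[-1]  # everything above to the last
    return probs


def inherit(parent_trait: TraitPair) -> TraitPair:
    """Traits pass unchanged from adult females to their progeny."""
    return parent_trait
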