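"""Simulation configuration and the factorial design grid.

A :class:`SimulationConfig` holds one cell of the study design: the eleven
varying population parameters (latent severity, change variability and its
correlation with baseline, SIM and anchor reliabilities, present-state bias,
proportion improved, the relative strengths of the auxiliary-only and
SIM-only latent components, and the cross-wave correlations of the two
nuisance traits), plus the sample size, the RNG seed and the fixed true MIC.

The default factorial levels multiply out to 15,552 cells
(3*2*2*2*2*3*3*3*3*2*2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "TABLE_DEFAULT_LEVELS",
    "build_parameter_grid",
    "subset_grid",
]

#: Factorial levels of the eleven varying parameters, in canonical order.
TABLE_DEFAULT_LEVELS: Mapping[str, tuple] = {
    "mean_theta_t1": (-1.0, 0.0, 1.0),
    "sd_delta_theta": (0.85, 1.15),
    "cor_theta_t1_delta": (-0.50, 0.00),
    "rel_sim_t1": (0.50, 0.80),
    "rel_trs": (0.40, 0.70),
    "psb": (0.0, 0.4, 0.8),
    "prop_improved": (0.2, 0.5, 0.8),
    "strength_xi": (0.0, 0.2, 0.5),
    "strength_theta_b": (0.0, 0.5, 1.0),
    "cor_xi": (0.50, 0.90),
    "cor_eta": (0.50, 0.90),
}

GRID_PARAMETERS = tuple(TABLE_DEFAULT_LEVELS)


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration or grid request."""


@dataclass(frozen=True)
class SimulationConfig:
    """Population parameters for one simulated two-wave dataset.

    Parameters outside the factorial design (item counts, the individual-MIC
    distribution, the eta share of the SIM's unreliable variance, the AUX
    item-parameter hyperparameters) are fixed design constants with defaults
    chosen to match the target data structure: an 11-point 0-10 NRS, an
    8-item 5-category auxiliary PROM, and a dichotomized transition anchor.
    """

    mean_theta_t1: float = 0.0
    sd_delta_theta: float = 0.85
    cor_theta_t1_delta: float = 0.0
    rel_sim_t1: float = 0.80
    rel_trs: float = 0.70
    psb: float = 0.0
    prop_improved: float = 0.5
    strength_xi: float = 0.2
    strength_theta_b: float = 0.5
    cor_xi: float = 0.9
    cor_eta: float = 0.9
    n_subjects: int = 2000
    seed: int = 0
    true_mic: float = 0.8

    # fixed design constants (not part of the factorial grid)
    sd_individual_mic: float = 0.2
    eta_share: float = 0.4          # share of the SIM's unreliable variance due to eta
    n_aux_items: int = 8
    n_aux_categories: int = 5
    aux_mean_slope: float = 1.6
    aux_slope_sigma: float = 0.25   # lognormal sigma of item discriminations
    aux_threshold_spacing: float = 1.6
    aux_threshold_shift: float = 0.15
    aux_shift_spread: float = 0.4   # item-location spread (uniform half-width)
    sim_offset: float = 5.5
    sim_min: int = 0
    sim_max: int = 10

    def __post_init__(self) -> None:
        if not -1.0 <= self.cor_theta_t1_delta <= 1.0:
            raise ConfigurationError("cor_theta_t1_delta must be in [-1, 1]")
        for name in ("cor_xi", "cor_eta"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [-1, 1]")
        for name in ("rel_sim_t1", "rel_trs"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if not 0.0 <= self.psb <= 1.0:
            raise ConfigurationError("psb must be in [0, 1]")
        if not 0.0 < self.prop_improved < 1.0:
            raise ConfigurationError("prop_improved must be strictly inside (0, 1)")
        if self.sd_delta_theta <= 0:
            raise ConfigurationError("sd_delta_theta must be positive")
        if self.strength_xi < 0 or self.strength_theta_b < 0:
            raise ConfigurationError("strength ratios must be non-negative")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if self.n_aux_items < 3 or self.n_aux_categories < 2:
            raise ConfigurationError("need >= 3 AUX items with >= 2 categories")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def build_parameter_grid(
    levels: Mapping[str, Sequence[float]] | None = None,
    n_subjects: int = 2000,
    base_seed: int = 0,
    **fixed,
) -> list[SimulationConfig]:
    """Cartesian product of parameter levels, in canonical parameter order.

    ``levels`` may override any subset of :data:`TABLE_DEFAULT_LEVELS`; each
    supplied parameter needs at least one level.  Every cell receives its own
    sub-seed derived deterministically from ``base_seed``.
    """
    merged = dict(TABLE_DEFAULT_LEVELS)
    if levels:
        unknown = set(levels) - set(merged)
        if unknown:
            raise ConfigurationError(f"unknown grid parameters: {sorted(unknown)}")
        for name, vals in levels.items():
            vals = tuple(vals)
            if not vals:
                raise ConfigurationError(f"empty level list for parameter {name!r}")
            merged[name] = vals

    combos = itertools.product(*(merged[p] for p in GRID_PARAMETERS))
    n_cells = int(np.prod([len(merged[p]) for p in GRID_PARAMETERS]))
    seeds = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_cells)
    grid = []
    for i, combo in enumerate(combos):
        kwargs = dict(zip(GRID_PARAMETERS, combo))
        grid.append(
            SimulationConfig(
                n_subjects=n_subjects, seed=int(seeds[i]), **kwargs, **fixed
            )
        )
    return grid


def subset_grid(
    grid: Sequence[SimulationConfig],
    fraction: float,
    seed: int = 0,
) -> list[SimulationConfig]:
    """Balanced deterministic subset of roughly ``fraction`` of the grid.

    Uses stride sampling with a stride coprime to 2 and 3.  Because every
    cycle length of the lexicographic factorial ordering is a product of 2s
    and 3s, a coprime stride visits the levels of every parameter in
    near-equal proportion, giving a stratified (balanced) subset without
    randomness.  ``seed`` rotates the starting offset so different seeds give
    different (equally balanced) subsets.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    stride = max(1, round(1.0 / fraction))
    while stride % 2 == 0 or stride % 3 == 0:
        stride += 1
    offset = seed % stride
    return [grid[i] for i in range(offset, len(grid), stride)]
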