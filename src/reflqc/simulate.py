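"""Synthetic unmerged reflection data with the statistical structure the
downstream analysis assumes, plus ground truth for recovery tests.

The generator emulates, at the reflection level (no pixels, profiles or
geometry):

* acentric Wilson statistics — per-unique true intensities drawn from an
  exponential distribution whose mean follows the Wilson falloff
  C * exp(-2 B s^2) with s = 1/(2d);
* configurable breaking of tetragonal symmetry — the two members of each
  4/mmm-equivalent pair of mmm-unique reflections, (h,k,l) and (k,h,l),
  are coupled through a correlation parameter tau in [0,1]: tau = 1
  restores exact 4/mmm equality, smaller tau decorrelates them;
* the physical noise decomposition sigma^2 = K_true*(k0 + I_true)
  + (g_true*I_true)^2, while the *delivered* sigma contains the first two
  terms only, sqrt(k0 + max(I,0)) — exactly the mismatch the (K, g)
  error-model refinement exists to repair.  Analytically the refinement
  should recover K ~= K_true and g ~= g_true/sqrt(K_true);
* ice-ring contamination — observations inside configured narrow
  resolution windows are inflated by an excess factor with some
  probability, without any sigma inflation;
* redundancy (multiplicity per unique ~ Poisson) and incompleteness
  (whole uniques dropped with probability 1 - p_observe).

Noise is Gaussian with the stated variance rather than literal Poisson
counts: the analysis operates in the large-count regime where the variance
decomposition, not the discreteness, is the operative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errormodel import NoiseModel
from .symmetry import (
    LAUE_MMM,
    UnitCell,
    d_spacing_array,
    generate_unique,
)

__all__ = [
    "NoiseModel",
    "IceContamination",
    "SimulationConfig",
    "simulate_dataset",
    "default_ice_contamination",
]

# standard hexagonal-ice powder-ring d-spacings (Å)
ICE_RING_CENTERS = (3.90, 3.67, 3.44)


@dataclass(frozen=True)
class IceContamination:
    """One contaminated resolution window of the generator."""

    d_center: float
    half_width: float = 0.05
    excess_factor: float = 10.0
    contamination_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.excess_factor < 1:
            raise ValueError("excess_factor must be >= 1")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must lie in [0, 1]")


def default_ice_contamination() -> tuple[IceContamination, ...]:
    """Windows at the standard hexagonal-ice spacings 3.90/3.67/3.44 Å."""
    return tuple(IceContamination(c) for c in ICE_RING_CENTERS)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated data collection.

    Defaults describe a tetragonal lysozyme-style crystal on a laboratory
    source: a = b = 78.5, c = 37.3 Å, Wilson B = 15 Å^2, mean redundancy
    20 (laboratory data sets of this kind run roughly 12-31), delivered
    sigmas from the additive + Poisson terms only, g_true = 0.03 and
    K_true = 1.0 (typical refined values fall in 0.02-0.04 and 0.7-1.5).
    """

    cell: UnitCell = field(default_factory=lambda: UnitCell(78.5, 78.5, 37.3))
    true_laue: str = "4/mmm"
    d_min: float = 1.7
    d_max: float = 20.0
    B_true: float = 15.0  # Å^2
    scale_C: float = 1000.0  # mean intensity at s = 0, ADU
    target_redundancy: float = 20.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    tau: float = 1.0  # 1 = perfect tetragonal symmetry
    ice_windows: tuple[IceContamination, ...] = ()
    p_observe: float = 0.95
    seed: int = 0
    n_batches: int = 360

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("require 0 < d_min < d_max")
        if self.target_redundancy <= 0:
            raise ValueError("target_redundancy must be positive")
        if not 0 < self.p_observe <= 1:
            raise ValueError("p_observe must lie in (0, 1]")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must lie in [0, 1]")
        _check_windows_disjoint(self.ice_windows)


def _check_windows_disjoint(windows: Sequence[IceContamination]) -> None:
    spans = sorted((w.d_center - w.half_width, w.d_center + w.half_width) for w in windows)
    for (lo1, hi1), (lo2, hi2) in zip(spans[:-1], spans[1:]):
        if hi1 > lo2:
            raise ValueError("ice windows overlap")


def simulate_dataset(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (observations, truth) for the configured study conditions.

    Returns
    -------
    observations : DataFrame
        Columns ``h k l batch I sigma d`` plus all-False rejection-flag
        columns and the generator-truth column ``contaminated`` marking
        ice-inflated observations.
    truth : DataFrame
        One row per mmm-unique reflection: ``h k l d I_true``.
    """
    rng = np.random.default_rng(cfg.seed)
    cell = cfg.cell

    uniq = np.array(sorted(generate_unique(cell, LAUE_MMM, cfg.d_min, cfg.d_max)),
                    dtype=np.int64)
    d = d_spacing_array(cell, uniq)
    s2 = (0.5 / d) ** 2
    mean_i = cfg.scale_C * np.exp(-2.0 * cfg.B_true * s2)

    # exponential (acentric Wilson) draws, coupled across 4/mmm pairs
    i_true = mean_i * rng.exponential(size=len(uniq))
    h, k = uniq[:, 0], uniq[:, 1]
    # partner of (h,k,l) under the lost 4-fold is (k,h,l); both are mmm
    # representatives when h != k.  The lexicographically greater member
    # (h > k) is drawn freely; the partner is tau-coupled to it, so tau = 1
    # restores exact 4/mmm equality.
    key = {(int(a), int(b), int(c)): j for j, (a, b, c) in enumerate(uniq)}
    second = np.flatnonzero(h < k)
    partner = np.array([key[(int(k[j]), int(h[j]), int(uniq[j, 2]))] for j in second],
                       dtype=np.int64)
    i_indep = mean_i[second] * rng.exponential(size=len(second))
    i_true[second] = cfg.tau * i_true[partner] + (1.0 - cfg.tau) * i_indep

    truth = pd.DataFrame(
        {"h": uniq[:, 0], "k": uniq[:, 1], "l": uniq[:, 2], "d": d, "I_true": i_true}
    )

    # per-unique inclusion (incompleteness), then Poisson multiplicity
    included = rng.random(len(uniq)) < cfg.p_observe
    mult = rng.poisson(cfg.target_redundancy, size=len(uniq))
    mult[~included] = 0

    idx = np.repeat(np.arange(len(uniq)), mult)
    n_obs = len(idx)
    i0 = i_true[idx]
    nm = cfg.noise
    poisson = 1.0 if nm.include_poisson else 0.0
    true_var = nm.K_true * (nm.k0 + poisson * i0) + (nm.g_true * i0) ** 2
    i_obs = i0 + rng.normal(size=n_obs) * np.sqrt(true_var)
    sigma = np.sqrt(nm.k0 + poisson * np.maximum(i_obs, 0.0))
    # fully noiseless debug data would deliver sigma = 0; use unit weights
    # instead so the output remains mergeable
    sigma[sigma == 0.0] = 1.0
    d_obs = d[idx]

    contaminated = np.zeros(n_obs, dtype=bool)
    for w in cfg.ice_windows:
        in_window = np.abs(d_obs - w.d_center) <= w.half_width
        hit = in_window & (rng.random(n_obs) < w.contamination_fraction)
        i_obs[hit] *= w.excess_factor
        contaminated |= hit

    obs = pd.DataFrame(
        {
            "h": uniq[idx, 0],
            "k": uniq[idx, 1],
            "l": uniq[idx, 2],
            "batch": rng.integers(1, cfg.n_batches + 1, size=n_obs),
            "I": i_obs,
            "sigma": sigma,
            "d": d_obs,
            "rejected_outlier": False,
            "rejected_ice": False,
            "rejected_lowres": False,
            "contaminated": contaminated,
        }
    )
    return obs, truth
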