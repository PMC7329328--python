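"""Poisson occupancy statistics for single-cell droplet loading.

When a diluted cell suspension is emulsified into monodisperse droplets,
the number of cells per droplet follows a Poisson distribution with mean
occupancy ``n̄ = ρV``, where ``ρ`` is the cell density of the suspension
and ``V`` the droplet volume.  Designing a droplet-culture experiment means
trading off the fraction of droplets that receive any cell at all against
the fraction of loaded droplets that are clonal (exactly one founding
cell).  At the dilutions used for community culture (``n̄`` between ~0.1
and ~0.3), 10--26% of droplets are loaded and 86--95% of those loaded
contain a single cell.

This module provides the forward model (occupancy probabilities from a
mean), the two inverse problems used at the bench (inferring ``n̄`` from
the observed empty-droplet fraction, and choosing ``n̄`` so that a target
fraction of droplets is clonally loaded), and the dilution equation
``ρ = K·n̄/V`` that converts a target occupancy into a cell density, with
``K`` the empirically determined CFU-to-OD600 conversion constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LoadingSpec",
    "LoadingSummary",
    "SingleFractionSolution",
    "occupancy_pmf",
    "loading_summary",
    "dilution_for_target",
    "infer_mean_from_empty_fraction",
    "mean_for_single_fraction",
]

#: Maximum of n̄·exp(−n̄); above this no dilution achieves the requested
#: clonal-droplet fraction.
MAX_SINGLE_FRACTION = math.exp(-1.0)


@dataclass(frozen=True)
class LoadingSpec:
    """Physical parameters of a droplet-loading experiment.

    Parameters
    ----------
    mean_occupancy:
        Expected cells per droplet, ``n̄`` (dimensionless).
    droplet_volume:
        Volume per droplet ``V``, in liters.
    od_cfu_constant:
        Constant ``K`` converting CFU/ml to OD600, determined from
        replicate plating of the inoculum.
    cell_density:
        Cells per ml, ``ρ``.  If omitted it is derived from
        ``ρ = K·n̄/V``; if given it must be consistent with that identity.
    """

    mean_occupancy: float
    droplet_volume: float
    od_cfu_constant: float
    cell_density: float | None = None

    def __post_init__(self) -> None:
        if self.mean_occupancy < 0:
            raise ValueError("mean_occupancy must be >= 0")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be > 0")
        if self.od_cfu_constant <= 0:
            raise ValueError("od_cfu_constant must be > 0")
        derived = dilution_for_target(
            self.mean_occupancy, self.droplet_volume, self.od_cfu_constant
        ) if self.mean_occupancy > 0 else 0.0
        if self.cell_density is None:
            object.__setattr__(self, "cell_density", derived)
        elif not math.isclose(self.cell_density, derived, rel_tol=1e-6, abs_tol=1e-12):
            raise ValueError(
                f"cell_density {self.cell_density!r} inconsistent with "
                f"K*mean/V = {derived!r}"
            )


@dataclass(frozen=True)
class LoadingSummary:
    """Occupancy probabilities of a Poisson-loaded droplet population."""

    mean_occupancy: float
    p_empty: float
    p_loaded: float
    p_single: float
    p_multi: float
    p_single_given_loaded: float


class SingleFractionSolution(NamedTuple):
    """Occupancy solving ``n̄·exp(−n̄) = target`` with its multi-cell cost."""

    mean_occupancy: float
    p_multi: float


def occupancy_pmf(mean_occupancy: float, n: int) -> float:
    """Probability that a droplet contains exactly ``n`` cells.

    Returns ``n̄ⁿ e^(−n̄) / n!`` for Poisson loading at mean ``n̄``.
    """
    if mean_occupancy < 0:
        raise ValueError("mean_occupancy must be >= 0")
    if n < 0 or int(n) != n:
        raise ValueError("occupancy n must be a nonnegative integer")
    return float(stats.poisson.pmf(int(n), mean_occupancy))


def loading_summary(mean_occupancy: float) -> LoadingSummary:
    """Summarise droplet occupancy at a given Poisson mean.

    ``p_loaded = 1 − e^(−n̄)``, ``p_single = n̄·e^(−n̄)`` and
    ``p_multi = p_loaded − p_single``.  At ``n̄ = 0`` the conditional
    clonality ``p_single_given_loaded`` is undefined and returned as NaN.
    """
    if mean_occupancy < 0:
        raise ValueError("mean_occupancy must be >= 0")
    p_empty = math.exp(-mean_occupancy)
    p_loaded = 1.0 - p_empty
    p_single = mean_occupancy * p_empty
    p_multi = p_loaded - p_single
    p_cond = p_single / p_loaded if p_loaded > 0 else float("nan")
    return LoadingSummary(
        mean_occupancy=mean_occupancy,
        p_empty=p_empty,
        p_loaded=p_loaded,
        p_single=p_single,
        p_multi=p_multi,
        p_single_given_loaded=p_cond,
    )


def dilution_for_target(
    mean_occupancy: float, droplet_volume: float, od_cfu_constant: float
) -> float:
    """Cell density achieving a target mean occupancy: ``ρ = K·n̄/V``."""
    if mean_occupancy <= 0 or droplet_volume <= 0 or od_cfu_constant <= 0:
        raise ValueError("all arguments must be > 0")
    return od_cfu_constant * mean_occupancy / droplet_volume


def infer_mean_from_empty_fraction(f_empty: float) -> float:
    """Mean occupancy implied by an observed empty-droplet fraction.

    Counting empty droplets under the microscope gives ``f_empty``; under
    Poisson loading the mean occupancy is ``−ln(f_empty)``.
    """
    if f_empty == 0:
        raise ValueError("empty fraction 0 implies infinite mean occupancy")
    if not 0 < f_empty <= 1:
        raise ValueError("f_empty must lie in (0, 1]")
    return -math.log(f_empty)


def mean_for_single_fraction(
    target_p_single: float, upper_branch: bool = False
) -> SingleFractionSolution:
    """Occupancy at which a target fraction of droplets is clonally loaded.

    Solves ``n̄·e^(−n̄) = target`` by bisection (tolerance 1e−12).  The
    equation has two roots; the smaller, dilution-regime root is returned
    by default since experiments dilute toward clonality.  Set
    ``upper_branch=True`` for the larger root.  The returned tuple also
    carries the implied multi-cell droplet probability at the solution.
    """
    if not 0 < target_p_single <= MAX_SINGLE_FRACTION:
        raise ValueError(
            "target single-cell fraction must lie in (0, e^-1]; "
            f"max achievable is {MAX_SINGLE_FRACTION:.6f}"
        )

    def f(n: float) -> float:
        return n * math.exp(-n) - target_p_single

    if math.isclose(target_p_single, MAX_SINGLE_FRACTION, rel_tol=0, abs_tol=1e-15):
        root = 1.0
    elif upper_branch:
        # upper root lies in [1, n_hi] where n_hi e^(-n_hi) < any target > 0
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
        root = float(optimize.bisect(f, 1.0, hi, xtol=1e-12))
    else:
        root = float(optimize.bisect(f, 0.0, 1.0, xtol=1e-12))
    summary = loading_summary(root)
    return SingleFractionSolution(mean_occupancy=root, p_multi=summary.p_multi)


def occupancy_table(mean_occupancy: float, max_n: int = 5) -> "np.ndarray":
    """PMF values for occupancies ``0..max_n`` (convenience for reporting)."""
    return np.array([occupancy_pmf(mean_occupancy, n) for n in range(max_n + 1)])
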