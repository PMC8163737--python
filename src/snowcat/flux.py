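"""Leucine-to-carbon secondary production and carbon-loss calculus.

Prokaryotic heterotrophic production (PHP) is measured as tritiated-leucine
incorporation (pmol Leu L-1 h-1) and converted to carbon biomass production
with a leucine-to-carbon conversion factor of 1.55 kg C per mol of leucine
incorporated (equivalently 1.55 ng C per pmol) at an isotopic dilution of 1.
Downstream conversions normalise production per cell, derive community growth
rates from a per-cell carbon content, and turn production into respiration /
carbon demand either through a prokaryotic growth efficiency (PGE) or a
respiratory coefficient.

All conversions are positively homogeneous of degree 1 in the rate argument:
doubling the measured uptake doubles every derived quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEUCINE_TO_CARBON_NG_PER_PMOL",
    "DEFAULT_CELL_CARBON_FG",
    "DEFAULT_PGE",
    "LeucineUptake",
    "PhpRate",
    "CellConcentration",
    "CellSpecificRate",
    "GrowthRate",
    "CarbonLoss",
    "PowerLawFit",
    "leucine_to_carbon",
    "cells_per_litre",
    "cell_specific",
    "growth_rate",
    "carbon_loss",
    "fit_power_law",
    "estimate_attached_cells",
]

#: 1.55 kg C per mol Leu incorporated == 1.55 ng C per pmol Leu.
LEUCINE_TO_CARBON_NG_PER_PMOL = 1.55
#: Conservative per-cell carbon content (fg C cell-1).
DEFAULT_CELL_CARBON_FG = 12.0
#: Prokaryotic growth efficiency used for the non-sinking fraction.
DEFAULT_PGE = 0.08


@dataclass(frozen=True)
class LeucineUptake:
    """Replicate leucine incorporation measurements for one sample.

    ``replicates`` are volumetric uptake rates in pmol Leu L-1 h-1 (already
    normalised by incubation time); ``incubation_h`` is kept as metadata.
    """

    replicates: tuple[float, ...]
    incubation_h: float = 4.0
    depth_m: float | None = None
    fraction: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(float(r) for r in self.replicates))
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate is required")
        if any(r < 0 for r in self.replicates):
            raise ValueError("leucine uptake replicates must be >= 0")
        if self.incubation_h <= 0:
            raise ValueError("incubation time must be > 0")


@dataclass(frozen=True)
class PhpRate:
    """Volumetric heterotrophic production, ng C L-1 h-1 (mean over replicates)."""

    mean: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("PHP mean and sd must be >= 0")


@dataclass(frozen=True)
class CellConcentration:
    """Prokaryotic cell concentration in cells per litre."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("cell concentration must be > 0")
        if self.sd < 0:
            raise ValueError("cell concentration sd must be >= 0")


@dataclass(frozen=True)
class CellSpecificRate:
    """Per-cell production, ng C cell-1 h-1."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("cell-specific rate must be >= 0")


@dataclass(frozen=True)
class GrowthRate:
    """Community growth rate in h-1 derived from a per-cell carbon content."""

    value: float
    cell_carbon_fg: float = DEFAULT_CELL_CARBON_FG

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("growth rate must be >= 0")
        if self.cell_carbon_fg <= 0:
            raise ValueError("cell carbon content must be > 0")


@dataclass(frozen=True)
class CarbonLoss:
    """Respiration and carbon demand derived from production.

    In ``pge`` mode demand = PHP / PGE and respiration = demand - PHP, so
    carbon is conserved exactly (respiration + PHP = demand).  In
    ``respiratory_coefficient`` mode respiration = PHP * RQ.
    """

    respiration: float
    demand: float
    mode: str
    pge: float | None = None
    rq: float | None = None

    def __post_init__(self) -> None:
        if self.respiration < 0 or self.demand < 0:
            raise ValueError("respiration and demand must be >= 0")
        if self.mode == "pge" and self.demand < self.respiration:
            raise ValueError("demand must be >= respiration in pge mode")


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law depth profile c(z) = a * z**b."""

    a: float
    b: float
    depth_range_m: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("power-law scale a must be > 0")

    def evaluate(self, depth_m: float) -> float:
        if depth_m <= 0:
            raise ValueError("depth must be > 0")
        return self.a * depth_m**self.b


def leucine_to_carbon(
    u: LeucineUptake,
    factor: float = LEUCINE_TO_CARBON_NG_PER_PMOL,
    isotope_dilution: float = 1.0,
) -> PhpRate:
    """Convert leucine incorporation to carbon production (ng C L-1 h-1).

    Per replicate: ng C L-1 h-1 = pmol Leu L-1 h-1 * factor * isotope_dilution.
    The replicate SD propagates exactly through the linear scaling.
    """
    if factor <= 0:
        raise ValueError("conversion factor must be > 0")
    if isotope_dilution <= 0:
        raise ValueError("isotopic dilution must be > 0")
    rates = np.asarray(u.replicates, dtype=float) * factor * isotope_dilution
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return PhpRate(mean=float(rates.mean()), sd=sd, n=int(rates.size))


def cells_per_litre(cells_per_ml: float, sd_per_ml: float = 0.0) -> CellConcentration:
    """Ingest a flow-cytometry concentration quoted per mL as cells per litre."""
    return CellConcentration(value=cells_per_ml * 1e3, sd=sd_per_ml * 1e3)


def cell_specific(php: PhpRate, cells: CellConcentration) -> CellSpecificRate:
    """Normalise volumetric production to per-cell production.

    Both quantities must refer to the same water volume (cells per litre).
    The SD is a first-order delta-method propagation of the two relative
    errors; it is reported for plotting, not used for inference.
    """
    value = php.mean / cells.value
    if php.mean > 0:
        rel = np.hypot(php.sd / php.mean, cells.sd / cells.value)
        sd = value * float(rel)
    else:
        sd = 0.0
    return CellSpecificRate(value=value, sd=sd)


def growth_rate(
    cs: CellSpecificRate, cell_carbon_fg: float = DEFAULT_CELL_CARBON_FG
) -> GrowthRate:
    """Growth rate in h-1: (ng C cell-1 h-1) / (fg C cell-1), units made
    consistent by the 1e6 fg/ng factor."""
    if cell_carbon_fg <= 0:
        raise ValueError("cell carbon content must be > 0")
    return GrowthRate(value=cs.value * 1e6 / cell_carbon_fg, cell_carbon_fg=cell_carbon_fg)


def carbon_loss(
    php: PhpRate | float,
    mode: str = "pge",
    pge: float = DEFAULT_PGE,
    rq: float = 1.0,
) -> CarbonLoss:
    """Convert production to respiration and total carbon demand.

    ``pge`` mode (non-sinking fraction): demand = PHP/PGE, respiration =
    PHP*(1-PGE)/PGE.  ``respiratory_coefficient`` mode (fast-sinking
    fraction): respiration = PHP*RQ, demand = PHP*(1+RQ).
    """
    p = php.mean if isinstance(php, PhpRate) else float(php)
    if p < 0:
        raise ValueError("production must be >= 0")
    if mode == "pge":
        if not 0 < pge <= 1:
            raise ValueError("prokaryotic growth efficiency must be in (0, 1]")
        demand = p / pge
        return CarbonLoss(respiration=demand - p, demand=demand, mode=mode, pge=pge)
    if mode == "respiratory_coefficient":
        if rq < 0:
            raise ValueError("respiratory coefficient must be >= 0")
        return CarbonLoss(respiration=p * rq, demand=p * (1.0 + rq), mode=mode, rq=rq)
    raise ValueError(f"unknown carbon-loss mode {mode!r}")


def fit_power_law(depths_m, concentrations) -> PowerLawFit:
    """Fit c(z) = a * z**b by OLS of log(c) on log(z).

    The log-log fit assumes a multiplicative error model, which is the usual
    choice for depth profiles of cell abundance, and is exact on noise-free
    power-law data.
    """
    z = np.asarray(depths_m, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if z.size != c.size or z.size < 2:
        raise ValueError("need >= 2 (depth, concentration) pairs")
    if np.any(z <= 0) or np.any(c <= 0):
        raise ValueError("depths and concentrations must be > 0")
    b, log_a = np.polyfit(np.log(z), np.log(c), 1)
    return PowerLawFit(a=float(np.exp(log_a)), b=float(b), depth_range_m=(float(z.min()), float(z.max())))


def estimate_attached_cells(
    nonsink: CellConcentration,
    reference_fit: PowerLawFit,
    reference_nonsink: CellConcentration | float,
    depth_m: float,
) -> CellConcentration:
    """Transfer a sinking/non-sinking cell ratio from a reference study.

    The ratio between fractions at depth ``z`` is taken as the reference
    study's sinking-pool power law evaluated at ``z`` divided by that study's
    non-sinking concentration at the same depth; applying the ratio to the
    local non-sinking concentration estimates the fast-sinking attached pool.
    Depths outside the reference fit's range are extrapolated with a warning.
    """
    ref = (
        reference_nonsink.value
        if isinstance(reference_nonsink, CellConcentration)
        else float(reference_nonsink)
    )
    if ref <= 0:
        raise ValueError("reference non-sinking concentration must be > 0")
    lo, hi = reference_fit.depth_range_m
    if not lo <= depth_m <= hi:
        warnings.warn(
            f"depth {depth_m} m outside reference fit range [{lo}, {hi}] m; extrapolating",
            stacklevel=2,
        )
    ratio = reference_fit.evaluate(depth_m) / ref
    return CellConcentration(value=ratio * nonsink.value, sd=ratio * nonsink.sd)
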