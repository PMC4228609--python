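"""Exponential litter-decomposition constants from litterbag mass-loss data.

A species' decay constant k (d^-1) is the negated slope of the ordinary
least-squares regression of ln(percent mass remaining) on time in days
(single-exponential decay, m(t) = m0 * exp(-k t)).  The litterbag protocol
buries bags of known initial dry mass (nominally 2 +/- 0.1 g) and harvests
them at a few time points; replicate bags at a harvest enter the regression
as separate points.  Because the initial mass is known, the default adds the
anchor point (t=0, ln 100) — disable with ``include_t0=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MassLossSeries", "DecayFit", "fit_k", "fit_k_table"]


@dataclass
class MassLossSeries:
    """One species' litterbag record: initial mass and harvest observations."""

    species: str
    initial_mass: float
    times: np.ndarray  # days since burial, > 0
    masses: np.ndarray  # grams remaining, > 0; replicates allowed per time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.shape != self.masses.shape:
            raise ValueError("times and masses must have equal length")
        if self.initial_mass <= 0:
            raise ValueError("initial mass must be positive")
        if np.any(self.times <= 0):
            raise ValueError("harvest times must be > 0 (t=0 is implied)")
        if np.any(self.masses <= 0):
            raise ValueError(
                f"non-positive mass remaining for {self.species!r}"
            )
        if len(np.unique(self.times)) < 2:
            raise ValueError(
                f"{self.species!r}: need >= 2 distinct harvest times"
            )


@dataclass
class DecayFit:
    species: str
    k: float  # d^-1
    intercept: float  # ln-percent units
    r_squared: float
    n_points: int


def fit_k(series: MassLossSeries, include_t0: bool = True) -> DecayFit:
    """OLS of ln(percent mass remaining) on time; k = -slope."""
    pct = 100.0 * series.masses / series.initial_mass
    x = series.times
    y = np.log(pct)
    if include_t0:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[math.log(100.0)], y])
    if len(x) < 2:
        raise ValueError("need at least 2 usable points")
    res = stats.linregress(x, y)
    return DecayFit(
        species=series.species,
        k=-float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def fit_k_table(df: pd.DataFrame, include_t0: bool = True) -> pd.DataFrame:
    """Per-species decay fits from a long-format mass-loss table.

    Expects columns species, time_days, mass_g, initial_mass_g; returns one
    row per species with k_per_day, intercept, r_squared, n_points.
    """
    required = {"species", "time_days", "mass_g", "initial_mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mass-loss table missing columns: {sorted(missing)}")
    rows = []
    for species, grp in df.groupby("species", sort=True):
        m0 = grp["initial_mass_g"].iloc[0]
        series = MassLossSeries(
            species=str(species),
            initial_mass=float(m0),
            times=grp["time_days"].to_numpy(dtype=float),
            masses=grp["mass_g"].to_numpy(dtype=float),
        )
        fit = fit_k(series, include_t0=include_t0)
        rows.append(
            {
                "species": fit.species,
                "k_per_day": fit.k,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)
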