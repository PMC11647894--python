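"""Bulk (per-glucose) energies from finite-size series of nanocrystals.

The per-chain energy of a chain of ``dp`` glucose units is, to excellent
approximation, linear in ``dp``: an interior glucose contributes the bulk
energy per unit (slope) while the chain ends contribute a constant offset
(intercept).  Fitting per-chain energies of crystals with increasing chain
length by ordinary least squares therefore separates the bulk energy per
glucose unit from end/surface effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .energetics import EnergyBreakdown

__all__ = [
    "SizeSeries",
    "BulkFitResult",
    "fit_bulk_energy",
    "assemble_size_series",
    "average_over_replicas",
]


@dataclass
class SizeSeries:
    """Per-chain energies (kcal/mol) of crystals of increasing chain length."""

    dp_values: list[int]
    per_chain_energy: list[float]
    term: str = ""  # e.g. "electrostatic interchain"
    variant: str = ""
    sem: list[float] | None = None  # replica spread where available

    def __post_init__(self) -> None:
        if len(self.dp_values) != len(self.per_chain_energy):
            raise ValueError("dp_values and per_chain_energy must align")
        if any(b <= a for a, b in zip(self.dp_values, self.dp_values[1:])):
            raise ValueError("dp values must be strictly increasing")


@dataclass
class BulkFitResult:
    """OLS fit of per-chain energy vs chain length.

    ``slope`` is the bulk energy per glucose unit; ``intercept`` collects
    chain-end contributions; ``slope_stderr`` is the standard error of the
    slope (NaN for a two-point fit, where it is undefined).
    """

    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float

    @property
    def two_point(self) -> bool:
        return not np.isfinite(self.slope_stderr)


def fit_bulk_energy(series: SizeSeries) -> BulkFitResult:
    """Unweighted OLS of per-chain energy against degree of polymerization."""
    x = np.asarray(series.dp_values, float)
    y = np.asarray(series.per_chain_energy, float)
    if len(x) < 2:
        raise ValueError("need at least two chain lengths to fit")
    if len(np.unique(x)) < 2:
        raise ValueError("dp values must be distinct")
    res = stats.linregress(x, y)
    if len(x) == 2:
        stderr = float("nan")
        r2 = 1.0
    else:
        stderr = float(res.stderr)
        # guard exact fits where rvalue may wobble numerically
        ss_res = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return BulkFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=stderr,
        r_squared=min(max(r2, 0.0), 1.0),
    )


def assemble_size_series(
    reports: list[tuple[int, EnergyBreakdown]],
    component: str = "electrostatic",
    term: str = "",
    variant: str = "",
) -> SizeSeries:
    """Collect per-chain mean energies of one term across crystal sizes.

    ``reports`` pairs each degree of polymerization with the energy
    breakdown of the corresponding crystal (computed over its central
    chains); the series value is the mean per-chain energy.
    """
    if not reports:
        raise ValueError("no reports given")
    scopes = {b.scope for _, b in reports}
    if len(scopes) > 1:
        raise ValueError(f"mixed scopes in size series: {sorted(scopes)}")
    dps, vals = [], []
    for dp, b in sorted(reports, key=lambda t: t[0]):
        per_chain = (
            b.per_chain_electrostatic if component == "electrostatic" else b.per_chain_vdw
        )
        dps.append(dp)
        vals.append(float(np.mean(list(per_chain.values()))))
    return SizeSeries(dps, vals, term=term or scopes.pop(), variant=variant)


def average_over_replicas(values) -> tuple[float, float]:
    """Mean and standard error of the mean of replica energies.

    SEM is the sample standard deviation (ddof=1) over sqrt(n); it is 0 for
    a single replica.
    """
    v = np.asarray(list(values), float)
    if v.size == 0:
        raise ValueError("no replica values given")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
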