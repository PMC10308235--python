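"""H2 source apportionment: Keeling plots, water-rock fractionation fits,
and alpha-vs-temperature origin classification.

A Keeling plot regresses the isotope composition of a two-endmember gas
mixture against the reciprocal of its mixing ratio; the intercept at
1/c -> 0 is the composition of the added (high-concentration) source.
Pore-gas H2 headspace samples are mixtures of sample-derived H2 and an
unavoidable air background (~0.5 ppmv, dD ~ +150 permil), so the intercept
recovers the subseafloor H2 endmember.

Fe-H2O batch experiments (anaerobic corrosion of zerovalent iron in
D-spiked water) constrain the kinetic D/H fractionation of low-temperature
water-rock H2 generation: (1000 + dD_H2) is proportional to
(1000 + dD_H2O) with slope alpha, fitted through the origin of the shifted
coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .isotopes import (
    FractionationFactor,
    FractionationKind,
    PERMIL_FLOOR,
    equilibrium_alpha,
)


@dataclass(frozen=True)
class KeelingSample:
    """One headspace observation: H2 mixing ratio (ppmv) and dD_H2 (permil)."""

    mixing_ratio: float
    delta_d_h2: float

    def __post_init__(self) -> None:
        if not self.mixing_ratio > 0.0:
            raise ValueError("mixing ratio must be positive (reciprocal must exist)")


@dataclass(frozen=True)
class KeelingFit:
    """OLS fit of dD_H2 on 1/mixing-ratio.

    ``intercept_delta`` is the source endmember dD (permil); ``slope`` has
    units permil*ppmv and equals c_bg*(dD_bg - dD_source) on the exact
    two-endmember mixing model.
    """

    intercept_delta: float
    slope: float
    stderr_intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class BatchExperiment:
    """A set of (dD_H2O, dD_H2) pairs from one reaction temperature."""

    t_celsius: float
    pairs: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        for d_h2o, d_h2 in self.pairs:
            if d_h2o <= PERMIL_FLOOR or d_h2 <= PERMIL_FLOOR:
                raise ValueError("all deltas must exceed -1000 permil")


class H2Origin(str, Enum):
    LOW_T_WATER_ROCK = "low_T_water_rock"
    EQUILIBRATED = "equilibrated"
    HIGH_T_KINETIC = "high_T_kinetic"


def keeling_forward(
    c_background: float,
    delta_background: float,
    added_concentrations: Iterable[float],
    delta_source: float,
) -> list[KeelingSample]:
    """Forward two-endmember mixing: background gas plus added source gas.

    Each sample's delta is the concentration-weighted mean
    (c_bg*d_bg + c_add*d_src)/(c_bg + c_add), which is exactly linear in
    1/(c_bg + c_add).
    """
    if c_background < 0.0:
        raise ValueError("background concentration must be >= 0")
    out = []
    for c_add in added_concentrations:
        if c_add < 0.0:
            raise ValueError("added concentrations must be >= 0")
        total = c_background + c_add
        if total == 0.0:
            raise ValueError("total mixing ratio is zero; delta undefined")
        delta = (c_background * delta_background + c_add * delta_source) / total
        out.append(KeelingSample(total, delta))
    return out


def keeling_fit(samples: Sequence[KeelingSample]) -> KeelingFit:
    """Ordinary least squares of delta on reciprocal mixing ratio.

    The intercept estimates the high-concentration source endmember.  With
    fewer than 3 samples the intercept standard error is undefined (NaN).
    """
    if len(samples) < 2:
        raise ValueError("Keeling fit needs at least 2 samples")
    x = np.array([1.0 / s.mixing_ratio for s in samples])
    y = np.array([s.delta_d_h2 for s in samples])
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all mixing ratios equal")
    res = stats.linregress(x, y)
    n = len(samples)
    stderr = float(res.intercept_stderr) if n >= 3 else float("nan")
    return KeelingFit(
        intercept_delta=float(res.intercept),
        slope=float(res.slope),
        stderr_intercept=stderr,
        r2=float(res.rvalue**2),
        n=n,
    )


def fit_alpha_origin(batch: BatchExperiment) -> FractionationFactor:
    """Kinetic alpha_(H2-H2O) from one batch by regression through the origin.

    Least squares slope of (1000 + dD_H2) on (1000 + dD_H2O) with zero
    intercept: alpha = sum(x*y)/sum(x^2).  Exact on data generated with a
    single alpha, and scale-consistent (multiplying both shifted coordinates
    by a constant leaves alpha unchanged).
    """
    if len(batch.pairs) < 2:
        raise ValueError("need at least 2 (dD_H2O, dD_H2) pairs")
    x = np.array([1000.0 + p[0] for p in batch.pairs])
    y = np.array([1000.0 + p[1] for p in batch.pairs])
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: single distinct dD_H2O level")
    alpha = float(x @ y / (x @ x))
    return FractionationFactor(alpha, ("H2", "H2O"), FractionationKind.KINETIC)


def classify_h2_origin(
    alpha: float,
    t_celsius: float,
    equilibrium_band: float = 0.02,
    high_t_cutoff: float = 0.6,
) -> H2Origin:
    """Classify the origin of H2 from its apparent alpha_(H2-H2O) at T.

    ``equilibrated`` when alpha sits within ``equilibrium_band`` of the
    H2-H2O equilibrium curve at T; ``low_T_water_rock`` when it falls below
    the curve by more than the band (strong kinetic D depletion);
    ``high_T_kinetic`` for D-rich H2 (alpha >= cutoff, the signature of
    fault-melt and high-temperature hydrothermal H2).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1) for H2-H2O systems")
    if not 0.0 <= t_celsius <= 400.0:
        raise ValueError("temperature outside the 0-400 C classification domain")
    eq = equilibrium_alpha("H2-H2O", t_celsius).alpha
    if abs(alpha - eq) <= equilibrium_band:
        return H2Origin.EQUILIBRATED
    if alpha >= high_t_cutoff:
        return H2Origin.HIGH_T_KINETIC
    if alpha < eq - equilibrium_band:
        return H2Origin.LOW_T_WATER_ROCK
    raise ValueError(
        f"alpha = {alpha} lies above the equilibrium curve ({eq:.3f}) at "
        f"{t_celsius} C but below the high-temperature cutoff; no origin class"
    )
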