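"""Stable-isotope delta/ratio/alpha algebra and equilibrium calibrations.

All isotope compositions are per-mil (permil) delta values relative to the
conventional reference standard of the element (VSMOW for H/O, VPDB for C,
VCDT for S):

    delta_X = (R_sample / R_reference - 1) * 1000

The fractionation factor between coexisting species A and B is

    alpha_(A-B) = (1000 + delta_A) / (1000 + delta_B),

which is exact (no linear approximation) and requires delta > -1000 so that
the underlying isotope ratio stays positive.

Equilibrium hydrogen-isotope fractionation between H2 and liquid water and
between CH4 and liquid water follows published polynomial-in-1/T
calibrations shipped in ``data/calibrations.tsv`` with their provenance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

from scipy.optimize import brentq

from ._resources import load_table

PERMIL_FLOOR = -1000.0  # delta at which the isotope ratio vanishes


class IsotopeSystem(str, Enum):
    D_H = "D/H"
    C13_C12 = "13C/12C"
    S33_S32 = "33S/32S"
    S34_S32 = "34S/32S"
    O18_O16 = "18O/16O"


class Standard(str, Enum):
    VSMOW = "VSMOW"
    VPDB = "VPDB"
    VCDT = "VCDT"


class FractionationKind(str, Enum):
    KINETIC = "kinetic"
    EQUILIBRIUM = "equilibrium"
    APPARENT = "apparent"


def _check_delta(delta: float, name: str = "delta") -> None:
    if not delta > PERMIL_FLOOR:
        raise ValueError(
            f"{name} = {delta} permil implies a non-positive isotope ratio "
            f"(must exceed {PERMIL_FLOOR})"
        )


@dataclass(frozen=True)
class IsotopeValue:
    """A delta value (permil) tied to an isotope system and its standard."""

    delta: float
    system: IsotopeSystem
    standard: Standard

    def __post_init__(self) -> None:
        _check_delta(self.delta)

    def ratio(self, reference_ratio: float) -> float:
        """Absolute isotope ratio given the standard's absolute ratio."""
        return reference_ratio * (1.0 + self.delta / 1000.0)

    @classmethod
    def from_ratio(
        cls, ratio: float, reference_ratio: float,
        system: IsotopeSystem, standard: Standard,
    ) -> "IsotopeValue":
        return cls((ratio / reference_ratio - 1.0) * 1000.0, system, standard)


@dataclass(frozen=True)
class FractionationFactor:
    """alpha_(A-B) for an ordered species pair, with its mechanistic kind."""

    alpha: float
    pair: tuple[str, str]
    kind: FractionationKind

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 2.0:
            raise ValueError(f"alpha = {self.alpha} outside (0, 2)")


def alpha_from_deltas(delta_a: float, delta_b: float,
                      pair: tuple[str, str] = ("A", "B")) -> FractionationFactor:
    """alpha_(A-B) = (1000 + delta_A) / (1000 + delta_B), kind 'apparent'."""
    _check_delta(delta_a, "delta_A")
    _check_delta(delta_b, "delta_B")
    return FractionationFactor(
        (1000.0 + delta_a) / (1000.0 + delta_b), pair, FractionationKind.APPARENT
    )


def delta_via_alpha(delta_b: float, alpha: float) -> float:
    """delta_A such that alpha_(A-B)(delta_A, delta_B) = alpha."""
    _check_delta(delta_b, "delta_B")
    if not alpha > 0.0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return alpha * (1000.0 + delta_b) - 1000.0


def mix_conservative(value: float, f_contam: float, contaminant_value: float) -> float:
    """Two-component volumetric mixture: (1-f)*value + f*contaminant."""
    if not 0.0 <= f_contam <= 1.0:
        raise ValueError(f"mixing fraction {f_contam} outside [0, 1]")
    return (1.0 - f_contam) * value + f_contam * contaminant_value


def unmix_conservative(measured: float, f_contam: float,
                       contaminant_value: float) -> float:
    """Invert linear volumetric mixing of a conservative quantity.

    Returns the indigenous value ``(measured - f*contaminant) / (1 - f)``;
    the exact inverse of :func:`mix_conservative` for any ``f < 1``.
    """
    if not 0.0 <= f_contam < 1.0:
        raise ValueError(
            f"contamination fraction {f_contam} must be in [0, 1); at f = 1 "
            "no indigenous component remains"
        )
    return (measured - f_contam * contaminant_value) / (1.0 - f_contam)


def methanotrophy_trajectory(
    delta13c_0: float, delta_d_0: float, shift13c: float, slope: float = 10.0
) -> tuple[float, float]:
    """Residual-CH4 composition after microbial CH4 oxidation.

    Methanotrophy enriches the remaining methane in both 13C and D with a
    characteristic dD/d13C slope of ~10; the trajectory is parameterised by
    the 13C shift (permil, >= 0).
    """
    if shift13c < 0.0:
        raise ValueError("shift13c must be non-negative")
    return delta13c_0 + shift13c, delta_d_0 + slope * shift13c


# ---------------------------------------------------------------------------
# equilibrium calibrations


@dataclass(frozen=True)
class EquilibriumCalibration:
    """Polynomial-in-1/T equilibrium fractionation curve for a species pair.

    alpha_(A-B)(T) = 1 / (c0 + c2/T^2 + c4/T^4 + c6/T^6), T in kelvin; the
    published fits express the inverse factor (B over A) as the polynomial.
    """

    pair: str
    coefficients: tuple[float, float, float, float]
    valid_t_range_c: tuple[float, float]
    citation: str

    def _check_t(self, t_celsius: float) -> None:
        lo, hi = self.valid_t_range_c
        if not lo <= t_celsius <= hi:
            raise ValueError(
                f"T = {t_celsius} C outside the {self.pair} calibration range "
                f"[{lo}, {hi}] C"
            )

    def alpha(self, t_celsius: float) -> float:
        self._check_t(t_celsius)
        t_k = t_celsius + 273.15
        c0, c2, c4, c6 = self.coefficients
        return 1.0 / (c0 + c2 / t_k**2 + c4 / t_k**4 + c6 / t_k**6)

    def alpha_range(self) -> tuple[float, float]:
        lo, hi = self.valid_t_range_c
        a_lo, a_hi = self.alpha(lo), self.alpha(hi)
        return (min(a_lo, a_hi), max(a_lo, a_hi))


@lru_cache(maxsize=None)
def get_calibration(pair: str) -> EquilibriumCalibration:
    """Load a shipped calibration by pair name ('H2-H2O' or 'CH4-H2O')."""
    table = load_table("calibrations.tsv")
    row = table[table["pair"] == pair]
    if row.empty:
        known = ", ".join(table["pair"])
        raise KeyError(f"no equilibrium calibration for pair {pair!r} (have {known})")
    r = row.iloc[0]
    return EquilibriumCalibration(
        pair=pair,
        coefficients=(r["c0"], r["c2"], r["c4"], r["c6"]),
        valid_t_range_c=(r["t_min_c"], r["t_max_c"]),
        citation=r["citation"],
    )


def equilibrium_alpha(pair: str, t_celsius: float) -> FractionationFactor:
    """Equilibrium alpha for a shipped pair at temperature T (deg C)."""
    cal = get_calibration(pair)
    a, b = pair.split("-", 1)
    return FractionationFactor(cal.alpha(t_celsius), (a, b),
                               FractionationKind.EQUILIBRIUM)


def temperature_from_alpha(pair: str, alpha: float) -> float:
    """Invert an equilibrium calibration: temperature (deg C) at which the
    pair's equilibrium fractionation equals ``alpha``.

    Uses monotone root bracketing over the calibration's validity range;
    raises if ``alpha`` is unattainable on the curve.
    """
    cal = get_calibration(pair)
    lo_a, hi_a = cal.alpha_range()
    if not lo_a <= alpha <= hi_a:
        raise ValueError(
            f"alpha = {alpha} unattainable for {pair}: calibration spans "
            f"[{lo_a:.4f}, {hi_a:.4f}] over {cal.valid_t_range_c} C"
        )
    lo_t, hi_t = cal.valid_t_range_c
    if math.isclose(cal.alpha(lo_t), alpha, rel_tol=0, abs_tol=1e-12):
        return lo_t
    if math.isclose(cal.alpha(hi_t), alpha, rel_tol=0, abs_tol=1e-12):
        return hi_t
    return float(brentq(lambda t: cal.alpha(t) - alpha, lo_t, hi_t, xtol=1e-8))
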