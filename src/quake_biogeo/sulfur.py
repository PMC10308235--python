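"""Multiple-sulfur-isotope systematics.

Compositions are (d33S, d34S) pairs on the VCDT scale. The capital-delta
value measures deviation from the mass-dependent reference array with
exponent 0.515:

    D33S = d33S - ((1 + d34S/1000)^0.515 - 1) * 1000   (exact form)

Microbial sulfate reduction (MSR) fractionates mass-dependently with a
magnitude eps34 (permil) and mass-law exponent lambda33 (~0.510-0.515):

    eps34    = 1000 * (1 - R34_sulfide / R34_sulfate)
    lambda33 = ln(R33_sulfide / R33_sulfate) / ln(R34_sulfide / R34_sulfate)

Juvenile (mantle-derived) sulfur sits at (0, 0); mixing between juvenile
sulfide and isotopically fractionated biogenic sulfide is computed by molar
mass balance on the 32S/33S/34S abundances, which is curved in
(d34S, D33S) space.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from ._resources import load_table
from .isotopes import PERMIL_FLOOR

REFERENCE_EXPONENT = 0.515  # mass-dependent reference array exponent


class SulfurRole(str, Enum):
    SULFIDE_CRS = "sulfide_CRS"
    SULFATE_POREWATER = "sulfate_porewater"
    JUVENILE = "juvenile"


def _check(delta: float, name: str) -> None:
    if not delta > PERMIL_FLOOR:
        raise ValueError(f"{name} = {delta} permil must exceed -1000")


@dataclass(frozen=True)
class SulfurRecord:
    """Paired d33S/d34S (permil VCDT) with sample context."""

    delta33: float
    delta34: float
    role: SulfurRole = SulfurRole.SULFIDE_CRS
    context: str = ""

    def __post_init__(self) -> None:
        _check(self.delta33, "d33S")
        _check(self.delta34, "d34S")

    @property
    def cap_delta33(self) -> float:
        return cap_delta33(self.delta33, self.delta34)


@dataclass(frozen=True)
class MsrFractionation:
    """Magnitude and mass-law exponent of a sulfate-reduction fractionation."""

    eps34: float
    lambda33: float = REFERENCE_EXPONENT

    def __post_init__(self) -> None:
        if not 0.500 <= self.lambda33 <= 0.520:
            raise ValueError(
                f"lambda33 = {self.lambda33} outside the mass-dependent "
                "window [0.500, 0.520]"
            )


def cap_delta33(delta33: float, delta34: float) -> float:
    """D33S (permil), exact exponential form with reference exponent 0.515."""
    _check(delta33, "d33S")
    _check(delta34, "d34S")
    ref = ((1.0 + delta34 / 1000.0) ** REFERENCE_EXPONENT - 1.0) * 1000.0
    return delta33 - ref


def epsilon34(delta34_sulfide: float, delta34_sulfate: float) -> float:
    """eps34 = 1000 * (1 - (1000 + d34_sulfide)/(1000 + d34_sulfate))."""
    _check(delta34_sulfide, "d34S(sulfide)")
    _check(delta34_sulfate, "d34S(sulfate)")
    return 1000.0 * (1.0 - (1000.0 + delta34_sulfide) / (1000.0 + delta34_sulfate))


def lambda33(
    delta33_sulfide: float,
    delta34_sulfide: float,
    delta33_sulfate: float,
    delta34_sulfate: float,
) -> float:
    """Mass-law exponent between a sulfate pool and its product sulfide."""
    for d, n in [(delta33_sulfide, "d33S(sulfide)"), (delta34_sulfide, "d34S(sulfide)"),
                 (delta33_sulfate, "d33S(sulfate)"), (delta34_sulfate, "d34S(sulfate)")]:
        _check(d, n)
    log34 = math.log((1000.0 + delta34_sulfide) / (1000.0 + delta34_sulfate))
    if log34 == 0.0:
        raise ZeroDivisionError(
            "d34S of sulfide and sulfate coincide; lambda33 undefined"
        )
    log33 = math.log((1000.0 + delta33_sulfide) / (1000.0 + delta33_sulfate))
    return log33 / log34


def msr_forward(sulfate: SulfurRecord, frac: MsrFractionation,
                context: str = "") -> SulfurRecord:
    """Product sulfide of mass-dependent sulfate reduction.

    Constructed so that :func:`epsilon34` and :func:`lambda33` of the
    (sulfate, product) pair recover ``frac`` exactly.
    """
    d34 = (1000.0 + sulfate.delta34) * (1.0 - frac.eps34 / 1000.0) - 1000.0
    ratio34 = (1000.0 + d34) / (1000.0 + sulfate.delta34)
    d33 = (1000.0 + sulfate.delta33) * ratio34**frac.lambda33 - 1000.0
    return SulfurRecord(d33, d34, SulfurRole.SULFIDE_CRS, context)


def _vcdt_ratios() -> tuple[float, float]:
    t = load_table("reference_ratios.tsv").set_index("ratio")["value"]
    return float(t["VCDT_33S_32S"]), float(t["VCDT_34S_32S"])


def mix_records(
    end1: SulfurRecord,
    end2: SulfurRecord,
    f: float,
    s_contents: tuple[float, float] = (1.0, 1.0),
    reference_ratios: tuple[float, float] | None = None,
) -> SulfurRecord:
    """Mix two sulfur pools by molar mass balance on isotope abundances.

    ``f`` is the fraction of total sulfur contributed by ``end2`` (scaled by
    ``s_contents`` when the endmembers carry different sulfur per unit of
    mixing fraction). Ratios are mixed weighted by each pool's 32S
    abundance, i.e. exact isotope mole balance; the result is insensitive to
    the absolute reference ratios to first order.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixing fraction must lie in [0, 1]")
    r33_ref, r34_ref = reference_ratios or _vcdt_ratios()

    def abundances(rec: SulfurRecord, amount: float):
        r33 = r33_ref * (1.0 + rec.delta33 / 1000.0)
        r34 = r34_ref * (1.0 + rec.delta34 / 1000.0)
        n32 = amount / (1.0 + r33 + r34)
        return n32, n32 * r33, n32 * r34

    w1 = (1.0 - f) * s_contents[0]
    w2 = f * s_contents[1]
    n32a, n33a, n34a = abundances(end1, w1)
    n32b, n33b, n34b = abundances(end2, w2)
    n32, n33, n34 = n32a + n32b, n33a + n33b, n34a + n34b
    d33 = (n33 / n32 / r33_ref - 1.0) * 1000.0
    d34 = (n34 / n32 / r34_ref - 1.0) * 1000.0
    return SulfurRecord(d33, d34, end1.role, f"mix(f={f:g})")


def sulfur_mixing_curve(
    end1: SulfurRecord,
    end2: SulfurRecord,
    fractions: Iterable[float],
    s_contents: tuple[float, float] = (1.0, 1.0),
) -> list[tuple[float, float]]:
    """(d34S, D33S) points along the abundance mass-balance mixing curve.

    Endpoints are reproduced exactly at f = 0 (end1) and f = 1 (end2).
    """
    out = []
    for f in fractions:
        rec = mix_records(end1, end2, f, s_contents)
        out.append((rec.delta34, rec.cap_delta33))
    return out


def seawater_sulfate(context: str = "seawater") -> SulfurRecord:
    """Modern seawater sulfate (d34S +21.3, D33S +0.050 permil VCDT)."""
    sw = load_table("seawater.tsv").set_index("key")["value"]
    d34 = float(sw["d34S_sulfate"])
    cap = float(sw["D33S_sulfate"])
    d33 = cap + ((1.0 + d34 / 1000.0) ** REFERENCE_EXPONENT - 1.0) * 1000.0
    return SulfurRecord(d33, d34, SulfurRole.SULFATE_POREWATER, context)


JUVENILE = SulfurRecord(0.0, 0.0, SulfurRole.JUVENILE, "mantle juvenile sulfur")
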