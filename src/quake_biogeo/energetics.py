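"""Catabolic Gibbs free-energy landscapes for competing hydrogenotrophic
metabolisms.

Three chemoautotrophic reactions involving H2 and CH4 are evaluated at in
situ conditions (default 25 C, 500 bar, pH 7.9, seawater-like ionic
strength):

    r1  4 H2(aq) +   CO2(aq) = CH4(aq)      + 2 H2O   hydrogenotrophic methanogenesis
    r2  4 H2(aq) + 2 CO2(aq) = CH3COOH(aq)  + 2 H2O   homoacetogenesis
    r3    CH4(aq) + CO2(aq)  = CH3COOH(aq)            (r2 - r1 by Hess's law)

Acetoclastic methanogenesis is the reverse of r3. The reaction energy is

    dGr = dG0r + R*T*ln(Qr)

with dG0r assembled from a shipped table of SUPCRT92-lineage formation
energies at 25 C / 500 bar (so Hess closure r3 = r2 - r1 is exact by
construction). Single-ion activity coefficients follow the B-dot extended
Debye-Hueckel model; neutral dissolved species default to unit activity
coefficient (a Setchenow salting-out option exists). Dissolved CO2 and the
neutral acetic-acid species are obtained from total carbonate and total
acetate by pH-dependent mass-balance speciation with shipped pK values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import brentq

from ._resources import load_table

R_GAS = 8.314462618e-3  # kJ mol-1 K-1


# --------------------------------------------------------------------------
# constant tables


@lru_cache(maxsize=None)
def _species_table():
    t = load_table("species.tsv").set_index("species")
    return t


@lru_cache(maxsize=None)
def _pk(acid: str) -> float:
    t = load_table("dissociation.tsv").set_index("acid")["pk"]
    return float(t[acid])


def species_charge(name: str) -> int:
    t = _species_table()
    if name not in t.index:
        raise KeyError(f"unknown species {name!r}: no charge on record")
    return int(t.loc[name, "charge"])


def species_ion_size(name: str) -> float:
    size = _species_table().loc[name, "ion_size_a"]
    if not np.isfinite(size):
        raise KeyError(f"species {name!r} has no ion-size parameter (neutral?)")
    return float(size)


def formation_energy(name: str) -> float:
    """Apparent Gibbs energy of formation, kJ/mol at 25 C / 500 bar."""
    g = _species_table().loc[name, "gf_kj_mol"]
    if not np.isfinite(g):
        raise KeyError(f"species {name!r} has no formation energy on record")
    return float(g)


def _composition(name: str) -> dict[str, int]:
    raw = str(_species_table().loc[name, "composition"])
    return {el: int(n) for el, n in (part.split(":") for part in raw.split(","))}


@dataclass(frozen=True)
class BdotParams:
    """B-dot activity-model constants at (T, P) plus per-ion sizes."""

    a_gamma: float
    b_gamma: float
    bdot: float

    def __post_init__(self) -> None:
        if self.a_gamma <= 0.0 or self.b_gamma <= 0.0:
            raise ValueError("Debye-Hueckel A and B must be positive")

    @classmethod
    def default(cls) -> "BdotParams":
        t = load_table("bdot.tsv").set_index("parameter")["value"]
        return cls(float(t["A_gamma"]), float(t["B_gamma"]), float(t["bdot"]))


# --------------------------------------------------------------------------
# activity model


def ionic_strength(composition: dict[str, float],
                   charges: dict[str, int] | None = None) -> float:
    """I = 1/2 * sum(m_i * z_i^2), mol/kg.

    Charges default to the shipped species registry; unknown species raise.
    """
    total = 0.0
    for sp, m in composition.items():
        if m < 0.0:
            raise ValueError(f"negative molality for {sp}")
        z = charges[sp] if charges and sp in charges else species_charge(sp)
        total += m * z * z
    return 0.5 * total


def bdot_log_gamma(
    z: int,
    ion_size_a: float,
    ionic_strength_molal: float,
    params: BdotParams | None = None,
    neutral_setchenow_b: float = 0.0,
) -> float:
    """log10 single-ion activity coefficient under the B-dot model.

    Neutral species (z = 0) return ``neutral_setchenow_b * I`` — zero (gamma
    = 1) under the default rule.
    """
    if ionic_strength_molal < 0.0:
        raise ValueError("ionic strength must be >= 0")
    if params is None:
        params = BdotParams.default()
    if z == 0:
        return neutral_setchenow_b * ionic_strength_molal
    sqrt_i = math.sqrt(ionic_strength_molal)
    return (
        -params.a_gamma * z * z * sqrt_i
        / (1.0 + params.b_gamma * ion_size_a * sqrt_i)
        + params.bdot * ionic_strength_molal
    )


def gamma(species: str, ionic_strength_molal: float,
          params: BdotParams | None = None) -> float:
    """Activity coefficient of a registered species at ionic strength I."""
    z = species_charge(species)
    size = species_ion_size(species) if z != 0 else 0.0
    return 10.0 ** bdot_log_gamma(z, size, ionic_strength_molal, params)


# --------------------------------------------------------------------------
# speciation


def speciate_weak_acid(
    total_molal: float,
    pka: float,
    ph: float,
    gammas: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Activities (a_HA, a_A-) of a monoprotic weak acid from its total.

    Mass balance total = m_HA + m_A with Ka = aH * gA * mA / (gHA * mHA);
    pH is on the activity scale (a_H = 10^-pH). The neutral-acid activity
    is strictly linear in the total at fixed pH.
    """
    if total_molal < 0.0:
        raise ValueError("total concentration must be >= 0")
    g_ha, g_a = gammas
    a_h = 10.0 ** (-ph)
    ka = 10.0 ** (-pka)
    ratio = ka * g_ha / (a_h * g_a)  # m_A / m_HA
    m_ha = total_molal / (1.0 + ratio)
    m_a = total_molal - m_ha
    return g_ha * m_ha, g_a * m_a


def speciate_carbonate(
    total_co2_molal: float,
    pk1: float,
    pk2: float,
    ph: float,
    gammas: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Activity of CO2(aq) from total dissolved inorganic carbon.

    Three-species mass balance (CO2(aq), HCO3-, CO3--) with activity-
    corrected dissociation quotients.
    """
    if total_co2_molal < 0.0:
        raise ValueError("total CO2 must be >= 0")
    g0, g1, g2 = gammas
    a_h = 10.0 ** (-ph)
    k1, k2 = 10.0 ** (-pk1), 10.0 ** (-pk2)
    r1 = k1 * g0 / (a_h * g1)       # m_HCO3 / m_CO2
    r2 = k2 * g1 / (a_h * g2)       # m_CO3 / m_HCO3
    m_co2 = total_co2_molal / (1.0 + r1 + r1 * r2)
    return g0 * m_co2


# --------------------------------------------------------------------------
# reactions


@dataclass(frozen=True)
class ReactionSpec:
    """Stoichiometry (products positive) with its standard reaction energy."""

    name: str
    stoichiometry: dict[str, float]
    delta_g0: float  # kJ/mol at 25 C, 500 bar

    def validate(self) -> None:
        """Element and charge balance from the species registry."""
        elements: dict[str, float] = {}
        charge = 0.0
        for sp, nu in self.stoichiometry.items():
            charge += nu * species_charge(sp)
            for el, n in _composition(sp).items():
                elements[el] = elements.get(el, 0.0) + nu * n
        bad = {el: v for el, v in elements.items() if abs(v) > 1e-9}
        if bad or abs(charge) > 1e-9:
            raise ValueError(
                f"reaction {self.name!r} unbalanced: elements {bad}, "
                f"charge {charge}"
            )

    def reversed(self, name: str | None = None) -> "ReactionSpec":
        return ReactionSpec(
            name or f"reverse({self.name})",
            {sp: -nu for sp, nu in self.stoichiometry.items()},
            -self.delta_g0,
        )


def _reaction(name: str, stoich: dict[str, float]) -> ReactionSpec:
    dg0 = sum(nu * formation_energy(sp) for sp, nu in stoich.items())
    spec = ReactionSpec(name, stoich, dg0)
    spec.validate()
    return spec


@lru_cache(maxsize=None)
def shipped_reactions() -> dict[str, ReactionSpec]:
    """The three metabolic reactions, dG0 assembled from formation energies
    (Hess closure r3 = r2 - r1 is exact by construction), plus acetoclastic
    methanogenesis as the reverse of r3."""
    r1 = _reaction(
        "hydrogenotrophic_methanogenesis",
        {"H2(aq)": -4.0, "CO2(aq)": -1.0, "CH4(aq)": 1.0, "H2O(l)": 2.0},
    )
    r2 = _reaction(
        "homoacetogenesis",
        {"H2(aq)": -4.0, "CO2(aq)": -2.0, "CH3COOH(aq)": 1.0, "H2O(l)": 2.0},
    )
    r3 = _reaction(
        "methane_carboxylation",
        {"CH4(aq)": -1.0, "CO2(aq)": -1.0, "CH3COOH(aq)": 1.0},
    )
    return {
        r1.name: r1,
        r2.name: r2,
        r3.name: r3,
        "acetoclastic_methanogenesis": r3.reversed("acetoclastic_methanogenesis"),
    }


@dataclass(frozen=True)
class SolutionCondition:
    """In situ context for reaction-energy evaluation.

    Totals are molal (mol/kg, taken numerically equal to molar at these
    conditions); pH is on the activity scale.
    """

    t_celsius: float = 25.0
    p_bar: float = 500.0
    ph: float = 7.9
    total_co2: float = 0.050
    total_acetate: float = 1.0e-3
    ch4: float = 5.0e-3
    ionic_strength: float = 0.66
    neutral_setchenow_b: float = 0.0

    def __post_init__(self) -> None:
        if self.t_celsius != 25.0 or self.p_bar != 500.0:
            raise ValueError(
                "shipped dG0/pK constants are valid only at 25 C and 500 bar"
            )
        for name in ("total_co2", "total_acetate", "ch4", "ionic_strength"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def t_kelvin(self) -> float:
        return self.t_celsius + 273.15


def baseline_activities(condition: SolutionCondition) -> dict[str, float]:
    """Activities of all reaction species implied by the condition.

    H2(aq) is left out: it is the free variable of the landscapes. Water
    activity is fixed at 1.
    """
    params = BdotParams.default()
    i = condition.ionic_strength
    g_neutral = 10.0 ** bdot_log_gamma(
        0, 0.0, i, params, condition.neutral_setchenow_b
    )
    g_m1 = gamma("CH3COO-", i, params)
    g_m2 = gamma("CO3-2", i, params)
    a_hac, _ = speciate_weak_acid(
        condition.total_acetate, _pk("acetic"), condition.ph, (g_neutral, g_m1)
    )
    a_co2 = speciate_carbonate(
        condition.total_co2, _pk("carbonic_k1"), _pk("carbonic_k2"),
        condition.ph, (g_neutral, g_m1, g_m2),
    )
    return {
        "H2O(l)": 1.0,
        "CH4(aq)": g_neutral * condition.ch4,
        "CO2(aq)": a_co2,
        "CH3COOH(aq)": a_hac,
    }


def delta_g(
    reaction: ReactionSpec,
    activities: dict[str, float],
    condition: SolutionCondition | None = None,
) -> float:
    """dGr = dG0r + R*T*ln(Qr), kJ/mol. Water activity defaults to 1."""
    t_k = (condition or SolutionCondition()).t_kelvin
    ln_q = 0.0
    for sp, nu in reaction.stoichiometry.items():
        a = activities.get(sp, 1.0 if sp == "H2O(l)" else None)
        if a is None:
            raise KeyError(f"no activity provided for species {sp!r}")
        if a <= 0.0:
            raise ValueError(f"non-positive activity for {sp!r}")
        ln_q += nu * math.log(a)
    return reaction.delta_g0 + R_GAS * t_k * ln_q


def threshold_activity(
    reaction: ReactionSpec,
    condition: SolutionCondition | None = None,
    free_species: str = "H2(aq)",
    log10_bracket: tuple[float, float] = (-12.0, 0.0),
    tol_kj: float = 0.01,
) -> tuple[float, float]:
    """Activity of ``free_species`` at which dGr crosses zero.

    Bisection on log10 activity over the bracket; returns
    (activity, log10 activity). Raises when dGr does not change sign on the
    bracket (reaction never reaches equilibrium in range).
    """
    condition = condition or SolutionCondition()
    base = baseline_activities(condition)

    def g_of(log_a: float) -> float:
        acts = dict(base)
        acts[free_species] = 10.0**log_a
        return delta_g(reaction, acts, condition)

    lo, hi = log10_bracket
    g_lo, g_hi = g_of(lo), g_of(hi)
    if g_lo * g_hi > 0.0:
        raise ValueError(
            f"dGr of {reaction.name!r} does not change sign for "
            f"log10 a[{free_species}] in [{lo}, {hi}]"
        )
    root = float(brentq(g_of, lo, hi, xtol=1e-10))
    # tighten until the root satisfies the energy tolerance
    if abs(g_of(root)) > tol_kj:
        root = float(brentq(g_of, lo, hi, xtol=1e-14))
    return 10.0**root, root


def energy_landscape(
    reaction: ReactionSpec,
    condition: SolutionCondition | None = None,
    free_species: str = "H2(aq)",
    log10_grid: Iterable[float] = (),
) -> "pd.DataFrame":
    """dGr along a log10-activity sweep of one species.

    Returns a DataFrame with columns ``log10_activity``, ``activity`` and
    ``delta_g_kj``. Species absent from the reaction's stoichiometry yield
    a constant profile.
    """
    import pandas as pd

    condition = condition or SolutionCondition()
    grid = np.asarray(list(log10_grid), dtype=float)
    if grid.size == 0:
        grid = np.arange(-12.0, 0.0 + 1e-9, 0.1)
    if not np.all(np.isfinite(grid)) or np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be finite and strictly increasing")
    base = baseline_activities(condition)
    rows = []
    for log_a in grid:
        acts = dict(base)
        acts[free_species] = 10.0**log_a
        rows.append((log_a, 10.0**log_a, delta_g(reaction, acts, condition)))
    return pd.DataFrame(rows, columns=["log10_activity", "activity", "delta_g_kj"])
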