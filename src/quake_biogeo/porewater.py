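"""Pore-water depth profiles: lithological units, seawater-contamination
quantification via the sulfate tracer, and endmember recovery.

Fragmented cores are exposed to seawater during recovery, so measured
pore-water compositions are linear volumetric mixtures of indigenous fluid
and seawater. In the prism units (U1-U3) indigenous sulfate is taken to be
fully consumed by past microbial sulfate reduction, so the observed sulfate
concentration directly traces the seawater volume fraction
f = SO4_obs / SO4_seawater, and every conservative quantity can be
extrapolated back to zero sulfate. In the underthrust section (U5) the
zero-indigenous-sulfate assumption demonstrably fails; the correction is
masked off there by default and negative extrapolations are reported
as-is with a warning flag because they diagnose exactly that failure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._resources import load_table
from .isotopes import unmix_conservative

ION_SPECIES = ("Cl", "SO4", "K", "Ca", "Mg", "Mn", "NH4")
ISOTOPE_COLUMNS = ("dD_H2O", "d18O_H2O")
DEFAULT_APPLICABLE_UNITS = ("U1", "U2", "U3")


class ContaminationWarning(UserWarning):
    """Sulfate above the seawater reference, or other tracer anomalies."""


@dataclass(frozen=True)
class SeawaterReference:
    """Seawater endmember: ion concentrations (mM) and isotope values (permil)."""

    ions: dict[str, float]
    dD_H2O: float = 0.0
    d18O_H2O: float = 0.0
    d34S_sulfate: float = 21.3
    cap_delta33_sulfate: float = 0.050

    def __post_init__(self) -> None:
        if "SO4" not in self.ions or self.ions["SO4"] <= 0.0:
            raise ValueError("seawater reference needs a positive SO4 entry")
        if any(v < 0.0 for v in self.ions.values()):
            raise ValueError("seawater ion concentrations must be >= 0")

    @classmethod
    def default(cls) -> "SeawaterReference":
        sw = load_table("seawater.tsv").set_index("key")["value"]
        ions = {sp: float(sw[sp]) for sp in ION_SPECIES if sp in sw.index}
        return cls(
            ions=ions,
            dD_H2O=float(sw["dD_H2O"]),
            d18O_H2O=float(sw["d18O_H2O"]),
            d34S_sulfate=float(sw["d34S_sulfate"]),
            cap_delta33_sulfate=float(sw["D33S_sulfate"]),
        )


def _unit_table() -> pd.DataFrame:
    table = load_table("units.tsv").sort_values("top_mbsf").reset_index(drop=True)
    tops = table["top_mbsf"].to_numpy()
    bots = table["bottom_mbsf"].to_numpy()
    if np.any(bots <= tops):
        raise ValueError("unit table has an empty or inverted interval")
    if np.any(tops[1:] < bots[:-1]):
        raise ValueError("unit table intervals overlap")
    return table


def assign_unit(depth_mbsf: float) -> str:
    """Lithological unit containing a depth; 'gap' for uncovered intervals.

    Intervals are half-open [top, bottom) except the deepest, which is
    closed, so shared printed boundaries resolve to the deeper unit.
    """
    if depth_mbsf < 0.0:
        raise ValueError("depth must be >= 0 mbsf")
    table = _unit_table()
    last = len(table) - 1
    for i, row in table.iterrows():
        in_row = (row["top_mbsf"] <= depth_mbsf < row["bottom_mbsf"]) or (
            i == last and depth_mbsf == row["bottom_mbsf"]
        )
        if in_row:
            return str(row["unit"])
    return "gap"


def contamination_fraction(so4_obs: float, ref: SeawaterReference) -> float:
    """Seawater volume fraction from the sulfate tracer: f = SO4_obs/SO4_sw.

    Assumes zero indigenous sulfate. Values above 1 are clipped to 1.0 with
    a :class:`ContaminationWarning` (observed sulfate exceeding seawater is
    inconsistent with the pure-contamination model).
    """
    if so4_obs < 0.0:
        raise ValueError("observed sulfate must be >= 0")
    f = so4_obs / ref.ions["SO4"]
    if f >= 1.0:
        if f > 1.0:
            warnings.warn(
                f"sulfate {so4_obs} mM exceeds the seawater reference "
                f"({ref.ions['SO4']} mM); contamination fraction clipped to 1",
                ContaminationWarning,
            )
        else:
            warnings.warn(
                "sulfate equals the seawater reference: sample is pure "
                "seawater, no indigenous fraction remains",
                ContaminationWarning,
            )
        return 1.0
    return f


def extrapolate_zero_sulfate(
    so4_obs: float, c_obs: float, ref: SeawaterReference, species: str
) -> float:
    """Endmember concentration by extrapolating the sulfate trend to zero.

    The line through (SO4_sw, c_sw) and (SO4_obs, c_obs) evaluated at
    SO4 = 0; algebraically identical to
    ``unmix_conservative(c_obs, so4_obs/SO4_sw, c_sw)``.
    """
    so4_sw = ref.ions["SO4"]
    if so4_obs == so4_sw:
        raise ZeroDivisionError(
            "sample sulfate equals the seawater reference; extrapolation "
            "line is undefined (pure seawater)"
        )
    c_sw = ref.ions[species]
    slope = (c_sw - c_obs) / (so4_sw - so4_obs)
    return c_obs - slope * so4_obs


def correct_profile(
    table: pd.DataFrame,
    ref: SeawaterReference | None = None,
    applicable_units: tuple[str, ...] = DEFAULT_APPLICABLE_UNITS,
) -> pd.DataFrame:
    """Seawater-contamination correction of a pore-water profile table.

    Input columns: ``depth_mbsf``, ion columns (mM, subset of
    Cl/SO4/K/Ca/Mg/Mn/NH4) and optional ``dD_H2O``/``d18O_H2O`` (permil).
    Each row's contamination fraction comes from its sulfate; every ion is
    extrapolated to zero sulfate and water isotopes are unmixed with the
    same fraction. Rows outside ``applicable_units`` (by default U4+, where
    indigenous sulfate is real) pass through uncorrected.

    Returns a copy with added columns ``unit``, ``f_contam``,
    ``correction_applied``, ``negative_corrected`` (assumption-violation
    diagnostic) and ``error`` (per-row degenerate-correction messages;
    collected, never fatal).
    """
    if table.empty:
        raise ValueError("pore-water table is empty")
    if ref is None:
        ref = SeawaterReference.default()
    out = table.copy()
    ions = [c for c in table.columns if c in ION_SPECIES]
    isotopes = [c for c in table.columns if c in ISOTOPE_COLUMNS]
    units, fs, applied, negative, errors = [], [], [], [], []
    for idx, row in table.iterrows():
        unit = assign_unit(float(row["depth_mbsf"]))
        units.append(unit)
        so4 = float(row.get("SO4", np.nan))
        if unit not in applicable_units:
            fs.append(np.nan)
            applied.append(False)
            negative.append(False)
            errors.append("correction not applicable for unit " + unit)
            continue
        if not np.isfinite(so4):
            fs.append(np.nan)
            applied.append(False)
            negative.append(False)
            errors.append("missing sulfate tracer")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ContaminationWarning)
            f = contamination_fraction(so4, ref)
        fs.append(f)
        if f >= 1.0:
            applied.append(False)
            negative.append(False)
            errors.append("pure seawater (f >= 1); no indigenous component")
            continue
        saw_negative = False
        for sp in ions:
            c_obs = float(row[sp])
            if not np.isfinite(c_obs):
                continue
            corrected = extrapolate_zero_sulfate(so4, c_obs, ref, sp)
            if corrected < 0.0:
                saw_negative = True
            out.at[idx, sp] = corrected
        for col in isotopes:
            v = float(row[col])
            if np.isfinite(v):
                sw_val = ref.dD_H2O if col == "dD_H2O" else ref.d18O_H2O
                out.at[idx, col] = unmix_conservative(v, f, sw_val)
        applied.append(True)
        negative.append(saw_negative)
        errors.append("")
        if saw_negative:
            warnings.warn(
                f"negative corrected concentration at depth "
                f"{row['depth_mbsf']} mbsf: zero-indigenous-sulfate "
                "assumption violated",
                ContaminationWarning,
            )
    out["unit"] = units
    out["f_contam"] = fs
    out["correction_applied"] = applied
    out["negative_corrected"] = negative
    out["error"] = errors
    return out
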