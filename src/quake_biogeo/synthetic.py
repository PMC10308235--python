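"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure of the expedition's core
measurements — background-plus-peak H2 depth profiles, two-endmember
Keeling mixtures with an air H2 contaminant, Fe-H2O batch experiments with
temperature-dependent kinetic fractionation and D-spiked water, pore-water
profiles linearly contaminated by seawater, sulfide sulfur-isotope records
from microbial sulfate reduction mixed with juvenile sulfur, and endpoint
dilution-cultivation series — and returns the observable table together
with a hidden-truth sidecar so estimators can be validated.

A single integer seed drives a named substream per generator (SeedSequence
spawn keys), so adding a generator never perturbs existing streams and
identical configs produce byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .h2 import BatchExperiment, keeling_forward
from .isotopes import delta_via_alpha, mix_conservative
from .porewater import ION_SPECIES, SeawaterReference
from .quantify import DilutionSeries
from .sulfur import JUVENILE, MsrFractionation, mix_records, msr_forward, seawater_sulfate

_STREAMS = {
    "gas": 11, "porewater": 12, "keeling": 13,
    "feh2o": 14, "sulfur": 15, "dilution": 16,
}

AIR_H2_PPMV = 0.5          # tropospheric H2 background in sampling vials
AIR_DD_H2 = 150.0          # permil, dD of air H2
H2_QUANT_LIMIT_UM = 3.0    # onboard quantification limit


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------


def gen_gas_profile(
    seed: int = 0,
    peak_centers_mbsf: tuple[float, float] = (695.0, 818.5),
    peak_amplitudes_um: tuple[float, float] = (209.0, 26.0),
    peak_width_m: float = 1.5,
    h2_background_um: float = 0.3,
    source_dd_h2: float = -850.0,
    headspace_ppmv_per_um: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Depth-indexed gas table: H2/CH4 concentrations and isotope values.

    H2 is a low lognormal background overlain by Gaussian-shaped fault-zone
    peaks (plume values replace the background, so the profile maximum
    equals the first peak amplitude exactly at its center). CH4 sits in the
    1-20 mM band in the prism and below 5 mM past the decollement;
    d13C_CH4 drifts from -64 to -84 permil with depth; dD_H2 follows
    two-endmember mixing between sample H2 and the air contaminant.
    """
    rng = _rng(seed, "gas")
    depths = np.unique(np.concatenate([
        np.linspace(176.5, 185.2, 4),
        np.arange(650.0, 837.0, 3.0),
        np.asarray(peak_centers_mbsf, dtype=float),
    ]))
    n = depths.size

    background = h2_background_um * np.exp(rng.normal(0.0, 0.5, n))
    h2 = background.copy()
    for center, amp in zip(peak_centers_mbsf, peak_amplitudes_um):
        peak = amp * np.exp(-((depths - center) ** 2) / (2.0 * peak_width_m**2))
        h2 = np.maximum(h2, peak)

    prism = depths < 821.5
    ch4 = np.where(
        prism,
        np.clip(6.0 * np.exp(rng.normal(0.0, 0.5, n)), 1.0, 20.0),
        rng.uniform(1.0, 5.0, n),
    )
    d13c_ch4 = np.where(
        depths < 754.0, -64.0,
        -64.0 - 20.0 * np.clip((depths - 754.0) / (837.0 - 754.0), 0.0, 1.0),
    ) + rng.normal(0.0, 0.3, n)
    d13c_co2 = d13c_ch4 + 60.0 + rng.normal(0.0, 0.5, n)
    dd_ch4 = -200.0 + rng.normal(0.0, 5.0, n)

    sample_ppmv = h2 * headspace_ppmv_per_um
    total_ppmv = sample_ppmv + AIR_H2_PPMV
    dd_h2 = (AIR_H2_PPMV * AIR_DD_H2 + sample_ppmv * source_dd_h2) / total_ppmv

    table = pd.DataFrame({
        "depth_mbsf": depths,
        "h2_um": h2,
        "h2_below_ql": h2 < H2_QUANT_LIMIT_UM,
        "ch4_mm": ch4,
        "h2_ppmv": total_ppmv,
        "dD_h2_permil": dd_h2,
        "d13C_ch4_permil": d13c_ch4,
        "d13C_co2_permil": d13c_co2,
        "dD_ch4_permil": dd_ch4,
    })
    truth = {
        "peak_centers_mbsf": tuple(peak_centers_mbsf),
        "peak_amplitudes_um": tuple(peak_amplitudes_um),
        "source_dd_h2": source_dd_h2,
        "air_ppmv": AIR_H2_PPMV,
        "air_dd_h2": AIR_DD_H2,
    }
    return table, truth


def default_indigenous_endmember() -> dict[str, float]:
    """Prism (U1-U3) indigenous pore-water endmember: seawater-like ions,
    zero sulfate, elevated ammonium, slightly D-enriched water."""
    return {
        "Cl": 559.0, "SO4": 0.0, "K": 10.5, "Ca": 9.0, "Mg": 50.0,
        "Mn": 0.05, "NH4": 1.5, "dD_H2O": 3.0, "d18O_H2O": 0.2,
    }


def gen_porewater_table(
    seed: int = 0,
    n: int = 12,
    endmember: dict[str, float] | None = None,
    f_max: float = 0.4,
    ref: SeawaterReference | None = None,
    depth_range: tuple[float, float] = (690.0, 820.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pore-water rows as exact convex combinations of an indigenous
    endmember and seawater, with per-row contamination fraction f in
    [0, f_max] (first row forced to f = 0). Truth sidecar carries f and the
    endmember."""
    rng = _rng(seed, "porewater")
    if endmember is None:
        endmember = default_indigenous_endmember()
    if ref is None:
        ref = SeawaterReference.default()
    depths = np.sort(rng.uniform(*depth_range, n))
    f = rng.uniform(0.0, f_max, n)
    f[0] = 0.0
    sw = dict(ref.ions, dD_H2O=ref.dD_H2O, d18O_H2O=ref.d18O_H2O)
    cols: dict[str, np.ndarray] = {"depth_mbsf": depths}
    for key in list(ION_SPECIES) + ["dD_H2O", "d18O_H2O"]:
        cols[key] = np.array([
            mix_conservative(endmember[key], fi, sw[key]) for fi in f
        ])
    table = pd.DataFrame(cols)
    truth = pd.DataFrame({"depth_mbsf": depths, "f_contam": f})
    for key, v in endmember.items():
        truth["endmember_" + key] = v
    return table, truth


def gen_keeling_dataset(
    seed: int = 0,
    n: int = 12,
    source_delta: float = -850.0,
    background_ppmv: float = AIR_H2_PPMV,
    background_delta: float = AIR_DD_H2,
    added_ppmv: Sequence[float] | None = None,
    noise_sd: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Keeling mixture samples: air background plus variable source H2,
    with Gaussian measurement noise on dD_H2."""
    rng = _rng(seed, "keeling")
    if added_ppmv is None:
        added_ppmv = np.geomspace(0.3, 60.0, n)
    samples = keeling_forward(background_ppmv, background_delta,
                              added_ppmv, source_delta)
    noise = rng.normal(0.0, noise_sd, len(samples)) if noise_sd > 0 else 0.0
    table = pd.DataFrame({
        "h2_ppmv": [s.mixing_ratio for s in samples],
        "dD_h2_permil": np.array([s.delta_d_h2 for s in samples]) + noise,
    })
    truth = {
        "source_delta": source_delta,
        "background_ppmv": background_ppmv,
        "background_delta": background_delta,
    }
    return table, truth


DEFAULT_FE_H2O_ALPHAS = {4.0: 0.13, 25.0: 0.19, 55.0: 0.23}


def gen_fe_h2o_batches(
    seed: int = 0,
    alphas_by_t: dict[float, float] | None = None,
    n_levels: int = 8,
    dd_h2o_max: float = 3000.0,
    noise_sd: float = 10.0,
) -> tuple[list[BatchExperiment], dict[float, float]]:
    """Fe-H2O anaerobic-corrosion batches with D-spiked water.

    Water dD levels span 0 to ``dd_h2o_max`` (~+3000 permil); generated H2
    follows the temperature-specific kinetic alpha with Gaussian noise on
    dD_H2.
    """
    rng = _rng(seed, "feh2o")
    alphas = dict(alphas_by_t) if alphas_by_t else dict(DEFAULT_FE_H2O_ALPHAS)
    batches = []
    for t_c in sorted(alphas):
        alpha = alphas[t_c]
        levels = np.linspace(0.0, dd_h2o_max, n_levels)
        dd_h2 = np.array([delta_via_alpha(level, alpha) for level in levels])
        if noise_sd > 0:
            dd_h2 = dd_h2 + rng.normal(0.0, noise_sd, n_levels)
        batches.append(BatchExperiment(
            t_celsius=t_c,
            pairs=tuple(zip(levels.tolist(), dd_h2.tolist())),
            label=f"Fe-H2O {t_c:g}C",
        ))
    return batches, alphas


def gen_sulfur_records(
    seed: int = 0,
    n: int = 20,
    eps34_range: tuple[float, float] = (10.0, 68.0),
    lambda33_mean: float = 0.514,
    juvenile_fraction_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sulfide (CRS-like) records: microbial sulfate reduction of seawater
    sulfate mixed with juvenile sulfur at per-row fractions."""
    rng = _rng(seed, "sulfur")
    sulfate = seawater_sulfate()
    eps = rng.uniform(*eps34_range, n)
    f_juv = rng.uniform(*juvenile_fraction_range, n)
    rows, truth_rows = [], []
    for i in range(n):
        biogenic = msr_forward(sulfate, MsrFractionation(eps[i], lambda33_mean))
        mixed = mix_records(biogenic, JUVENILE, f_juv[i])
        rows.append({
            "sample_id": f"syn{i:02d}",
            "d33S_permil": mixed.delta33,
            "d34S_permil": mixed.delta34,
            "role": "sulfide_CRS",
        })
        truth_rows.append({
            "sample_id": f"syn{i:02d}", "eps34": eps[i],
            "lambda33": lambda33_mean, "f_juvenile": f_juv[i],
        })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_dilution_series(
    seed: int = 0,
    true_densities: Sequence[float] = (1.0e3, 1.0e5),
    n_steps: int = 8,
    step_factor: float = 11.0,
    v_inoculum_ml: float = 0.5,
    slurry_dilution: float = 10.0,
) -> tuple[list[DilutionSeries], list[float]]:
    """Endpoint dilution series with Poisson presence/absence per step.

    The expected organisms in the step-k inoculum is the true density times
    the effective inoculum volume 1/density_formula(k), the volume implied
    by the endpoint estimator's own convention, so noise-free recovery is
    within one step factor.
    """
    rng = _rng(seed, "dilution")
    series = []
    for density in true_densities:
        if density < 0.0:
            raise ValueError("true density must be >= 0")
        positives = []
        for k in range(1, n_steps + 1):
            lam = density * v_inoculum_ml / (step_factor**k * slurry_dilution)
            positives.append(bool(rng.poisson(lam) > 0))
        series.append(DilutionSeries(
            positives=tuple(positives),
            step_factor=step_factor,
            v_inoculum_ml=v_inoculum_ml,
            slurry_dilution=slurry_dilution,
            label=f"density={density:g}",
        ))
    return series, list(true_densities)
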