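"""End-to-end orchestration: simulate (or load) inputs, run every analysis
stage, and write per-stage TSVs plus a run manifest.

The manifest records inputs, the seed, and sha256 hashes of the shipped
constant tables, so equal manifests imply byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._resources import data_file_hashes
from .energetics import (
    SolutionCondition,
    energy_landscape,
    shipped_reactions,
    threshold_activity,
)
from .h2 import BatchExperiment, KeelingSample, fit_alpha_origin, keeling_fit
from .io import write_table
from .porewater import SeawaterReference, correct_profile
from .sulfur import cap_delta33, epsilon34, lambda33, seawater_sulfate
from .synthetic import (
    gen_fe_h2o_batches,
    gen_gas_profile,
    gen_keeling_dataset,
    gen_porewater_table,
    gen_sulfur_records,
)

logger = logging.getLogger("quake_biogeo")
if not logger.handlers:  # stage-scoped logging to stderr; results never there
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
    logger.addHandler(handler)


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; unknown keys are rejected at load time."""

    out_dir: str = "quake_biogeo_run"
    seed: int = 0
    applicable_units: tuple[str, ...] = ("U1", "U2", "U3")
    acetate_mm: float = 1.0
    landscape_log10_min: float = -12.0
    landscape_log10_max: float = 0.0
    landscape_log10_step: float = 0.1
    verbosity: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(
                "unknown configuration key(s): " + ", ".join(sorted(unknown))
            )
        if "applicable_units" in mapping:
            mapping = dict(mapping, applicable_units=tuple(mapping["applicable_units"]))
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate inputs and execute all analysis stages.

    Stages: pore-water correction -> CH4 isotope systematics -> Keeling and
    Fe-H2O alpha fitting -> sulfur statistics -> energetics landscapes.
    Writes one TSV per stage plus manifest.json; returns the manifest.
    """
    logger.setLevel(config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    outputs: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = write_table(df, out / name)
        outputs[name.removesuffix(".tsv")] = str(path)
        logger.info("wrote %s (%d rows)", path, len(df))

    # stage 1: pore-water correction
    pw_table, pw_truth = gen_porewater_table(seed)
    corrected = correct_profile(pw_table, applicable_units=config.applicable_units)
    save("porewater_corrected.tsv", corrected)

    # stage 2: gas profile and CH4 systematics
    gas, _ = gen_gas_profile(seed)
    gas = gas.assign(
        alpha13C_ch4_co2=(1000.0 + gas["d13C_ch4_permil"])
        / (1000.0 + gas["d13C_co2_permil"]),
        alphaD_ch4_h2o=(1000.0 + gas["dD_ch4_permil"]) / 1000.0,
    )
    save("gas_systematics.tsv", gas)

    # stage 3: Keeling endmember
    keeling_table, keeling_truth = gen_keeling_dataset(seed)
    samples = [
        KeelingSample(r.h2_ppmv, r.dD_h2_permil)
        for r in keeling_table.itertuples()
    ]
    fit = keeling_fit(samples)
    save("keeling_fit.tsv", pd.DataFrame([{
        "intercept_dD_permil": fit.intercept_delta,
        "slope_permil_ppmv": fit.slope,
        "stderr_intercept": fit.stderr_intercept,
        "r2": fit.r2,
        "n": fit.n,
        "true_source_dD": keeling_truth["source_delta"],
    }]))

    # stage 4: Fe-H2O kinetic alpha per temperature
    batches, alpha_truth = gen_fe_h2o_batches(seed)
    save("fe_h2o_alpha.tsv", pd.DataFrame([
        {
            "T_C": b.t_celsius,
            "alpha_fit": fit_alpha_origin(b).alpha,
            "alpha_truth": alpha_truth[b.t_celsius],
            "n_pairs": len(b.pairs),
        }
        for b in batches
    ]))

    # stage 5: sulfur statistics
    sulfur_table, _ = gen_sulfur_records(seed)
    sulfate = seawater_sulfate()
    sulfur_table = sulfur_table.assign(
        D33S_permil=[
            cap_delta33(r.d33S_permil, r.d34S_permil)
            for r in sulfur_table.itertuples()
        ],
        eps34_vs_seawater=[
            epsilon34(r.d34S_permil, sulfate.delta34)
            for r in sulfur_table.itertuples()
        ],
        lambda33_vs_seawater=[
            lambda33(r.d33S_permil, r.d34S_permil, sulfate.delta33, sulfate.delta34)
            for r in sulfur_table.itertuples()
        ],
    )
    save("sulfur_systematics.tsv", sulfur_table)

    # stage 6: energetics landscapes and thresholds
    condition = SolutionCondition(total_acetate=config.acetate_mm * 1e-3)
    grid = np.arange(
        config.landscape_log10_min,
        config.landscape_log10_max + 1e-9,
        config.landscape_log10_step,
    )
    reactions = shipped_reactions()
    frames = []
    for name in ("hydrogenotrophic_methanogenesis", "homoacetogenesis",
                 "acetoclastic_methanogenesis"):
        frame = energy_landscape(reactions[name], condition, log10_grid=grid)
        frame.insert(0, "reaction", name)
        frames.append(frame)
    save("energy_landscapes.tsv", pd.concat(frames, ignore_index=True))
    thresholds = []
    for name in ("hydrogenotrophic_methanogenesis", "homoacetogenesis"):
        a, log_a = threshold_activity(reactions[name], condition)
        thresholds.append({"reaction": name, "a_h2": a, "log10_a_h2": log_a})
    save("h2_thresholds.tsv", pd.DataFrame(thresholds))

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "constants_sha256": data_file_hashes(),
        "outputs": outputs,
        "n_stages": 6,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
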