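"""Population-density estimation: endpoint serial-dilution cultivation and
filter-microscopy cell counts.

The serial-dilution estimator uses the documented endpoint convention: a
slurry (``slurry_dilution`` mL slurry per mL sediment equivalent) is
inoculated and serially transferred with per-step dilution factor
``step_factor``; the estimated density is

    density = (1 / v_inoculum_ml) * step_factor**k * slurry_dilution

with k the highest positive step (1-based). This is an endpoint
(highest-positive-dilution) estimate, not a multi-replicate MPN
likelihood — single tubes per dilution step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field


class NonMonotoneSeriesWarning(UserWarning):
    """A negative tube below a positive one in a dilution series."""


@dataclass(frozen=True)
class DilutionSeries:
    """Endpoint dilution-to-extinction series for one sample."""

    positives: tuple[bool, ...]
    step_factor: float = 11.0       # 0.5 mL transferred into 5.0 mL
    v_inoculum_ml: float = 0.5
    slurry_dilution: float = 10.0   # 0.5 g sediment (~0.5 mL) in 5 mL
    label: str = ""

    def __post_init__(self) -> None:
        if self.step_factor <= 1.0:
            raise ValueError("step factor must exceed 1")
        if self.v_inoculum_ml <= 0.0 or self.slurry_dilution <= 0.0:
            raise ValueError("inoculum volume and slurry dilution must be positive")


@dataclass(frozen=True)
class DilutionEstimate:
    density: float              # cells per mL sediment (detection limit if below)
    below_detection: bool
    highest_positive_step: int  # 0 when all negative


@dataclass(frozen=True)
class CountRecord:
    """Epifluorescence filter-count geometry for one sample."""

    mean_count_per_field: float
    n_fields: int
    field_area_mm2: float
    filtration_area_mm2: float
    volume_filtered_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("need at least one counted field")
        if min(self.field_area_mm2, self.filtration_area_mm2,
               self.volume_filtered_ml, self.dilution_factor) <= 0.0:
            raise ValueError("areas, volume and dilution factor must be positive")
        if self.mean_count_per_field < 0.0:
            raise ValueError("mean count must be >= 0")


def _density_at_step(series: DilutionSeries, k: int) -> float:
    return (1.0 / series.v_inoculum_ml) * series.step_factor**k * series.slurry_dilution


def endpoint_dilution_density(series: DilutionSeries) -> DilutionEstimate:
    """Cultivable density (cells/mL sediment) from an endpoint series.

    All-negative series return a below-detection marker carrying the
    detection limit (the density formula at k = 0). Non-monotone positivity
    (a skip followed by a positive) warns and uses the highest positive.
    """
    positives = series.positives
    if not any(positives):
        return DilutionEstimate(_density_at_step(series, 0), True, 0)
    k = max(i + 1 for i, p in enumerate(positives) if p)
    if not all(positives[: k]):
        warnings.warn(
            f"non-monotone positivity pattern {positives}; using the highest "
            f"positive step ({k})",
            NonMonotoneSeriesWarning,
        )
    return DilutionEstimate(_density_at_step(series, k), False, k)


def cell_density_from_counts(rec: CountRecord) -> float:
    """Total cell density (cells/mL) from filter microscopy.

    density = mean_count * (filtration_area / field_area) / volume * dilution.
    Counts averaged over fewer than 100 fields warn (convention for a
    stable mean at low densities).
    """
    if rec.n_fields < 100:
        warnings.warn(
            f"mean from only {rec.n_fields} fields (< 100); estimate may be noisy",
            UserWarning,
        )
    return (
        rec.mean_count_per_field
        * (rec.filtration_area_mm2 / rec.field_area_mm2)
        / rec.volume_filtered_ml
        * rec.dilution_factor
    )
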