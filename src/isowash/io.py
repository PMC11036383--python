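"""Result serialization: series/wash-curve CSVs and JSON summaries.

Interface units follow the lab tables (s, mL, g, mbar); internal SI
quantities are converted here at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidSeriesError
from .filtration import CakeState, DarcyFit, FiltrationResult
from .units import kg_to_g, m3_to_ml
from .washing import WashResult

SERIES_COLUMNS = ("time_s", "filtrate_volume_ml")


def read_series_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an experimental filtrate series (time_s, filtrate_volume_ml).

    Returns times in seconds and volumes in m3.
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidSeriesError(
            f"series CSV {path} lacks required columns {missing}; "
            f"expected header {','.join(SERIES_COLUMNS)}"
        )
    return (
        df["time_s"].to_numpy(dtype=float),
        df["filtrate_volume_ml"].to_numpy(dtype=float) * 1e-6,
    )


def write_series_csv(result: FiltrationResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_wash_curve_csv(result: WashResult, path) -> None:
    curve = result.curve
    if curve is None:
        raise InvalidSeriesError("wash result carries no curve")
    data = {"wash_ratio": curve.wash_ratios}
    for name, ratio in curve.exit_concentration_ratio.items():
        data[f"c_over_c0_{name}"] = ratio
    pd.DataFrame(data).to_csv(path, index=False)


def cake_record(cake: CakeState) -> dict[str, Any]:
    return {
        "solid_mass_g": kg_to_g(cake.solid_mass),
        "porosity": cake.porosity,
        "height_mm": cake.height * 1e3,
        "bulk_volume_ml": m3_to_ml(cake.bulk_volume),
        "void_volume_ml": m3_to_ml(cake.void_volume),
        "liquor_mass_g": kg_to_g(cake.liquor_mass),
        "liquor_volume_ml": m3_to_ml(cake.liquor_volume),
        "saturation": cake.saturation,
        "liquor_mass_fractions": dict(cake.liquor.mass_fractions),
    }


def filtration_record(result: FiltrationResult) -> dict[str, Any]:
    rec = {
        "scenario": result.scenario_name,
        "stopped_at": result.stopped_at,
        "filtration_time_s": float(result.times[-1]),
        "filtrate_volume_ml": m3_to_ml(float(result.filtrate_volumes[-1])),
        "filtrate_mass_g": kg_to_g(result.filtrate_mass),
        "alpha_m_per_kg": result.alpha_used,
        "medium_resistance_per_m": result.medium_resistance,
        "viscosity_pa_s": result.viscosity,
        "filtrate_density_kg_m3": result.filtrate_density,
    }
    if result.end_state is not None:
        rec["cake"] = cake_record(result.end_state)
    return rec


def wash_record(result: WashResult) -> dict[str, Any]:
    return {
        "stages": [
            {
                "mechanism": rec.mechanism,
                "wash_volume_ml": m3_to_ml(rec.wash_volume),
                "wash_ratio": rec.wash_ratio,
                "filtrate_mass_g": kg_to_g(rec.filtrate_mass),
                "filtrate_mass_fractions": (
                    dict(rec.filtrate_composition.mass_fractions)
                    if rec.filtrate_composition is not None
                    else None
                ),
                "species_removed_g": {
                    k: kg_to_g(v) for k, v in rec.species_removed.items()
                },
            }
            for rec in result.per_stage
        ],
        "final_cake": cake_record(result.final_cake),
    }


def darcy_record(fit: DarcyFit) -> dict[str, Any]:
    return {
        "alpha_m_per_kg": fit.alpha,
        "medium_resistance_per_m": fit.medium_resistance,
        "slope_s_per_m6": fit.slope,
        "intercept_s_per_m3": fit.intercept,
        "warnings": fit.warnings(),
    }


def write_json(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
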