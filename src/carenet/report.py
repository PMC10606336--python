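"""Tabular report layer: rounded, publication-style tables.

Internal computation is always full precision; this module owns the
presentation rounding — rates to one decimal, utilization to a whole
percent, entropies to two decimals.
"""

from __future__ import annotations

import pandas as pd

from .network import CareNetwork, effective_arrival_rates, utilization
from .simulate import SimulationResult

__all__ = ["utilization_table", "simulation_summary_table", "entropy_long_table"]


def utilization_table(network: CareNetwork) -> pd.DataFrame:
    """Per-unit capacity/demand/utilization table.

    One row per unit: staffed beds ``c``, external and effective arrival
    rates (1 decimal), service rate, and utilization as a whole percent.
    """
    eff = effective_arrival_rates(network)
    rows = []
    for u in network.units:
        rows.append(
            {
                "unit": u.id,
                "name": u.name,
                "c": u.staffed_beds,
                "external_rate": round(u.external_arrival_rate, 1),
                "eff_rate": round(eff[u.id], 1),
                "mu": u.service_rate,
                "utilization_pct": round(100 * utilization(eff[u.id], u)),
            }
        )
    return pd.DataFrame(rows).set_index("unit")


def simulation_summary_table(results: dict[str, SimulationResult]) -> pd.DataFrame:
    """Mismatch aggregates per named design (model -> simulation result).

    Over- and under-utilization are reported as labelled magnitudes: the
    ``mean_overutilized_beds`` column is the average number of beds the
    system is *short* on a day (some conventions print it with a negative
    sign; here the direction is carried by the column name).
    """
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "model": name,
                "mean_overutilized_beds": round(res.mean_over, 1),
                "sd_overutilized_beds": round(res.sd_over, 1),
                "mean_underutilized_beds": round(res.mean_under, 1),
                "sd_underutilized_beds": round(res.sd_under, 1),
                "days_overutilized": res.days_overutilized,
            }
        )
    return pd.DataFrame(rows).set_index("model")


def entropy_long_table(comparison_table: pd.DataFrame) -> pd.DataFrame:
    """Tidy long format of a comparison table: one measure per row."""
    value_cols = [
        "days_overutilized",
        "mean_over",
        "mean_under",
        "arrival_bits",
        "arrival_max_bits",
        "positional_bits",
        "positional_max_bits",
        "decision_bits",
        "total_bits",
    ]
    return comparison_table.melt(
        id_vars=["model", "strategy", "aggregated"],
        value_vars=value_cols,
        var_name="measure",
        value_name="value",
    )
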