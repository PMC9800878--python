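"""Quantification formulas for the validation assays.

Small, exact arithmetic used when scoring wet-lab readouts: Oil red O
absorbance normalized to cell number, percent change of a treated group
against vehicle, and relative qPCR expression via 2^-dCt.  Group
summaries report mean +/- SEM over replicate wells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_absorbance",
    "percent_change",
    "relative_expression",
    "summarize_wells",
]


def normalize_absorbance(raw_absorbance, cell_count):
    """Raw absorbance (OD 490 nm) divided by cell number.

    Accepts scalars or aligned arrays; cell counts must be positive (a
    count of zero makes the normalization undefined).
    """
    raw = np.asarray(raw_absorbance, dtype=float)
    count = np.asarray(cell_count, dtype=float)
    if np.any(raw < 0):
        raise ValueError("absorbance must be non-negative")
    if np.any(count <= 0):
        raise ValueError("cell count must be positive")
    out = raw / count
    return float(out) if out.ndim == 0 else out


def percent_change(treated_mean: float, vehicle_mean: float) -> float:
    """Percent decrease of the treated mean versus vehicle.

    100 * (vehicle - treated) / vehicle; a negative result means the
    treated group increased.
    """
    if vehicle_mean <= 0:
        raise ValueError("vehicle mean must be positive")
    return 100.0 * (vehicle_mean - treated_mean) / vehicle_mean


def relative_expression(ct_gene, ct_housekeeping):
    """Relative qPCR expression: 2^-(Ct_gene - Ct_housekeeping)."""
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_hk = np.asarray(ct_housekeeping, dtype=float)
    if not (np.all(np.isfinite(ct_gene)) and np.all(np.isfinite(ct_hk))):
        raise ValueError("Ct values must be finite")
    out = 2.0 ** -(ct_gene - ct_hk)
    return float(out) if out.ndim == 0 else out


def summarize_wells(
    wells: pd.DataFrame, vehicle: str, group_column: str = "group"
) -> pd.DataFrame:
    """Per-group mean +/- SEM of normalized absorbance plus percent change.

    ``wells`` needs columns ``absorbance``, ``cell_count`` and the group
    label; the vehicle group anchors the percent-change column.
    """
    wells = wells.copy()
    wells["normalized"] = normalize_absorbance(
        wells["absorbance"], wells["cell_count"]
    )
    grouped = wells.groupby(group_column)["normalized"]
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.sem(),
            "n": grouped.size(),
        }
    )
    if vehicle not in out.index:
        raise ValueError(f"vehicle group {vehicle!r} not present")
    vehicle_mean = out.loc[vehicle, "mean"]
    out["pct_change_vs_vehicle"] = [
        percent_change(m, vehicle_mean) for m in out["mean"]
    ]
    return out.reset_index()
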