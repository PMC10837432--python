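"""Symbiodiniaceae cell-density estimation.

Cells are counted in a dilute subsample of the fixed algal homogenate and
scaled back up the dilution chain to the whole fragment, then normalised
to fragment surface area:

    cells/ml       = counted_cells / counted_volume_ml * dilution_factor
    cells/fragment = cells/ml * homogenate_volume_ml
    cells/cm^2     = cells/fragment / surface_area_cm2

The chain is a pure scaling: any fixation dilution (e.g. a 1:1 PFA step)
is folded into ``dilution_factor`` by the data loader, never hard-coded
here.  Surface areas come in as numbers; the two measurement methods
(ImageJ planimetry vs aluminium foil) are compared for consensus but the
pipeline consumes the ImageJ values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CellCountRecord",
    "DensityEstimate",
    "estimate_density",
    "estimate_densities",
    "compare_sa_methods",
]


@dataclass(frozen=True)
class CellCountRecord:
    fragment_id: str
    counted_cells: int
    counted_volume_ml: float
    dilution_factor: float
    homogenate_volume_ml: float
    surface_area_cm2: float
    sa_method: str = "imagej"

    def __post_init__(self) -> None:
        if self.counted_cells < 0 or self.counted_cells != int(self.counted_cells):
            raise ValueError("counted_cells must be a non-negative integer")
        for name in ("counted_volume_ml", "homogenate_volume_ml", "surface_area_cm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.sa_method not in ("imagej", "foil"):
            raise ValueError("sa_method must be 'imagej' or 'foil'")


@dataclass(frozen=True)
class DensityEstimate:
    fragment_id: str
    cells_per_ml: float
    cells_per_fragment: float
    cells_per_cm2: float


def estimate_density(rec: CellCountRecord) -> DensityEstimate:
    """Scale a chamber count up the dilution chain to cells per cm^2."""
    cells_per_ml = rec.counted_cells / rec.counted_volume_ml * rec.dilution_factor
    cells_per_fragment = cells_per_ml * rec.homogenate_volume_ml
    return DensityEstimate(
        fragment_id=rec.fragment_id,
        cells_per_ml=cells_per_ml,
        cells_per_fragment=cells_per_fragment,
        cells_per_cm2=cells_per_fragment / rec.surface_area_cm2,
    )


def estimate_densities(records: pd.DataFrame) -> pd.DataFrame:
    """Vector version over a table with the CellCountRecord columns."""
    out = []
    for row in records.itertuples(index=False):
        rec = CellCountRecord(
            fragment_id=str(row.fragment_id),
            counted_cells=int(row.counted_cells),
            counted_volume_ml=float(row.counted_volume_ml),
            dilution_factor=float(row.dilution_factor),
            homogenate_volume_ml=float(row.homogenate_volume_ml),
            surface_area_cm2=float(row.surface_area_cm2),
            sa_method=str(getattr(row, "sa_method", "imagej")),
        )
        est = estimate_density(rec)
        out.append(est.__dict__)
    return pd.DataFrame(out)


def compare_sa_methods(paired: pd.DataFrame) -> dict:
    """Agreement summary between ImageJ and foil surface areas.

    ``paired`` needs columns ``fragment_id``, ``area_imagej_cm2`` and
    ``area_foil_cm2``.  Rows with a missing member of the pair are dropped
    with a warning.  Returns per-fragment imagej/foil ratios, their mean,
    and the Spearman rank correlation across fragments.  Report only — the
    pipeline itself uses the ImageJ areas.
    """
    cols = ["fragment_id", "area_imagej_cm2", "area_foil_cm2"]
    missing = [c for c in cols if c not in paired.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = paired[cols].copy()
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        warnings.warn(f"{n_dropped} unpaired fragment(s) excluded from the "
                      "surface-area comparison", stacklevel=2)
    if len(complete) < 2:
        raise ValueError("need >= 2 paired fragments")
    if (complete[["area_imagej_cm2", "area_foil_cm2"]] <= 0).any().any():
        raise ValueError("surface areas must be > 0")
    ratio = complete["area_imagej_cm2"] / complete["area_foil_cm2"]
    if complete["area_imagej_cm2"].nunique() == 1 or complete["area_foil_cm2"].nunique() == 1:
        rho = float("nan")  # rank correlation undefined for a constant side
    else:
        rho = float(sps.spearmanr(complete["area_imagej_cm2"],
                                  complete["area_foil_cm2"]).statistic)
    return {
        "n_pairs": int(len(complete)),
        "n_excluded": int(n_dropped),
        "per_fragment_ratio": pd.Series(ratio.to_numpy(),
                                        index=complete["fragment_id"].to_numpy()),
        "mean_ratio": float(ratio.mean()),
        "spearman_rho": rho,
    }
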