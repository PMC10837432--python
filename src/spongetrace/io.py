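"""Readers and writers for the pipeline's tabular interfaces.

All tables are plain CSV.  Deposited datasets arrive with arbitrary
column headers, so every reader takes a ``column_map`` of
canonical-name -> file-header; the mapping is configuration, never a
code change.  Row-level validation failures are collected and reported
with their file line numbers rather than aborting the whole load.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping, Optional

import pandas as pd

from .experiment import SAMPLE_COLUMNS, validate_samples

log = logging.getLogger("spongetrace")

CELL_COUNT_COLUMNS = [
    "fragment_id", "counted_cells", "counted_volume_ml", "dilution_factor",
    "homogenate_volume_ml", "surface_area_cm2", "sa_method",
]


def _remap(df: pd.DataFrame, canonical, column_map: Optional[Mapping[str, str]],
           optional=()) -> pd.DataFrame:
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in canonical if c not in df.columns and c not in optional]
    if missing:
        raise ValueError(
            f"input is missing columns {missing}; present: {list(df.columns)}. "
            "Provide a column_map of canonical -> file header.")
    return df


def read_samples(path, column_map: Optional[Mapping[str, str]] = None):
    """Load and validate a bulk-sample CSV.

    Returns ``(samples, rejects)``.  ``rejects`` lists each invalid row
    with its reason and 1-based file line number (header = line 1).
    """
    raw = pd.read_csv(path)
    raw = _remap(raw, SAMPLE_COLUMNS, column_map)
    clean, rejects = validate_samples(raw)
    if len(rejects):
        rejects = rejects.copy()
        rejects["line"] = rejects["row"] + 2
        for r in rejects.itertuples(index=False):
            log.warning("rejected %s line %d (%s): %s",
                        os.path.basename(str(path)), r.line, r.sample_id, r.reason)
    log.info("read %d samples from %s (%d rejected)",
             len(clean), path, len(rejects))
    return clean, rejects


def read_cell_counts(path, column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Load a fragment cell-count / surface-area CSV.

    ``sa_method`` defaults to 'imagej' when absent.
    """
    raw = pd.read_csv(path)
    raw = _remap(raw, CELL_COUNT_COLUMNS, column_map, optional=("sa_method",))
    if "sa_method" not in raw.columns:
        raw["sa_method"] = "imagej"
    log.info("read %d cell-count records from %s", len(raw), path)
    return raw[CELL_COUNT_COLUMNS]


def write_table(df: pd.DataFrame, path) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
    log.info("wrote %d rows to %s", len(df), path)
    return str(path)


def write_report(report: dict, path) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return str(path)
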