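"""Reading and writing cohort tables (CSV) with validation.

Column dictionary
-----------------
``pregnancies.csv``: pregnancy_id, female_id, group_id, season, status
(dominant/subordinate), treatment (fed/unfed/none), litter_size,
maternal_age (days), body_condition (g), group_size, n_concurrent, ndvi,
temperature (°C), conception_day, birth_day, gestation_length (days; empty
unless the start was observed), plus optional ``true_*`` ground-truth columns
from the simulator.

``weighings.csv``: pregnancy_id, day (gestation day, 0 = conception or
oestrus), mass_g (grams).

``pups.csv``: pup_id, pregnancy_id, emergence_mass_g (g), emergence_age_d
(days), telomere_ts (relative T/S ratio, optional), survived_90d,
survived_1y (0/1).
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("gwgrowth")

MANDATORY = {
    "pregnancies": ("pregnancy_id", "female_id", "litter_size", "status"),
    "weighings": ("pregnancy_id", "day", "mass_g"),
    "pups": ("pup_id", "pregnancy_id", "emergence_mass_g", "emergence_age_d"),
}

_NUMERIC = {
    "weighings": ("day", "mass_g"),
    "pregnancies": ("litter_size",),
    "pups": ("emergence_mass_g", "emergence_age_d"),
}


@dataclass
class ReadReport:
    """Row-level problems found while reading; line numbers are 1-based file
    lines including the header."""

    rejected: dict = field(default_factory=dict)  # table -> list of line numbers

    @property
    def n_rejected(self) -> int:
        return sum(len(v) for v in self.rejected.values())


def _read_table(path, kind: str, report: ReadReport) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in MANDATORY[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    bad_rows = pd.Series(False, index=df.index)
    for col in _NUMERIC[kind]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_rows |= bad
        df[col] = coerced
    if bad_rows.any():
        lines = [int(i) + 2 for i in df.index[bad_rows]]  # +2: header + 0-base
        report.rejected[kind] = lines
        log.warning("%s: rejected %d unparseable row(s) at line(s) %s",
                    path, len(lines), lines[:10])
        df = df[~bad_rows].reset_index(drop=True)
    # coerce the remaining numeric-looking columns quietly
    for col in df.columns:
        if col in MANDATORY[kind] and col.endswith("_id"):
            continue
        if df[col].dtype == object and col not in ("status", "treatment", "season",
                                                   "female_id", "group_id", "pup_id",
                                                   "pregnancy_id"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    return df


def _validate_units(weighings: pd.DataFrame) -> None:
    if (weighings["mass_g"] < 50).any() or (weighings["mass_g"] > 5000).any():
        log.warning("weighings contain masses outside 50–5000 g; check units (grams expected)")
    if (weighings["day"] < 0).any():
        raise ValueError("weighings contain negative gestation days")


def read_cohort(
    pregnancies_path,
    weighings_path,
    pups_path=None,
) -> tuple:
    """Read (pregnancies, weighings, pups_or_None, report) from CSV files.

    Unparseable rows are dropped and reported with their file line numbers;
    an empty weighing table is an error.
    """
    report = ReadReport()
    pregnancies = _read_table(pregnancies_path, "pregnancies", report)
    weighings = _read_table(weighings_path, "weighings", report)
    if len(weighings) == 0:
        raise ValueError(f"{weighings_path}: empty cohort (no weighing records)")
    _validate_units(weighings)
    pups = _read_table(pups_path, "pups", report) if pups_path else None
    return pregnancies, weighings, pups, report


def write_cohort(pregnancies, weighings, pups, directory, seed=None) -> dict:
    """Write the three cohort tables plus a small metadata file; returns the
    mapping of table name to written path."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("pregnancies", pregnancies), ("weighings", weighings),
                     ("pups", pups)):
        if df is None:
            continue
        p = directory / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    meta = {"seed": seed, "tables": {k: str(v) for k, v in paths.items()}}
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    paths["metadata"] = str(directory / "metadata.json")
    return paths
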