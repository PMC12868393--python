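"""Inclusion rules and descriptive statistics for pregnancy weighing cohorts.

The inclusion rule keeps only pregnancies with dense enough coverage to
resolve the biphasic curve: at least four weighings in each 25-day trimester
of the assumed 75-day gestation.  Trimester bins are half-open —
[0, 25), [25, 50), [50, 75] — with day-75 records counted in the third
trimester (the boundary convention is pinned here; either choice is defensible
and this one never discards a final-day weighing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of a filtered weighing cohort."""

    n_pregnancies: int
    n_females: int
    n_weighings: int
    mean_weighings_per_pregnancy: float
    mean_interval_hours: float
    pct_dominant: float
    mean_pregnancies_per_female: float
    litter_mean_by_status: dict
    litter_sd_by_status: dict

    def to_dict(self) -> dict:
        return {
            "n_pregnancies": self.n_pregnancies,
            "n_females": self.n_females,
            "n_weighings": self.n_weighings,
            "mean_weighings_per_pregnancy": self.mean_weighings_per_pregnancy,
            "mean_interval_hours": self.mean_interval_hours,
            "pct_dominant": self.pct_dominant,
            "mean_pregnancies_per_female": self.mean_pregnancies_per_female,
            "litter_mean_by_status": self.litter_mean_by_status,
            "litter_sd_by_status": self.litter_sd_by_status,
        }


def trimester_filter(
    weighings: pd.DataFrame,
    pregnancies: pd.DataFrame,
    min_per_trimester: int = 4,
    trimester_days: float = 25.0,
) -> pd.DataFrame:
    """Return the pregnancies with >= ``min_per_trimester`` weighings in every
    trimester.  Idempotent and invariant to row order."""
    horizon = 3 * trimester_days
    days = weighings["day"].to_numpy(float)
    if np.any(days < 0) or np.any(days > horizon):
        raise ValueError(f"weighing days must lie in [0, {horizon:g}]")
    unknown = set(weighings["pregnancy_id"]) - set(pregnancies["pregnancy_id"])
    if unknown:
        raise ValueError(
            f"weighings reference unknown pregnancies: {sorted(unknown)[:5]}"
        )
    # bins [0, T), [T, 2T), [2T, 3T]; the final day belongs to the last bin
    tri = np.minimum((days // trimester_days).astype(int), 2)
    counts = (
        pd.DataFrame({"pregnancy_id": weighings["pregnancy_id"], "tri": tri})
        .groupby(["pregnancy_id", "tri"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[0, 1, 2], fill_value=0)
    )
    ok = counts[(counts >= min_per_trimester).all(axis=1)].index
    return pregnancies[pregnancies["pregnancy_id"].isin(ok)].reset_index(drop=True)


def summarize_cohort(
    weighings: pd.DataFrame,
    pregnancies: pd.DataFrame,
    gestation_days: float = 75.0,
) -> CohortSummary:
    """Cohort descriptives; the mean inter-weighing interval is defined as
    gestation hours divided by the mean number of weighings per pregnancy."""
    if len(pregnancies) == 0:
        raise ValueError("cannot summarize an empty cohort")
    w = weighings[weighings["pregnancy_id"].isin(pregnancies["pregnancy_id"])]
    per_preg = w.groupby("pregnancy_id").size()
    mean_w = float(per_preg.reindex(pregnancies["pregnancy_id"], fill_value=0).mean())
    interval_h = gestation_days * 24.0 / mean_w if mean_w > 0 else float("nan")
    n_fem = int(pregnancies["female_id"].nunique())
    dominant = pregnancies["status"].astype(str) == "dominant"
    litter_mean = {
        s: float(g["litter_size"].mean())
        for s, g in pregnancies.groupby(pregnancies["status"].astype(str))
    }
    litter_sd = {
        s: float(g["litter_size"].std(ddof=1)) if len(g) > 1 else float("nan")
        for s, g in pregnancies.groupby(pregnancies["status"].astype(str))
    }
    return CohortSummary(
        n_pregnancies=len(pregnancies),
        n_females=n_fem,
        n_weighings=int(len(w)),
        mean_weighings_per_pregnancy=mean_w,
        mean_interval_hours=float(interval_h),
        pct_dominant=100.0 * float(dominant.mean()),
        mean_pregnancies_per_female=len(pregnancies) / n_fem,
        litter_mean_by_status=litter_mean,
        litter_sd_by_status=litter_sd,
    )


def backdate_conception(end_day, mode: str = "full_term",
                        gestation_days: float = 75.0,
                        abortion_offset: float = 35.0):
    """Estimated conception day from the observed end of a pregnancy.

    ``full_term``: conception = birth − gestation_days (default 75).
    ``abortion``: conception = loss − abortion_offset (default 35; pregnancies
    are typically detected about 40 days before birth, i.e. 35 after
    conception).
    """
    if mode == "full_term":
        return np.asarray(end_day, dtype=float) - gestation_days
    if mode == "abortion":
        return np.asarray(end_day, dtype=float) - abortion_offset
    raise ValueError("mode must be 'full_term' or 'abortion'")


def assign_gestation_days(
    weighings: pd.DataFrame,
    pregnancies: pd.DataFrame,
) -> pd.DataFrame:
    """Convert calendar-day weighings to day-of-gestation via the back-dated
    conception.

    Expects a ``calendar_day`` column in the weighings and ``conception_day``
    / ``birth_day`` columns in the pregnancy table.  Records before conception
    or after birth are dropped, with the count logged.
    """
    import logging

    pm = pregnancies.set_index("pregnancy_id")
    out = weighings.copy()
    conception = pm["conception_day"].reindex(out["pregnancy_id"]).to_numpy(float)
    birth = pm["birth_day"].reindex(out["pregnancy_id"]).to_numpy(float)
    out["day"] = out["calendar_day"].to_numpy(float) - conception
    keep = (out["day"] >= 0) & (out["calendar_day"].to_numpy(float) <= birth)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logging.getLogger("gwgrowth").warning(
            "dropped %d weighing(s) outside [conception, birth]", n_dropped
        )
    return out[keep].reset_index(drop=True)


def inter_pregnancy_intervals(pregnancies: pd.DataFrame) -> pd.DataFrame:
    """Inter-pregnancy intervals per female: days between one birth and the
    (back-dated) conception of the next pregnancy.

    Requires ``conception_day`` and ``birth_day`` columns; returns one row per
    consecutive pregnancy pair with the gestation length of the first.
    """
    rows = []
    for fid, g in pregnancies.sort_values("conception_day").groupby("female_id"):
        g = g.reset_index(drop=True)
        for i in range(len(g) - 1):
            rows.append(
                {
                    "female_id": fid,
                    "first_pregnancy_id": g.loc[i, "pregnancy_id"],
                    "next_pregnancy_id": g.loc[i + 1, "pregnancy_id"],
                    "gestation_length": g.loc[i, "birth_day"] - g.loc[i, "conception_day"],
                    "ipi": g.loc[i + 1, "conception_day"] - g.loc[i, "birth_day"],
                }
            )
    return pd.DataFrame(rows, columns=["female_id", "first_pregnancy_id",
                                       "next_pregnancy_id", "gestation_length", "ipi"])
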