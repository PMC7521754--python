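"""Assemble back-calculated observations into per-age year-class cohorts.

Each annulus observation gets a calendar-year label: the last annulus of a
fish is attributed to the year before capture, and earlier annuli count back
one year each, i.e. ``year = (capture_year - 1) - (A - i)`` for annulus i of
a fish aged A.  For a full age-1..A_max sample captured in year Y this puts
the age-i labels in ``[(Y-1) - (A_max - i), Y-1]`` — with Y = 2015 and
A_max = 12 the age-1 cohorts span 2003-2014 and the age-10 cohorts 2012-2014.
An alternative birth-year labelling (``capture_year - A``) is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, FishRecord


def assign_year_label(capture_year: int, age_at_capture: int, i: int,
                      rule: str = "formation") -> int:
    """Calendar label of annulus ``i`` for a fish aged ``age_at_capture``."""
    if not 1 <= i <= age_at_capture:
        raise ValueError(
            f"annulus index {i} outside 1..{age_at_capture}"
        )
    if rule == "formation":
        return (capture_year - 1) - (age_at_capture - i)
    if rule == "birth":
        return capture_year - age_at_capture
    raise ValueError(f"unknown year label rule {rule!r}")


def add_year_labels(obs: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Return a copy of ``obs`` with a ``year`` column appended."""
    cfg = cfg or AnalysisConfig()
    obs = obs.copy()
    if cfg.year_label_rule == "formation":
        obs["year"] = (obs["capture_year"] - 1) - (obs["age_at_capture"] - obs["age"])
    else:
        obs["year"] = obs["capture_year"] - obs["age_at_capture"]
    return obs


@dataclass
class AgeCohortDataset:
    """All back-calculated observations at one age, labelled by status and year."""

    age: int
    data: pd.DataFrame  # columns include status, year, length, fish_id

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_by_status(self) -> dict:
        return self.data["status"].value_counts().to_dict()

    @property
    def n_status_levels(self) -> int:
        return int(self.data["status"].nunique())

    @property
    def n_year_levels(self) -> int:
        return int(self.data["year"].nunique())


def pool_by_age(obs: pd.DataFrame, cfg: AnalysisConfig | None = None) -> dict[int, AgeCohortDataset]:
    """Partition observations into one dataset per age present (ascending).

    Ages with no observations are omitted.  Adds year labels if absent.
    The per-status count at age i equals the number of fish with
    age-at-capture >= i (the cumulative-tail identity of pooled stocks).
    """
    if "year" not in obs.columns:
        obs = add_year_labels(obs, cfg)
    return {
        int(age): AgeCohortDataset(age=int(age), data=grp.reset_index(drop=True))
        for age, grp in obs.groupby("age", sort=True)
    }


def sample_size_table(records: list[FishRecord], obs: pd.DataFrame) -> pd.DataFrame:
    """Original vs back-calculated sample sizes per status and age.

    Rows are a (data, status) MultiIndex — original counts are fish aged
    exactly i, back-calculated counts are pooled observations at age i —
    and columns are the ages present.  Empty inputs yield an empty table.
    """
    if not records and len(obs) == 0:
        return pd.DataFrame()
    orig = pd.DataFrame(
        [(r.status, r.age) for r in records], columns=["status", "age"]
    )
    ages = sorted(set(orig["age"]).union(obs["age"].unique() if len(obs) else []))
    rows = {}
    for status in ("MR", "FR"):
        rows[("original", status)] = [
            int(((orig["status"] == status) & (orig["age"] == a)).sum()) for a in ages
        ]
    for status in ("MR", "FR"):
        rows[("back_calculated", status)] = [
            int(((obs["status"] == status) & (obs["age"] == a)).sum()) if len(obs) else 0
            for a in ages
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[f"age_{a}" for a in ages])
    table.index = pd.MultiIndex.from_tuples(table.index, names=["data", "status"])
    return table
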