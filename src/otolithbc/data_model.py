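"""Domain types, CSV schemas, validation and configuration.

The pipeline's unit of input is one sampled fish: its protection status
(marine reserve ``MR`` vs fished reef ``FR``), site, capture year, age at
capture (annulus count), standard length at capture (mm), otolith radius at
capture, and the otolith radius at each annulus.  Lengths and radii are
unit-agnostic but must be consistent within a file; reports label lengths mm.

Two on-disk dialects are accepted for fish tables:

* **long** (canonical): one row per fish-annulus, fish-level columns repeated,
  with ``annulus`` (1-based ring index) and ``annulus_radius`` columns;
* **wide**: one row per fish with annulus radii in columns ``r1..rN``
  (cells beyond the fish's age left empty).

Back-calculated observations travel as a plain :class:`pandas.DataFrame`
(one row per fish-age observation) whose schema is :data:`OBS_COLUMNS`.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

log = logging.getLogger("otolithbc")

STATUSES = ("MR", "FR")

#: Fish-level columns shared by both dialects.
FISH_COLUMNS = (
    "fish_id",
    "status",
    "site",
    "capture_year",
    "age",
    "length",
    "radius",
)

#: Canonical schema of a back-calculated observation table.  ``age`` is the
#: annulus age i of the observation, ``age_at_capture`` the source fish's age,
#: ``year`` the calendar label of the annulus (absent until cohort labelling).
OBS_COLUMNS = (
    "fish_id",
    "status",
    "site",
    "capture_year",
    "age_at_capture",
    "age",
    "length",
)


class SchemaError(ValueError):
    """A required column is missing or a dialect cannot be identified."""


class ValidationError(ValueError):
    """One or more records violate a structural invariant."""


class ConfigError(ValueError):
    """An analysis or simulation configuration is inconsistent."""


@dataclass(frozen=True)
class FishRecord:
    """One sampled fish with its otolith growth record.

    Invariants (enforced by :meth:`validate`): ``len(radii) == age``; radii
    strictly increasing and positive; ``radii[-1] <= radius_capture``;
    ``length_capture > 0``; ``age >= 1``.
    """

    fish_id: str
    status: str
    site: str
    capture_year: int
    age: int
    length_capture: float
    radius_capture: float
    radii: tuple[float, ...]

    def validate(self) -> None:
        problems = self.problems()
        if problems:
            raise ValidationError(
                f"fish {self.fish_id!r}: " + "; ".join(problems)
            )

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty list if valid)."""
        out: list[str] = []
        if self.status not in STATUSES:
            out.append(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.age < 1:
            out.append(f"age must be >= 1, got {self.age}")
        if not self.length_capture > 0:
            out.append(f"length at capture must be > 0, got {self.length_capture}")
        if not self.radius_capture > 0:
            out.append(f"otolith radius at capture must be > 0, got {self.radius_capture}")
        if len(self.radii) != self.age:
            out.append(
                f"expected {self.age} annulus radii (one per year of age), "
                f"got {len(self.radii)}"
            )
        if any(not r > 0 for r in self.radii):
            out.append("all annulus radii must be > 0")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            out.append("annulus radii must be strictly increasing")
        if self.radii and self.radii[-1] > self.radius_capture:
            out.append(
                f"last annulus radius {self.radii[-1]} exceeds radius at "
                f"capture {self.radius_capture}"
            )
        return out


@dataclass
class AnalysisConfig:
    """Tunable knobs for the statistical pipeline.

    alpha
        significance level of the per-age tests (default 0.05).
    loess_span
        LOESS smoothing span in (0, 1]; 0.95 emphasises broad-scale trends.
    min_year_levels_for_loess
        minimum distinct year labels for a LOESS panel (default 3).
    r0p_mode
        ``population_mean`` anchors every fish at the sample-mean first-annulus
        radius; ``per_fish`` anchors each fish at its own first annulus.
    ss_type
        ANOVA sums-of-squares type for the unbalanced design (default 2).
    year_label_rule
        ``formation`` labels annulus i of a fish aged A caught in year Y with
        (Y - 1) - (A - i); ``birth`` labels every observation with Y - A.
    """

    alpha: float = 0.05
    loess_span: float = 0.95
    loess_degree: int = 2
    min_year_levels_for_loess: int = 3
    rng_seed: int = 0
    a_override: float | None = None
    L0p_override: float | None = None
    R0p_override: float | None = None
    r0p_mode: str = "population_mean"
    use_capture_radius_at_final_age: bool = False
    ss_type: int = 2
    year_label_rule: str = "formation"
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.loess_span:
            raise ConfigError(f"loess_span must be > 0, got {self.loess_span}")
        if self.r0p_mode not in ("population_mean", "per_fish"):
            raise ConfigError(f"unknown r0p_mode {self.r0p_mode!r}")
        if self.ss_type not in (1, 2, 3):
            raise ConfigError(f"ss_type must be 1, 2 or 3, got {self.ss_type}")
        if self.year_label_rule not in ("formation", "birth"):
            raise ConfigError(f"unknown year_label_rule {self.year_label_rule!r}")
        if self.loess_degree not in (1, 2):
            raise ConfigError(f"loess_degree must be 1 or 2, got {self.loess_degree}")


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict ({} for an empty file)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _records_from_groups(groups, path) -> list[FishRecord]:
    records, problems = [], []
    for (fid, rows), radii in groups:
        first = rows.iloc[0]
        rec = FishRecord(
            fish_id=str(fid),
            status=str(first["status"]),
            site=str(first["site"]),
            capture_year=int(first["capture_year"]),
            age=int(first["age"]),
            length_capture=float(first["length"]),
            radius_capture=float(first["radius"]),
            radii=tuple(float(r) for r in radii),
        )
        issues = rec.problems()
        if issues:
            rownums = [int(i) + 2 for i in rows.index]  # 1-based incl. header
            problems.append(f"rows {rownums} fish {fid!r}: " + "; ".join(issues))
        else:
            records.append(rec)
    if problems:
        raise ValidationError(f"{path}: invalid records:\n" + "\n".join(problems))
    return records


def read_fish_table(path: str | Path) -> list[FishRecord]:
    """Read a fish table in either the long or the wide dialect.

    Raises
    ------
    SchemaError
        if required columns are missing or neither dialect is recognised.
    ValidationError
        if any fish violates a :class:`FishRecord` invariant (the message
        names the fish and the offending 1-based file rows).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FISH_COLUMNS, path)
    wide_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"r\d+", c)),
        key=lambda c: int(c[1:]),
    )
    groups = []
    if "annulus" in df.columns and "annulus_radius" in df.columns:
        for fid, rows in df.groupby("fish_id", sort=False):
            rows = rows.sort_values("annulus")
            groups.append(((fid, rows), rows["annulus_radius"].tolist()))
    elif wide_cols:
        for fid, rows in df.groupby("fish_id", sort=False):
            first = rows.iloc[0]
            radii = [
                float(first[c])
                for c in wide_cols
                if int(c[1:]) <= int(first["age"]) and pd.notna(first[c])
            ]
            groups.append(((fid, rows), radii))
    else:
        raise SchemaError(
            f"{path}: need either long-format columns (annulus, annulus_radius) "
            "or wide-format columns r1..rN"
        )
    records = _records_from_groups(groups, path)
    years = {r.capture_year for r in records}
    if len(years) > 1:
        log.warning(
            "%s: mixed capture years %s; year labels are computed per fish",
            path, sorted(years),
        )
    return records


def write_fish_table(records: Sequence[FishRecord], path: str | Path) -> None:
    """Write records in the canonical long dialect (one row per annulus)."""
    if not records:
        raise ValueError("refusing to write an empty fish table")
    rows = []
    for rec in records:
        for i, r in enumerate(rec.radii, start=1):
            rows.append(
                dict(
                    fish_id=rec.fish_id, status=rec.status, site=rec.site,
                    capture_year=rec.capture_year, age=rec.age,
                    length=rec.length_capture, radius=rec.radius_capture,
                    annulus=i, annulus_radius=r,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    """Write back-calculated observations to CSV at full float precision."""
    if obs is None or len(obs) == 0:
        raise ValueError("refusing to write an empty observation table")
    obs.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, [c for c in OBS_COLUMNS if c != "site"], path)
    return df
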