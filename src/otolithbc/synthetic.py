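"""Synthetic fish populations with known ground truth.

The generator emulates a single-campaign otolith survey of a reef surgeonfish:
each fish gets an age from a per-status age distribution, an individual von
Bertalanffy growth trajectory (with a protection-status effect and a
birth-year trend injected through the asymptotic length), true body lengths at
integer annulus ages, and otolith annulus radii derived from those lengths
through an allometric body-otolith relation, optionally perturbed by
multiplicative lognormal increment noise (which preserves monotonicity).

Because the radii are generated by inverting exactly the allometry the
back-calculation model assumes, the noise-free generator doubles as an
exactness oracle for the whole back-calculation stage.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ConfigError, FishRecord

# Per-age specimen counts of the 2015 Zambales survey this generator emulates
# (ages 1..12, marine-reserve and fished-reef stocks respectively).
DEFAULT_AGE_COUNTS = {
    "MR": (30, 24, 11, 10, 9, 9, 5, 3, 4, 3, 1, 2),
    "FR": (31, 25, 28, 21, 20, 18, 5, 1, 1, 6, 2, 1),
}

N_SITES_PER_STATUS = 5


@dataclass
class SimConfig:
    """Study-design and biology parameters of the simulated survey.

    Growth: individual asymptotic length ``Linf_i`` is drawn as
    ``linf_mean + year_trend * (birth_year - first_birth_year) + N(0, cv_linf * linf_mean)``
    and true length at age a is ``Linf_i * (1 - exp(-growth_k * (a - t0)))``.
    For MR fish, growth increments accrued at ages within
    ``status_effect_ages`` are multiplied by ``status_effect`` (a factor > 1
    makes protected fish larger; applying it to increments keeps lengths
    strictly increasing for any age window).

    Allometry: body length L and otolith radius R are linked by
    ``L = a_true + b_true * R**c_true``; annulus radii are the exact inverse
    of the true lengths, then perturbed (if ``noise_sd_radius > 0``) by
    lognormal factors on the radius increments.  The radius at capture is the
    last annulus radius inflated by ``capture_growth_frac`` (marginal growth
    after the last annulus), and the length at capture is the allometric
    length at that radius times a lognormal factor of sd ``cv_length_capture``.
    """

    n_mr: int = 111
    n_fr: int = 159
    capture_year: int = 2015
    max_age: int = 12
    age_weights: dict = field(default_factory=lambda: dict(DEFAULT_AGE_COUNTS))
    sampling: str = "quota"  # or "multinomial"
    linf_mean: float = 100.0   # mm
    growth_k: float = 0.2      # 1/yr
    t0: float = -1.3           # yr
    cv_linf: float = 0.10
    status_effect: float = 1.25
    status_effect_ages: tuple[int, int] = (3, 6)
    year_trend: float = 2.0    # mm of Linf per birth year
    a_true: float = 5.0        # mm, biological intercept
    b_true: float = 50.0
    c_true: float = 1.2
    noise_sd_radius: float = 0.05
    cv_length_capture: float = 0.03
    capture_growth_frac: float = 0.05

    def validate(self) -> None:
        if self.n_mr < 0 or self.n_fr < 0:
            raise ConfigError("sample sizes must be non-negative")
        if self.max_age < 1:
            raise ConfigError("max_age must be >= 1")
        if self.growth_k <= 0:
            raise ConfigError("growth_k must be > 0")
        if self.t0 >= 1:
            raise ConfigError("t0 must lie below the first annulus age (1)")
        if self.cv_linf < 0 or self.noise_sd_radius < 0 or self.cv_length_capture < 0:
            raise ConfigError("noise parameters must be >= 0")
        if not (self.linf_mean > self.a_true >= 0):
            raise ConfigError("need linf_mean > a_true >= 0")
        if self.b_true <= 0 or self.c_true <= 0:
            raise ConfigError("allometric b_true and c_true must be > 0")
        if self.status_effect <= 0:
            raise ConfigError("status_effect must be > 0")
        if self.capture_growth_frac < 0:
            raise ConfigError("capture_growth_frac must be >= 0")
        if self.sampling not in ("quota", "multinomial"):
            raise ConfigError(f"unknown sampling mode {self.sampling!r}")
        for status in ("MR", "FR"):
            w = np.asarray(self.age_weights[status], dtype=float)
            if len(w) != self.max_age or (w < 0).any() or w.sum() <= 0:
                raise ConfigError(
                    f"age_weights[{status!r}] must be {self.max_age} "
                    "non-negative weights with positive sum"
                )


def vbgf_length(age, linf, k, t0):
    """Von Bertalanffy length at ``age``: ``linf * (1 - exp(-k (age - t0)))``.

    Strictly increasing in age, saturating at ``linf``; requires ``age > t0``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= t0):
        raise ValueError(f"age must exceed t0={t0}")
    out = linf * (1.0 - np.exp(-k * (age - t0)))
    return out if out.ndim else float(out)


def length_from_radius(radius, a, b, c):
    """Allometric body length at otolith radius R: ``a + b * R**c``."""
    radius = np.asarray(radius, dtype=float)
    out = a + b * radius ** c
    return out if out.ndim else float(out)


def radius_from_length(length, a, b, c):
    """Invert the allometry: ``R = ((L - a) / b) ** (1 / c)``; needs L > a."""
    length = np.asarray(length, dtype=float)
    if np.any(length <= a):
        raise ValueError(f"length must exceed the biological intercept a={a}")
    out = ((length - a) / b) ** (1.0 / c)
    return out if out.ndim else float(out)


def _quota_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Allocate n across ages proportionally to weights (largest remainder)."""
    if n == 0:
        return np.zeros(len(weights), dtype=int)
    exact = weights / weights.sum() * n
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _draw_ages(cfg: SimConfig, status: str, n: int, rng: np.random.Generator):
    weights = np.asarray(cfg.age_weights[status], dtype=float)
    ages = np.arange(1, cfg.max_age + 1)
    if cfg.sampling == "quota":
        counts = _quota_counts(weights, n)
        return np.repeat(ages, counts)
    return rng.choice(ages, size=n, p=weights / weights.sum())


def simulate_population(
    cfg: SimConfig, seed: int | np.random.Generator = 0
) -> tuple[list[FishRecord], pd.DataFrame]:
    """Simulate one survey; returns (fish records, long-format truth table).

    The truth table has one row per fish-annulus with the noise-free true
    length, plus fish-level columns (individual Linf, birth year, injected
    status factor).  Reproducible given the seed.
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[FishRecord] = []
    truth_rows: list[dict] = []
    first_birth_year = cfg.capture_year - cfg.max_age
    lo, hi = cfg.status_effect_ages

    counter = 0
    for status, n in (("MR", cfg.n_mr), ("FR", cfg.n_fr)):
        ages = _draw_ages(cfg, status, n, rng)
        sites = [f"{status}{1 + i % N_SITES_PER_STATUS}" for i in range(len(ages))]
        for age, site in zip(ages, sites):
            counter += 1
            fid = f"F{counter:04d}"
            age = int(age)
            birth_year = cfg.capture_year - age
            linf = (
                cfg.linf_mean
                + cfg.year_trend * (birth_year - first_birth_year)
                + rng.normal(0.0, cfg.cv_linf * cfg.linf_mean)
            )
            linf = max(linf, cfg.a_true + 1.0)  # keep above the intercept
            base = vbgf_length(np.arange(1, age + 1), linf, cfg.growth_k, cfg.t0)
            inc = np.diff(base, prepend=0.0)
            if status == "MR" and cfg.status_effect != 1.0:
                window = (np.arange(1, age + 1) >= lo) & (np.arange(1, age + 1) <= hi)
                inc = np.where(window, inc * cfg.status_effect, inc)
            true_len = np.cumsum(inc)
            true_rad = radius_from_length(true_len, cfg.a_true, cfg.b_true, cfg.c_true)
            rinc = np.diff(true_rad, prepend=0.0)
            if cfg.noise_sd_radius > 0:
                rinc = rinc * np.exp(rng.normal(0.0, cfg.noise_sd_radius, size=age))
            radii = np.cumsum(rinc)
            r_cpt = radii[-1] * (1.0 + cfg.capture_growth_frac)
            l_cpt = length_from_radius(r_cpt, cfg.a_true, cfg.b_true, cfg.c_true)
            if cfg.cv_length_capture > 0:
                l_cpt *= math.exp(rng.normal(0.0, cfg.cv_length_capture))
            records.append(
                FishRecord(
                    fish_id=fid, status=status, site=site,
                    capture_year=cfg.capture_year, age=age,
                    length_capture=float(l_cpt), radius_capture=float(r_cpt),
                    radii=tuple(float(r) for r in radii),
                )
            )
            for i in range(1, age + 1):
                truth_rows.append(
                    dict(
                        fish_id=fid, status=status, site=site,
                        age_at_capture=age, birth_year=birth_year,
                        linf_individual=float(linf),
                        status_factor=(cfg.status_effect if status == "MR" else 1.0),
                        annulus=i, true_length=float(true_len[i - 1]),
                    )
                )
    truth = pd.DataFrame(truth_rows)
    for rec in records:
        rec.validate()
    return records, truth
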