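"""Modified Fry back-calculation (MFBC) of length-at-age.

The MFBC model interpolates ``ln(length - a)`` linearly in ``ln(radius)``
between a formation anchor ``(R0p, L0p)`` and the capture anchor
``(R_cpt, L_cpt)``::

    Li = a + exp( ln(L0p - a)
                  + [ln(L_cpt - a) - ln(L0p - a)]
                    * [ln(Ri) - ln(R0p)] / [ln(R_cpt) - ln(R0p)] )

where ``a`` is the biological intercept of the allometric body-otolith
relation ``L = a + b * R**c``, ``L0p`` the body length at increment
formation, and ``R0p`` the mean radius of the first annulus.  When the
population truly grows on the allometry, ``ln(L - a)`` *is* linear in
``ln R`` and the interpolation is exact — the basis of the generative
exactness tests.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data_model import AnalysisConfig, FishRecord, OBS_COLUMNS

log = logging.getLogger("otolithbc")


class DegenerateDesignError(ValueError):
    """The capture data cannot identify the allometric parameters."""


class DegenerateAnchorError(ValueError):
    """R_cpt equals R0p, so the log-interpolation is undefined."""


@dataclass(frozen=True)
class BackCalcParams:
    """Fitted allometric constants plus the MFBC anchors.

    ``a`` is the biological intercept (mm), ``b``/``c`` the allometric
    coefficient and exponent, ``R0p`` the population-mean first-annulus
    radius and ``L0p`` the length at increment formation.  ``fitted`` flags
    whether each of (a, L0p, R0p) was estimated from the data (True) or
    supplied as an override (False).
    """

    a: float
    b: float
    c: float
    R0p: float = float("nan")
    L0p: float = float("nan")
    fitted: dict = dataclasses.field(default_factory=dict)
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def with_anchors(
        self, R0p: float, L0p: float, fitted: dict | None = None
    ) -> "BackCalcParams":
        return dataclasses.replace(
            self, R0p=R0p, L0p=L0p, fitted={**self.fitted, **(fitted or {})}
        )


def _allometry(r, a, b, c):
    return a + b * np.power(r, c)


def fit_allometry(
    records: Sequence[FishRecord], a_override: float | None = None
) -> BackCalcParams:
    """Least-squares fit of ``L_cpt = a + b * R_cpt**c`` over the pooled sample.

    Initialised from a log-linear regression of ``ln(L_cpt - a0)`` on
    ``ln(R_cpt)`` with ``a0 = 0`` (or the override), then refined jointly by
    nonlinear least squares under the constraint ``a < min(L_cpt)``.
    Deterministic given the data.  Falls back to a straight line (c = 1) with
    a warning if the nonlinear fit fails to converge.
    """
    if len(records) < 5:
        raise DegenerateDesignError(
            f"need at least 5 fish to fit the allometry, got {len(records)}"
        )
    L = np.array([rec.length_capture for rec in records], dtype=float)
    R = np.array([rec.radius_capture for rec in records], dtype=float)
    if np.unique(R).size < 3:
        raise DegenerateDesignError(
            "capture radii are (nearly) constant; allometry is unidentifiable"
        )
    a0 = 0.0 if a_override is None else float(a_override)
    mask = L > a0
    slope, intercept = np.polyfit(np.log(R[mask]), np.log(L[mask] - a0), 1)
    b0, c0 = float(np.exp(intercept)), float(slope)
    a_hi = float(L.min()) - 1e-9
    try:
        if a_override is not None:
            popt, _ = curve_fit(
                lambda r, b, c: _allometry(r, a0, b, c), R, L,
                p0=[b0, max(c0, 1e-6)],
                bounds=([1e-12, 1e-9], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, maxfev=20000,
            )
            a_hat, b_hat, c_hat = a0, float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(
                _allometry, R, L,
                p0=[min(0.0, a_hi - 1.0), b0, max(c0, 1e-6)],
                bounds=([-np.inf, 1e-12, 1e-9], [a_hi, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, maxfev=20000,
            )
            a_hat, b_hat, c_hat = (float(v) for v in popt)
    except RuntimeError:
        warnings.warn(
            "nonlinear allometry fit did not converge; "
            "falling back to a linear model (c = 1)",
            RuntimeWarning,
        )
        b_hat, a_hat = np.polyfit(R, L, 1)
        a_hat, b_hat, c_hat = float(a_hat), float(b_hat), 1.0
    resid = L - _allometry(R, a_hat, b_hat, c_hat)
    return BackCalcParams(
        a=a_hat, b=b_hat, c=c_hat,
        fitted={"a": a_override is None},
        diagnostics={"n": len(records), "rss": float(resid @ resid)},
    )


def compute_anchors(
    records: Sequence[FishRecord],
    params: BackCalcParams,
    cfg: AnalysisConfig | None = None,
) -> tuple[float, float]:
    """Population anchors: R0p = mean first-annulus radius; L0p = a + b*R0p**c.

    Either anchor may be pinned by a config override (e.g. a settlement-size
    prior for L0p).
    """
    cfg = cfg or AnalysisConfig()
    if not records:
        raise ValueError("cannot compute anchors from an empty sample")
    if cfg.R0p_override is not None:
        r0p = float(cfg.R0p_override)
    else:
        r0p = float(np.mean([rec.radii[0] for rec in records]))
    if cfg.L0p_override is not None:
        l0p = float(cfg.L0p_override)
    else:
        l0p = float(_allometry(r0p, params.a, params.b, params.c))
    return r0p, l0p


def fit(records: Sequence[FishRecord], cfg: AnalysisConfig | None = None) -> BackCalcParams:
    """Convenience: fit the allometry and attach population anchors."""
    cfg = cfg or AnalysisConfig()
    params = fit_allometry(records, a_override=cfg.a_override)
    r0p, l0p = compute_anchors(records, params, cfg)
    return params.with_anchors(
        r0p, l0p,
        fitted={"R0p": cfg.R0p_override is None, "L0p": cfg.L0p_override is None},
    )


def mfbc_length(ri, l_cpt, r_cpt, a, l0p, r0p):
    """Back-calculated length at otolith radius ``ri`` (vectorised over ri).

    Raises ``ValueError`` naming the offending quantity for any non-positive
    log argument, and :class:`DegenerateAnchorError` when ``r_cpt == r0p``.
    Endpoint identities: ``ri == r_cpt -> l_cpt`` and ``ri == r0p -> l0p``.
    """
    ri = np.asarray(ri, dtype=float)
    for name, val in (("L_cpt - a", l_cpt - a), ("L0p - a", l0p - a),
                      ("R_cpt", r_cpt), ("R0p", r0p)):
        if not val > 0:
            raise ValueError(f"MFBC domain error: {name} must be > 0, got {val}")
    if np.any(ri <= 0):
        raise ValueError("MFBC domain error: Ri must be > 0")
    denom = np.log(r_cpt) - np.log(r0p)
    if denom == 0.0:
        raise DegenerateAnchorError("R_cpt equals R0p; anchors are degenerate")
    frac = (np.log(ri) - np.log(r0p)) / denom
    li = a + np.exp(
        np.log(l0p - a) + (np.log(l_cpt - a) - np.log(l0p - a)) * frac
    )
    return li if li.ndim else float(li)


def mfbc_length_record(ri, fish: FishRecord, params: BackCalcParams):
    """MFBC length for one fish using the population anchors in ``params``."""
    return mfbc_length(
        ri, fish.length_capture, fish.radius_capture,
        params.a, params.L0p, params.R0p,
    )


def back_calculate_all(
    records: Sequence[FishRecord],
    params: BackCalcParams,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Back-calculate every fish at every annulus.

    A fish of age A yields exactly A observations, using ``Ri = r[i]`` for
    ``i = 1..A`` (the capture-age observation uses the last annulus radius;
    set ``cfg.use_capture_radius_at_final_age`` to use ``R_cpt`` instead, in
    which case the final observation equals the capture length exactly).
    Fish violating the model's preconditions are skipped with a logged
    reason, never clamped; the returned frame records the skip count in
    ``.attrs["skipped"]``.
    """
    cfg = cfg or AnalysisConfig()
    rows: list[dict] = []
    skipped: list[tuple[str, str]] = []
    for rec in records:
        if cfg.r0p_mode == "per_fish":
            r0p = rec.radii[0]
            l0p = float(_allometry(r0p, params.a, params.b, params.c))
        else:
            r0p, l0p = params.R0p, params.L0p
        radii = np.array(rec.radii, dtype=float)
        if cfg.use_capture_radius_at_final_age:
            radii = radii.copy()
            radii[-1] = rec.radius_capture
        try:
            lengths = mfbc_length(
                radii, rec.length_capture, rec.radius_capture,
                params.a, l0p, r0p,
            )
        except (ValueError, DegenerateAnchorError) as err:
            skipped.append((rec.fish_id, str(err)))
            log.warning("skipping fish %s: %s", rec.fish_id, err)
            continue
        lengths = np.atleast_1d(lengths)
        for i, li in enumerate(lengths, start=1):
            rows.append(
                dict(
                    fish_id=rec.fish_id, status=rec.status, site=rec.site,
                    capture_year=rec.capture_year, age_at_capture=rec.age,
                    age=i, length=float(li),
                )
            )
    obs = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    obs.attrs["skipped"] = skipped
    return obs
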