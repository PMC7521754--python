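"""LOESS trends of length-at-age by year class, with confidence bands.

The smoother is a locally weighted polynomial regression: at each evaluation
point the nearest ``ceil(span * n)`` observations are fit with a quadratic
(by default) weighted by the tricube kernel, and the fitted value is the
local intercept.  A span >= 1 disables locality entirely (uniform weights,
one global polynomial), so span 1 with degree 1 reduces to ordinary least
squares.  Pointwise confidence bands are approximate t-intervals built from
the smoother matrix: ``fit +/- t(1 - alpha/2, df_resid) * sigma * ||l(x0)||``
with residual degrees of freedom ``n - 2 tr(H) + tr(H H')``.

Panels replicate the study's figures: per-age scatter of back-calculated
length against year class by protection status, both LOESS curves with 95%
bands, and the ANOVA summary in the lower-left corner.  Ages with fewer
distinct year classes than the configured minimum (default 3) are gated and
produce no panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cohorts import AgeCohortDataset
from .data_model import AnalysisConfig

STATUS_COLORS = {"MR": "#1b7837", "FR": "#762a83"}


class InsufficientDataError(ValueError):
    """Too few distinct x values to support a LOESS fit."""


@dataclass
class LoessFit:
    """A fitted LOESS curve on a grid with its pointwise confidence band."""

    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    resid_df: float
    sigma2: float
    span: float
    degree: int


def _local_row(x: np.ndarray, x0: float, span: float, degree: int) -> np.ndarray:
    """Equivalent-kernel row l(x0): fitted(x0) = l(x0) @ y."""
    n = len(x)
    d = np.abs(x - x0)
    if span >= 1.0:
        w = np.ones(n)
    else:
        q = max(degree + 1, int(np.ceil(span * n)))
        q = min(q, n)
        h = np.partition(d, q - 1)[q - 1]
        if h <= 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    X = np.vander(x - x0, degree + 1, increasing=True)
    XtW = X.T * w
    A = XtW @ X
    return (np.linalg.pinv(A) @ XtW)[0]


def loess_fit(
    x,
    y,
    span: float = 0.95,
    degree: int = 2,
    grid=None,
    conf: float = 0.95,
    min_distinct: int = 3,
) -> LoessFit:
    """Locally weighted polynomial fit of y on x with a pointwise band.

    Exact on polynomials up to ``degree`` (a quadratic smoother reproduces
    any line or parabola to rounding error) and equivariant under adding a
    constant to y.  Raises :class:`InsufficientDataError` when x has fewer
    than ``min_distinct`` distinct values.
    """
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    distinct = np.unique(x).size
    if distinct < min_distinct:
        raise InsufficientDataError(
            f"LOESS needs >= {min_distinct} distinct x values, got {distinct}"
        )
    n = len(x)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), max(50, distinct))
    grid = np.asarray(grid, dtype=float)

    H = np.empty((n, n))
    for i in range(n):
        H[i] = _local_row(x, x[i], span, degree)
    resid = y - H @ y
    rss = float(resid @ resid)
    resid_df = n - 2.0 * np.trace(H) + float(np.sum(H * H))
    resid_df = max(resid_df, 1.0)
    sigma2 = rss / resid_df

    fitted = np.empty(len(grid))
    se = np.empty(len(grid))
    for j, x0 in enumerate(grid):
        l = _local_row(x, x0, span, degree)
        fitted[j] = l @ y
        se[j] = np.sqrt(sigma2 * (l @ l))
    tcrit = sps.t.isf((1.0 - conf) / 2.0, resid_df)
    return LoessFit(
        grid=grid, fitted=fitted, se=se,
        lower=fitted - tcrit * se, upper=fitted + tcrit * se,
        resid_df=resid_df, sigma2=sigma2, span=span, degree=degree,
    )


def fit_status_curves(
    dataset: AgeCohortDataset, cfg: AnalysisConfig | None = None
) -> dict[str, LoessFit]:
    """One LOESS fit per protection status present in the cohort.

    Statuses whose year coverage is below the gate are omitted; an empty dict
    means the whole age is gated.
    """
    cfg = cfg or AnalysisConfig()
    fits: dict[str, LoessFit] = {}
    if dataset.n_year_levels < cfg.min_year_levels_for_loess:
        return fits
    for status, grp in dataset.data.groupby("status"):
        try:
            fits[status] = loess_fit(
                grp["year"].to_numpy(), grp["length"].to_numpy(),
                span=cfg.loess_span, degree=cfg.loess_degree,
                min_distinct=cfg.min_year_levels_for_loess,
            )
        except InsufficientDataError:
            continue
    return fits


def plot_age_cohort(
    dataset: AgeCohortDataset,
    fits: dict[str, LoessFit],
    result=None,
    cfg: AnalysisConfig | None = None,
    path: str | Path | None = None,
):
    """Render one age panel; returns the Figure (saved to ``path`` if given).

    The ANOVA summary is printed in the lower-left corner; when the year
    effect is significant the distinct year classes are marked above the
    curves.  Raises if the age is gated (no fits).
    """
    cfg = cfg or AnalysisConfig()
    if not fits:
        raise InsufficientDataError(
            f"age {dataset.age}: insufficient temporal cohorts for a panel"
        )
    fig, ax = plt.subplots(figsize=(5.2, 4.0))
    for status, grp in dataset.data.groupby("status"):
        ax.scatter(
            grp["year"], grp["length"], s=12, alpha=0.55,
            color=STATUS_COLORS.get(status, "gray"), label=status,
        )
    for status, f in fits.items():
        color = STATUS_COLORS.get(status, "gray")
        ax.plot(f.grid, f.fitted, color=color, lw=1.8)
        ax.fill_between(f.grid, f.lower, f.upper, color=color, alpha=0.2, lw=0)
    if result is not None and np.isfinite(getattr(result, "status_F", np.nan)):
        txt = (
            f"Status: F={result.status_F:.2f}, p={result.status_p:.3f}\n"
            f"Year: F={result.year_F:.2f}, p={result.year_p:.3f}\n"
            f"Power={result.power:.2f}"
        )
        ax.text(
            0.02, 0.02, txt, transform=ax.transAxes, va="bottom", ha="left",
            fontsize=7, family="monospace",
        )
        if result.year_p < cfg.alpha:
            top = max(f.upper.max() for f in fits.values())
            for yr in sorted(dataset.data["year"].unique()):
                ax.text(yr, top, str(int(yr)), fontsize=6, rotation=90,
                        ha="center", va="bottom", color="0.35")
    ax.set_xlabel("Year class")
    ax.set_ylabel("Back-calculated standard length (mm)")
    ax.set_title(f"Age {dataset.age}")
    ax.legend(frameon=False, fontsize=8, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_all(
    datasets: dict[int, AgeCohortDataset],
    results: pd.DataFrame | None,
    cfg: AnalysisConfig | None = None,
    outdir: str | Path = "figs",
    fmt: str = "png",
) -> list[Path]:
    """One panel per non-gated age; returns the files written."""
    cfg = cfg or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for age, ds in sorted(datasets.items()):
        fits = fit_status_curves(ds, cfg)
        if not fits:
            continue
        result = None
        if results is not None:
            row = results[results["age"] == age]
            if len(row):
                result = row.iloc[0]
        path = outdir / f"age_{age:02d}.{fmt}"
        plot_age_cohort(ds, fits, result=result, cfg=cfg, path=path)
        written.append(path)
    return written
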