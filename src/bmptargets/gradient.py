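"""Spatial quantification of morphogen-signaling gradients.

Two procedures are implemented:

* **Nuclear arc profiles** (sea anemone): each nucleus in an embryo is
  ordered from the strongest-signal midpoint outward and assigned an
  angular coordinate theta_i = (i / N) * pi along a 180-degree arc.
  Intensities of a control-experiment pair are jointly normalized to the
  upper quantile of the pooled values, and the per-condition profile is a
  LOESS curve (local linear regression, tricube weights) with a pointwise
  t-based confidence band for the mean (99% by default).

* **Embryonic axis profiles** (zebrafish): a masked 2-D intensity image is
  reduced to per-column means, mapped to percent of embryo length, binned
  at 0.5% resolution, optionally background-subtracted bin-wise with
  no-primary-antibody control profiles, and trimmed of the first and last
  5% of the axis where few pixels make the averages unreliable (180 of
  200 bins remain at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GradientProfile",
    "AxisProfile",
    "assign_arc_positions",
    "normalize_upper_quantile",
    "loess_profile",
    "axis_profile",
    "read_nuclei_tsv",
    "plot_profile",
]


@dataclass
class GradientProfile:
    grid: np.ndarray  # theta positions of the evaluation grid
    fit: np.ndarray  # LOESS curve
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float
    span: float
    n_points: int


@dataclass
class AxisProfile:
    bin_centers: np.ndarray  # % embryo length
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    background_subtracted: bool
    n_empty_columns: int = 0


def assign_arc_positions(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``theta`` = (seq_index / N) * pi per (embryo_id, layer) group.

    ``seq_index`` runs 1..N from the strongest-signal midpoint, so the
    first nucleus maps to pi/N and the last exactly to pi. Gaps or
    duplicates in the index raise a validation error naming the embryo.
    """
    required = {"embryo_id", "layer", "seq_index", "raw_intensity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"nucleus table missing columns: {sorted(missing)}")
    out = records.copy()
    group_n = pd.Series(0, index=out.index, dtype=float)
    for (embryo, layer), sub in out.groupby(["embryo_id", "layer"], sort=False):
        idx = np.sort(sub["seq_index"].to_numpy())
        n = len(idx)
        if not np.array_equal(idx, np.arange(1, n + 1)):
            raise ValueError(
                f"embryo {embryo!r} ({layer}): seq_index must be 1..N without gaps"
            )
        group_n.loc[sub.index] = n
    out["theta"] = out["seq_index"].to_numpy() / group_n.to_numpy() * np.pi
    return out


def normalize_upper_quantile(
    pooled: pd.DataFrame | np.ndarray,
    q: float = 0.75,
    column: str = "raw_intensity",
) -> pd.DataFrame | np.ndarray:
    """Divide intensities by the q-quantile of the pooled values.

    The pool spans all replicates and both conditions of one
    control-experiment pair; the quantile uses linear interpolation, so
    the pool quantile of the normalized data is exactly 1.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    values = pooled[column].to_numpy() if isinstance(pooled, pd.DataFrame) else np.asarray(pooled)
    if values.size == 0:
        raise ValueError("empty intensity pool")
    divisor = float(np.quantile(values, q))
    if divisor <= 0:
        raise ValueError(f"upper-quantile divisor is {divisor}; must be > 0")
    if isinstance(pooled, pd.DataFrame):
        out = pooled.copy()
        out["norm_intensity"] = out[column] / divisor
        return out
    return values / divisor


def loess_profile(
    theta: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    level: float = 0.99,
    grid: np.ndarray | None = None,
    grid_n: int = 100,
) -> GradientProfile:
    """Local linear regression with tricube weights and a pointwise CI.

    At each grid point the nearest ceil(span * n) points enter a weighted
    linear fit; the bandwidth is the k-th nearest distance (lowess rule,
    so statsmodels' lowess reproduces the curve). The confidence band for
    the mean uses the local weighted residual variance on the local
    effective degrees of freedom with a t quantile; zero-noise data give
    zero band width.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape != y.shape or theta.ndim != 1:
        raise ValueError("theta and y must be 1-D arrays of equal length")
    n = len(theta)
    if n < 10:
        raise ValueError(f"need >= 10 points for a LOESS profile (got {n})")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < 3:
        raise ValueError("span * n must cover at least 3 points")
    order = np.argsort(theta, kind="mergesort")
    x_s, y_s = theta[order], y[order]
    if grid is None:
        grid = np.linspace(float(x_s.min()), np.pi, grid_n)
    grid = np.asarray(grid, dtype=float)

    fit = np.empty(len(grid))
    half = np.empty(len(grid))
    tcrit_cache: dict[float, float] = {}
    for i, x0 in enumerate(grid):
        d = np.abs(x_s - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            # all nearest points coincide with x0
            sel = d == 0
            fit[i] = y_s[sel].mean()
            half[i] = 0.0
            continue
        u = np.clip(d / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        sel = w > 0
        ws, xs, ys = w[sel], x_s[sel] - x0, y_s[sel]
        sw = ws.sum()
        swx = (ws * xs).sum()
        swxx = (ws * xs * xs).sum()
        det = sw * swxx - swx * swx
        n_eff = sw**2 / (ws**2).sum()  # Kish effective sample size
        if det <= 0 or sel.sum() < 2:
            # degenerate abscissae: weighted mean
            fit[i] = float((ws * ys).sum() / sw)
            li = ws / sw
            resid = ys - fit[i]
            dof = max(n_eff - 1.0, 1.0)
        else:
            # smoother weights for the intercept at x0
            li = ws * (swxx - swx * xs) / det
            fit[i] = float(li @ ys)
            b1 = float((ws * (sw * xs - swx) / det) @ ys)
            resid = ys - (fit[i] + b1 * xs)
            dof = max(n_eff - 2.0, 1.0)
        # weighted residual variance, bias-corrected on the effective dof
        sigma2 = float((ws * resid**2).sum() / sw) * n_eff / dof
        key = round(dof, 6)
        if key not in tcrit_cache:
            tcrit_cache[key] = float(stats.t.ppf(0.5 + level / 2.0, dof))
        half[i] = tcrit_cache[key] * np.sqrt(sigma2 * float(li @ li))
    return GradientProfile(
        grid=grid,
        fit=fit,
        ci_low=fit - half,
        ci_high=fit + half,
        level=level,
        span=span,
        n_points=n,
    )


def axis_profile(
    image: np.ndarray,
    roi_mask: np.ndarray,
    bin_pct: float = 0.5,
    trim_pct: float = 5.0,
    background: list[np.ndarray] | None = None,
) -> AxisProfile:
    """Binned ventral-to-dorsal axis profile of a masked intensity image.

    Per-column means over masked pixels are mapped to percent of the
    masked extent (ventral at column 0), averaged into ``bin_pct`` bins
    (pixel-count weighted), background-subtracted bin-wise if control
    profiles are given, and trimmed of bins in the first/last
    ``trim_pct``. Empty mask columns are skipped and counted.
    """
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.shape != roi_mask.shape:
        raise ValueError("image and mask shapes differ")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    col_counts = roi_mask.sum(axis=0)
    nonempty = np.nonzero(col_counts > 0)[0]
    first, last = int(nonempty[0]), int(nonempty[-1])
    extent = last - first + 1
    cols = np.arange(first, last + 1)
    counts = col_counts[cols]
    with np.errstate(invalid="ignore"):
        col_means = np.where(
            counts > 0, (image * roi_mask).sum(axis=0)[cols] / np.maximum(counts, 1), np.nan
        )
    n_empty = int((counts == 0).sum())
    pct = (cols - first + 0.5) / extent * 100.0

    n_bins = int(round(100.0 / bin_pct))
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(pct, edges) - 1, 0, n_bins - 1)
    mean_int = np.full(n_bins, np.nan)
    n_pix = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = (bin_idx == b) & (counts > 0)
        if sel.any():
            wsum = counts[sel].sum()
            mean_int[b] = float((col_means[sel] * counts[sel]).sum() / wsum)
            n_pix[b] = int(wsum)
    subtracted = False
    if background:
        bg = np.nanmean(np.vstack([np.asarray(b, dtype=float) for b in background]), axis=0)
        if bg.shape != mean_int.shape:
            raise ValueError("background profiles must match the bin count before trimming")
        mean_int = mean_int - bg
        subtracted = True
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = (edges[:-1] >= trim_pct - 1e-9) & (edges[1:] <= 100.0 - trim_pct + 1e-9)
    return AxisProfile(
        bin_centers=centers[keep],
        mean_intensity=mean_int[keep],
        n_pixels=n_pix[keep],
        background_subtracted=subtracted,
        n_empty_columns=n_empty,
    )


def read_nuclei_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"embryo_id", "layer", "seq_index", "raw_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def plot_profile(profile: GradientProfile, ax=None, label: str | None = None, color=None):
    """Plot the LOESS curve with its shaded confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    (line,) = ax.plot(profile.grid, profile.fit, label=label, color=color)
    ax.fill_between(
        profile.grid, profile.ci_low, profile.ci_high, alpha=0.25, color=line.get_color()
    )
    ax.set_xlabel("arc position (rad)")
    ax.set_ylabel("normalized intensity")
    if label:
        ax.legend()
    return ax
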