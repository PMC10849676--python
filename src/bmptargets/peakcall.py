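"""Sliding-window ChIP-seq peak calling with cross-lane quantile normalization.

One sequenced replicate library ("lane") yields a :class:`FragmentSet` of
paired-end fragments. Candidate peaks are windows whose fragment-midpoint
count exceeds a Poisson upper tail for the genome-wide background rate;
merged candidates are reduced to a summit (position of maximal midpoint
density), and each peak carries

* ``H`` — height: midpoints per million library fragments within the
  summit-centred window,
* ``E`` — fold enrichment over the identically computed, library-size
  scaled control height (with a pseudocount),
* ``D`` — distribution score in [0, 1], penalising left/right midpoint
  asymmetry around the summit,
* ``S = H * D`` — overall peak score.

Peak heights are then quantile-normalized across lanes so that every lane
shares one height distribution before cross-lane joining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "Peak",
    "PeakCallParams",
    "pileup_midpoints",
    "call_peaks",
    "quantile_normalize_heights",
    "read_bedpe",
    "write_bedpe",
    "peaks_to_frame",
    "write_peaks_tsv",
    "read_peaks_tsv",
]


@dataclass
class FragmentSet:
    """Per-lane collection of sequenced fragments (0-based, half-open)."""

    lane_id: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end"]
        if list(df.columns[:3]) != required:
            df = df.rename(columns=dict(zip(df.columns[:3], required)))
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError(f"lane {self.lane_id}: fragment with start >= end")
        self.intervals = (
            df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        )

    @property
    def library_size(self) -> int:
        return len(self.intervals)

    def midpoints(self) -> dict[str, np.ndarray]:
        """Sorted fragment midpoints per chromosome, floor((start+end)/2)."""
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=True):
            mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
            mids.sort()
            out[str(chrom)] = mids
        return out

    def shift(self, delta: int) -> "FragmentSet":
        df = self.intervals.copy()
        df["start"] += delta
        df["end"] += delta
        return FragmentSet(self.lane_id, df)


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    height: float  # H, fragments-per-million in window
    enrichment: float  # E, fold over scaled control
    dist_score: float  # D in [0, 1]
    score: float  # S = H * D
    lane_id: str

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit outside peak span")
        if self.height < 0 or self.enrichment < 0:
            raise ValueError("negative height/enrichment")
        if not (0.0 <= self.dist_score <= 1.0):
            raise ValueError("distribution score outside [0, 1]")


@dataclass
class PeakCallParams:
    """Caller tuning; window 300 bp with quarter-window steps by default."""

    window: int = 300
    step: int = 75
    pseudocount: float = 0.5
    poisson_p: float = 1e-3  # candidate-window upper-tail cutoff
    min_enrichment: float = 2.0  # candidate-stage enrichment floor
    chrom_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.step > self.window:
            raise ValueError("require 0 < step <= window")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")


def pileup_midpoints(
    frags: FragmentSet,
    window: int,
    step: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Count fragment midpoints per sliding window.

    Returns ``{chrom: (window_starts, counts)}``; window ``[s, s + window)``
    is half-open, so a midpoint exactly at ``s`` belongs to that window and
    one at ``s + window`` does not.
    """
    if window <= 0 or step <= 0 or step > window:
        raise ValueError("require 0 < step <= window")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mids_by_chrom = frags.midpoints()
    chroms = set(mids_by_chrom)
    if chrom_sizes:
        chroms |= set(chrom_sizes)
    for chrom in sorted(chroms):
        mids = mids_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        if chrom_sizes and chrom in chrom_sizes:
            extent = chrom_sizes[chrom]
        elif len(mids):
            extent = int(mids[-1]) + 1
        else:
            extent = 0
        if extent <= 0:
            out[chrom] = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            continue
        starts = np.arange(0, extent, step, dtype=np.int64)
        counts = np.searchsorted(mids, starts + window, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
        out[chrom] = (starts, counts.astype(np.int64))
    return out


def _window_count(mids: np.ndarray, lo: int, hi: int) -> int:
    return int(np.searchsorted(mids, hi, side="left") - np.searchsorted(mids, lo, side="left"))


def call_peaks(
    chip: FragmentSet,
    control: FragmentSet,
    params: PeakCallParams | None = None,
) -> list[Peak]:
    """Call peaks for one ChIP lane against its input control.

    Candidate windows pass a Poisson upper-tail test against the genome-wide
    ChIP midpoint rate; overlapping candidates are merged, the summit is the
    position of maximal midpoint density within the merged span, and peaks
    failing the candidate enrichment floor or with no flanking midpoints
    (undefined distribution score) are dropped. Output ordered by
    (chrom, summit).
    """
    params = params or PeakCallParams()
    if control.library_size == 0:
        raise ValueError("control library is empty")
    if chip.library_size == 0:
        return []
    W = params.window
    half = W // 2
    chip_mids = chip.midpoints()
    ctrl_mids = control.midpoints()
    genome = (
        sum(params.chrom_sizes.values())
        if params.chrom_sizes
        else sum(int(m[-1]) + 1 for m in chip_mids.values() if len(m))
    )
    if genome <= 0:
        raise ValueError("cannot determine genome extent")
    lam = chip.library_size * W / genome
    # smallest count with upper-tail P(X >= c) < cutoff
    min_count = int(stats.poisson.isf(params.poisson_p, lam)) + 1

    pileups = pileup_midpoints(chip, W, params.step, params.chrom_sizes or None)
    peaks: list[Peak] = []
    for chrom in sorted(pileups):
        starts, counts = pileups[chrom]
        hot = starts[counts >= min_count]
        if not len(hot):
            continue
        mids = chip_mids.get(chrom, np.empty(0, dtype=np.int64))
        cmids = ctrl_mids.get(chrom, np.empty(0, dtype=np.int64))
        # merge overlapping/adjacent candidate windows [s, s+W)
        regions: list[list[int]] = []
        for s in hot:
            s = int(s)
            if regions and s <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], s + W)
            else:
                regions.append([s, s + W])
        for lo, hi in regions:
            rmids = mids[np.searchsorted(mids, lo) : np.searchsorted(mids, hi)]
            if not len(rmids):
                continue
            # summit: midpoint position maximising local midpoint density;
            # the middle of a tied plateau avoids leftward bias
            uniq = np.unique(rmids)
            dens = np.searchsorted(rmids, uniq + half, side="left") - np.searchsorted(
                rmids, uniq - half, side="left"
            )
            best = np.nonzero(dens == dens.max())[0]
            summit = int(uniq[best[len(best) // 2]])
            # refine to the median midpoint around the density maximum:
            # centres the summit on the fragment mass and stabilises it
            # across replicate lanes well below the cross-lane join distance
            wmids = mids[
                np.searchsorted(mids, summit - half) : np.searchsorted(mids, summit + half)
            ]
            if len(wmids):
                summit = int(np.median(wmids))
            n_win = _window_count(mids, summit - half, summit + half)
            H = 1e6 * n_win / chip.library_size
            Hc = 1e6 * _window_count(cmids, summit - half, summit + half) / control.library_size
            E = (H + params.pseudocount) / (Hc + params.pseudocount)
            L = _window_count(mids, summit - half, summit)
            R = _window_count(mids, summit, summit + half)
            if L + R == 0:
                continue
            D = 1.0 - abs(L - R) / (L + R)
            if D == 0.0:
                continue  # all midpoints one-sided: not a point-source peak
            if E < params.min_enrichment:
                continue
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=max(lo, summit - half),
                    end=min(hi, summit + half) if hi > summit else summit + 1,
                    summit=summit,
                    height=H,
                    enrichment=E,
                    dist_score=D,
                    score=H * D,
                    lane_id=chip.lane_id,
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.summit))
    return peaks


def _mean_quantile_curve(sorted_by_lane: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled mean quantile function over lanes, nodes at p = (r - 0.5)/n."""
    grid = np.unique(
        np.concatenate([(np.arange(1, len(v) + 1) - 0.5) / len(v) for v in sorted_by_lane])
    )
    curves = []
    for v in sorted_by_lane:
        p = (np.arange(1, len(v) + 1) - 0.5) / len(v)
        curves.append(np.interp(grid, p, v))
    return grid, np.mean(curves, axis=0)


def quantile_normalize_heights(
    peaks_by_lane: Mapping[str, Sequence[Peak]],
) -> dict[str, list[Peak]]:
    """Quantile-normalize peak heights across lanes; scores recomputed.

    Rank r in every lane receives the across-lane mean of the r-th order
    statistic; unequal lane sizes use linear interpolation of the mean
    quantile function, and tied heights share the mean of their would-be
    values. Lanes without peaks pass through unchanged (with a warning).
    """
    if not peaks_by_lane:
        raise ValueError("no lanes supplied")
    nonempty = {k: v for k, v in peaks_by_lane.items() if len(v)}
    for lane in peaks_by_lane:
        if lane not in nonempty:
            logger.warning("lane %s has no peaks; passed through unchanged", lane)
    if not nonempty:
        return {k: list(v) for k, v in peaks_by_lane.items()}

    sorted_h = [np.sort([p.height for p in v]) for v in nonempty.values()]
    grid, qbar = _mean_quantile_curve(sorted_h)

    out: dict[str, list[Peak]] = {k: list(v) for k, v in peaks_by_lane.items() if k not in nonempty}
    for lane, lane_peaks in nonempty.items():
        h = np.array([p.height for p in lane_peaks])
        n = len(h)
        order = np.argsort(h, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = np.interp((np.arange(1, n + 1) - 0.5) / n, grid, qbar)
        # ties share the mean of their would-be values
        for val in np.unique(h):
            mask = h == val
            if mask.sum() > 1:
                assigned[mask] = assigned[mask].mean()
        out[lane] = [
            replace(p, height=float(a), score=float(a) * p.dist_score)
            for p, a in zip(lane_peaks, assigned)
        ]
    return out


# ---------------------------------------------------------------------------
# plain-text I/O


def read_bedpe(path, lane_id: str | None = None) -> FragmentSet:
    """Read fragments from BEDPE (10 or 6+ columns) or 3-column interval TSV.

    For BEDPE the fragment spans min(start1, start2)..max(end1, end2).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    lane = lane_id or str(path)
    if df.shape[1] >= 6 and df[3].dtype == object:
        frag = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[[1, 4]].min(axis=1).astype(int),
                "end": df[[2, 5]].max(axis=1).astype(int),
            }
        )
    else:
        frag = pd.DataFrame(
            {"chrom": df[0].astype(str), "start": df[1].astype(int), "end": df[2].astype(int)}
        )
    return FragmentSet(lane, frag)


def write_bedpe(frags: FragmentSet, path, read_length: int = 50) -> None:
    """Write fragments as BEDPE mate pairs (outermost read_length bp each)."""
    df = frags.intervals
    n = len(df)
    end1 = np.minimum(df["start"] + read_length, df["end"])
    start2 = np.maximum(df["end"] - read_length, df["start"])
    out = pd.DataFrame(
        {
            "chrom1": df["chrom"],
            "start1": df["start"],
            "end1": end1,
            "chrom2": df["chrom"],
            "start2": start2,
            "end2": df["end"],
            "name": [f"{frags.lane_id}_frag{i}" for i in range(n)],
            "score": np.zeros(n, dtype=int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


_PEAK_COLS = ["chrom", "start", "end", "name", "summit", "H", "E", "D", "S", "lane"]


def peaks_to_frame(peaks: Iterable[Peak]) -> pd.DataFrame:
    rows = [
        (
            p.chrom,
            p.start,
            p.end,
            f"{p.lane_id}_peak{i}",
            p.summit,
            p.height,
            p.enrichment,
            p.dist_score,
            p.score,
            p.lane_id,
        )
        for i, p in enumerate(peaks)
    ]
    return pd.DataFrame(rows, columns=_PEAK_COLS)


def write_peaks_tsv(peaks: Iterable[Peak], path) -> None:
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t")
    return [
        Peak(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            summit=int(r.summit),
            height=float(r.H),
            enrichment=float(r.E),
            dist_score=float(r.D),
            score=float(r.S),
            lane_id=str(r.lane),
        )
        for r in df.itertuples()
    ]
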