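"""Sliding-window chromosomal metrics, PELT segmentation and deletion calls.

The scan runs over differential-transcription records carrying gene
coordinates: per 10 Mbp window (1 Mbp step) it computes the ratios of each
DT class to the transcribed total and the unweighted mean logFC, segments
each track with an exact PELT minimizer of a penalized Gaussian
change-in-mean cost, re-profiles each segment at gene level and calls
deletion candidates from segments that are almost entirely down-regulated
and near-silent in the test genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

MB = 1_000_000
RATIO_METRICS = ("R_notDT_Trans", "R_Up_Trans", "R_Down_Trans")
ALL_METRICS = RATIO_METRICS + ("mean_logFC", "transcribed_density")


def attach_coordinates(dt: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Join DT records with annotation coordinates (inner, on gene id)."""
    ann = annotation.set_index("gene_id")[["chromosome", "start", "end"]]
    return dt.join(ann, how="inner")


@dataclass
class WindowTrack:
    """One chromosomal metric evaluated on sliding windows.

    Windows have fixed width and step; the last windows are truncated at the
    chromosome end rather than dropped (a terminal deletion must stay
    visible).  Ratio and mean-logFC values are NaN where a window holds no
    transcribed gene.
    """

    chromosome: str
    metric: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    n_transcribed: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


class RegionRatio(NamedTuple):
    count_class: int
    count_transcribed: int
    ratio: float | None


def window_metrics(
    dt_coords: pd.DataFrame,
    chromosome: str,
    chrom_length: int,
    window: int = 10 * MB,
    step: int = MB,
    assign: str = "start",
) -> dict:
    """Sliding-window class ratios, mean logFC and transcribed density.

    A gene belongs to a window iff its assignment position (gene ``start`` by
    default, optionally the midpoint) lies in ``[w_start, w_start + window)``.
    Returns a dict of metric name -> :class:`WindowTrack`.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    if assign not in ("start", "midpoint"):
        raise ValueError("assign must be 'start' or 'midpoint'")
    sub = dt_coords[dt_coords["chromosome"] == chromosome]
    if assign == "start":
        pos = sub["start"].to_numpy(dtype=np.int64)
    else:
        pos = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=np.int64)
    order = np.argsort(pos, kind="mergesort")
    pos = pos[order]
    cls = sub["dt_class"].to_numpy()[order]
    logfc = sub["logFC"].to_numpy(dtype=float)[order]

    starts = np.arange(0, chrom_length, step, dtype=np.int64)
    ends = np.minimum(starts + window, chrom_length)

    # prefix sums over position-sorted genes make each window an O(log n) query
    ind_up = np.concatenate(([0], np.cumsum(cls == "up")))
    ind_down = np.concatenate(([0], np.cumsum(cls == "down")))
    ind_not = np.concatenate(([0], np.cumsum(cls == "not_DT")))
    cum_fc = np.concatenate(([0.0], np.cumsum(logfc)))

    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    n_tr = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_up = np.where(n_tr > 0, (ind_up[hi] - ind_up[lo]) / n_tr, np.nan)
        r_down = np.where(n_tr > 0, (ind_down[hi] - ind_down[lo]) / n_tr, np.nan)
        r_not = np.where(n_tr > 0, (ind_not[hi] - ind_not[lo]) / n_tr, np.nan)
        mean_fc = np.where(n_tr > 0, (cum_fc[hi] - cum_fc[lo]) / n_tr, np.nan)

    n_int = (hi - lo).astype(np.int64)
    values = {
        "R_notDT_Trans": r_not,
        "R_Up_Trans": r_up,
        "R_Down_Trans": r_down,
        "mean_logFC": mean_fc,
        "transcribed_density": n_tr,
    }
    return {
        name: WindowTrack(chromosome, name, starts, ends, vals, n_int)
        for name, vals in values.items()
    }


# ---------------------------------------------------------------------------
# PELT segmentation


@dataclass
class SegmentSet:
    """Exact penalized segmentation of one track."""

    chromosome: str
    metric: str
    penalty: float
    breakpoints: list = field(default_factory=list)  # window indices
    segment_bounds_bp: list = field(default_factory=list)  # (start, end) bp
    segment_means: list = field(default_factory=list)
    window_starts: np.ndarray | None = None

    @property
    def changepoints_bp(self) -> list:
        return [int(self.window_starts[i]) for i in self.breakpoints]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "metric": self.metric,
                "start": [b[0] for b in self.segment_bounds_bp],
                "end": [b[1] for b in self.segment_bounds_bp],
                "mean": self.segment_means,
            }
        )


def impute_missing(values: np.ndarray) -> np.ndarray:
    """Replace NaNs with the nearest non-missing value (ties go left)."""
    values = np.asarray(values, dtype=float)
    ok = np.flatnonzero(~np.isnan(values))
    if ok.size == 0:
        raise ValueError("track has no non-missing windows")
    idx = np.arange(values.size)
    left = np.searchsorted(ok, idx, side="right") - 1
    right = np.clip(left + 1, 0, ok.size - 1)
    left = np.clip(left, 0, ok.size - 1)
    d_left = np.abs(idx - ok[left])
    d_right = np.abs(ok[right] - idx)
    nearest = np.where(d_left <= d_right, ok[left], ok[right])
    return values[nearest]


def resolve_penalty(penalty, n: int) -> float:
    """Numeric penalty for a track of ``n`` windows.

    ``MBIC`` -> 3 log n, ``BIC`` -> 2 log n, or a manual numeric beta; all
    applied to the variance-scaled Gaussian change-in-mean cost.
    """
    if isinstance(penalty, str):
        key = penalty.upper()
        if key == "MBIC":
            return 3.0 * np.log(n)
        if key in ("BIC", "SIC"):
            return 2.0 * np.log(n)
        raise ValueError(f"unknown penalty {penalty!r}")
    beta = float(penalty)
    if beta < 0:
        raise ValueError("penalty must be >= 0")
    return beta


def gaussian_cost_terms(values: np.ndarray):
    """Cumulative sums and global variance for the change-in-mean cost.

    The noise variance is estimated from first differences (robust to mean
    shifts): var(diff)/2.  Returns (cumsum, cumsum of squares, sigma2).
    """
    x = np.asarray(values, dtype=float)
    if x.size >= 2:
        d = np.diff(x)
        sigma2 = float(np.var(d)) / 2.0
    else:
        sigma2 = 0.0
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    return s1, s2, sigma2


def _segment_cost(s1, s2, sigma2, i, j):
    """Cost of segment x[i:j] (variance-scaled residual sum of squares)."""
    n = j - i
    ss = s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / n
    return ss / sigma2


def pelt_segment(
    track: WindowTrack,
    penalty="MBIC",
    min_size: int = 2,
) -> SegmentSet:
    """Exact PELT segmentation of a window track under a Gaussian mean cost.

    Minimizes ``sum(segment costs) + beta * (number of changepoints)`` where a
    segment's cost is its residual sum of squares divided by a global noise
    variance (estimated from first differences).  Missing windows are imputed
    from the nearest non-missing neighbour for segmentation only.  A constant
    track yields a single segment.
    """
    values = impute_missing(track.values)
    n = values.size
    if np.sum(~np.isnan(track.values)) < 2 or n < 2 * min_size:
        bounds = [(int(track.starts[0]), int(track.ends[-1]))]
        return SegmentSet(
            track.chromosome, track.metric, 0.0, [], bounds,
            [float(np.nanmean(values))], track.starts,
        )
    beta = resolve_penalty(penalty, n)
    value_var = float(np.var(values))
    scale = max(1.0, float(np.mean(values)) ** 2)
    if value_var <= 1e-18 * scale:  # constant up to rounding noise
        bounds = [(int(track.starts[0]), int(track.ends[-1]))]
        return SegmentSet(
            track.chromosome, track.metric, beta, [], bounds,
            [float(values.mean())], track.starts,
        )
    _, _, sigma2 = gaussian_cost_terms(values)
    # noiseless-but-stepped tracks would give sigma2 ~ 0; floor it relative
    # to the overall variance so costs stay finite
    sigma2 = max(sigma2, value_var * 1e-9)

    breakpoints = pelt_changepoints(values, beta, sigma2=sigma2, min_size=min_size)
    return _build_segment_set(track, values, breakpoints, beta)


def pelt_changepoints(
    values: np.ndarray,
    beta: float,
    sigma2: float | None = None,
    min_size: int = 2,
) -> list:
    """PELT recursion; returns interior changepoint indices.

    A changepoint at index ``i`` means a new segment starts at ``values[i]``.
    Candidates not yet eligible under ``min_size`` are exempt from pruning,
    which preserves exactness of the constrained optimum.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if sigma2 is None:
        _, _, sigma2 = gaussian_cost_terms(x)
        sigma2 = max(sigma2, 1e-300)
    s1, s2, _ = gaussian_cost_terms(x)

    f = np.full(n + 1, np.inf)
    f[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    candidates = [0]
    for t in range(min_size, n + 1):
        eligible = [s for s in candidates if t - s >= min_size]
        if not eligible:
            continue
        costs = np.array(
            [f[s] + _segment_cost(s1, s2, sigma2, s, t) + beta for s in eligible]
        )
        best = int(np.argmin(costs))
        f[t] = costs[best]
        prev[t] = eligible[best]
        kept = [
            s
            for s, c in zip(eligible, costs)
            if c - beta <= f[t] + 1e-9
        ]
        candidates = kept + [s for s in candidates if t - s < min_size] + [t]

    breakpoints = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            breakpoints.append(s)
        t = s
    return sorted(breakpoints)


def _build_segment_set(track, values, breakpoints, beta) -> SegmentSet:
    n = values.size
    edges = [0] + list(breakpoints) + [n]
    bounds, means = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        start_bp = int(track.starts[a])
        end_bp = int(track.starts[b]) if b < n else int(track.ends[-1])
        bounds.append((start_bp, end_bp))
        means.append(float(values[a:b].mean()))
    return SegmentSet(
        track.chromosome, track.metric, beta, list(breakpoints), bounds, means,
        track.starts,
    )


# ---------------------------------------------------------------------------
# segment profiles and deletion calls


def classify_segments(
    segments: SegmentSet,
    dt_coords: pd.DataFrame,
    fpkm_test: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene-level profile of each segment (not window-averaged).

    Counts classes and averages logFC over the transcribed genes whose start
    lies inside each segment's bp span; optionally averages a per-gene
    test-group mean FPKM series.
    """
    sub = dt_coords[dt_coords["chromosome"] == segments.chromosome]
    rows = []
    for (start_bp, end_bp), seg_mean in zip(
        segments.segment_bounds_bp, segments.segment_means
    ):
        inside = sub[(sub["start"] >= start_bp) & (sub["start"] < end_bp)]
        n = len(inside)
        n_up = int((inside["dt_class"] == "up").sum())
        n_down = int((inside["dt_class"] == "down").sum())
        n_not = int((inside["dt_class"] == "not_DT").sum())
        row = {
            "chromosome": segments.chromosome,
            "start": start_bp,
            "end": end_bp,
            "track_mean": seg_mean,
            "n_transcribed": n,
            "n_up": n_up,
            "n_down": n_down,
            "n_not_DT": n_not,
            "R_Up_Trans": n_up / n if n else np.nan,
            "R_Down_Trans": n_down / n if n else np.nan,
            "R_notDT_Trans": n_not / n if n else np.nan,
            "mean_logFC": float(inside["logFC"].mean()) if n else np.nan,
            "first_gene_start": int(inside["start"].min()) if n else -1,
            "last_gene_end": int(inside["end"].max()) if n else -1,
        }
        if fpkm_test is not None:
            vals = fpkm_test.reindex(inside.index)
            row["mean_fpkm_test"] = float(vals.mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DeletionCall:
    """A candidate chromosomal deletion inferred from expression loss."""

    chromosome: str
    start: int
    end: int
    n_transcribed: int
    n_down: int
    n_not_DT: int
    n_up: int
    mean_fpkm_test: float
    mean_logFC: float


def call_deletions(
    profile: pd.DataFrame,
    dt_coords: pd.DataFrame,
    fpkm_test: pd.Series,
    r_down_min: float = 0.9,
    r_up_max: float = 0.0,
    fpkm_max: float = 1.0,
    refine: bool = True,
    round_to: int = MB,
) -> list:
    """Call deletion candidates from gene-level segment profiles.

    A segment qualifies iff ``R_Down_Trans >= r_down_min``,
    ``R_Up_Trans <= r_up_max`` and test-group mean FPKM ``< fpkm_max``;
    adjacent qualifying segments are merged.  With ``refine`` the merged span
    is walked outwards gene by gene while the neighbouring transcribed genes
    are still down-regulated, which corrects boundaries that a mid-ramp
    window changepoint would otherwise truncate.  Reported bounds span the
    first to last transcribed gene, rounded outwards to ``round_to``.
    """
    if profile.empty:
        return []
    qualifies = (
        (profile["n_transcribed"] > 0)
        & (profile["R_Down_Trans"] >= r_down_min)
        & (profile["R_Up_Trans"] <= r_up_max)
        & (profile["mean_fpkm_test"] < fpkm_max)
    ).to_numpy()
    chromosome = profile["chromosome"].iloc[0]
    sub = dt_coords[dt_coords["chromosome"] == chromosome].sort_values("start")
    pos = sub["start"].to_numpy()
    cls = sub["dt_class"].to_numpy()
    ends_arr = sub["end"].to_numpy()

    calls = []
    i = 0
    while i < len(profile):
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(profile) and qualifies[j + 1]:
            j += 1
        span_start = int(profile["start"].iloc[i])
        span_end = int(profile["end"].iloc[j])
        lo = int(np.searchsorted(pos, span_start, side="left"))
        hi = int(np.searchsorted(pos, span_end, side="left"))
        if hi > lo:
            if refine:
                while lo > 0 and cls[lo - 1] == "down":
                    lo -= 1
                while hi < len(pos) and cls[hi] == "down":
                    hi += 1
            genes = sub.iloc[lo:hi]
            n = len(genes)
            n_down = int((genes["dt_class"] == "down").sum())
            n_up = int((genes["dt_class"] == "up").sum())
            n_not = int((genes["dt_class"] == "not_DT").sum())
            start_bp = int(pos[lo] // round_to * round_to)
            end_bp = int(-(-int(ends_arr[lo:hi].max()) // round_to) * round_to)
            calls.append(
                DeletionCall(
                    chromosome=chromosome,
                    start=start_bp,
                    end=end_bp,
                    n_transcribed=n,
                    n_down=n_down,
                    n_not_DT=n_not,
                    n_up=n_up,
                    mean_fpkm_test=float(fpkm_test.reindex(genes.index).mean()),
                    mean_logFC=float(genes["logFC"].mean()),
                )
            )
        i = j + 1
    return calls


def region_ratio(
    dt_coords: pd.DataFrame,
    chromosome: str,
    start: int,
    end: int,
    dt_class: str,
) -> RegionRatio:
    """Class-to-transcribed ratio over genes starting in ``[start, end]``.

    With no transcribed genes in the region the ratio is ``None`` (undefined)
    while both counts are still returned.
    """
    sub = dt_coords[
        (dt_coords["chromosome"] == chromosome)
        & (dt_coords["start"] >= start)
        & (dt_coords["start"] <= end)
    ]
    n = len(sub)
    k = int((sub["dt_class"] == dt_class).sum())
    return RegionRatio(k, n, k / n if n else None)
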