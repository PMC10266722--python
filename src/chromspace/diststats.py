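"""Signal as a function of inter-promoter distance.

Promoters are rank-ordered by the distance to their nearest upstream
promoter (largest first) and a sliding window one decile wide is slid over
the ranking; at each position the window median (or mean) of the signal is
plotted against the window median of the distance. The decile window is
forced odd so the two half-windows flanking the focal promoter are equal.

Also here: the upstream-window sum used for torsion (psoralen-intercalation)
tracks, a z-score outlier filter, threshold-stratified median comparisons
between conditions, and localization of the distance at which one
condition's curve starts to dominate another's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .matrices import oriented_window_values
from .spacing import PromoterRecord

__all__ = [
    "DistanceResponseCurve",
    "OutlierReport",
    "GroupComparison",
    "decile_window",
    "moving_median_curve",
    "stratum_medians",
    "threshold_group_medians",
    "upstream_sum",
    "filter_outliers",
    "switch_point",
]


@dataclass
class DistanceResponseCurve:
    """Moving-statistic curve of signal versus inter-promoter distance.

    ``points`` has columns ``median_distance``, ``median_signal``,
    ``n_window``, ordered by decreasing distance. ``window`` is the (odd)
    number of promoters per window; ``statistic`` applies to the signal
    (the distance coordinate is always the window median).
    """

    points: pd.DataFrame
    window: int
    statistic: str = "median"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        if self.statistic not in ("median", "mean"):
            raise ValueError("statistic must be 'median' or 'mean'")
        d = self.points["median_distance"].to_numpy()
        if len(d) > 1 and (np.diff(d) > 0).any():
            raise ValueError("points must be ordered by decreasing distance")

    @property
    def half_window(self) -> int:
        return (self.window - 1) // 2


@dataclass
class OutlierReport:
    """Record of a z-score outlier pass: the moments used and what was removed."""

    mean: float
    sd: float
    threshold_sds: float
    removed: list[tuple[str, float, float]]  # (promoter_id, value, z)


@dataclass
class GroupComparison:
    """Treated-vs-control medians within a distance stratum, with a rank test."""

    stratum: str
    threshold: int
    treated_median: float
    control_median: float
    n_treated: int
    n_control: int
    u_statistic: float
    p_value: float


def decile_window(n_promoters: int) -> int:
    """One tenth of the promoter set, forced odd.

    ``floor(n/10)``, minus one when even, so the window splits into the
    focal promoter plus two equal half-windows. With the 16,972 promoters
    of the fly promoter catalogue this gives 1,697 (half-windows of 848).
    """
    if n_promoters < 10:
        raise ValueError(f"need at least 10 promoters, got {n_promoters}")
    w = n_promoters // 10
    if w % 2 == 0:
        w -= 1
    return max(w, 1)


def _sorted_by_distance(signal: dict, distances: dict) -> pd.DataFrame:
    if set(signal) != set(distances):
        raise ValueError("signal and distance maps must have identical keys")
    ids = sorted(distances, key=lambda k: (-distances[k], k))  # ties broken by promoter ID
    return pd.DataFrame({"promoter_id": ids,
                         "distance": [float(distances[i]) for i in ids],
                         "signal": [float(signal[i]) for i in ids]})


def moving_median_curve(signal: dict, distances: dict, window: int | None = None,
                        statistic: str = "median") -> DistanceResponseCurve:
    """Sliding-window statistic of signal over the distance ranking.

    Promoters are sorted by distance, largest first (ties broken by ID).
    Every position with a full window contributes one point: the window
    median of distances on x, the window ``statistic`` of signal on y.
    Incomplete edge windows are dropped, preserving the equal-half-window
    symmetry. ``window`` defaults to :func:`decile_window` of the input size.
    """
    df = _sorted_by_distance(signal, distances)
    n = len(df)
    if window is None:
        window = decile_window(n)
    if window > n:
        raise ValueError(f"window {window} exceeds number of promoters {n}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    roll = df.rolling(window, center=True, min_periods=window)
    dist_med = roll["distance"].median()
    sig = roll["signal"].median() if statistic == "median" else roll["signal"].mean()
    keep = dist_med.notna()
    points = pd.DataFrame({"median_distance": dist_med[keep].to_numpy(),
                           "median_signal": sig[keep].to_numpy(),
                           "n_window": window})
    return DistanceResponseCurve(points, window=window, statistic=statistic)


def stratum_medians(signal: dict, distances: dict, threshold: int = 2000) -> dict:
    """Median signal for promoters closer / farther than a distance threshold."""
    df = _sorted_by_distance(signal, distances)
    close = df[df["distance"] < threshold]["signal"]
    far = df[df["distance"] >= threshold]["signal"]
    for name, s in (("close", close), ("far", far)):
        if s.empty:
            raise ValueError(f"empty stratum: no promoters with distance "
                             f"{'<' if name == 'close' else '>='} {threshold}")
    return {"close_median": float(close.median()), "far_median": float(far.median()),
            "n_close": int(len(close)), "n_far": int(len(far)), "threshold": threshold}


def threshold_group_medians(treated: dict, control: dict, distances: dict,
                            threshold: int = 2000) -> list[GroupComparison]:
    """Compare treated vs control signal within each distance stratum.

    Promoters are split at ``threshold`` bp of inter-promoter distance;
    within each stratum the treated and control signal distributions are
    summarized by their medians and compared by a two-sided Mann-Whitney U
    test (a rank test matching the median framing of the summary).
    """
    if set(treated) != set(control) or set(treated) != set(distances):
        raise ValueError("treated, control and distance maps must share keys")
    out = []
    for stratum, pred in (("close", lambda d: d < threshold),
                          ("far", lambda d: d >= threshold)):
        ids = [k for k in distances if pred(distances[k])]
        if not ids:
            raise ValueError(f"empty stratum {stratum!r} at threshold {threshold}")
        t = np.array([treated[i] for i in ids], dtype=float)
        c = np.array([control[i] for i in ids], dtype=float)
        if np.ptp(t) == 0 and np.ptp(c) == 0 and t[0] == c[0]:
            u, p = len(t) * len(c) / 2.0, 1.0  # identical constant samples
        else:
            u, p = stats.mannwhitneyu(t, c, alternative="two-sided")
        out.append(GroupComparison(stratum, threshold, float(np.median(t)),
                                   float(np.median(c)), len(t), len(c), float(u), float(p)))
    return out


def upstream_sum(track: CoverageTrack, promoters: list[PromoterRecord],
                 window: int = 200) -> dict[str, float]:
    """Total signal in the strand-oriented window ``[TSS-window, TSS)``.

    The region immediately upstream of the TSS is where transcription-
    generated negative supercoiling concentrates, so this is the summary
    used for torsion tracks. Truncated at chromosome ends.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = {}
    for p in promoters:
        vals = oriented_window_values(track, p, upstream=window, downstream=0)
        out[p.id] = float(np.nansum(vals))
    return out


def filter_outliers(values: dict[str, float], threshold_sds: float = 64.0,
                    mean: float | None = None, sd: float | None = None
                    ) -> tuple[dict[str, float], OutlierReport]:
    """Single-pass z-score filter: drop values more than ``threshold_sds``
    standard deviations above the mean (strict inequality).

    Mean and SD default to the full-sample moments of the input (sample SD,
    ddof=1) computed once before any removal; explicit ``mean``/``sd``
    override them when the moments come from elsewhere. SD of zero removes
    nothing (with a warning).
    """
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    arr = np.array(list(values.values()), dtype=float)
    m = float(np.mean(arr)) if mean is None else float(mean)
    s = float(np.std(arr, ddof=1)) if sd is None else float(sd)
    if s == 0:
        warnings.warn("standard deviation is zero; no outliers removed", stacklevel=2)
        return dict(values), OutlierReport(m, s, threshold_sds, [])
    removed = []
    kept = {}
    cut = m + threshold_sds * s  # strict >, so a value exactly at the cut survives
    for k, v in values.items():
        if v > cut:
            removed.append((k, float(v), float((v - m) / s)))
        else:
            kept[k] = v
    return kept, OutlierReport(m, s, threshold_sds, removed)


def switch_point(curve_a: DistanceResponseCurve,
                 curve_b: DistanceResponseCurve) -> float | None:
    """Distance below which curve_a consistently exceeds curve_b.

    Both curves must come from the same promoter ranking (equal length,
    matching distance coordinates). Scanning from the smallest distance,
    the longest suffix of points where ``a > b`` at every point is found;
    the returned estimate is the largest distance in that suffix — the
    point where consistent dominance begins. Returns None when curve_a
    does not dominate at the smallest distance (no switch).
    """
    a, b = curve_a.points, curve_b.points
    if len(a) != len(b):
        raise ValueError("curves have different numbers of points")
    if not np.allclose(a["median_distance"], b["median_distance"]):
        raise ValueError("curves are not on a shared distance coordinate")
    dominance = (a["median_signal"].to_numpy() > b["median_signal"].to_numpy())
    if len(dominance) == 0 or not dominance[-1]:
        return None
    i = len(dominance) - 1
    while i > 0 and dominance[i - 1]:
        i -= 1
    return float(a["median_distance"].iloc[i])
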