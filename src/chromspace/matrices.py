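"""TSS-anchored binned coverage matrices, promoter clustering, profiles.

The central container is :class:`CoverageMatrix`: one row per promoter, one
column per fixed-width bin (default 10 bp) spanning a window around the
TSS. Rows are strand-oriented — minus-strand windows are reversed so the
bin axis always runs upstream → downstream in the transcriptional sense.

Windows truncated at a chromosome end contribute only the covered bases;
bins that fall entirely outside the chromosome are recorded as NaN and
excluded from means (same edge policy as the deepTools matrix tools).
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .coverage import CoverageTrack
from .spacing import PromoterRecord

__all__ = [
    "CoverageMatrix",
    "ClusterAssignment",
    "compute_matrix",
    "kmeans_promoters",
    "apply_clusters",
    "mean_profile",
    "region_profile",
    "region_sum",
    "oriented_window_values",
    "write_matrix",
    "read_matrix",
    "write_cluster_regions",
    "roman",
]


def roman(n: int) -> str:
    """Roman numeral for a small positive integer (cluster labels I, II, ...)."""
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
                (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    if n <= 0:
        raise ValueError("roman() needs a positive integer")
    out = []
    for val, sym in numerals:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class CoverageMatrix:
    """Promoters x bins matrix of strand-oriented track signal.

    ``values[i, j]`` is the per-base mean (or sum, per ``statistic``) of the
    track over bin ``j`` of promoter ``rows[i]``; NaN marks bins outside
    the chromosome. Bin ``j`` covers oriented offsets
    ``[j*bin_size - upstream, (j+1)*bin_size - upstream)`` relative to the TSS.
    """

    rows: list[str]
    bin_size: int
    upstream: int
    downstream: int
    values: np.ndarray
    statistic: str = "mean"

    def __post_init__(self) -> None:
        n_bins = (self.upstream + self.downstream) // self.bin_size
        if self.values.shape != (len(self.rows), n_bins):
            raise ValueError(f"values shape {self.values.shape} != ({len(self.rows)}, {n_bins})")
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate row IDs")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0) < 0:
                raise ValueError("matrix values must be nonnegative")

    @property
    def n_bins(self) -> int:
        return (self.upstream + self.downstream) // self.bin_size

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centers in bp relative to the TSS (negative = upstream)."""
        j = np.arange(self.n_bins)
        return j * self.bin_size - self.upstream + self.bin_size / 2

    def same_grid(self, other: "CoverageMatrix") -> bool:
        return (self.bin_size == other.bin_size and self.upstream == other.upstream
                and self.downstream == other.downstream)

    def subset(self, ids) -> "CoverageMatrix":
        index = {r: i for i, r in enumerate(self.rows)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"IDs not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        sel = [index[i] for i in ids]
        return CoverageMatrix(list(ids), self.bin_size, self.upstream, self.downstream,
                              self.values[sel].copy(), self.statistic)


@dataclass
class ClusterAssignment:
    """Promoter → cluster label, with clusters named I..k by descending mean signal."""

    labels: dict[str, str]
    k: int
    seed: int

    def members(self, label: str) -> list[str]:
        return [pid for pid, lab in self.labels.items() if lab == label]

    @property
    def cluster_names(self) -> list[str]:
        return [roman(i + 1) for i in range(self.k)]


def oriented_window_values(track: CoverageTrack, promoter: PromoterRecord,
                           upstream: int, downstream: int) -> np.ndarray:
    """Per-base track values over ``[TSS-upstream, TSS+downstream)`` in
    transcriptional orientation; bases beyond the chromosome end are NaN.

    For a minus-strand promoter "downstream" runs toward smaller genomic
    coordinates: oriented offset ``o`` maps to genomic base ``tss - o``.
    """
    if promoter.chrom not in track.genome:
        raise ValueError(f"promoter {promoter.id!r} on undeclared chromosome {promoter.chrom!r}")
    clen = track.genome.length_of(promoter.chrom)
    arr = track.values[promoter.chrom]
    w = upstream + downstream
    out = np.full(w, np.nan)
    if promoter.strand == "+":
        g0 = promoter.tss - upstream
        lo, hi = max(g0, 0), min(g0 + w, clen)
        if hi > lo:
            out[lo - g0:hi - g0] = arr[lo:hi]
    else:
        # oriented offset o in [-upstream, downstream) -> genomic tss - o
        g0 = promoter.tss - downstream + 1  # genomic window [g0, g0 + w)
        lo, hi = max(g0, 0), min(g0 + w, clen)
        if hi > lo:
            rev = arr[lo:hi][::-1]
            # genomic hi-1 maps to oriented index (tss + upstream) - (hi - 1)
            start = (promoter.tss + upstream) - (hi - 1)
            out[start:start + (hi - lo)] = rev
    return out


def compute_matrix(track: CoverageTrack, promoters: list[PromoterRecord],
                   upstream: int = 2500, downstream: int = 2500, bin_size: int = 10,
                   statistic: str = "mean") -> CoverageMatrix:
    """Bin strand-oriented track signal around each promoter's TSS.

    ``bin_size`` must divide both flanks. Each bin value is the mean
    per-base signal within the bin (``statistic="sum"`` gives sums instead);
    partially covered edge bins use only the covered bases.
    """
    if bin_size <= 0 or upstream % bin_size or downstream % bin_size:
        raise ValueError("bin_size must be positive and divide both flanks")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    n_bins = (upstream + downstream) // bin_size
    vals = np.full((len(promoters), n_bins), np.nan)
    for i, p in enumerate(promoters):
        window = oriented_window_values(track, p, upstream, downstream)
        binned = window.reshape(n_bins, bin_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            vals[i] = np.nanmean(binned, axis=1) if statistic == "mean" \
                else np.nansum(binned, axis=1) + np.where(np.all(np.isnan(binned), axis=1),
                                                          np.nan, 0.0)
    return CoverageMatrix([p.id for p in promoters], bin_size, upstream, downstream, vals,
                          statistic)


def kmeans_promoters(matrix: CoverageMatrix, k: int, seed: int = 0,
                     n_init: int = 10) -> ClusterAssignment:
    """K-means (Euclidean) on matrix rows, relabeled I..k by descending mean.

    The relabeling makes cluster names reproducible across seeds: cluster I
    always has the highest mean signal. NaN bins are treated as zero for
    the distance computation. Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(matrix.rows) < k:
        raise ValueError(f"cannot form {k} clusters from {len(matrix.rows)} rows")
    X = np.nan_to_num(matrix.values, nan=0.0)
    if k == 1 or np.allclose(X, X[0]):
        if k > 1:
            warnings.warn("all rows identical: a single effective cluster", stacklevel=2)
        return ClusterAssignment({r: "I" for r in matrix.rows}, k=1, seed=seed)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(X)
    means = np.array([X[raw_labels == c].mean() if (raw_labels == c).any() else -np.inf
                      for c in range(k)])
    order = np.argsort(-means)  # descending mean signal
    rename = {int(c): roman(rank + 1) for rank, c in enumerate(order)}
    return ClusterAssignment({r: rename[int(l)] for r, l in zip(matrix.rows, raw_labels)},
                             k=k, seed=seed)


def apply_clusters(matrix: CoverageMatrix, clusters: ClusterAssignment) -> CoverageMatrix:
    """Reorder matrix rows by cluster (I first), then by descending row mean.

    Values are untouched; the reordering is stable and purely a row
    permutation, so clusters learned on one matrix can order another matrix
    of the same promoters (the cross-dataset sorting workflow).
    """
    missing = [r for r in matrix.rows if r not in clusters.labels]
    if missing:
        raise KeyError(f"rows without cluster assignment: {missing[:5]}"
                       f"{'...' if len(missing) > 5 else ''}")
    cluster_rank = {name: i for i, name in enumerate(clusters.cluster_names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(matrix.values, axis=1)
    order = sorted(range(len(matrix.rows)),
                   key=lambda i: (cluster_rank[clusters.labels[matrix.rows[i]]],
                                  -(row_means[i] if np.isfinite(row_means[i]) else -np.inf), i))
    return CoverageMatrix([matrix.rows[i] for i in order], matrix.bin_size, matrix.upstream,
                          matrix.downstream, matrix.values[order].copy(), matrix.statistic)


def mean_profile(matrix: CoverageMatrix, row_subset=None) -> pd.Series:
    """Per-bin arithmetic mean over the selected rows (all rows by default).

    Returns a Series indexed by bin center (bp relative to TSS). NaN bins
    are excluded bin-wise.
    """
    if row_subset is not None:
        row_subset = list(row_subset)
        if not row_subset:
            raise ValueError("row_subset must be nonempty")
        matrix = matrix.subset(row_subset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof = np.nanmean(matrix.values, axis=0)
    return pd.Series(prof, index=matrix.bin_centers, name="mean_signal")


def region_profile(tracks: dict[str, CoverageTrack], chrom: str, start: int, end: int,
                   bin_size: int = 10) -> pd.DataFrame:
    """Mean signal per fixed-width bin across a genomic region, per condition.

    Returns a DataFrame indexed by bin start coordinate with one column per
    condition. The last bin may be partial and averages only its covered
    bases.
    """
    if end <= start:
        raise ValueError("empty region")
    for name, track in tracks.items():
        if chrom not in track.genome or end > track.genome.length_of(chrom) or start < 0:
            raise ValueError(f"region {chrom}:{start}-{end} outside genome of track {name!r}")
    edges = np.arange(start, end, bin_size)
    out = {}
    for name, track in tracks.items():
        arr = track.values[chrom]
        out[name] = [float(arr[s:min(s + bin_size, end)].mean()) for s in edges]
    return pd.DataFrame(out, index=pd.Index(edges, name="bin_start"))


def region_sum(track: CoverageTrack, promoter: PromoterRecord,
               upstream: int = 100, downstream: int = 500) -> float:
    """Total signal over the strand-oriented window ``[TSS-upstream, TSS+downstream)``.

    The promoter-proximal summary used for distance-response analyses
    (default window 100 bp upstream to 500 bp downstream). Truncated at
    chromosome ends.
    """
    window = oriented_window_values(track, promoter, upstream, downstream)
    return float(np.nansum(window))


# ---------------------------------------------------------------------------
# I/O


def write_matrix(matrix: CoverageMatrix, path) -> None:
    """Gzipped TSV with a JSON header line (grid parameters and row order)."""
    header = {"bin_size": matrix.bin_size, "upstream": matrix.upstream,
              "downstream": matrix.downstream, "statistic": matrix.statistic}
    # mtime=0 keeps the gzip header reproducible run-to-run
    with open(path, "wb") as raw, gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
        fh = io.TextIOWrapper(gz)
        fh.write("#" + json.dumps(header) + "\n")
        pd.DataFrame(matrix.values, index=pd.Index(matrix.rows, name="promoter_id")).to_csv(
            fh, sep="\t", header=False)
        fh.flush()
        fh.detach()


def read_matrix(path) -> CoverageMatrix:
    with gzip.open(path, "rt") as fh:
        header = json.loads(fh.readline().lstrip("#"))
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    return CoverageMatrix(list(df.index.astype(str)), header["bin_size"], header["upstream"],
                          header["downstream"], df.to_numpy(dtype=float), header["statistic"])


def write_cluster_regions(promoters: list[PromoterRecord], clusters: ClusterAssignment,
                          path) -> None:
    """BED6 of promoters with the cluster label appended to the name column."""
    with open(path, "w") as fh:
        for p in promoters:
            lab = clusters.labels.get(p.id, "NA")
            fh.write(f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{p.id}|cluster_{lab}\t0\t{p.strand}\n")
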