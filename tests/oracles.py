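"""Brute-force reference implementations used only to check the package.

Each oracle recomputes a quantity by the most literal method available —
per-base membership counting, all-pairs search, explicit window slicing —
independently of the vectorized implementations under test.
"""

import statistics

import numpy as np


def pileup_oracle(frags, genome):
    """Per-base fragment depth by direct membership counting."""
    out = {}
    for chrom in genome.chrom_names:
        L = genome.length_of(chrom)
        xs = np.arange(L)
        sub = frags.intervals[frags.intervals["chrom"] == chrom]
        if len(sub) == 0:
            out[chrom] = np.zeros(L)
            continue
        s = sub["start"].to_numpy()[None, :]
        e = sub["end"].to_numpy()[None, :]
        out[chrom] = ((s <= xs[:, None]) & (xs[:, None] < e)).sum(axis=1).astype(float)
    return out


def oriented_base(track, promoter, offset):
    """Track value at oriented offset (0 = TSS, negative = upstream), or NaN."""
    g = promoter.tss + offset if promoter.strand == "+" else promoter.tss - offset
    clen = track.genome.length_of(promoter.chrom)
    if 0 <= g < clen:
        return float(track.values[promoter.chrom][g])
    return float("nan")


def matrix_oracle(track, promoters, upstream, downstream, bin_size):
    """Per-bin means by explicit per-base iteration."""
    n_bins = (upstream + downstream) // bin_size
    out = np.full((len(promoters), n_bins), np.nan)
    for i, p in enumerate(promoters):
        for j in range(n_bins):
            vals = []
            for b in range(bin_size):
                off = j * bin_size + b - upstream
                v = oriented_base(track, p, off)
                if v == v:  # not NaN
                    vals.append(v)
            if vals:
                out[i, j] = sum(vals) / len(vals)
    return out


def region_sum_oracle(track, promoter, upstream, downstream):
    total = 0.0
    for off in range(-upstream, downstream):
        v = oriented_base(track, promoter, off)
        if v == v:
            total += v
    return total


def spacing_oracle(promoters):
    """All-pairs nearest-upstream search with the documented tie-break."""
    out = {}
    for p in promoters:
        candidates = []
        for q in promoters:
            if q.chrom != p.chrom or q.id == p.id:
                continue
            if p.strand == "+" and q.tss < p.tss:
                candidates.append(q)
            elif p.strand == "-" and q.tss > p.tss:
                candidates.append(q)
        if not candidates:
            out[p.id] = (None, None, "none")
            continue
        best_d = min(abs(q.tss - p.tss) for q in candidates)
        nearest = [q for q in candidates if abs(q.tss - p.tss) == best_d]
        opposite = [q for q in nearest if q.strand != p.strand]
        pool = opposite if opposite else nearest
        q = min(pool, key=lambda r: r.id)
        out[p.id] = (q.id, best_d, "divergent" if q.strand != p.strand else "tandem")
    return out


def moving_median_oracle(signal, distances, window, statistic="median"):
    """Sliding medians by explicit sorting and slicing."""
    ids = sorted(distances, key=lambda k: (-distances[k], k))
    half = (window - 1) // 2
    points = []
    for i in range(half, len(ids) - half):
        win = ids[i - half:i + half + 1]
        d = statistics.median(distances[k] for k in win)
        s = (statistics.median(signal[k] for k in win) if statistic == "median"
             else statistics.fmean(signal[k] for k in win))
        points.append((d, s))
    return points
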