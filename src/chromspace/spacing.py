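"""Nearest-upstream promoter distances and divergent/tandem classification.

Closely spaced promoter pairs respond differently to chromatin-disrupting
drugs depending on their relative orientation. For every promoter we find
the nearest promoter *upstream of it in its own transcriptional sense* —
for a plus-strand promoter the largest TSS strictly to its left, for a
minus-strand promoter the smallest TSS strictly to its right — record the
TSS-to-TSS distance, and classify the pair:

* **divergent** — neighbor on the opposite strand (head-to-head, the two
  promoters transcribe away from each other);
* **tandem** — neighbor on the same strand (codirectional).

Promoters with no upstream neighbor on their chromosome get orientation
``none`` and are excluded from distance-stratified analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PromoterRecord",
    "SpacingAnnotation",
    "annotate_spacing",
    "orientation_fractions",
    "read_promoters_bed",
    "write_promoters_bed",
    "annotations_to_frame",
    "write_annotations",
]


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter anchored at a single TSS base (0-based), with strand."""

    chrom: str
    tss: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"promoter {self.id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"promoter {self.id!r}: negative TSS")


@dataclass(frozen=True)
class SpacingAnnotation:
    """Per-promoter nearest-upstream neighbor, distance, and orientation call."""

    promoter_id: str
    neighbor_id: str | None
    distance: int | None
    orientation: str  # divergent | tandem | none

    def __post_init__(self) -> None:
        if self.orientation not in ("divergent", "tandem", "none"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.neighbor_id is None) != (self.orientation == "none"):
            raise ValueError("orientation is 'none' iff there is no neighbor")
        if self.neighbor_id is not None and (self.distance is None or self.distance < 0):
            raise ValueError("neighbor present requires nonnegative distance")


def annotate_spacing(promoters: list[PromoterRecord]) -> list[SpacingAnnotation]:
    """Annotate each promoter with its nearest upstream neighbor.

    Upstream is relative to the focal promoter's own strand. Distance is
    TSS-to-TSS. When two upstream promoters are equidistant (same TSS,
    opposite strands) the opposite-strand one is chosen, else the
    lexicographically smaller ID — deterministic by construction.
    """
    seen: set[tuple[str, int, str]] = set()
    ids: set[str] = set()
    for p in promoters:
        key = (p.chrom, p.tss, p.strand)
        if key in seen:
            raise ValueError(f"duplicate promoter at {p.chrom}:{p.tss} strand {p.strand}")
        if p.id in ids:
            raise ValueError(f"duplicate promoter id {p.id!r}")
        seen.add(key)
        ids.add(p.id)

    by_chrom: dict[str, list[PromoterRecord]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)

    out: dict[str, SpacingAnnotation] = {}
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda p: (p.tss, p.id))
        tss = np.array([p.tss for p in recs])
        for i, p in enumerate(recs):
            if p.strand == "+":
                # largest TSS strictly less than our own
                j = int(np.searchsorted(tss, p.tss, side="left")) - 1
                target = tss[j] if j >= 0 else None
            else:
                j = int(np.searchsorted(tss, p.tss, side="right"))
                target = tss[j] if j < len(tss) else None
            if target is None:
                out[p.id] = SpacingAnnotation(p.id, None, None, "none")
                continue
            lo = int(np.searchsorted(tss, target, side="left"))
            hi = int(np.searchsorted(tss, target, side="right"))
            candidates = recs[lo:hi]
            opposite = [q for q in candidates if q.strand != p.strand]
            pool = opposite if opposite else candidates
            neighbor = min(pool, key=lambda q: q.id)
            orientation = "divergent" if neighbor.strand != p.strand else "tandem"
            out[p.id] = SpacingAnnotation(p.id, neighbor.id, int(abs(p.tss - neighbor.tss)),
                                          orientation)
    return [out[p.id] for p in promoters]


def orientation_fractions(annotations: list[SpacingAnnotation],
                          distance_cutoffs: list[int]) -> pd.DataFrame:
    """Fraction of divergent promoters among those closer than each cutoff.

    For each cutoff the denominator is the number of promoters with any
    upstream neighbor at distance < cutoff; the numerator counts the
    divergent ones. An empty stratum reports fraction NaN.
    """
    for c in distance_cutoffs:
        if c <= 0:
            raise ValueError("distance cutoffs must be positive")
    dist = np.array([a.distance if a.distance is not None else -1 for a in annotations])
    div = np.array([a.orientation == "divergent" for a in annotations])
    has = dist >= 0
    rows = []
    for c in distance_cutoffs:
        mask = has & (dist < c)
        n = int(mask.sum())
        nd = int((mask & div).sum())
        rows.append({"cutoff": c, "n_divergent": nd, "n_total": n,
                     "fraction": nd / n if n else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_promoters_bed(path) -> list[PromoterRecord]:
    """Read a BED6 promoter table; the TSS is the start of a 1-bp interval."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "name": str})
    return [PromoterRecord(r.chrom, int(r.start), r.strand, r.name) for r in df.itertuples()]


def write_promoters_bed(promoters: list[PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{p.id}\t0\t{p.strand}\n")


def annotations_to_frame(annotations: list[SpacingAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {"promoter_id": [a.promoter_id for a in annotations],
         "neighbor_id": [a.neighbor_id if a.neighbor_id is not None else "." for a in annotations],
         "distance": [a.distance if a.distance is not None else -1 for a in annotations],
         "orientation": [a.orientation for a in annotations]}
    )


def write_annotations(annotations: list[SpacingAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
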