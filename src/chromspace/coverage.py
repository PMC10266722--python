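"""Per-base coverage tracks from fragment intervals, with two calibrations.

Fragment libraries from tagmentation assays (CUT&Tag, CUTAC) arrive as
paired-end fragment intervals. This module piles them up into per-base
coverage and calibrates the result in either of two conventions:

* **spike** — multiply by ``spike_constant / spike_count`` where
  ``spike_count`` is the number of fragments mapped to a spike-in genome,
  so tracks are comparable across samples;
* **normcount** — the fraction of counts at each base scaled by the
  reference length, so uniformly distributed coverage reads exactly 1 at
  every position.

Tracks round-trip through 4-column bedGraph (0-based, half-open) with
adjacent equal-valued runs merged on write and zero runs omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import SyntheticGenome

__all__ = [
    "FragmentSet",
    "CoverageTrack",
    "SPIKE_CONSTANT",
    "spike_scale_factor",
    "fragment_pileup",
    "calibrate_spike",
    "calibrate_normcount",
    "read_bedgraph",
    "write_bedgraph",
]

#: Default numerator of the spike-in scaling factor. A configuration value,
#: not a law of nature; 10,000 is the conventional choice.
SPIKE_CONSTANT = 10_000


@dataclass
class FragmentSet:
    """A sample's fragment intervals plus its spike-in fragment count.

    ``intervals`` is a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open). ``spike_count`` is the number of fragments that
    mapped to the spike-in genome, carried verbatim for calibration.
    """

    intervals: pd.DataFrame
    sample_id: str = "sample"
    spike_count: int = 0

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"intervals must have columns {sorted(required)}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"fragment {bad} has start >= end")
        if self.spike_count < 0:
            raise ValueError("spike_count must be >= 0")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class CoverageTrack:
    """Per-base signal over a genome, with its calibration mode recorded.

    ``values`` maps chromosome name to a float64 array of per-base signal.
    ``calibration`` is one of ``raw``, ``spike``, ``normcount``;
    ``scale_used`` is the multiplicative factor that produced it (1 for raw).
    """

    genome: SyntheticGenome
    values: dict[str, np.ndarray]
    calibration: str = "raw"
    scale_used: float = 1.0

    def __post_init__(self) -> None:
        if self.calibration not in ("raw", "spike", "normcount"):
            raise ValueError(f"unknown calibration {self.calibration!r}")
        if self.calibration == "raw" and self.scale_used != 1.0:
            raise ValueError("raw tracks must have scale_used == 1")
        for chrom in self.genome.chrom_names:
            if chrom not in self.values:
                self.values[chrom] = np.zeros(self.genome.length_of(chrom))
        for chrom, arr in self.values.items():
            if chrom not in self.genome:
                raise ValueError(f"track has values for undeclared chromosome {chrom!r}")
            if len(arr) != self.genome.length_of(chrom):
                raise ValueError(
                    f"values for {chrom!r} have length {len(arr)}, "
                    f"expected {self.genome.length_of(chrom)}"
                )
            if len(arr) and float(np.min(arr)) < 0:
                raise ValueError(f"negative signal on {chrom!r}")

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    @classmethod
    def zeros(cls, genome: SyntheticGenome, calibration: str = "raw", scale_used: float = 1.0):
        return cls(genome, {c: np.zeros(genome.length_of(c)) for c in genome.chrom_names},
                   calibration, scale_used)


def spike_scale_factor(spike_count: int, spike_constant: int = SPIKE_CONSTANT,
                       sample_id: str = "") -> float:
    """Spike-in scaling factor: ``spike_constant / spike_count``.

    Raises if the spike count is zero — a sample with no spike-in fragments
    cannot be calibrated.
    """
    if spike_count <= 0:
        name = f" for sample {sample_id!r}" if sample_id else ""
        raise ValueError(
            f"cannot compute spike scale factor{name}: spike_count must be > 0, got {spike_count}"
        )
    return spike_constant / spike_count


def fragment_pileup(frags: FragmentSet, genome: SyntheticGenome) -> CoverageTrack:
    """Raw per-base fragment coverage (depth of overlapping fragments).

    The value at base ``x`` is the number of fragments whose half-open
    interval contains ``x``; consequently the track total equals the sum of
    fragment lengths exactly.
    """
    values = {c: np.zeros(genome.length_of(c)) for c in genome.chrom_names}
    df = frags.intervals
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            i = sub.index[0]
            raise ValueError(
                f"fragment {i} of sample {frags.sample_id!r} is on undeclared chromosome {chrom!r}"
            )
        clen = genome.length_of(chrom)
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if (starts < 0).any() or (ends > clen).any():
            bad = sub.index[(starts < 0) | (ends > clen)][0]
            rec = df.loc[bad]
            raise ValueError(
                f"fragment {bad} ({rec['chrom']}:{rec['start']}-{rec['end']}) of sample "
                f"{frags.sample_id!r} runs off chromosome {chrom!r} (length {clen})"
            )
        diff = np.zeros(clen + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        values[chrom] = np.cumsum(diff)[:-1]
    return CoverageTrack(genome, values, calibration="raw", scale_used=1.0)


def calibrate_spike(raw: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply a raw track by a spike-in scaling factor."""
    if raw.calibration != "raw":
        raise ValueError(f"calibrate_spike expects a raw track, got {raw.calibration!r}")
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    values = {c: arr * factor for c, arr in raw.values.items()}
    return CoverageTrack(raw.genome, values, calibration="spike", scale_used=float(factor))


def calibrate_normcount(raw: CoverageTrack, reference_length: int | None = None) -> CoverageTrack:
    """Normalized-count calibration.

    Each per-base value becomes its fraction of the track total multiplied
    by ``reference_length`` (the genome length by default), so that if
    coverage were uniformly distributed the track would read 1 everywhere.
    The operation is idempotent: a normcount track re-calibrated against the
    same reference length is unchanged.
    """
    total = raw.total
    if total <= 0:
        raise ValueError("cannot normalize an all-zero track")
    if reference_length is None:
        reference_length = raw.genome.total_length
    factor = reference_length / total
    values = {c: arr * factor for c, arr in raw.values.items()}
    return CoverageTrack(raw.genome, values, calibration="normcount", scale_used=factor)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as 4-column bedGraph, merging equal-valued runs.

    Zero-valued runs are omitted; a leading comment records the calibration
    so round-trips restore it. Values are written with ``repr`` so finite
    decimals survive exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"# chromspace calibration={track.calibration} scale={track.scale_used!r}\n")
        for chrom in track.genome.chrom_names:
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            # run boundaries: positions where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            vals = arr[starts]
            for s, e, v in zip(starts, ends, vals):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(path, genome: SyntheticGenome) -> CoverageTrack:
    """Read a 4-column bedGraph into a per-base track.

    Intervals must be sorted and non-overlapping within each chromosome;
    violations are rejected with the offending line number. Bases not
    covered by any interval are zero.
    """
    values = {c: np.zeros(genome.length_of(c)) for c in genome.chrom_names}
    calibration, scale = "raw", 1.0
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                if "calibration=" in line:
                    for tok in line.split():
                        if tok.startswith("calibration="):
                            calibration = tok.split("=", 1)[1]
                        elif tok.startswith("scale="):
                            scale = float(tok.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: undeclared chromosome {chrom!r}")
            if not (0 <= s < e <= genome.length_of(chrom)):
                raise ValueError(f"{path}:{lineno}: interval [{s},{e}) outside {chrom!r}")
            if s < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: unsorted or overlapping interval on {chrom!r}")
            last_end[chrom] = e
            values[chrom][s:e] = v
    if calibration == "raw":
        scale = 1.0
    return CoverageTrack(genome, values, calibration=calibration, scale_used=scale)
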