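"""Reference genome descriptions.

A genome here is nothing more than an ordered table of chromosome names and
lengths — enough to allocate per-base coverage arrays and to validate
coordinates. All coordinates throughout the package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SyntheticGenome", "read_chrom_sizes", "write_chrom_sizes"]


@dataclass(frozen=True)
class SyntheticGenome:
    """An ordered set of chromosomes with lengths in base pairs.

    Stands in for a real assembly's chromosome-size table; the field name
    is historical — real chromosome sizes load into the same type via
    :func:`read_chrom_sizes`.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(names) == 0:
            raise ValueError("genome must have at least one chromosome")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(names, lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        """Total genome length in base pairs (sum of chromosome lengths)."""
        return sum(self.chrom_lengths)

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome {list(self.chrom_names)}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes


def read_chrom_sizes(path) -> SyntheticGenome:
    """Read a UCSC-style two-column chromosome-size TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str})
    return SyntheticGenome(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


def write_chrom_sizes(genome: SyntheticGenome, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
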