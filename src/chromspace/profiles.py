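"""Drug-versus-control fold-change profiles and expression stratification.

A fold-change profile divides the per-bin average of a treated matrix by
the per-bin average of the control matrix over the same promoters —
means first, then the ratio, matching how average metaprofiles are
compared. No pseudocount is applied: bins whose control mean is zero (or
missing) propagate as NaN gaps.

Expression quintiles split promoters into descending fifths by expression:
Q1 holds the most highly expressed genes, Q5 the least. Ranking always
uses raw expression values; ``log_display_transform`` (log10(x+1)) exists
purely so zero-expression genes remain visible on log-scale plots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import CoverageMatrix, mean_profile

__all__ = [
    "FoldChangeProfile",
    "QuintileAssignment",
    "foldchange_profile",
    "expression_quintiles",
    "log_display_transform",
    "stratified_profiles",
]

QUINTILE_NAMES = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclass
class FoldChangeProfile:
    """Per-bin treated/control ratio around the TSS.

    ``bins`` are bin centers in bp relative to the TSS; ``ratio`` is the
    per-bin (treated mean)/(control mean), log2-transformed when
    ``scale == "log2"``; NaN marks bins with no defined ratio.
    """

    bins: np.ndarray
    ratio: np.ndarray
    scale: str = "linear"
    groups: tuple[str, str] = ("treated", "control")
    subset: str = "all"
    n_rows: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError("scale must be 'linear' or 'log2'")
        if len(self.bins) != len(self.ratio):
            raise ValueError("bins and ratio differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bins, "ratio": self.ratio,
                             "scale": self.scale, "subset": self.subset,
                             "n_rows": self.n_rows})


@dataclass
class QuintileAssignment:
    """Promoter → expression quintile (Q1 = highest, Q5 = lowest).

    Contiguous blocks of the descending expression ranking, sizes as equal
    as possible with remainders going to the top quintiles; expression
    ties broken by promoter ID.
    """

    labels: dict[str, str]

    def members(self, quintile: str) -> list[str]:
        return [k for k, v in self.labels.items() if v == quintile]


def foldchange_profile(treated: CoverageMatrix, control: CoverageMatrix,
                       subset=None, scale: str = "linear",
                       subset_label: str = "all") -> FoldChangeProfile:
    """Per-bin ratio of treated to control mean profiles over a row subset.

    Both matrices must share the bin grid and (at least) the subset rows.
    The ratio is taken between the per-bin means, not averaged per-row
    ratios. Control-zero bins give NaN (no pseudocount).
    """
    if not treated.same_grid(control):
        raise ValueError("matrices are on different bin grids")
    ids = list(subset) if subset is not None else list(treated.rows)
    if not ids:
        raise ValueError("subset must be nonempty")
    t = mean_profile(treated, ids).to_numpy()
    c = mean_profile(control, ids).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, t / c, np.nan)
        if scale == "log2":
            ratio = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), np.nan)
    return FoldChangeProfile(treated.bin_centers, ratio, scale=scale,
                             subset=subset_label, n_rows=len(ids))


def expression_quintiles(expression: dict[str, float]) -> QuintileAssignment:
    """Split genes into five descending-expression fifths.

    The ranking is by raw expression value (ties broken by promoter ID for
    determinism); block sizes differ by at most one, with the larger
    blocks at the top. Adding any constant to all values leaves the
    assignment unchanged.
    """
    if len(expression) < 5:
        raise ValueError(f"need at least 5 genes, got {len(expression)}")
    ids = sorted(expression, key=lambda k: (-expression[k], k))
    labels: dict[str, str] = {}
    for q, block in zip(QUINTILE_NAMES, np.array_split(np.array(ids, dtype=object), 5)):
        for pid in block:
            labels[str(pid)] = q
    return QuintileAssignment(labels)


def log_display_transform(expression: dict[str, float]) -> dict[str, float]:
    """log10(x + 1) display transform; never used for quintile ranking."""
    out = {}
    for k, v in expression.items():
        if v < 0:
            raise ValueError(f"negative expression value for {k!r}: {v}")
        out[k] = math.log10(v + 1.0)
    return out


def stratified_profiles(treated: CoverageMatrix, control: CoverageMatrix,
                        quintiles: QuintileAssignment,
                        orientations: dict[str, str],
                        scale: str = "linear") -> list[FoldChangeProfile]:
    """One fold-change profile per (quintile, orientation) stratum.

    ``orientations`` maps promoter ID to 'divergent'/'tandem' (promoters
    with other values are left out). Empty strata are omitted with a
    warning rather than raising — sparse corners are expected.
    """
    profiles = []
    row_set = set(treated.rows) & set(control.rows)
    for q in QUINTILE_NAMES:
        q_members = set(quintiles.members(q))
        for orient in ("divergent", "tandem"):
            ids = sorted(pid for pid in q_members
                         if orientations.get(pid) == orient and pid in row_set)
            if not ids:
                warnings.warn(f"empty stratum ({q}, {orient}); omitted", stacklevel=2)
                continue
            prof = foldchange_profile(treated, control, subset=ids, scale=scale,
                                      subset_label=f"{q}:{orient}")
            profiles.append(prof)
    return profiles
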