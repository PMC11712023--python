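"""Sucrose-fraction co-migration screening and co-IP uniqueness logic.

Membrane compartments separated on a sucrose step gradient leave each
protein with an abundance profile across the collected fractions
(6/12%, 12%, 12/18%, 18/25% interphases and fractions in the original
gradient).  Proteins whose row-normalized profile correlates with a tagged
bait's profile (Pearson r above a strict cutoff, 0.8 by convention) are
candidate co-residents; intersecting those with proteins detected only in
the bait co-IP — not in the untagged control — yields high-confidence
interactor candidates.

With only four fractions a Pearson coefficient is coarse; the module
refuses tables with fewer than three fractions and reports zero-variance
profiles (undefined r) in an exclusion list rather than scoring them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError

__all__ = [
    "FractionProfileTable",
    "ComigrationResult",
    "CoIPComparison",
    "normalize_profiles",
    "bait_correlation",
    "coip_unique",
    "cross_reference",
]

DEFAULT_FRACTIONS = ("6/12%", "12%", "12/18%", "18/25%")


@dataclass(frozen=True)
class FractionProfileTable:
    """Protein × fraction abundance table with a designated bait row.

    ``abundances`` is a DataFrame indexed by protein id with one column per
    ordered fraction label; values are nonnegative (relative band/peptide
    intensities).  ``bait_id`` names the reference protein whose profile the
    screen correlates against.
    """

    abundances: pd.DataFrame
    bait_id: str
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.abundances
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate protein ids: {dupes[:5]}")
        if df.shape[1] < 2:
            raise InputError("need >= 2 fractions")
        if self.bait_id not in df.index:
            raise InputError(f"bait {self.bait_id!r} not in table")
        vals = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InputError("abundances must be finite and nonnegative")

    @property
    def protein_ids(self) -> list:
        return list(self.abundances.index)

    @property
    def fraction_labels(self) -> list:
        return list(self.abundances.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.abundances)

    @classmethod
    def from_csv(cls, path, bait_id: str, sep: str = None) -> "FractionProfileTable":
        """Load a protein_id-indexed CSV/TSV (first column = protein id)."""
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        return cls(abundances=df, bait_id=bait_id)


@dataclass(frozen=True)
class ComigrationResult:
    """Per-protein Pearson r versus the bait profile, and the passing set."""

    r_by_protein: pd.Series
    cutoff: float
    passing_set: frozenset
    n_detected: int
    n_passing: int
    undefined_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.n_passing != len(self.passing_set):
            raise InputError("n_passing must equal |passing_set|")

    def to_frame(self) -> pd.DataFrame:
        out = self.r_by_protein.rename("pearson_r").to_frame()
        out["passes"] = out.index.isin(self.passing_set)
        return out


@dataclass(frozen=True)
class CoIPComparison:
    """Proteins detected with the tagged bait vs an untagged control."""

    bait_detected: frozenset
    control_detected: frozenset
    unique_to_bait: frozenset = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "unique_to_bait", frozenset(self.bait_detected - self.control_detected)
        )


def normalize_profiles(table: FractionProfileTable) -> tuple[FractionProfileTable, list]:
    """Row-normalize each protein's profile to sum to 1.

    Mirrors plotting each component's quantitative distribution across
    fractions.  Proteins whose total abundance is zero cannot be normalized;
    they are dropped and returned in an exclusion report instead of raising.

    Returns ``(normalized_table, excluded_ids)``.
    """
    df = table.abundances
    totals = df.sum(axis=1)
    excluded = list(df.index[totals <= 0])
    if table.bait_id in excluded:
        raise AnalysisError("bait profile has zero total abundance")
    kept = df.loc[totals > 0]
    normed = kept.div(kept.sum(axis=1), axis=0)
    return (
        FractionProfileTable(abundances=normed, bait_id=table.bait_id, normalized=True),
        excluded,
    )


def bait_correlation(table: FractionProfileTable, cutoff: float = 0.8) -> ComigrationResult:
    """Pearson correlation of every protein's profile with the bait's.

    Passing requires **strictly** ``r > cutoff``.  Zero-variance profiles
    have undefined r (reported as NaN, listed in ``undefined_ids``) and
    never pass.  The bait itself correlates at r = 1 and is included in the
    passing set, as it is in the detected-protein count.
    """
    if table.abundances.shape[1] < 3:
        raise AnalysisError("co-migration screening requires >= 3 fractions")
    X = table.abundances.to_numpy(dtype=float)
    bait = table.abundances.loc[table.bait_id].to_numpy(dtype=float)
    if bait.std() == 0:
        raise AnalysisError("bait profile has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    bc = bait - bait.mean()
    row_ss = (Xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ bc) / np.sqrt(row_ss * (bc**2).sum())
    r[row_ss == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    series = pd.Series(r, index=table.abundances.index, name="pearson_r")
    undefined = tuple(series.index[series.isna()])
    passing = frozenset(series.index[series > cutoff])
    return ComigrationResult(
        r_by_protein=series,
        cutoff=cutoff,
        passing_set=passing,
        n_detected=table.n_proteins,
        n_passing=len(passing),
        undefined_ids=undefined,
    )


def coip_unique(bait_detected, control_detected) -> CoIPComparison:
    """Set difference of co-IP detections: bait \\ control."""
    return CoIPComparison(
        bait_detected=frozenset(bait_detected),
        control_detected=frozenset(control_detected),
    )


def cross_reference(coip: CoIPComparison, comig: ComigrationResult) -> pd.DataFrame:
    """Proteins supported by both lines of evidence, with their r values.

    Returns a DataFrame (indexed by protein id, column ``pearson_r``) of ids
    that are both unique to the bait co-IP and above the co-migration
    cutoff — the shape of evidence behind the exocyst-subunit candidates.
    """
    overlap = sorted(coip.unique_to_bait & comig.passing_set)
    return comig.r_by_protein.loc[overlap].to_frame()
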