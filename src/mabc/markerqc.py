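"""Marker QC filter cascade.

Reproduces the array-genotyping filter cascade used before ABH encoding:
(1) "functional" markers — complete (or near-complete) call rate,
(2) minor-allele-frequency filter (default MAF >= 0.001, removing
monomorphic markers and genotyping artifacts),
(3) parent-polymorphism filter — only markers at which the recurrent
and donor parents carry different homozygous genotypes are informative
for ABH encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "functional_filter",
    "maf_filter",
    "parent_polymorphic_filter",
    "qc_report",
]


@dataclass
class FilterReport:
    """Counts and removed-marker lists of the QC cascade."""

    n_input: int
    n_functional: int
    n_after_maf: int
    n_parent_polymorphic: int
    removed_functional: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_parent: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (self.n_input, self.n_functional, self.n_after_maf, self.n_parent_polymorphic)
        if any(a < b for a, b in zip(counts, counts[1:])) or counts[-1] < 0:
            raise ValueError(f"filter cascade counts must be nonincreasing: {counts}")
        if self.n_input - self.n_functional != len(self.removed_functional):
            raise ValueError("functional removed-list inconsistent with counts")
        if self.n_functional - self.n_after_maf != len(self.removed_maf):
            raise ValueError("MAF removed-list inconsistent with counts")
        if self.n_after_maf - self.n_parent_polymorphic != len(self.removed_parent):
            raise ValueError("parent removed-list inconsistent with counts")
        sets = (set(self.removed_functional), set(self.removed_maf), set(self.removed_parent))
        if len(sets[0] | sets[1] | sets[2]) != sum(len(s) for s in sets):
            raise ValueError("removed-marker lists overlap")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "functional", "maf", "parent_polymorphic"],
                "n_markers": [
                    self.n_input,
                    self.n_functional,
                    self.n_after_maf,
                    self.n_parent_polymorphic,
                ],
                "n_removed": [
                    0,
                    len(self.removed_functional),
                    len(self.removed_maf),
                    len(self.removed_parent),
                ],
            }
        )


def functional_filter(
    matrix: GenotypeMatrix, max_missing_fraction: float = 0.0
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep markers whose missing-call fraction is <= threshold.

    The default 0 keeps only markers with complete data ("functional"
    markers); the threshold is exposed for real-world tolerance.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss = (matrix.calls == MISSING).mean(axis=0) if matrix.n_samples else np.zeros(matrix.n_markers)
    keep = miss <= max_missing_fraction
    removed = matrix.panel.ids[~keep].tolist()
    return matrix.subset_markers(keep), removed


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF over all non-missing calls of all samples.

    All-missing markers get MAF 0 (monomorphic by vacuity).
    """
    calls = matrix.calls
    nonmiss = calls != MISSING
    alt = np.where(nonmiss, calls, 0).sum(axis=0)  # alt dosage sum
    total = 2 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def maf_filter(
    matrix: GenotypeMatrix, min_maf: float = 0.001
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove monomorphic markers and markers with MAF < ``min_maf``.

    The keep rule is inclusive at the bound (MAF >= min_maf) but
    monomorphic markers (MAF = 0) are always removed — the filter's
    purpose is to exclude both genotyping artifacts and monomorphic
    markers, so ``maf_filter(matrix, 0)`` removes exactly the
    monomorphic ones.  MAF is computed on the full matrix including
    parental controls.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = minor_allele_frequency(matrix)
    keep = (maf >= min_maf) & (maf > 0)
    removed = matrix.panel.ids[~keep].tolist()
    return matrix.subset_markers(keep), removed


def parent_polymorphic_filter(
    matrix: GenotypeMatrix, sheet: SampleSheet
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep markers with different fixed (homozygous) parental genotypes.

    Markers at which either parent is heterozygous or missing are not
    informative for ABH encoding and are removed.
    """
    try:
        rp = matrix.row(sheet.recurrent_parent_id)
        dp = matrix.row(sheet.donor_parent_id)
    except KeyError as e:
        raise ValueError(f"parent sample absent from matrix: {e.args[0]}") from None
    fixed = np.isin(rp, (HOM_REF, HOM_ALT)) & np.isin(dp, (HOM_REF, HOM_ALT))
    keep = fixed & (rp != dp)
    removed = matrix.panel.ids[~keep].tolist()
    return matrix.subset_markers(keep), removed


def qc_report(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    max_missing_fraction: float = 0.0,
    min_maf: float = 0.001,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the cascade functional -> MAF -> parent-polymorphic.

    Returns the fully filtered matrix plus the counts report.
    """
    n_input = matrix.n_markers
    m1, rem_f = functional_filter(matrix, max_missing_fraction)
    m2, rem_m = maf_filter(m1, min_maf)
    m3, rem_p = parent_polymorphic_filter(m2, sheet)
    report = FilterReport(
        n_input=n_input,
        n_functional=m1.n_markers,
        n_after_maf=m2.n_markers,
        n_parent_polymorphic=m3.n_markers,
        removed_functional=rem_f,
        removed_maf=rem_m,
        removed_parent=rem_p,
    )
    logger.info(
        "QC cascade: %d -> %d functional -> %d after MAF -> %d parent-polymorphic",
        report.n_input, report.n_functional, report.n_after_maf, report.n_parent_polymorphic,
    )
    return m3, report
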