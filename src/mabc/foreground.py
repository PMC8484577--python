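"""Marker-assisted foreground selection.

Identifies progeny carrying the target mutant allele(s) — heterozygous
at one target locus for a BC1, at both loci for an F1 x F1 double
hybrid — and tests the observed class counts against the expected
Mendelian segregation ratio (1:1 for BC1 carriers : non-carriers,
1:1:1:1 for the joint two-locus carrier classes of a double cross) with
a Pearson chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genio import GenotypeMatrix, HET, MISSING
from .genome import MarkerPanel

__all__ = [
    "TargetLocus",
    "SegregationResult",
    "CarrierSelection",
    "resolve_marker",
    "select_carriers",
    "chi_square_ratio_test",
    "bc1_segregation_test",
    "f1xf1_segregation_test",
]


@dataclass(frozen=True)
class TargetLocus:
    """A target mutation locus, mapped to a marker column.

    ``marker_id`` designates the assaying marker directly; otherwise the
    marker on ``chromosome`` nearest to ``cm`` is used.  The expected
    carrier genotype is heterozygous for the donor (mutant) allele.
    """

    locus_id: str
    chromosome: str
    cm: float
    bp: "int | None" = None
    marker_id: "str | None" = None


def resolve_marker(panel: MarkerPanel, locus: TargetLocus) -> int:
    """Column index of the marker assaying ``locus``."""
    if locus.marker_id is not None:
        return panel.index_of(locus.marker_id)
    on_chrom = np.flatnonzero(panel.chromosomes == locus.chromosome)
    if on_chrom.size == 0:
        raise KeyError(f"no markers on chromosome {locus.chromosome!r}")
    cm = panel.cm[on_chrom]
    if np.isnan(cm).all():
        raise KeyError(
            f"markers on {locus.chromosome} have no cM positions; designate marker_id"
        )
    return int(on_chrom[np.nanargmin(np.abs(cm - locus.cm))])


@dataclass
class CarrierSelection:
    """Outcome of foreground selection at the target loci."""

    carriers: list[str]
    non_carriers: list[str]
    unclassified: list[str]  # missing call at >= 1 target locus
    marker_ids: list[str] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return len(self.carriers) + len(self.non_carriers)


def select_carriers(matrix: GenotypeMatrix, loci: list[TargetLocus]) -> CarrierSelection:
    """Samples heterozygous at every target locus.

    Samples with a missing call at any target locus are reported
    separately and never classified.
    """
    if not loci:
        raise ValueError("need at least one target locus")
    cols = [resolve_marker(matrix.panel, l) for l in loci]
    sub = matrix.calls[:, cols]
    any_missing = (sub == MISSING).any(axis=1)
    all_het = (sub == HET).all(axis=1)
    ids = np.asarray(matrix.sample_ids)
    return CarrierSelection(
        carriers=ids[all_het & ~any_missing].tolist(),
        non_carriers=ids[~all_het & ~any_missing].tolist(),
        unclassified=ids[any_missing].tolist(),
        marker_ids=[str(matrix.panel.ids[c]) for c in cols],
    )


@dataclass
class SegregationResult:
    """Pearson chi-square goodness-of-fit to a segregation ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    statistic: float
    df: int
    pvalue: float
    class_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.statistic >= 0 and 0 <= self.pvalue <= 1
        assert self.df == len(self.observed) - 1


def chi_square_ratio_test(
    observed: "list[int] | tuple[int, ...]",
    expected_ratio: "list[float] | tuple[float, ...]" = (1, 1),
    class_labels: tuple[str, ...] = (),
) -> SegregationResult:
    """Test observed class counts against an expected ratio.

    Pearson statistic sum((O-E)^2 / E) with E = total * ratio/sum(ratio);
    upper-tail p-value from the chi-square distribution with
    (classes - 1) degrees of freedom.  No continuity correction.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need at least two classes")
    if obs.size != ratio.size:
        raise ValueError("observed and ratio lengths differ")
    if (obs < 0).any():
        raise ValueError("negative counts")
    if (ratio <= 0).any():
        raise ValueError("expected ratio terms must be positive")
    total = obs.sum()
    if total == 0:
        raise ValueError("zero total count")
    expected = total * ratio / ratio.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    pvalue = float(stats.chi2.sf(stat, df))
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(r) for r in ratio),
        statistic=stat,
        df=df,
        pvalue=pvalue,
        class_labels=class_labels,
    )


def bc1_segregation_test(matrix: GenotypeMatrix, locus: TargetLocus) -> SegregationResult:
    """1:1 carrier : non-carrier test at a single BC1 target locus.

    Missing-genotype samples are excluded from the denominator.
    """
    sel = select_carriers(matrix, [locus])
    return chi_square_ratio_test(
        (len(sel.carriers), len(sel.non_carriers)),
        (1, 1),
        class_labels=("het", "hom"),
    )


def f1xf1_segregation_test(
    matrix: GenotypeMatrix, loci: list[TargetLocus]
) -> SegregationResult:
    """1:1:1:1 test over the joint two-locus classes of a double cross.

    Classes are het/het, het/hom, hom/het, hom/hom, where "hom" is any
    homozygote (non-carrier) at that locus; samples missing at either
    locus are excluded.
    """
    if len(loci) != 2:
        raise ValueError("double-cross segregation needs exactly two loci")
    cols = [resolve_marker(matrix.panel, l) for l in loci]
    sub = matrix.calls[:, cols]
    ok = (sub != MISSING).all(axis=1)
    het = sub[ok] == HET
    labels = ("het/het", "het/hom", "hom/het", "hom/hom")
    counts = (
        int((het[:, 0] & het[:, 1]).sum()),
        int((het[:, 0] & ~het[:, 1]).sum()),
        int((~het[:, 0] & het[:, 1]).sum()),
        int((~het[:, 0] & ~het[:, 1]).sum()),
    )
    return chi_square_ratio_test(counts, (1, 1, 1, 1), class_labels=labels)
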