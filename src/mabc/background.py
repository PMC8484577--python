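"""Genomic background selection.

The core statistic: encode progeny genotypes relative to the two
parents (A = homozygous recurrent, B = homozygous donor, H =
heterozygous) and score each plant's recurrent-parent genome share

    share(%) = (2 * n_A + 1 * n_H) / (2 * (n_A + n_H + n_B)) * 100,

i.e. the fraction of scored alleles that descend from the recurrent
parent.  Missing calls are excluded from the denominator, which keeps
share_recurrent + share_donor = 100 exactly.  Expected values are 75%
for a BC1, 100*(1 - (1/2)^(t+1)) for t backcrosses, and 50% for an
F1 x F1 double hybrid; background selection keeps the plants above the
expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import (
    ABH_A,
    ABH_B,
    ABH_H,
    ABHMatrix,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleSheet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeShareRecord",
    "ShareReport",
    "encode_abh",
    "genome_share",
    "genome_share_table",
    "expected_share",
    "share_report",
    "per_chromosome_share",
    "ABHMatrix",
]


def encode_abh(matrix: GenotypeMatrix, sheet: SampleSheet) -> ABHMatrix:
    """Recode calls relative to the parents.

    Per marker the recurrent parent's homozygous allele defines A and
    the donor's defines B; heterozygotes become H, missing stays
    missing.  The matrix must already be parent-polymorphic-filtered:
    a marker whose parents are not fixed for different alleles is a
    pipeline-ordering violation and raises.
    """
    sheet.check_matches(matrix)
    rp = matrix.row(sheet.recurrent_parent_id)
    dp = matrix.row(sheet.donor_parent_id)
    informative = np.isin(rp, (HOM_REF, HOM_ALT)) & np.isin(dp, (HOM_REF, HOM_ALT)) & (rp != dp)
    if not informative.all():
        bad = matrix.panel.ids[~informative][:5].tolist()
        raise ValueError(
            f"markers not fixed-polymorphic between parents reached ABH encoding: {bad}"
            " — run parent_polymorphic_filter first"
        )
    calls = matrix.calls
    # donor-allele dosage == ABH code (A=0, H=1, B=2)
    abh = np.where(rp == HOM_REF, calls, 2 - calls).astype(np.int8)
    abh[calls == MISSING] = MISSING
    return ABHMatrix(
        list(matrix.sample_ids),
        matrix.panel,
        abh,
        recurrent_parent=sheet.recurrent_parent_id,
        donor_parent=sheet.donor_parent_id,
    )


@dataclass
class GenomeShareRecord:
    """Per-plant ABH call counts and genome shares (%)."""

    sample_id: str
    n_a: int
    n_h: int
    n_b: int
    n_missing: int
    share_recurrent: float
    share_donor: float


def _counts(row: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int((row == ABH_A).sum()),
        int((row == ABH_H).sum()),
        int((row == ABH_B).sum()),
        int((row == MISSING).sum()),
    )


def genome_share(abh: ABHMatrix, sample_id: str, parent: str = "recurrent") -> GenomeShareRecord:
    """Weighted-allele genome share of one plant.

    (2*hom + het) / (2 * scored markers) * 100 for the requested
    parent; "total number of alleles" counts only non-missing calls.
    """
    if parent not in ("recurrent", "donor"):
        raise ValueError("parent must be 'recurrent' or 'donor'")
    n_a, n_h, n_b, n_miss = _counts(abh.row(sample_id))
    scored = n_a + n_h + n_b
    if scored == 0:
        raise ValueError(f"sample {sample_id!r} has no non-missing ABH calls")
    share_r = 100.0 * (2 * n_a + n_h) / (2 * scored)
    share_d = 100.0 * (2 * n_b + n_h) / (2 * scored)
    # the record carries both shares; `parent` only names the one asked about
    return GenomeShareRecord(sample_id, n_a, n_h, n_b, n_miss, share_r, share_d)


def genome_share_table(abh: ABHMatrix, sample_ids: "list[str] | None" = None) -> pd.DataFrame:
    """Genome-share records for many samples as a DataFrame (matrix order)."""
    ids = sample_ids if sample_ids is not None else abh.sample_ids
    rows = [genome_share(abh, s) for s in ids]
    n_b_progeny = sum(r.n_b for r in rows)
    if n_b_progeny:
        logger.info("genome_share_table: %d B calls across %d samples", n_b_progeny, len(rows))
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "n_a": [r.n_a for r in rows],
            "n_h": [r.n_h for r in rows],
            "n_b": [r.n_b for r in rows],
            "n_missing": [r.n_missing for r in rows],
            "share_recurrent": [r.share_recurrent for r in rows],
            "share_donor": [r.share_donor for r in rows],
        }
    )


def expected_share(scheme_kind: str, n_backcrosses: "int | None" = None) -> float:
    """Expected recurrent-parent genome share (%) of a cross type.

    Backcross series: 100 * (1 - (1/2)^(t+1)) after t backcrosses
    (BC1 -> 75, BC2 -> 87.5); F1 x F1 double hybrids -> 50.
    """
    kind = scheme_kind.replace("_", "").replace("×", "x")
    if kind.upper() in ("F1XF1", "F1F1"):
        return 50.0
    if kind.upper().startswith("BC"):
        if n_backcrosses is None:
            tail = kind[2:]
            if not tail.isdigit():
                raise ValueError(f"cannot infer backcross number from {scheme_kind!r}")
            n_backcrosses = int(tail)
        if n_backcrosses < 0:
            raise ValueError("n_backcrosses must be >= 0")
        return 100.0 * (1.0 - 0.5 ** (n_backcrosses + 1))
    raise ValueError(f"unknown scheme kind {scheme_kind!r}")


@dataclass
class ShareReport:
    """Population summary of recurrent-genome shares plus the per-plant ranking."""

    summary: pd.DataFrame   # population, generation, n, min, max, mean, expected, n_above, pct_above
    per_plant: pd.DataFrame  # ranked descending by share, ties by sample id

    def rounded(self) -> "tuple[pd.DataFrame, pd.DataFrame]":
        """Report-formatted copies, percentages at 1 decimal place."""
        s = self.summary.copy()
        for c in ("min", "max", "mean", "expected", "pct_above"):
            s[c] = s[c].round(1)
        p = self.per_plant.copy()
        for c in ("share_recurrent", "share_donor"):
            p[c] = p[c].round(1)
        return s, p


def share_report(
    records: pd.DataFrame,
    sheet: SampleSheet,
    expected: "float | dict[str, float] | None" = None,
) -> ShareReport:
    """Table-1-style report: per population range, mean and plants above expectation.

    ``records`` is a :func:`genome_share_table` frame; only progeny
    samples enter the population summaries.  ``expected`` is a single
    percentage, a per-population mapping, or None to derive it from each
    population's generation label.  "Above" is strict (share > expected).
    """
    sheet_t = sheet.table.set_index("sample_id")
    df = records.copy()
    df["population"] = df["sample_id"].map(sheet_t["population"])
    df["generation"] = df["sample_id"].map(sheet_t["generation"])
    df["role"] = df["sample_id"].map(sheet_t["role"])
    prog = df[df["role"] == "progeny"].copy()
    if prog.empty:
        raise ValueError("no progeny records to report on")

    rows = []
    for pop, grp in prog.groupby("population", sort=True):
        gen = grp["generation"].iloc[0]
        if isinstance(expected, dict):
            exp = float(expected[pop])
        elif expected is None:
            exp = expected_share(gen, 1 if gen.upper() == "BC1" else None)
        else:
            exp = float(expected)
        shares = grp["share_recurrent"].to_numpy(float)
        n_above = int((shares > exp).sum())
        rows.append(
            {
                "population": pop,
                "generation": gen,
                "n": len(grp),
                "min": float(shares.min()),
                "max": float(shares.max()),
                "mean": float(shares.mean()),
                "expected": exp,
                "n_above": n_above,
                "pct_above": 100.0 * n_above / len(grp),
            }
        )
    per_plant = prog.sort_values(
        ["share_recurrent", "sample_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ShareReport(pd.DataFrame(rows), per_plant)


def per_chromosome_share(
    abh: ABHMatrix, sample_id: str, parent: str = "recurrent"
) -> pd.Series:
    """Genome-share formula restricted to each chromosome's markers.

    Chromosomes without a scored (non-missing) marker for the sample are
    NaN, not 0.  The whole-genome share is the scored-marker-weighted
    mean of these values.
    """
    row = abh.row(sample_id)
    chroms = abh.panel.chromosomes
    out = {}
    hom_code = ABH_A if parent == "recurrent" else ABH_B
    for chrom in pd.unique(chroms):
        sub = row[chroms == chrom]
        n_hom = int((sub == hom_code).sum())
        n_h = int((sub == ABH_H).sum())
        scored = int((sub != MISSING).sum())
        out[str(chrom)] = (
            100.0 * (2 * n_hom + n_h) / (2 * scored) if scored else np.nan
        )
    return pd.Series(out, name=sample_id)
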