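"""Genotype-matrix containers and file I/O.

Formats handled: VCF 4.2 (read via cyvcf2, written natively), the array
CSV export (sample rows x marker columns, two-letter allele cells,
``--`` missing), the parent-referenced ABH CSV, the sample sheet and the
marker map.  All genotypes are treated as unphased diploid biallelic
calls.

Call encoding (``int8``): 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing.  ABH encoding: 0 = A (hom recurrent), 1 = H (het),
2 = B (hom donor), -1 = missing — so the ABH code of a call is its donor
allele dosage.  The :class:`ABHMatrix` lives here (rather than with the
genome-share statistics) so both the I/O layer and the background
selection layer can use it without circular imports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, MarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING", "HOM_REF", "HET", "HOM_ALT",
    "ABH_A", "ABH_H", "ABH_B",
    "ROLES", "GenotypeMatrix", "ABHMatrix", "SampleSheet",
    "read_vcf", "write_vcf",
    "read_array_csv", "write_array_csv",
    "read_abh_csv", "write_abh_csv",
    "read_sample_sheet", "write_sample_sheet",
    "read_marker_map", "write_marker_map",
]

MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

ABH_A: int = 0
ABH_H: int = 1
ABH_B: int = 2
_ABH_CHAR = {ABH_A: "A", ABH_H: "H", ABH_B: "B", MISSING: "-"}
_ABH_CODE = {v: k for k, v in _ABH_CHAR.items()}

ROLES = ("recurrent_parent", "donor_parent", "F1_control", "M3_parent", "progeny")


def _check_calls(calls: np.ndarray, n_samples: int, n_markers: int, name: str) -> np.ndarray:
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape != (n_samples, n_markers):
        raise ValueError(
            f"{name} shape {calls.shape} != (samples={n_samples}, markers={n_markers})"
        )
    if not np.isin(calls, (-1, 0, 1, 2)).all():
        raise ValueError(f"{name} contains codes outside {{-1,0,1,2}}")
    return calls


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid biallelic genotype calls with missing support."""

    sample_ids: list[str]
    panel: MarkerPanel
    calls: np.ndarray  # (n_samples, n_markers) int8

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.calls = _check_calls(self.calls, len(self.sample_ids), len(self.panel), "calls")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(list(self.sample_ids), self.panel.subset(idx), self.calls[:, idx])

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(list(ids), self.panel, self.calls[idx])

    def equals(self, other: "GenotypeMatrix", check_cm: bool = True) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.panel.equals(other.panel, check_cm=check_cm)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class ABHMatrix:
    """Parent-referenced recoding of a genotype matrix.

    A = homozygous for the recurrent parent's allele, B = homozygous
    donor, H = heterozygous.  Defined only on markers at which both
    parents are fixed for different alleles.
    """

    sample_ids: list[str]
    panel: MarkerPanel
    calls: np.ndarray  # (n_samples, n_markers) int8, codes ABH_A/ABH_H/ABH_B/MISSING
    recurrent_parent: str = "recurrent_parent"
    donor_parent: str = "donor_parent"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.calls = _check_calls(self.calls, len(self.sample_ids), len(self.panel), "ABH calls")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None


@dataclass
class SampleSheet:
    """Role assignment for every sample of an analysis run.

    ``table`` columns: ``sample_id, role[, population, generation]``.
    Exactly one recurrent parent and one donor parent per run.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" not in df.columns or "role" not in df.columns:
            raise ValueError("sample sheet needs 'sample_id' and 'role' columns")
        for col in ("population", "generation"):
            if col not in df.columns:
                df[col] = ""
        df["sample_id"] = df["sample_id"].astype(str)
        df["population"] = df["population"].fillna("").astype(str)
        df["generation"] = df["generation"].fillna("").astype(str)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; allowed: {ROLES}")
        for role in ("recurrent_parent", "donor_parent"):
            n = int((df["role"] == role).sum())
            if n != 1:
                raise ValueError(f"sample sheet must have exactly one {role}, found {n}")
        self.table = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def recurrent_parent_id(self) -> str:
        return str(self.table.loc[self.table["role"] == "recurrent_parent", "sample_id"].iloc[0])

    @property
    def donor_parent_id(self) -> str:
        return str(self.table.loc[self.table["role"] == "donor_parent", "sample_id"].iloc[0])

    def ids_with_role(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "sample_id"].tolist()

    @property
    def progeny_ids(self) -> list[str]:
        return self.ids_with_role("progeny")

    def population_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return str(row["population"].iloc[0])

    def check_matches(self, matrix: GenotypeMatrix) -> None:
        """Every matrix sample must appear exactly once in the sheet."""
        missing = set(matrix.sample_ids) - set(self.ids)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_NUCS = {"A", "C", "G", "T"}


def read_vcf(path: str | Path, marker_map: "pd.DataFrame | None" = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Multiallelic or non-SNP records are skipped with a logged count,
    never silently.  1-based VCF positions become the panel's ``bp``.
    ``marker_map`` (columns ``id, chromosome, cm, bp``) supplies genetic
    positions; without it ``cm`` is NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, bps, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in _NUCS or var.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        bps.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(remap[np.asarray(var.gt_types)])
    vcf.close()
    if n_skipped:
        logger.warning("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    table = pd.DataFrame(
        {"id": ids, "chromosome": chroms, "cm": np.nan, "bp": bps, "ref": refs, "alt": alts}
    )
    if marker_map is not None:
        cm = marker_map.set_index("id")["cm"]
        table["cm"] = table["id"].map(cm).to_numpy(float)
    panel = MarkerPanel(table)
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, panel, calls)


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal valid VCF 4.2 with unphased GT calls."""
    panel = matrix.panel
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mabc\n")
        for chrom in pd.unique(panel.table["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        chroms, bps = panel.chromosomes, panel.bp
        ids, refs, alts = panel.ids, panel.ref, panel.alt
        for j in range(matrix.n_markers):
            gts = "\t".join(_GT_STR[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{chroms[j]}\t{bps[j]}\t{ids[j]}\t{refs[j]}\t{alts[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Array CSV (vendor-export stand-in)
# ---------------------------------------------------------------------------

MISSING_TOKEN = "--"


def write_array_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the array-export CSV: sample rows, marker columns, 'AG'-style cells."""
    ref, alt = matrix.panel.ref, matrix.panel.alt
    cell = np.empty((4, matrix.n_markers), dtype=object)
    cell[HOM_REF] = np.char.add(ref, ref)
    cell[HET] = np.char.add(ref, alt)
    cell[HOM_ALT] = np.char.add(alt, alt)
    cell[3] = MISSING_TOKEN  # index -1 wraps to row 3
    out = cell[matrix.calls, np.arange(matrix.n_markers)]
    df = pd.DataFrame(out, index=matrix.sample_ids, columns=matrix.panel.ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_array_csv(path: str | Path, panel: MarkerPanel) -> GenotypeMatrix:
    """Read an array-export CSV, reconciling alleles against ``panel``.

    Cells are unordered two-letter allele pairs; any allele outside the
    marker's declared {ref, alt} raises with the offending cells listed.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicated sample id in array CSV")
    got = list(df.columns)
    want = list(panel.ids)
    if set(got) != set(want):
        extra = sorted(set(got) - set(want))[:5]
        missing = sorted(set(want) - set(got))[:5]
        raise ValueError(f"array CSV markers disagree with panel (extra={extra}, missing={missing})")
    df = df[want]
    calls = np.full((len(sample_ids), len(panel)), MISSING, dtype=np.int8)
    bad: list[str] = []
    ref, alt = panel.ref, panel.alt
    cells = df.to_numpy(str)
    for j in range(len(panel)):
        r, a = ref[j], alt[j]
        code = {
            r + r: HOM_REF, a + a: HOM_ALT,
            r + a: HET, a + r: HET,
            MISSING_TOKEN: MISSING,
        }
        for i, c in enumerate(cells[:, j]):
            try:
                calls[i, j] = code[c]
            except KeyError:
                bad.append(f"({sample_ids[i]}, {want[j]})={c!r}")
    if bad:
        raise ValueError(f"alleles not in marker panel at cells: {bad[:10]}")
    return GenotypeMatrix(sample_ids, panel, calls)


# ---------------------------------------------------------------------------
# ABH CSV
# ---------------------------------------------------------------------------

def write_abh_csv(abh: ABHMatrix, path: str | Path) -> None:
    """Write the ABH matrix as CSV: sample rows, marker columns, cells A/B/H/'-'."""
    chars = np.array([_ABH_CHAR[ABH_A], _ABH_CHAR[ABH_H], _ABH_CHAR[ABH_B], _ABH_CHAR[MISSING]])
    out = chars[abh.calls]  # MISSING=-1 wraps to the last entry
    df = pd.DataFrame(out, index=abh.sample_ids, columns=abh.panel.ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_abh_csv(path: str | Path, panel: "MarkerPanel | None" = None) -> ABHMatrix:
    """Read an ABH CSV.

    Without ``panel`` a positional placeholder panel is built (unknown
    chromosome/positions) — enough for genome-share computation, not for
    per-chromosome reporting.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    if panel is None:
        table = pd.DataFrame(
            {
                "id": list(df.columns),
                "chromosome": "un",
                "cm": np.nan,
                "bp": np.arange(1, len(df.columns) + 1),
                "ref": "A",
                "alt": "B",
            }
        )
        panel = MarkerPanel(table)
    else:
        if list(df.columns) != list(panel.ids):
            df = df[list(panel.ids)]
    try:
        calls = np.vectorize(_ABH_CODE.__getitem__, otypes=[np.int8])(df.to_numpy(str))
    except KeyError as e:
        raise ValueError(f"invalid ABH symbol {e.args[0]!r} in {path}") from None
    return ABHMatrix(sample_ids, panel, calls)


# ---------------------------------------------------------------------------
# Sample sheet and marker map
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype=str))


def write_marker_map(panel: MarkerPanel, path: str | Path) -> None:
    panel.table[["id", "chromosome", "cm", "bp"]].to_csv(path, index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"id", "chromosome", "cm", "bp"}
    if not need <= set(df.columns):
        raise ValueError(f"marker map needs columns {sorted(need)}")
    df["id"] = df["id"].astype(str)
    return df
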