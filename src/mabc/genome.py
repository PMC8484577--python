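"""Genome frame and marker panel containers.

A :class:`GenomeModel` holds the chromosomes of the crossing program's
species — for winter × spring oilseed rape that is the 19 *Brassica napus*
chromosomes A01–A10 and C01–C09 — with a genetic length in centimorgans
(the frame for simulated meiosis) and a physical length in base pairs
(used only for reporting, e.g. marker density per Mbp).

A :class:`MarkerPanel` is the ordered list of biallelic SNP markers an
array interrogates: id, chromosome, genetic position (cM), physical
position (bp) and the two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeModel",
    "MarkerPanel",
    "default_genome_model",
    "marker_density",
]

_A_NAMES = [f"A{i:02d}" for i in range(1, 11)]
_C_NAMES = [f"C{i:02d}" for i in range(1, 10)]
DEFAULT_CHROMOSOME_NAMES = _A_NAMES + _C_NAMES

#: Default per-chromosome physical length; 19 x 59.5 Mbp ~ 1.13 Gbp,
#: the assembly size of the B. napus genome.
DEFAULT_PHYSICAL_LENGTH = 59_500_000


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, genetic length (cM) and physical length (bp)."""

    name: str
    genetic_length: float
    physical_length: int = DEFAULT_PHYSICAL_LENGTH

    def __post_init__(self) -> None:
        if self.genetic_length <= 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be > 0")
        if self.physical_length <= 0:
            raise ValueError(f"chromosome {self.name}: physical length must be > 0")


@dataclass(frozen=True)
class GenomeModel:
    """Ordered collection of chromosomes defining the simulation frame."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("a genome model needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_genetic_length(self) -> float:
        """Total map length in cM."""
        return float(sum(c.genetic_length for c in self.chromosomes))

    @property
    def total_physical_length(self) -> int:
        """Total physical genome size in bp."""
        return int(sum(c.physical_length for c in self.chromosomes))

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.names


def default_genome_model(
    n_chromosomes: int = 19,
    cm_lengths: "list[float] | None" = None,
    physical_lengths: "list[int] | None" = None,
    names: "list[str] | None" = None,
) -> GenomeModel:
    """Build a genome model emulating the B. napus A/C subgenomes.

    Defaults to 19 chromosomes named A01–A10, C01–C09 of 100 cM each,
    with physical lengths summing to ~1.13 Gbp.  Any of the length lists
    overrides both the defaults and ``n_chromosomes``.
    """
    if cm_lengths is not None:
        n_chromosomes = len(cm_lengths)
    elif physical_lengths is not None:
        n_chromosomes = len(physical_lengths)
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if names is None:
        if n_chromosomes <= len(DEFAULT_CHROMOSOME_NAMES):
            names = DEFAULT_CHROMOSOME_NAMES[:n_chromosomes]
        else:
            names = [f"chr{i:02d}" for i in range(1, n_chromosomes + 1)]
    if len(names) != n_chromosomes:
        raise ValueError("names length does not match chromosome count")
    if cm_lengths is None:
        cm_lengths = [100.0] * n_chromosomes
    if physical_lengths is None:
        physical_lengths = [DEFAULT_PHYSICAL_LENGTH] * n_chromosomes
    if not (len(cm_lengths) == len(physical_lengths) == n_chromosomes):
        raise ValueError("length lists disagree on chromosome count")
    return GenomeModel(
        tuple(
            Chromosome(n, float(g), int(p))
            for n, g, p in zip(names, cm_lengths, physical_lengths)
        )
    )


def marker_density(n_markers: int, genome: GenomeModel) -> float:
    """Markers per Mbp of physical genome (reporting helper)."""
    return n_markers / (genome.total_physical_length / 1e6)


_PANEL_COLUMNS = ["id", "chromosome", "cm", "bp", "ref", "alt"]


@dataclass
class MarkerPanel:
    """Ordered biallelic SNP marker panel.

    ``table`` columns: ``id, chromosome, cm, bp, ref, alt``.  Within a
    chromosome markers are expected sorted by cM position (ties broken by
    id); :meth:`from_records` normalises the order, the plain constructor
    preserves it (call order must match any genotype matrix built on it).
    ``cm`` may be NaN for panels read from positional-only sources (VCF
    without a genetic map).
    """

    table: pd.DataFrame
    genome: "GenomeModel | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker panel missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate marker ids: {dups} ...")
        if self.genome is not None:
            self.validate(self.genome)

    @classmethod
    def from_records(
        cls, records: pd.DataFrame, genome: "GenomeModel | None" = None
    ) -> "MarkerPanel":
        """Build a panel, sorting within chromosome by (cm, id).

        Chromosomes keep their first-appearance order (or genome order
        when a genome is given).
        """
        df = records.copy()
        if genome is not None:
            order = {n: i for i, n in enumerate(genome.names)}
        else:
            order = {n: i for i, n in enumerate(pd.unique(df["chromosome"]))}
        df["_c"] = df["chromosome"].map(order)
        if df["_c"].isna().any():
            bad = df.loc[df["_c"].isna(), "chromosome"].unique().tolist()
            raise ValueError(f"markers on chromosomes absent from the genome: {bad}")
        df = df.sort_values(["_c", "cm", "id"], kind="stable").drop(columns="_c")
        return cls(df.reset_index(drop=True), genome)

    def validate(self, genome: GenomeModel) -> None:
        """Check chromosome labels, position bounds and within-chromosome order."""
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            if chrom not in genome:
                raise ValueError(f"marker chromosome {chrom!r} not in genome model")
            cm = grp["cm"].to_numpy(float)
            if np.isnan(cm).all():
                continue
            L = genome[str(chrom)].genetic_length
            if np.nanmin(cm) < 0 or np.nanmax(cm) > L:
                raise ValueError(
                    f"marker cM position outside [0, {L}] on chromosome {chrom}"
                )
            if not np.all(np.diff(cm[~np.isnan(cm)]) >= 0):
                raise ValueError(f"markers not sorted by cM on chromosome {chrom}")

    # -- accessors -------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(str)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy(str)

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(float)

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy(np.int64)

    @property
    def ref(self) -> np.ndarray:
        return self.table["ref"].to_numpy(str)

    @property
    def alt(self) -> np.ndarray:
        return self.table["alt"].to_numpy(str)

    def index_of(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"unknown marker id {marker_id!r}")
        return int(idx[0])

    def subset(self, mask: np.ndarray) -> "MarkerPanel":
        """Panel restricted to a boolean mask or integer index array (order kept)."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MarkerPanel(self.table.iloc[idx].reset_index(drop=True), self.genome)

    def equals(self, other: "MarkerPanel", check_cm: bool = True) -> bool:
        a, b = self.table, other.table
        if len(a) != len(b):
            return False
        cols = ["id", "chromosome", "bp", "ref", "alt"] + (["cm"] if check_cm else [])
        for c in cols:
            if c == "cm":
                x = a[c].to_numpy(float)
                y = b[c].to_numpy(float)
                if not np.allclose(x, y, equal_nan=True):
                    return False
            elif not (a[c].to_numpy() == b[c].to_numpy()).all():
                return False
        return True
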