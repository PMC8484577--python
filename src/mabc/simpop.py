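"""Backcross-population simulator.

Simulates the crossing program the analysis pipeline is built for: two
inbred founders (recurrent elite parent and mutagenized donor), F1
hybrids, BC1 backcross populations and F1 x F1 double-hybrid
populations, with optional foreground conditioning (progeny must be
heterozygous for the donor allele at the target mutation loci).

Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the map length in Morgans, crossover
positions are uniform, and there is no interference and no obligate
chiasma.  Each individual carries two :class:`GameteMosaic` haplotypes —
founder-origin segment lists — which are the exact ground truth the
marker-based genome-share statistic is benchmarked against.

Array genotyping is emulated by reading the founder of origin of each
haplotype at every marker position and emitting the founder's allele,
with optional symmetric genotyping error and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HET, MISSING, SampleSheet
from .genome import GenomeModel, MarkerPanel

__all__ = [
    "GameteMosaic",
    "SimIndividual",
    "CrossScheme",
    "founder_individual",
    "simulate_gamete",
    "cross",
    "simulate_population",
    "true_parent_fraction",
    "genotype_panel",
    "random_marker_panel",
    "simulate_dataset",
    "write_segments",
    "SimulatedDataset",
]

Segment = tuple[float, float, str]  # (start_cm, end_cm, founder)


@dataclass
class GameteMosaic:
    """Founder-origin mosaic of one gamete (haplotype).

    ``segments[chrom]`` is an ordered list of ``(start_cm, end_cm,
    founder)`` tuples that tile ``[0, genetic_length]`` without gaps or
    overlaps; adjacent segments carry distinct founders, so every
    internal boundary is a real crossover.
    """

    segments: dict[str, list[Segment]]

    def founder_at(self, chrom: str, cm: float) -> str:
        for start, end, founder in self.segments[chrom]:
            if start <= cm <= end:
                return founder
        raise ValueError(f"position {cm} cM outside chromosome {chrom}")

    def founders(self) -> set[str]:
        return {f for segs in self.segments.values() for _, _, f in segs}

    def validate(self, genome: GenomeModel) -> None:
        if set(self.segments) != set(genome.names):
            raise ValueError("mosaic chromosomes disagree with genome model")
        for chrom in genome.names:
            segs = self.segments[chrom]
            L = genome[chrom].genetic_length
            if not segs or segs[0][0] != 0.0 or segs[-1][1] != L:
                raise ValueError(f"mosaic does not cover chromosome {chrom}")
            for (s0, e0, f0), (s1, e1, f1) in zip(segs, segs[1:]):
                if e0 != s1:
                    raise ValueError(f"gap/overlap at {e0} on {chrom}")
                if f0 == f1:
                    raise ValueError(f"adjacent segments share founder {f0} on {chrom}")
            if any(e <= s for s, e, _ in segs):
                raise ValueError(f"non-increasing segment on {chrom}")


@dataclass
class SimIndividual:
    """A simulated plant: two gamete mosaics plus pedigree bookkeeping."""

    id: str
    maternal: GameteMosaic
    paternal: GameteMosaic
    pedigree_class: str = "founder"  # founder | F1 | BC1 | BC2 | F1xF1 | cross

    def is_het_at(self, chrom: str, cm: float) -> bool:
        return self.maternal.founder_at(chrom, cm) != self.paternal.founder_at(chrom, cm)


@dataclass
class CrossScheme:
    """Crossing-scheme description for :func:`simulate_population`.

    BC1: F1 (donor x recurrent) backcrossed to the recurrent parent,
    one target mutation locus.  F1xF1: two independent F1s crossed,
    two target loci (double mutant).  With ``conditioning`` on, progeny
    are rejection-sampled until heterozygous for the donor allele at
    every target locus.
    """

    scheme_kind: str  # "BC1" | "F1xF1"
    recurrent_parent: str = "RP"
    donor_parent: str = "DP"
    target_loci: list[tuple[str, float]] = field(default_factory=list)
    conditioning: bool = False

    def __post_init__(self) -> None:
        if self.scheme_kind not in ("BC1", "F1xF1"):
            raise ValueError(f"unknown scheme kind {self.scheme_kind!r}")
        if self.recurrent_parent == self.donor_parent:
            raise ValueError("recurrent and donor parents must differ")
        if self.conditioning:
            need = 1 if self.scheme_kind == "BC1" else 2
            if len(self.target_loci) != need:
                raise ValueError(
                    f"{self.scheme_kind} conditioning needs {need} target loci, "
                    f"got {len(self.target_loci)}"
                )

    @property
    def expected_recurrent_share(self) -> float:
        return 75.0 if self.scheme_kind == "BC1" else 50.0


def founder_individual(label: str, genome: GenomeModel, id: "str | None" = None) -> SimIndividual:
    """Fully inbred founder: both haplotypes one segment per chromosome."""
    def mosaic() -> GameteMosaic:
        return GameteMosaic(
            {c.name: [(0.0, c.genetic_length, label)] for c in genome.chromosomes}
        )

    return SimIndividual(id or label, mosaic(), mosaic(), "founder")


def _clip(segs: list[Segment], a: float, b: float) -> list[Segment]:
    out = []
    for s, e, f in segs:
        if e <= a or s >= b:
            continue
        out.append((max(s, a), min(e, b), f))
    return out


def simulate_gamete(
    parent: SimIndividual, genome: GenomeModel, rng: np.random.Generator
) -> GameteMosaic:
    """Draw one meiotic product of ``parent`` under the Haldane model.

    Per chromosome: crossover count ~ Poisson(length in Morgans),
    positions uniform, starting strand fair coin; the parent's two
    mosaics are spliced at the crossover points and runs of identical
    founder merged (a crossover between identical-origin regions leaves
    no breakpoint).
    """
    if set(parent.maternal.segments) != set(genome.names):
        raise ValueError("parent mosaics do not match the genome model")
    out: dict[str, list[Segment]] = {}
    for chrom in genome.chromosomes:
        m = parent.maternal.segments[chrom.name]
        p = parent.paternal.segments[chrom.name]
        if len(m) == 1 and len(p) == 1 and m[0][2] == p[0][2]:
            # homozygous chromosome: result independent of crossovers
            out[chrom.name] = [m[0]]
            continue
        L = chrom.genetic_length
        k = int(rng.poisson(L / 100.0))
        haps = (m, p)
        h = int(rng.integers(2))
        if k == 0:
            merged = list(haps[h])
        else:
            xs = np.sort(rng.uniform(0.0, L, size=k))
            bounds = [0.0, *xs.tolist(), L]
            raw: list[Segment] = []
            for i in range(len(bounds) - 1):
                raw.extend(_clip(haps[(h + i) % 2], bounds[i], bounds[i + 1]))
            merged = []
            for s, e, f in raw:
                if e <= s:
                    continue
                if merged and merged[-1][2] == f:
                    merged[-1] = (merged[-1][0], e, f)
                else:
                    merged.append((s, e, f))
        out[chrom.name] = merged
    return GameteMosaic(out)


def cross(
    mother: SimIndividual,
    father: SimIndividual,
    genome: GenomeModel,
    rng: np.random.Generator,
    id: str = "cross",
    pedigree_class: str = "cross",
) -> SimIndividual:
    """Cross two individuals: one gamete from each (mother first)."""
    if set(mother.maternal.segments) != set(father.maternal.segments):
        raise ValueError("parents are on different genome models")
    return SimIndividual(
        id,
        simulate_gamete(mother, genome, rng),
        simulate_gamete(father, genome, rng),
        pedigree_class,
    )


def true_parent_fraction(ind: SimIndividual, founder: str, genome: GenomeModel) -> float:
    """Exact genome share (%) of ``founder``, from segment lengths.

    Sums the cM length of segments of founder origin over both
    haplotypes and divides by twice the total map length.  This is the
    marker-free oracle the marker-based estimate is checked against.
    """
    present = ind.maternal.founders() | ind.paternal.founders()
    if founder not in present:
        raise ValueError(f"founder {founder!r} not present in individual {ind.id!r}")
    total = 0.0
    for mosaic in (ind.maternal, ind.paternal):
        for segs in mosaic.segments.values():
            total += sum(e - s for s, e, f in segs if f == founder)
    return 100.0 * total / (2.0 * genome.total_genetic_length)


@dataclass
class _PopulationParts:
    recurrent: SimIndividual
    donor: SimIndividual
    f1s: list[SimIndividual]
    progeny: list[SimIndividual]


_MAX_TRIES = 100_000


def _build_population(
    scheme: CrossScheme, n: int, genome: GenomeModel, rng: np.random.Generator
) -> _PopulationParts:
    if n < 1:
        raise ValueError("population size must be >= 1")
    if scheme.conditioning and not scheme.target_loci:
        raise ValueError("conditioning requested with empty target loci")
    rp = founder_individual(scheme.recurrent_parent, genome)
    dp = founder_individual(scheme.donor_parent, genome)
    if scheme.scheme_kind == "BC1":
        f1s = [cross(dp, rp, genome, rng, id="F1", pedigree_class="F1")]
        def make(i: int) -> SimIndividual:
            return cross(f1s[0], rp, genome, rng, id=f"BC1_{i:05d}", pedigree_class="BC1")
    else:
        f1s = [
            cross(dp, rp, genome, rng, id="F1_a", pedigree_class="F1"),
            cross(dp, rp, genome, rng, id="F1_b", pedigree_class="F1"),
        ]
        def make(i: int) -> SimIndividual:
            return cross(f1s[0], f1s[1], genome, rng, id=f"F1xF1_{i:05d}", pedigree_class="F1xF1")

    donor = scheme.donor_parent
    progeny: list[SimIndividual] = []
    for i in range(n):
        for _ in range(_MAX_TRIES):
            child = make(i)
            if not scheme.conditioning:
                break
            ok = all(
                child.maternal.founder_at(c, x) == donor
                and child.paternal.founder_at(c, x) != donor
                or child.maternal.founder_at(c, x) != donor
                and child.paternal.founder_at(c, x) == donor
                for c, x in scheme.target_loci
            )
            if ok:
                break
        else:  # pragma: no cover - acceptance probability >= 1/4
            raise RuntimeError("rejection sampling failed to satisfy conditioning")
        progeny.append(child)
    return _PopulationParts(rp, dp, f1s, progeny)


def simulate_population(
    scheme: CrossScheme, n: int, genome: GenomeModel, rng: np.random.Generator
) -> list[SimIndividual]:
    """Simulate ``n`` progeny of the scheme's pedigree class.

    Founders and F1s are built internally; with conditioning on, each
    retained individual is heterozygous for the donor allele at every
    target locus (rejection sampling).
    """
    return _build_population(scheme, n, genome, rng).progeny


def random_marker_panel(
    genome: GenomeModel,
    n_markers: int,
    rng: np.random.Generator,
    prefix: str = "M",
) -> MarkerPanel:
    """Uniform random informative marker panel on the genome.

    Markers are allotted to chromosomes in proportion to genetic length,
    placed uniformly in cM, and given bp positions by the affine
    cM -> bp map of each chromosome.  Ref/alt are random distinct
    nucleotides (every marker is polymorphic between the two founders by
    construction of :func:`genotype_panel`).
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    lengths = np.array([c.genetic_length for c in genome.chromosomes])
    counts = rng.multinomial(n_markers, lengths / lengths.sum())
    # guarantee every chromosome at least one marker when possible
    while n_markers >= genome.n_chromosomes and (counts == 0).any():
        i = int(np.argmax(counts))
        j = int(np.argmin(counts))
        counts[i] -= 1
        counts[j] += 1
    nucs = np.array(list("ACGT"))
    recs = []
    for chrom, k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        cm = np.sort(rng.uniform(0.0, chrom.genetic_length, size=int(k)))
        bp = np.maximum(1, np.round(cm / chrom.genetic_length * chrom.physical_length)).astype(np.int64)
        ref_idx = rng.integers(0, 4, size=int(k))
        alt_idx = (ref_idx + rng.integers(1, 4, size=int(k))) % 4
        recs.append(
            pd.DataFrame(
                {
                    "id": "",
                    "chromosome": chrom.name,
                    "cm": cm,
                    "bp": bp,
                    "ref": nucs[ref_idx],
                    "alt": nucs[alt_idx],
                }
            )
        )
    table = pd.concat(recs, ignore_index=True)
    width = max(5, len(str(n_markers)))
    table["id"] = [f"{prefix}{i + 1:0{width}d}" for i in range(len(table))]
    return MarkerPanel(table, genome)


def _marker_layout(panel: MarkerPanel) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per chromosome: (name, marker column indices, cm positions)."""
    out = []
    chroms = panel.chromosomes
    cm = panel.cm
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        out.append((str(chrom), idx, cm[idx]))
    return out


def genotype_panel(
    inds: list[SimIndividual],
    panel: MarkerPanel,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    rng: "np.random.Generator | None" = None,
    founder_alleles: "dict[str, int] | None" = None,
    genome: "GenomeModel | None" = None,
) -> GenotypeMatrix:
    """Emulate array genotyping of simulated individuals.

    Each haplotype contributes the allele of its founder of origin at
    the marker's cM position; ``founder_alleles`` maps founder label to
    allele index (0 = ref, 1 = alt) and defaults to sorted founder
    labels -> (ref, alt), which makes every marker polymorphic between
    two founders.  Genotyping error replaces a true call by a uniformly
    random non-missing genotype with probability ``error_rate``; calls
    are then masked missing with probability ``missing_rate``.
    """
    if not 0 <= error_rate < 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must be in [0, 1)")
    if rng is None and (error_rate > 0 or missing_rate > 0):
        raise ValueError("rng required when error or missing rates are nonzero")
    genome = genome or panel.genome
    if genome is not None:
        for chrom, _, cms in _marker_layout(panel):
            L = genome[chrom].genetic_length
            if cms.min() < 0 or cms.max() > L:
                raise ValueError(f"marker position outside chromosome {chrom}")
    if founder_alleles is None:
        founders = sorted(set().union(*(i.maternal.founders() | i.paternal.founders() for i in inds)))
        if len(founders) > 2:
            raise ValueError("more than two founders: pass founder_alleles explicitly")
        founder_alleles = {f: i for i, f in enumerate(founders)}

    layout = _marker_layout(panel)
    n, m = len(inds), len(panel)
    calls = np.empty((n, m), dtype=np.int8)
    for i, ind in enumerate(inds):
        for chrom, idx, cms in layout:
            dose = np.zeros(len(idx), dtype=np.int8)
            for mosaic in (ind.maternal, ind.paternal):
                segs = mosaic.segments[chrom]
                ends = np.array([e for _, e, _ in segs])
                alleles = np.array([founder_alleles[f] for _, _, f in segs], dtype=np.int8)
                pos = np.minimum(np.searchsorted(ends, cms, side="right"), len(segs) - 1)
                dose += alleles[pos]
            calls[i, idx] = dose
    if error_rate > 0:
        mask = rng.random(calls.shape) < error_rate
        calls[mask] = rng.integers(0, 3, size=int(mask.sum()), dtype=np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return GenotypeMatrix([ind.id for ind in inds], panel, calls)


@dataclass
class SimulatedDataset:
    """One simulated genotyping run: matrix, sheet, targets and truth."""

    genome: GenomeModel
    panel: MarkerPanel
    scheme: CrossScheme
    matrix: GenotypeMatrix           # parents + F1 control(s) + progeny
    sheet: SampleSheet
    individuals: list[SimIndividual]  # same order as matrix rows
    true_recurrent_share: dict[str, float]

    @property
    def progeny_ids(self) -> list[str]:
        return self.sheet.progeny_ids


def simulate_dataset(
    scheme: CrossScheme,
    n: int,
    genome: GenomeModel,
    panel: MarkerPanel,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    population: str = "A",
) -> SimulatedDataset:
    """Simulate a population and genotype it together with its controls.

    The genotyped set mirrors a real run: recurrent parent, donor
    parent, F1 control(s), then the progeny.  Founder alleles are
    assigned recurrent -> ref, donor -> alt at every marker.
    """
    parts = _build_population(scheme, n, genome, rng)
    inds = [parts.recurrent, parts.donor, *parts.f1s, *parts.progeny]
    founder_alleles = {scheme.recurrent_parent: 0, scheme.donor_parent: 1}
    matrix = genotype_panel(
        inds, panel, error_rate, missing_rate, rng,
        founder_alleles=founder_alleles, genome=genome,
    )
    roles = (
        ["recurrent_parent", "donor_parent"]
        + ["F1_control"] * len(parts.f1s)
        + ["progeny"] * len(parts.progeny)
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [i.id for i in inds],
                "role": roles,
                "population": population,
                "generation": scheme.scheme_kind,
            }
        )
    )
    truth = {
        ind.id: true_parent_fraction(ind, scheme.recurrent_parent, genome)
        for ind in inds
        if scheme.recurrent_parent in (ind.maternal.founders() | ind.paternal.founders())
    }
    return SimulatedDataset(genome, panel, scheme, matrix, sheet, inds, truth)


def write_segments(inds: list[SimIndividual], path: str | Path) -> None:
    """Write ground-truth ancestry segments as TSV.

    Columns: individual, chromosome, start_cm, end_cm, haplotype
    (0 maternal / 1 paternal), founder.
    """
    rows = []
    for ind in inds:
        for h, mosaic in enumerate((ind.maternal, ind.paternal)):
            for chrom, segs in mosaic.segments.items():
                for s, e, f in segs:
                    rows.append((ind.id, chrom, s, e, h, f))
    pd.DataFrame(
        rows, columns=["individual", "chromosome", "start_cm", "end_cm", "haplotype", "founder"]
    ).to_csv(path, sep="\t", index=False)
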