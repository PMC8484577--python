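"""End-to-end pipeline: simulate -> qc -> foreground -> background -> pca -> report.

Each stage reads only the files written by earlier stages and writes its
own outputs into the run directory; a manifest of SHA-256 hashes over
the text outputs is written at the end, so identical config + seed give
an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background, foreground, genio, markerqc, simpop, structure
from .genome import default_genome_model, marker_density

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 1
    scheme: str = "BC1"            # BC1 | F1xF1
    n: int = 100                   # progeny count
    n_markers: int = 1000
    n_chromosomes: int = 19
    cm_length: float = 100.0
    condition: bool = False
    error_rate: float = 0.0
    missing_rate: float = 0.0
    max_missing: float = 0.0
    min_maf: float = 0.001
    expected: "str | float" = "auto"
    n_components: int = 10
    population: str = "A"
    out_dir: str = "mabc_run"
    log_level: str = "INFO"
    plot: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size n must be >= 1")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.scheme not in ("BC1", "F1xF1"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a nonnegative 31-bit integer")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _default_targets(config: RunConfig, genome) -> list[tuple[str, float]]:
    """Target mutation loci: mid-chromosome on the first one (two) chromosome(s)."""
    k = 1 if config.scheme == "BC1" else 2
    return [(genome.names[i], genome[genome.names[i]].genetic_length / 2) for i in range(k)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_simulate(config: RunConfig, out: Path) -> None:
    genome = default_genome_model(
        n_chromosomes=config.n_chromosomes,
        cm_lengths=[config.cm_length] * config.n_chromosomes,
    )
    rng = np.random.default_rng(config.seed)
    panel = simpop.random_marker_panel(genome, config.n_markers, rng)
    targets = _default_targets(config, genome)
    scheme = simpop.CrossScheme(
        scheme_kind=config.scheme,
        target_loci=targets,
        conditioning=config.condition,
    )
    ds = simpop.simulate_dataset(
        scheme, config.n, genome, panel, rng,
        error_rate=config.error_rate,
        missing_rate=config.missing_rate,
        population=config.population,
    )
    genio.write_vcf(ds.matrix, out / "genotypes.vcf")
    genio.write_marker_map(panel, out / "marker_map.csv")
    genio.write_sample_sheet(ds.sheet, out / "samples.csv")
    simpop.write_segments(ds.individuals, out / "segments.tsv")
    pd.DataFrame(
        {
            "sample_id": list(ds.true_recurrent_share),
            "true_share_recurrent": list(ds.true_recurrent_share.values()),
        }
    ).to_csv(out / "true_shares.csv", index=False)
    rows = []
    for i, (chrom, cm) in enumerate(targets, start=1):
        col = foreground.resolve_marker(panel, foreground.TargetLocus(f"L{i}", chrom, cm))
        rows.append(
            {
                "locus_id": f"L{i}",
                "chromosome": chrom,
                "cm": cm,
                "bp": int(panel.bp[col]),
                "marker_id": str(panel.ids[col]),
            }
        )
    pd.DataFrame(rows).to_csv(out / "targets.csv", index=False)
    logger.info(
        "simulate: %d %s progeny, %d markers (%.2f markers/Mbp)",
        config.n, config.scheme, len(panel), marker_density(len(panel), genome),
    )


def _load_matrix(out: Path, vcf_name: str) -> genio.GenotypeMatrix:
    marker_map = genio.read_marker_map(out / "marker_map.csv")
    return genio.read_vcf(out / vcf_name, marker_map=marker_map)


def stage_qc(config: RunConfig, out: Path) -> None:
    matrix = _load_matrix(out, "genotypes.vcf")
    sheet = genio.read_sample_sheet(out / "samples.csv")
    filtered, report = markerqc.qc_report(
        matrix, sheet, max_missing_fraction=config.max_missing, min_maf=config.min_maf
    )
    genio.write_vcf(filtered, out / "filtered.vcf")
    report.to_frame().to_csv(out / "qc_report.csv", index=False)


def stage_foreground(config: RunConfig, out: Path) -> None:
    matrix = _load_matrix(out, "genotypes.vcf")
    targets = pd.read_csv(out / "targets.csv")
    loci = [
        foreground.TargetLocus(
            str(r.locus_id), str(r.chromosome), float(r.cm), int(r.bp), str(r.marker_id)
        )
        for r in targets.itertuples()
    ]
    sheet = genio.read_sample_sheet(out / "samples.csv")
    prog = matrix.subset_samples(sheet.progeny_ids)
    sel = foreground.select_carriers(prog, loci)
    pd.DataFrame(
        {
            "sample_id": sel.carriers + sel.non_carriers + sel.unclassified,
            "class": ["carrier"] * len(sel.carriers)
            + ["non_carrier"] * len(sel.non_carriers)
            + ["unclassified"] * len(sel.unclassified),
        }
    ).to_csv(out / "carriers.csv", index=False)
    if config.scheme == "BC1":
        seg = foreground.bc1_segregation_test(prog, loci[0])
    else:
        seg = foreground.f1xf1_segregation_test(prog, loci)
    pd.DataFrame(
        {
            "class": list(seg.class_labels),
            "observed": list(seg.observed),
            "expected_ratio": list(seg.expected_ratio),
            "statistic": seg.statistic,
            "df": seg.df,
            "pvalue": seg.pvalue,
        }
    ).to_csv(out / "segregation.csv", index=False)


def stage_background(config: RunConfig, out: Path) -> None:
    matrix = _load_matrix(out, "filtered.vcf")
    sheet = genio.read_sample_sheet(out / "samples.csv")
    abh = background.encode_abh(matrix, sheet)
    genio.write_abh_csv(abh, out / "abh.csv")
    records = background.genome_share_table(abh)
    if config.expected == "auto":
        expected = None
    else:
        expected = float(config.expected)
    report = background.share_report(records, sheet, expected)
    summary, per_plant = report.rounded()
    summary.to_csv(out / "share_report.csv", index=False)
    per_plant.to_csv(out / "shares.csv", index=False)
    chrom_rows = {
        s: background.per_chromosome_share(abh, s) for s in sheet.progeny_ids
    }
    pd.DataFrame(chrom_rows).T.rename_axis("sample_id").round(1).to_csv(
        out / "per_chromosome_share.csv"
    )


def stage_pca(config: RunConfig, out: Path) -> None:
    matrix = _load_matrix(out, "filtered.vcf")
    sheet = genio.read_sample_sheet(out / "samples.csv")
    X = structure.dosage_encode(matrix)
    result = structure.pca(X, n_components=config.n_components, sample_ids=matrix.sample_ids)
    k = result.n_components
    pd.DataFrame(
        result.scores, index=matrix.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    ).rename_axis("sample_id").to_csv(out / "pca_scores.csv")
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(k)], "variance_explained_pct": result.variance_explained}
    ).to_csv(out / "pca_variance.csv", index=False)
    if config.plot:
        structure.plot_pca(result, sheet, str(out / "pca.png"))


def stage_report(config: RunConfig, out: Path) -> None:
    """Assemble the run summary and the manifest of output hashes."""
    qc = pd.read_csv(out / "qc_report.csv")
    share = pd.read_csv(out / "share_report.csv")
    seg = pd.read_csv(out / "segregation.csv")
    carriers = pd.read_csv(out / "carriers.csv")
    summary = {
        "scheme": config.scheme,
        "n_progeny": config.n,
        "qc": qc.to_dict(orient="records"),
        "n_carriers": int((carriers["class"] == "carrier").sum()),
        "segregation_pvalue": float(seg["pvalue"].iloc[0]),
        "share_report": share.to_dict(orient="records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    # run_config.yaml is the input copy (it embeds out_dir), not an output
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".tsv", ".vcf", ".json")
        and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


_STAGES = [
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("foreground", stage_foreground),
    ("background", stage_background),
    ("pca", stage_pca),
    ("report", stage_report),
]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the output directory.

    A copy of the configuration is written into the run directory; any
    stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "run_config.yaml")
    for name, fn in _STAGES:
        try:
            logger.info("stage %s ...", name)
            fn(config, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    return out
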