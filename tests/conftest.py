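"""Shared fixtures: simulated study-scale populations built once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import mabc
from mabc import background as bg


@dataclass
class SimBundle:
    """A simulated dataset plus its ABH encoding and share table."""

    ds: mabc.simpop.SimulatedDataset
    abh: bg.ABHMatrix
    shares: pd.DataFrame        # genome_share_table of all samples
    progeny_shares: np.ndarray  # recurrent share of progeny, matrix order


def _bundle(scheme_kind: str, n: int, n_markers: int, seed: int) -> SimBundle:
    genome = mabc.default_genome_model()
    rng = np.random.default_rng(seed)
    panel = mabc.random_marker_panel(genome, n_markers, rng)
    scheme = mabc.CrossScheme(scheme_kind, target_loci=[], conditioning=False)
    ds = mabc.simulate_dataset(scheme, n, genome, panel, rng)
    abh = bg.encode_abh(ds.matrix, ds.sheet)
    shares = bg.genome_share_table(abh)
    prog = shares.set_index("sample_id").loc[ds.sheet.progeny_ids, "share_recurrent"]
    return SimBundle(ds, abh, shares, prog.to_numpy(float))


@pytest.fixture(scope="session")
def genome19() -> mabc.GenomeModel:
    return mabc.default_genome_model()


@pytest.fixture(scope="session")
def bc1_large() -> SimBundle:
    """Neutral BC1: 19 chromosomes x 100 cM, 5,000 markers, 2,000 plants."""
    return _bundle("BC1", 2000, 5000, seed=190_001)


@pytest.fixture(scope="session")
def f1xf1_large() -> SimBundle:
    """Neutral F1xF1 double hybrids: same genome, 5,000 markers, 2,000 plants."""
    return _bundle("F1xF1", 2000, 5000, seed=190_002)


@pytest.fixture(scope="session")
def mixed_small() -> SimBundle:
    """Small mixed panel (parents, F1, 60 BC1, 800 markers) for PCA checks."""
    return _bundle("BC1", 60, 800, seed=190_003)


def qc_fixture():
    """Matrix with a known filter-cascade construction.

    60 markers, 2 parents + 20 progeny:
      - markers 0-11: one missing call each        -> fail functional
      - markers 12-16: monomorphic hom-ref         -> fail MAF
      - marker 17: recurrent parent heterozygous   -> fail parent filter
      - markers 18-23: parents share hom-ref, progeny segregate
                                                    -> fail parent filter
      - markers 24-59: informative (RP hom-ref, DP hom-alt, progeny A/H)
    Cascade counts: 60 -> 48 -> 43 -> 36.
    """
    n_samples, n_markers = 22, 60
    genome = mabc.default_genome_model(n_chromosomes=2)
    rng = np.random.default_rng(190_004)
    table = pd.DataFrame(
        {
            "id": [f"Q{i:03d}" for i in range(n_markers)],
            "chromosome": ["A01"] * 30 + ["A02"] * 30,
            "cm": list(np.linspace(0, 99, 30)) * 2,
            "bp": list(np.linspace(1, 1e6, 30, dtype=np.int64)) * 2,
            "ref": "A",
            "alt": "G",
        }
    )
    panel = mabc.MarkerPanel(table, genome)
    calls = np.zeros((n_samples, n_markers), dtype=np.int8)
    # informative block: RP (row 0) hom-ref, DP (row 1) hom-alt, progeny alternate A/H
    calls[1, 24:] = 2
    calls[2::2, 24:] = 1
    # parent-nonpolymorphic block: both parents hom-ref, half the progeny het
    calls[2:12, 18:24] = 1
    # RP-het marker, still polymorphic overall
    calls[0, 17] = 1
    calls[2:8, 17] = 1
    # monomorphic block stays all hom-ref (cols 12-16)
    # missing block: informative pattern plus one missing call each
    calls[1, 0:12] = 2
    calls[2::2, 0:12] = 1
    for j in range(12):
        calls[2 + j, j] = -1
    sheet = mabc.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["RP", "DP"] + [f"P{i:02d}" for i in range(20)],
                "role": ["recurrent_parent", "donor_parent"] + ["progeny"] * 20,
                "population": "A",
                "generation": "BC1",
            }
        )
    )
    matrix = mabc.GenotypeMatrix(sheet.ids, panel, calls)
    return matrix, sheet


@pytest.fixture()
def qc_matrix_sheet():
    return qc_fixture()
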