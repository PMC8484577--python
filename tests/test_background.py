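"""ABH encoding and recurrent-parent genome-share statistics."""

import numpy as np
import pandas as pd
import pytest

import mabc
from mabc import background as bg
from mabc.genio import ABH_A, ABH_B, ABH_H, ABHMatrix, MISSING


def _abh_fixture(rows, ids=None, n_chrom=2):
    genome = mabc.default_genome_model(n_chromosomes=n_chrom)
    n = len(rows[0])
    per = n // n_chrom
    table = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(n)],
            "chromosome": np.repeat(genome.names[:n_chrom], per)[:n],
            "cm": list(np.linspace(0, 99, per)) * n_chrom,
            "bp": list(np.linspace(1, 1e6, per, dtype=np.int64)) * n_chrom,
            "ref": "A",
            "alt": "G",
        }
    )
    # no genome attached: permutation tests reorder markers freely
    panel = mabc.MarkerPanel(table)
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return ABHMatrix(ids, panel, np.array(rows, dtype=np.int8))


def test_share_formula_closed_forms():
    abh = _abh_fixture(
        [
            [ABH_A] * 100,               # pure recurrent -> 100
            [ABH_H] * 100,               # F1 -> 50
            [ABH_A] * 50 + [ABH_H] * 50,  # BC1 archetype -> 75
        ]
    )
    assert bg.genome_share(abh, "s0").share_recurrent == 100.0
    assert bg.genome_share(abh, "s1").share_recurrent == 50.0
    rec = bg.genome_share(abh, "s2")
    assert rec.share_recurrent == 75.0
    assert rec.share_donor == 25.0
    assert (rec.n_a, rec.n_h, rec.n_b) == (50, 50, 0)


def test_share_complementarity_and_missing_exclusion():
    abh = _abh_fixture([[ABH_A, ABH_H, ABH_B, MISSING] * 25])
    rec = bg.genome_share(abh, "s0")
    assert rec.share_recurrent + rec.share_donor == pytest.approx(100.0)
    assert rec.n_missing == 25
    # missing calls drop from the denominator: 25 A, 25 H, 25 B over 150 alleles
    assert rec.share_recurrent == pytest.approx(100 * (2 * 25 + 25) / 150)


def test_all_missing_sample_errors():
    abh = _abh_fixture([[MISSING] * 10])
    with pytest.raises(ValueError, match="no non-missing"):
        bg.genome_share(abh, "s0")


def test_share_invariant_under_marker_permutation_and_duplication():
    rng = np.random.default_rng(0)
    row = rng.integers(0, 3, size=60)
    abh = _abh_fixture([row])
    base = bg.genome_share(abh, "s0").share_recurrent
    perm = rng.permutation(60)
    abh_p = ABHMatrix(["s0"], abh.panel.subset(perm), abh.calls[:, perm])
    assert bg.genome_share(abh_p, "s0").share_recurrent == pytest.approx(base)
    dup_panel = pd.concat(
        [abh.panel.table, abh.panel.table.assign(id=lambda d: d["id"] + "_dup")],
        ignore_index=True,
    )
    abh_d = ABHMatrix(
        ["s0"], mabc.MarkerPanel(dup_panel), np.tile(abh.calls, 2)
    )
    assert bg.genome_share(abh_d, "s0").share_recurrent == pytest.approx(base)


def test_encode_abh_reference_rows(qc_matrix_sheet):
    matrix, sheet = qc_matrix_sheet
    filtered, _ = mabc.qc_report(matrix, sheet)
    abh = bg.encode_abh(filtered, sheet)
    assert (abh.row("RP") == ABH_A).all()
    assert (abh.row("DP") == ABH_B).all()


def test_encode_abh_rejects_unfiltered_markers(qc_matrix_sheet):
    matrix, sheet = qc_matrix_sheet
    with pytest.raises(ValueError, match="parent_polymorphic_filter"):
        bg.encode_abh(matrix, sheet)


def test_encode_abh_handles_swapped_reference_allele():
    """A marker where the recurrent parent is hom-alt must still map to A."""
    genome = mabc.default_genome_model(n_chromosomes=1)
    table = pd.DataFrame(
        {"id": ["m0", "m1"], "chromosome": "A01", "cm": [10.0, 20.0],
         "bp": [10, 20], "ref": "A", "alt": "G"}
    )
    panel = mabc.MarkerPanel(table, genome)
    #       m0: RP hom-ref, m1: RP hom-alt
    calls = np.array([[0, 2], [2, 0], [2, 2], [1, 1], [0, -1]], dtype=np.int8)
    sheet = mabc.SampleSheet(
        pd.DataFrame(
            {"sample_id": ["RP", "DP", "x1", "x2", "x3"],
             "role": ["recurrent_parent", "donor_parent"] + ["progeny"] * 3}
        )
    )
    abh = bg.encode_abh(mabc.GenotypeMatrix(sheet.ids, panel, calls), sheet)
    assert abh.row("x1").tolist() == [ABH_B, ABH_A]
    assert abh.row("x2").tolist() == [ABH_H, ABH_H]
    assert abh.row("x3").tolist() == [ABH_A, MISSING]


def test_bc1_progeny_have_no_donor_homozygotes(bc1_large):
    """Without genotyping error a BC1 cannot be donor-homozygous at fixed markers."""
    prog_idx = [bc1_large.abh.sample_ids.index(s) for s in bc1_large.ds.sheet.progeny_ids]
    assert (bc1_large.abh.calls[prog_idx] == ABH_B).sum() == 0


@pytest.mark.parametrize(
    "kind,t,expected",
    [("BC1", None, 75.0), ("BC2", None, 87.5), ("BC", 2, 87.5), ("BC", 0, 50.0),
     ("F1xF1", None, 50.0), ("F1_x_F1", None, 50.0)],
)
def test_expected_share_closed_form(kind, t, expected):
    assert bg.expected_share(kind, t) == expected


def test_expected_share_rejects_garbage():
    with pytest.raises(ValueError):
        bg.expected_share("BCx")
    with pytest.raises(ValueError):
        bg.expected_share("BC", -1)


def test_share_report_strict_above_rule():
    abh = _abh_fixture(
        [
            [ABH_A] * 24 + [ABH_H] * 26 + [ABH_A] * 24 + [ABH_H] * 26,  # 74
            [ABH_A] * 50 + [ABH_H] * 50,                                 # 75
            [ABH_A] * 52 + [ABH_H] * 48,                                 # 76
            [ABH_A] * 60 + [ABH_H] * 40,                                 # 80
        ],
        ids=["p1", "p2", "p3", "p4"],
    )
    records = bg.genome_share_table(abh)
    sheet = mabc.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["RP", "DP", "p1", "p2", "p3", "p4"],
                "role": ["recurrent_parent", "donor_parent"] + ["progeny"] * 4,
                "population": "A",
                "generation": "BC1",
            }
        )
    )
    rep = bg.share_report(records, sheet, expected=75.0)
    row = rep.summary.iloc[0]
    assert (row["min"], row["max"]) == (74.0, 80.0)
    assert row["n_above"] == 2 and row["pct_above"] == 50.0
    # ranked descending, ties by id
    assert rep.per_plant["sample_id"].tolist() == ["p4", "p3", "p2", "p1"]

    single = bg.share_report(records[records.sample_id == "p2"], sheet, expected=75.0)
    assert single.summary.iloc[0]["n_above"] == 0  # 75 is not above 75


def test_share_report_derives_expectation_from_generation(bc1_large):
    rep = bg.share_report(bc1_large.shares, bc1_large.ds.sheet, expected=None)
    assert rep.summary.iloc[0]["expected"] == 75.0
    # symmetric share distribution: about half the plants above expectation
    assert rep.summary.iloc[0]["pct_above"] == pytest.approx(50.0, abs=5.0)


def test_per_chromosome_share_identity_and_f1(bc1_large):
    abh = bc1_large.abh
    f1_id = bc1_large.ds.sheet.ids_with_role("F1_control")[0]
    per = bg.per_chromosome_share(abh, f1_id)
    assert np.allclose(per.to_numpy(float), 50.0)
    # whole-genome share equals scored-marker-weighted mean of per-chromosome shares
    sample = bc1_large.ds.sheet.progeny_ids[0]
    per_s = bg.per_chromosome_share(abh, sample)
    row = abh.row(sample)
    chroms = abh.panel.chromosomes
    weights = np.array([(row[chroms == c] != MISSING).sum() for c in per_s.index])
    whole = bg.genome_share(abh, sample).share_recurrent
    assert np.average(per_s.to_numpy(float), weights=weights) == pytest.approx(whole)


def test_per_chromosome_share_undefined_without_markers():
    abh = _abh_fixture([[ABH_A] * 10 + [MISSING] * 10], n_chrom=2)
    per = bg.per_chromosome_share(abh, "s0")
    assert per["A01"] == 100.0
    assert np.isnan(per["A02"])


def test_conditioned_target_chromosome_shows_linkage_drag(genome19):
    rng = np.random.default_rng(190_030)
    panel = mabc.random_marker_panel(genome19, 1900, rng)
    scheme = mabc.CrossScheme(
        "BC1", target_loci=[("A01", 50.0)], conditioning=True
    )
    ds = mabc.simulate_dataset(scheme, 150, genome19, panel, rng)
    abh = bg.encode_abh(ds.matrix, ds.sheet)
    per = pd.DataFrame({s: bg.per_chromosome_share(abh, s) for s in ds.sheet.progeny_ids}).T
    means = per.mean(axis=0)
    assert means["A01"] < means.drop("A01").min()
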