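"""Summary-statistics containers, harmonization and text round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (
    SumStats,
    harmonize,
    is_palindromic,
    read_sumstats,
    write_sumstats,
)
from conftest import make_record, make_sumstats


class TestValidation:
    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            make_record("rs1", 0.1, 0.0, 0.5)

    def test_rejects_out_of_range_pval(self):
        with pytest.raises(ValueError):
            make_record("rs1", 0.1, 0.1, 0.0)
        with pytest.raises(ValueError):
            make_record("rs1", 0.1, 0.1, 1.5)

    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            make_record("rs1", 0.1, 0.1, 0.5, ea="A", oa="A")

    def test_rejects_duplicate_rsids(self):
        rows = [
            {"rsid": "rs1", "beta": 0.1, "se": 0.1, "pval": 0.5},
            {"rsid": "rs1", "beta": 0.2, "se": 0.1, "pval": 0.5},
        ]
        with pytest.raises(ValueError):
            make_sumstats("x", rows)


@pytest.mark.parametrize(
    "ea,oa,expected",
    [
        ("A", "T", True),
        ("T", "A", True),
        ("C", "G", True),
        ("G", "C", True),
        ("A", "G", False),
        ("C", "T", False),
    ],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_is_palindromic_rejects_invalid_symbol():
    with pytest.raises(ValueError):
        is_palindromic("A", "N")


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, beta_out=0.05):
        exp = make_sumstats(
            "x",
            [{"rsid": "rs1", "beta": 0.10, "se": 0.02, "pval": 1e-6,
              "ea": exp_alleles[0], "oa": exp_alleles[1]}],
        )
        out = make_sumstats(
            "y",
            [{"rsid": "rs1", "beta": beta_out, "se": 0.01, "pval": 0.01,
              "ea": out_alleles[0], "oa": out_alleles[1]}],
        )
        return exp, out

    def test_identity_orientation_unchanged(self):
        h = harmonize(*self._pair(("A", "G"), ("A", "G")))
        assert h.table.loc[0, "beta_out"] == 0.05
        assert not h.table.loc[0, "flipped"]

    def test_swapped_alleles_flip_sign(self):
        h = harmonize(*self._pair(("A", "G"), ("G", "A")))
        assert h.table.loc[0, "beta_out"] == -0.05
        assert h.table.loc[0, "flipped"]

    def test_palindromic_dropped_in_strict_mode(self):
        exp, out = self._pair(("A", "T"), ("A", "T"))
        with pytest.raises(ValueError):  # the only row is dropped
            harmonize(exp, out)
        # alongside a non-palindromic row the counter is visible
        exp2 = make_sumstats(
            "x",
            [
                {"rsid": "rs1", "beta": 0.1, "se": 0.02, "pval": 1e-6, "ea": "A", "oa": "T"},
                {"rsid": "rs2", "beta": 0.1, "se": 0.02, "pval": 1e-6, "ea": "A", "oa": "G"},
            ],
        )
        out2 = make_sumstats(
            "y",
            [
                {"rsid": "rs1", "beta": 0.05, "se": 0.01, "pval": 0.1, "ea": "A", "oa": "T"},
                {"rsid": "rs2", "beta": 0.05, "se": 0.01, "pval": 0.1, "ea": "A", "oa": "G"},
            ],
        )
        h = harmonize(exp2, out2)
        assert h.n_dropped_palindromic == 1
        assert len(h) == 1

    def test_palindromic_kept_when_not_strict(self):
        h = harmonize(*self._pair(("A", "T"), ("A", "T")), drop_palindromic=False)
        assert len(h) == 1

    def test_mismatched_alleles_dropped_and_counted(self):
        exp2 = make_sumstats(
            "x",
            [
                {"rsid": "rs1", "beta": 0.1, "se": 0.02, "pval": 1e-6, "ea": "A", "oa": "G"},
                {"rsid": "rs2", "beta": 0.1, "se": 0.02, "pval": 1e-6, "ea": "A", "oa": "G"},
            ],
        )
        out2 = make_sumstats(
            "y",
            [
                {"rsid": "rs1", "beta": 0.05, "se": 0.01, "pval": 0.1, "ea": "A", "oa": "C"},
                {"rsid": "rs2", "beta": 0.05, "se": 0.01, "pval": 0.1, "ea": "A", "oa": "G"},
            ],
        )
        h = harmonize(exp2, out2)
        assert h.n_dropped_unmatched == 1
        assert h.rsids == ["rs2"]

    def test_empty_intersection_raises(self):
        exp = make_sumstats("x", [{"rsid": "rs1", "beta": 0.1, "se": 0.02, "pval": 1e-6}])
        out = make_sumstats("y", [{"rsid": "rs2", "beta": 0.1, "se": 0.02, "pval": 1e-6}])
        with pytest.raises(ValueError):
            harmonize(exp, out)

    def test_idempotent_on_aligned_pair(self):
        """Re-harmonizing an already aligned pair changes nothing."""
        rng = np.random.default_rng(1)
        rows_x, rows_y = [], []
        for i in range(8):
            rows_x.append({"rsid": f"rs{i}", "pos": i + 1, "beta": rng.normal(),
                           "se": 0.05, "pval": 0.001})
            rows_y.append({"rsid": f"rs{i}", "pos": i + 1, "beta": rng.normal(),
                           "se": 0.05, "pval": 0.5})
        exp, out = make_sumstats("x", rows_x), make_sumstats("y", rows_y)
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out)
        assert h1.table.equals(h2.table)
        assert not h1.table["flipped"].any()

    def test_double_flip_preserves_wald_ratios(self):
        """Swapping the outcome's allele roles flips the recorded sign but
        leaves every downstream Wald ratio identical."""
        exp = make_sumstats(
            "x", [{"rsid": "rs1", "beta": 0.1, "se": 0.02, "pval": 1e-6, "ea": "A", "oa": "G"}]
        )
        out_fwd = make_sumstats(
            "y", [{"rsid": "rs1", "beta": 0.05, "se": 0.01, "pval": 0.1, "ea": "A", "oa": "G"}]
        )
        out_swp = make_sumstats(
            "y", [{"rsid": "rs1", "beta": -0.05, "se": 0.01, "pval": 0.1, "ea": "G", "oa": "A"}]
        )
        h1, h2 = harmonize(exp, out_fwd), harmonize(exp, out_swp)
        assert h1.table.loc[0, "beta_out"] == h2.table.loc[0, "beta_out"]


class TestRoundTrip:
    def test_write_then_read_identical_records(self, tmp_path):
        rng = np.random.default_rng(2)
        rows = [
            {
                "rsid": f"rs{i}",
                "pos": (i + 1) * 1000,
                "beta": round(float(rng.normal()), 8),
                "se": round(float(rng.uniform(0.01, 0.1)), 8),
                "pval": float(f"{rng.uniform(1e-8, 1):.6e}"),
                "eaf": round(float(rng.uniform(0.05, 0.95)), 6),
                "n": 1000,
            }
            for i in range(5)
        ]
        ss = make_sumstats("trait", rows)
        path = tmp_path / "ss.tsv"
        write_sumstats(ss, path)
        back = read_sumstats(path, trait_id="trait")
        assert back.records == ss.records

    def test_second_write_is_byte_identical(self, tmp_path):
        ss = make_sumstats(
            "t", [{"rsid": "rs1", "beta": 0.123456789, "se": 0.05, "pval": 3.2e-7}]
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sumstats(ss, p1)
        write_sumstats(read_sumstats(p1, trait_id="t"), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_sumstats(SumStats("t", "quantitative", []), path)
        assert len(path.read_text().splitlines()) == 1

    def test_invalid_rows_dropped_with_count(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "rsid\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\t1\t100\tA\tG\t0.1\t0.05\t0.01\n"
            "rs2\t1\t200\tA\tG\t0.1\t0\t0.01\n"  # se = 0 -> dropped
        )
        ss = read_sumstats(path)
        assert ss.rsids == ["rs1"]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "nope.tsv")

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("rsid\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValueError):
            read_sumstats(path)

    def test_column_map_and_comma_dialect(self, tmp_path):
        path = tmp_path / "alt.csv"
        path.write_text(
            "SNP,CHR,BP,A1,A2,b,std,p\n" "rs1,1,100,A,G,0.1,0.05,0.01\n"
        )
        ss = read_sumstats(
            path,
            column_map={
                "rsid": "SNP", "chrom": "CHR", "pos": "BP",
                "effect_allele": "A1", "other_allele": "A2",
                "beta": "b", "se": "std", "pval": "p",
            },
        )
        assert ss.rsids == ["rs1"]
        assert ss.records[0].beta == 0.1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    beta=st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 8)),
    se=st.floats(0.001, 2).map(lambda x: round(x, 8)),
    pval=st.floats(1e-30, 1).map(lambda x: float(f"{x:.6e}")),
)
def test_round_trip_property(tmp_path_factory, beta, se, pval):
    """Any record at the documented precision survives write -> read."""
    if pval == 0 or se == 0:
        return
    ss = make_sumstats("t", [{"rsid": "rs1", "beta": beta, "se": se, "pval": pval}])
    path = tmp_path_factory.mktemp("rt") / "ss.tsv"
    write_sumstats(ss, path)
    rec = read_sumstats(path, trait_id="t").records[0]
    assert math.isclose(rec.beta, beta, rel_tol=1e-9, abs_tol=1e-12)
    assert math.isclose(rec.se, se, rel_tol=1e-9)
    assert math.isclose(rec.pval, pval, rel_tol=1e-9)
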