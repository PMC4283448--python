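"""Entropy decomposition: column statistics, recursion rules, tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoscope.oligotyping import (
    AlignedReadSet,
    OligotypingParams,
    OTUTooSmallError,
    UndefinedEntropyError,
    column_entropy,
    decompose,
    dominant_fraction,
    drop_incomplete,
    max_entropy_position,
    remove_singletons,
    tabulate,
)


def _reads(rows: list[str]) -> np.ndarray:
    return np.array([list(r) for r in rows], dtype="<U1")


def _read_set(rows, sites=None, otu="OTU1"):
    reads = _reads(rows)
    if sites is None:
        sites = ["s1"] * reads.shape[0]
    return AlignedReadSet(otu_id=otu, reads=reads, site_of_read=np.array(sites))


class TestColumnStatistics:
    @pytest.mark.parametrize(
        "column, expected",
        [
            (list("AAAAAAC"), 0.5917),  # 1:6 minority, the round threshold
            (list("AAAAAA"), 0.0),
            (list("AAATTT"), 1.0),
            (list("ACGT-"), np.log2(5)),
        ],
    )
    def test_entropy_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected, abs=1e-4)

    def test_missing_excluded_from_frequencies(self):
        assert column_entropy(list("AAA...")) == 0.0
        assert column_entropy(list("AT..")) == pytest.approx(1.0)

    def test_all_missing_column_is_undefined(self):
        with pytest.raises(UndefinedEntropyError):
            column_entropy(list("...."))
        with pytest.raises(UndefinedEntropyError):
            dominant_fraction(list("."))

    @pytest.mark.parametrize(
        "column, expected",
        [
            (list("AAAAAAC"), 85.714),
            (list("A" * 10 + "C"), 90.909),
            (list("GGGG"), 100.0),
        ],
    )
    def test_dominant_fraction(self, column, expected):
        assert dominant_fraction(column) == pytest.approx(expected, abs=1e-3)

    def test_gap_is_a_legitimate_character(self):
        # internal gaps count toward entropy like any nucleotide
        assert column_entropy(list("AAA---")) == pytest.approx(1.0)


class TestMaxEntropyPosition:
    def test_monomorphic_alignment_returns_leftmost_zero(self):
        pos, ent = max_entropy_position(_reads(["ACGT", "ACGT"]))
        assert (pos, ent) == (0, 0.0)

    def test_tie_broken_leftmost(self):
        # columns 1 and 3 both split 1:1
        pos, _ = max_entropy_position(_reads(["AAGA", "ACGT"]))
        assert pos == 1

    def test_planted_column_found_by_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), size=60)
        reads = np.tile(base, (40, 1))
        reads[:15, 33] = "T" if base[33] != "T" else "G"
        # oracle: exhaustive per-column entropy scan
        oracle = max(
            range(60), key=lambda j: column_entropy(reads[:, j])
        )
        pos, ent = max_entropy_position(reads)
        assert pos == oracle == 33
        assert ent == pytest.approx(column_entropy(reads[:, 33]))


class TestDecompose:
    def test_single_round_binary_split(self):
        rows = ["AACG"] * 60 + ["ATCG"] * 40
        olig, log = decompose(_read_set(rows), OligotypingParams(min_otu_reads=50))
        assert sorted((o.label, o.n_reads) for o in olig) == [("A", 60), ("T", 40)]
        assert [r["position"] for r in log.rounds] == [1]

    def test_entropy_below_threshold_stops(self):
        # 86:14 split has H ≈ 0.584 < 0.6, verified against the closed form
        rows = ["A"] * 86 + ["C"] * 14
        rs = _read_set([r + "GGG" for r in rows])
        h = column_entropy(rs.reads[:, 0])
        assert h == pytest.approx(
            -(0.86 * np.log2(0.86) + 0.14 * np.log2(0.14)), abs=1e-12
        )
        assert h < 0.6
        olig, _ = decompose(rs, OligotypingParams(min_otu_reads=50))
        assert len(olig) == 1 and olig[0].n_reads == 100

    def test_group_below_sequence_floor_is_terminal(self):
        rows = ["AG"] * 10 + ["TG"] * 10
        olig, _ = decompose(_read_set(rows), OligotypingParams(min_otu_reads=10))
        assert len(olig) == 1

    def test_small_otu_rejected(self):
        with pytest.raises(OTUTooSmallError):
            decompose(_read_set(["ACGT"] * 100))  # needs strictly more than 100

    def test_recursive_two_position_labels(self):
        rows = (
            ["AAAA"] * 40 + ["AAAT"] * 30 + ["CAAA"] * 30
        )
        olig, _ = decompose(_read_set(rows), OligotypingParams(min_otu_reads=50))
        labels = sorted((o.label, o.n_reads) for o in olig)
        # first split at position 0 (A/C), then A-group splits at position 3
        assert labels == [("AA", 40), ("AT", 30), ("C", 30)]

    def test_reads_partition_into_oligotypes(self):
        rows = ["AACG"] * 60 + ["ATCG"] * 30 + ["AT-G"] * 20
        rs = _read_set(rows)
        olig, _ = decompose(rs, OligotypingParams(min_otu_reads=50))
        all_idx = np.sort(np.concatenate([o.read_indices for o in olig]))
        assert np.array_equal(all_idx, np.arange(rs.n_reads))

    def test_monotonicity_in_entropy_threshold(self):
        rng = np.random.default_rng(5)
        reads = rng.choice(list("ACGT"), size=(200, 30), p=[0.6, 0.2, 0.1, 0.1])
        rs = AlignedReadSet("o", reads, np.array(["s"] * 200))
        counts = []
        for h in (0.3, 0.6, 0.9, 1.3):
            olig, _ = decompose(
                rs, OligotypingParams(min_entropy=h, min_otu_reads=50)
            )
            counts.append(len(olig))
        assert counts == sorted(counts, reverse=True)


class TestDropIncomplete:
    def test_no_missing_is_identity(self):
        rows = ["AC"] * 60 + ["TC"] * 40
        olig, _ = decompose(_read_set(rows), OligotypingParams(min_otu_reads=50))
        kept, fill = drop_incomplete(olig, np.array(["s1"] * 100))
        assert len(kept) == len(olig)
        assert fill["s1"] == 1.0

    def test_incomplete_reads_set_aside_during_split(self):
        rows = ["AC"] * 60 + ["TC"] * 30 + [".C"] * 10
        rs = _read_set(rows)
        olig, log = decompose(rs, OligotypingParams(min_otu_reads=50))
        assert log.n_reads_incomplete == 10
        assert sum(o.n_reads for o in olig) == 90
        kept, fill = drop_incomplete(olig, rs.site_of_read)
        assert sum(o.n_reads for o in kept) == 90
        assert fill["s1"] == pytest.approx(0.9)

    def test_drop_oligotype_policy_removes_descendants(self):
        rows = ["AC"] * 60 + ["TC"] * 30 + [".C"] * 10
        rs = _read_set(rows)
        olig, _ = decompose(rs, OligotypingParams(min_otu_reads=50))
        assert all(o.incomplete_derived for o in olig)
        kept, _ = drop_incomplete(olig, rs.site_of_read, policy="drop_oligotype")
        assert kept == []

    def test_missing_outside_discriminant_positions_is_harmless(self):
        rows = ["AC."] * 60 + ["TC."] * 40  # '.' only in a constant column
        olig, log = decompose(_read_set(rows), OligotypingParams(min_otu_reads=50))
        assert log.n_reads_incomplete == 0
        assert sum(o.n_reads for o in olig) == 100


class TestTabulate:
    def test_counts_conserve_reads_and_fix_site_order(self):
        rows = ["AC"] * 60 + ["TC"] * 40
        sites = (["HGIV"] * 30 + ["HGI"] * 30) + (["S3"] * 20 + ["HGI"] * 20)
        rs = _read_set(rows, sites)
        olig, _ = decompose(rs, OligotypingParams(min_otu_reads=50))
        table = tabulate(olig)
        assert list(table.counts.columns) == ["HGI", "HGIV", "S3"]
        assert table.counts.to_numpy().sum() == 100
        assert sorted(table.counts.sum(axis=1)) == [40, 60]

    def test_unknown_site_label_raises(self):
        rows = ["AC"] * 60 + ["TC"] * 40
        rs = _read_set(rows, ["s1"] * 100)
        olig, _ = decompose(rs, OligotypingParams(min_otu_reads=50))
        from oligoscope.oligotyping import LabelingError

        with pytest.raises(LabelingError):
            tabulate(olig, site_order=["HGI"])

    def test_empty_oligotype_list(self):
        table = tabulate([], site_order=["a", "b"])
        assert table.n_oligotypes == 0 and table.sites == ["a", "b"]


class TestRemoveSingletons:
    def test_rows_with_total_one_removed(self):
        rows = ["AC"] * 60 + ["TC"] * 40 + ["GC"]  # G-read is an absolute singleton
        rs = _read_set(rows + [])
        olig, _ = decompose(rs, OligotypingParams(min_otu_reads=50))
        table = tabulate(olig)
        filtered, n_removed = remove_singletons(table)
        assert n_removed == 1
        assert (filtered.counts.sum(axis=1) > 1).all()

    def test_no_singletons_is_identity(self):
        rows = ["AC"] * 60 + ["TC"] * 40
        olig, _ = decompose(_read_set(rows), OligotypingParams(min_otu_reads=50))
        table = tabulate(olig)
        filtered, n_removed = remove_singletons(table)
        assert n_removed == 0 and filtered.counts.equals(table.counts)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_a=st.integers(1, 200),
    n_c=st.integers(0, 200),
    n_g=st.integers(0, 200),
)
def test_entropy_matches_scipy_formula(n_a, n_c, n_g):
    """Column entropy agrees with scipy.stats.entropy on the same counts."""
    from scipy.stats import entropy as scipy_entropy

    column = ["A"] * n_a + ["C"] * n_c + ["G"] * n_g
    counts = [c for c in (n_a, n_c, n_g) if c > 0]
    assert column_entropy(column) == pytest.approx(
        scipy_entropy(counts, base=2), abs=1e-12
    )
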