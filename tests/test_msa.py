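"""Alignment I/O and uncorrected p-distance behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronocal.msa import (
    Alignment,
    AlignmentError,
    SpeciesMap,
    distance_matrix,
    p_distance,
    read_alignment,
    read_species_map,
    round_half_away,
    species_pair_ranges,
    within_species_divergence,
)

GOOD = set("ACGT")


def pdist_bruteforce(a: str, b: str) -> tuple[float, int]:
    """Naive per-column re-count: the oracle for the vectorised engine."""
    pairs = [
        (x, y) for x, y in zip(a.upper(), b.upper())
        if x in GOOD and y in GOOD
    ]
    if not pairs:
        return math.nan, 0
    mism = sum(1 for x, y in pairs if x != y)
    return mism / len(pairs), len(pairs)


def random_alignment(rng, n_rows, n_sites, missing_frac=0.1):
    symbols = np.array(list("ACGTN-?RY"))
    probs = np.full(9, missing_frac / 5)
    probs[:4] = (1 - missing_frac * 9 / 5 + 4 * missing_frac / 5) / 4
    probs = probs / probs.sum()
    rows = [
        "".join(rng.choice(symbols, size=n_sites, p=probs))
        for _ in range(n_rows)
    ]
    return Alignment(tuple(f"t{i}" for i in range(n_rows)), tuple(rows))


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, frac, sites",
        [
            ("ACGT", "ACGT", 0.0, 4),          # identity
            ("AAAA", "TTTT", 1.0, 4),          # full mismatch
            ("ACGTNA", "ACGA-A", 0.2, 5),      # N and gap columns excluded
            ("acgt", "ACGT", 0.0, 4),          # case-insensitive
            ("ACGU", "ACGT", 0.0, 4),          # U treated as T
        ],
    )
    def test_examples(self, a, b, frac, sites):
        assert p_distance(a, b) == (frac, sites)

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError, match="length mismatch"):
            p_distance("ACGT", "ACGTA")

    def test_all_missing_pair_is_flagged_not_zero(self):
        frac, sites = p_distance("NN--", "??NN")
        assert math.isnan(frac) and sites == 0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.data())
    def test_symmetric_bounded_and_matches_bruteforce(self, data):
        n = data.draw(st.integers(4, 60))
        alphabet = "ACGTN-?RYKM"
        a = data.draw(st.text(alphabet=alphabet, min_size=n, max_size=n))
        b = data.draw(st.text(alphabet=alphabet, min_size=n, max_size=n))
        fab, mab = p_distance(a, b)
        fba, mba = p_distance(b, a)
        exp_f, exp_m = pdist_bruteforce(a, b)
        assert mab == mba == exp_m
        if mab == 0:
            assert math.isnan(fab) and math.isnan(fba)
        else:
            assert fab == fba == pytest.approx(exp_f, abs=0)
            assert 0.0 <= fab <= 1.0
            assert (fab == 0.0) == all(
                x == y for x, y in zip(a.upper(), b.upper())
                if x in GOOD and y in GOOD
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_pairwise_equals_complete_deletion_when_missingness_shared(
        self, data
    ):
        """When every row is missing at the same columns, excluding those
        columns globally (complete deletion) and pairwise agree."""
        n = data.draw(st.integers(4, 40))
        miss = data.draw(st.sets(st.integers(0, n - 1), max_size=n // 2))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        rows = []
        for _ in range(3):
            row = rng.choice(list("ACGT"), size=n)
            row[list(miss)] = "N"
            rows.append("".join(row))
        aln = Alignment(("a", "b", "c"), tuple(rows))
        dm_pair = distance_matrix(aln, min_comparable_sites=0)
        dm_comp = distance_matrix(
            aln, deletion="complete", min_comparable_sites=0
        )
        assert np.allclose(dm_pair.p, dm_comp.p, equal_nan=True)
        assert (dm_pair.comparable_sites == dm_comp.comparable_sites).all()


class TestDistanceMatrix:
    def test_hand_counted_matrix(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "AATT", "TTTT"))
        dm = distance_matrix(aln, min_comparable_sites=0)
        assert dm.get("a", "b") == 0.5
        assert dm.get("a", "c") == 1.0
        assert dm.get("b", "c") == 0.5
        assert np.all(np.diag(dm.p) == 0.0)

    def test_identical_rows_all_zero(self):
        aln = Alignment(("a", "b", "c"), ("ACGT",) * 3)
        dm = distance_matrix(aln, min_comparable_sites=0)
        assert np.all(dm.p == 0.0)

    def test_matches_double_loop_oracle_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            aln = random_alignment(
                rng, int(rng.integers(2, 12)), int(rng.integers(10, 120))
            )
            with pytest.warns(UserWarning):
                dm = distance_matrix(aln, min_comparable_sites=10**6)
            for i, ta in enumerate(aln.tip_ids):
                for j, tb in enumerate(aln.tip_ids):
                    exp_f, exp_m = pdist_bruteforce(aln.rows[i], aln.rows[j])
                    assert dm.comparable_sites[i, j] == exp_m
                    if exp_m:
                        assert dm.p[i, j] == pytest.approx(exp_f, abs=0)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, 8, 100)
        dm = distance_matrix(aln, min_comparable_sites=0)
        assert np.allclose(dm.p, dm.p.T, equal_nan=True)

    def test_single_row_rejected(self):
        with pytest.raises(AlignmentError, match="at least 2"):
            distance_matrix(Alignment(("a",), ("ACGT",)))

    def test_low_comparable_sites_warns(self):
        aln = Alignment(("a", "b"), ("ACGTNNNN", "ACGANNNN"))
        with pytest.warns(UserWarning, match="comparable sites"):
            distance_matrix(aln, min_comparable_sites=50)


class TestReadAlignment:
    def test_round_trip(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">s1\nACGT\n>s2\nacga\n")
        aln = read_alignment(f)
        assert aln.tip_ids == ("s1", "s2")
        assert aln.rows == ("ACGT", "ACGA")  # lowercase normalised
        assert aln.n_sites == 4

    def test_ragged_rejected_with_record_named(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">s1\nACGT\n>s2\nACGTA\n")
        with pytest.raises(AlignmentError, match="s2"):
            read_alignment(f)

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">s1\nACGT\n>s1\nACGA\n")
        with pytest.raises(AlignmentError, match="s1"):
            read_alignment(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_alignment(tmp_path / "nope.fasta")

    def test_non_fasta_content(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text("this is not fasta\n")
        with pytest.raises(AlignmentError, match="no FASTA records"):
            read_alignment(f)

    def test_invalid_symbols_rejected(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">s1\nAC9T\n")
        with pytest.raises(AlignmentError, match="s1"):
            read_alignment(f)


class TestSpeciesRanges:
    def test_cross_pair_example(self):
        # X = {x1, x2}, Y = {y1}; p(x1,y1)=0.10, p(x2,y1)=0.14
        aln = Alignment(
            ("x1", "x2", "y1"),
            ("A" * 50, "A" * 48 + "GG", "T" * 5 + "A" * 45),
        )
        sm = SpeciesMap({"x1": "X", "x2": "X", "y1": "Y"})
        dm = distance_matrix(aln, min_comparable_sites=0)
        assert dm.get("x1", "y1") == pytest.approx(0.10)
        assert dm.get("x2", "y1") == pytest.approx(0.14)
        ranges = species_pair_ranges(dm, sm)
        assert ranges.get("X", "Y") == (10.0, 14.0)

    def test_enumeration_oracle_on_random_alignment(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 9, 200, missing_frac=0.05)
        species = ["s1", "s1", "s1", "s2", "s2", "s3", "s3", "s3", "s4"]
        sm = SpeciesMap(dict(zip(aln.tip_ids, species)))
        dm = distance_matrix(aln, min_comparable_sites=0)
        ranges = species_pair_ranges(dm, sm, decimals=4)
        groups = {}
        for tid, sp in sm.entries.items():
            groups.setdefault(sp, []).append(aln.tip_ids.index(tid))
        for a in groups:
            for b in groups:
                if a >= b:
                    continue
                vals = [
                    round_half_away(100 * dm.p[i, j], 4)
                    for i in groups[a]
                    for j in groups[b]
                ]
                assert ranges.get(a, b) == (min(vals), max(vals))

    def test_single_individuals_collapse(self):
        aln = Alignment(("a", "b"), ("AAAA", "AATT"))
        sm = SpeciesMap({"a": "A", "b": "B"})
        dm = distance_matrix(aln, min_comparable_sites=0)
        ranges = species_pair_ranges(dm, sm)
        lo, hi = ranges.get("A", "B")
        assert lo == hi == 50.0
        assert ranges.format_range((lo, hi)) == "50"

    def test_unmapped_tip_rejected(self):
        aln = Alignment(("a", "b"), ("AAAA", "AATT"))
        dm = distance_matrix(aln, min_comparable_sites=0)
        with pytest.raises(AlignmentError, match="no species assignment"):
            species_pair_ranges(dm, SpeciesMap({"a": "A"}))

    def test_matrix_frame_has_range_cells(self):
        aln = Alignment(
            ("a1", "a2", "b1"), ("AAAAAAAAAA", "AAAAAAAAAT", "TTTTTAAAAA")
        )
        sm = SpeciesMap({"a1": "A", "a2": "A", "b1": "B"})
        dm = distance_matrix(aln, min_comparable_sites=0)
        frame = species_pair_ranges(dm, sm).to_matrix_frame()
        # a1-b1: 5/10, a2-b1: 6/10 (five leading sites plus the final T)
        assert frame.loc["B", "A"] == "50–60"
        assert frame.loc["A", "A"] == "10"


class TestWithinSpecies:
    def _dm(self, rows):
        aln = Alignment(tuple(f"t{i}" for i in range(len(rows))), tuple(rows))
        return aln, distance_matrix(aln, min_comparable_sites=0)

    def test_identical_conspecifics_below_reference(self):
        _, dm = self._dm(["A" * 100, "A" * 100])
        sm = SpeciesMap({"t0": "X", "t1": "X"})
        w = within_species_divergence(dm, sm, "X")
        assert (w.min_percent, w.max_percent) == (0.0, 0.0)
        assert w.relation == "below"

    def test_two_of_500_sites_is_inside_reference(self):
        rows = ["A" * 500, "A" * 498 + "TT"]
        _, dm = self._dm(rows)
        sm = SpeciesMap({"t0": "X", "t1": "X"})
        w = within_species_divergence(dm, sm, "X")
        assert (w.min_percent, w.max_percent) == (0.4, 0.4)
        assert w.relation == "inside"
        assert w.inside_reference

    def test_three_conspecifics_range(self):
        # pairwise p: t0-t1 = 2/1000, t0-t2 = 4/1000, t1-t2 = 6/1000
        base = list("A" * 1000)
        s1 = base.copy()
        s2 = base.copy()
        s2[0:2] = "TT"
        s3 = base.copy()
        s3[2:6] = "TTTT"
        _, dm = self._dm(["".join(s) for s in (s1, s2, s3)])
        sm = SpeciesMap({f"t{i}": "X" for i in range(3)})
        w = within_species_divergence(dm, sm, "X")
        assert (w.min_percent, w.max_percent) == (0.2, 0.6)

    def test_singleton_species_rejected(self):
        _, dm = self._dm(["A" * 100, "T" * 100])
        sm = SpeciesMap({"t0": "X", "t1": "Y"})
        with pytest.raises(AlignmentError, match="single individual"):
            within_species_divergence(dm, sm, "X")
        with pytest.raises(AlignmentError, match="no tips"):
            within_species_divergence(dm, sm, "Z")


@pytest.mark.parametrize(
    "value, decimals, expected",
    [
        (0.25, 1, 0.3),      # ties away from zero, not banker's
        (0.35, 1, 0.4),
        (-0.25, 1, -0.3),
        (2.249, 1, 2.2),
        (0.449, 2, 0.45),
    ],
)
def test_round_half_away(value, decimals, expected):
    assert round_half_away(value, decimals) == expected


def test_species_map_tsv_round_trip(tmp_path):
    sm = SpeciesMap({"t1": "A", "t2": "A", "t3": "B"})
    path = tmp_path / "map.tsv"
    sm.to_tsv(path)
    back = read_species_map(path)
    assert back.entries == sm.entries
    assert back.counts() == {"A": 2, "B": 1}
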