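"""Inversion-scan pipeline: orientation and purity predicates, binning,
support filtering, frequency matrices and the population contrast."""

import numpy as np
import pytest

from bamsift import (
    AlignmentFields,
    BinKey,
    FrequencyMatrix,
    IafRecord,
    Manifest,
    SampleInfo,
    ScanParams,
    ValidationError,
    bin_alignments,
    is_clean_alignment,
    population_difference,
    render_heatmap,
    same_strand_pair,
    scan_records,
    support_filter,
)


def fields(**kw) -> AlignmentFields:
    base = dict(
        qname="q", flag=65, rname="1", pos=30_000_001, mapq=60,
        cigar="100M", rnext="=", pnext=30_900_001, tlen=900_000,
        seq="ACGT", qual="IIII",
    )
    base.update(kw)
    return AlignmentFields(**base)


def iaf(individual="I0", **kw) -> IafRecord:
    return IafRecord(individual, "all", fields(**kw))


class TestSameStrandPair:
    def test_both_reverse_is_same_strand(self):
        assert same_strand_pair(fields(flag=0x1 | 0x10 | 0x20))

    def test_both_forward_is_same_strand(self):
        assert same_strand_pair(fields(flag=0x1))

    def test_flag_83_is_opposite_strands(self):
        # 0x10 set but 0x20 unset: read reverse, mate forward
        assert not same_strand_pair(fields(flag=83))

    def test_unpaired_record_excluded_not_error(self):
        assert not same_strand_pair(fields(flag=0x10 | 0x20))


class TestCleanAlignment:
    @pytest.mark.parametrize(
        "cigar, tags, expected",
        [
            ("100M", (), True),
            ("76M", (("NM", "i", "0"),), True),
            ("50M2I48M", (), False),
            ("5S95M", (), False),
            ("*", (), False),
            ("76M", (("XA", "Z", "alt,+1,76M,0;"),), False),
        ],
    )
    def test_single_match_cigar_and_no_xa(self, cigar, tags, expected):
        assert is_clean_alignment(fields(cigar=cigar, tags=tags)) is expected


class TestBinning:
    def test_kb_projection_by_floor_division(self):
        key = BinKey.for_record(fields(pos=30_000_001, tlen=900_000), 1000, 1000)
        assert key == BinKey("1", 30_000, 900)

    def test_start_bin_zero_below_one_scale(self):
        assert BinKey.for_record(fields(pos=999, tlen=0), 1000, 1000).start_bin == 0

    def test_tlen_bin_uses_absolute_value(self):
        a = BinKey.for_record(fields(tlen=900_000), 1000, 1000)
        b = BinKey.for_record(fields(tlen=-900_000), 1000, 1000)
        assert a == b

    def test_duplicate_contributions_count_once(self):
        table = bin_alignments([iaf("I0") for _ in range(25)])
        assert len(table) == 1
        (key, inds), = table.items()
        assert inds == {"I0"}
        assert table.support(key) == 1

    def test_distinct_count_bounded_by_cohort(self):
        table = bin_alignments([iaf(f"I{i}") for i in range(7)])
        (key, _), = table.items()
        assert table.support(key) == 7


class TestSupportFilter:
    def _records(self, n_individuals):
        return [iaf(f"I{i}") for i in range(n_individuals)]

    def test_nineteen_individuals_removed_twenty_kept(self):
        under = self._records(19)
        table = bin_alignments(under)
        assert support_filter(under, table) == []
        at = self._records(20)
        table = bin_alignments(at)
        assert support_filter(at, table) == at  # boundary inclusive

    def test_min_support_one_is_identity(self):
        records = self._records(3)
        table = bin_alignments(records)
        assert support_filter(records, table, min_support=1) == records

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ValidationError):
            support_filter([], bin_alignments([]), min_support=0)

    def test_support_filter_depends_on_surviving_set(self):
        # unlike the per-record predicates, support is set-dependent: after
        # removing half the individuals the same bin can fall under threshold
        records = self._records(25)
        table_full = bin_alignments(records)
        subset = records[:10]
        assert support_filter(subset, table_full) == subset  # old table: passes
        table_sub = bin_alignments(subset)
        assert support_filter(subset, table_sub) == []  # rebuilt: fails


def _manifest(n):
    return Manifest(
        [SampleInfo(f"{i}.bam", f"I{i}", "CEU" if i % 2 else "YRI",
                    "EUR" if i % 2 else "AFR") for i in range(n)]
    )


class TestScan:
    def test_frequency_is_distinct_carriers_over_cohort(self):
        records = [iaf(f"I{i}") for i in range(30)]
        mats = scan_records(records, _manifest(100), ScanParams(min_support=20))
        assert list(mats) == ["1"]
        assert mats["1"].nonzero_bins() == [(30, 90, pytest.approx(0.30))]

    def test_orientation_and_purity_predicates_commute(self, rng):
        from conftest import random_record

        records = [random_record(rng) for _ in range(500)]
        a = [r for r in records if same_strand_pair(r) and is_clean_alignment(r)]
        b = [r for r in records if is_clean_alignment(r) and same_strand_pair(r)]
        assert a == b

    def test_deletion_signature_contributes_nothing(self):
        # proper orientation (read forward, mate reverse) with large |TLEN|
        records = [iaf(f"I{i}", flag=97) for i in range(30)]
        assert scan_records(records, _manifest(100), ScanParams(min_support=20)) == {}

    def test_empty_input_gives_no_matrices(self):
        assert scan_records([], _manifest(10)) == {}

    def test_unknown_individual_rejected(self):
        with pytest.raises(ValidationError, match="absent from manifest"):
            scan_records([iaf("STRANGER")], _manifest(3))

    def test_population_restriction_changes_denominator(self):
        carriers = [iaf(f"I{i}") for i in range(1, 10, 2)]  # 5 odd = CEU/EUR
        manifest = _manifest(20)
        mats = scan_records(carriers, manifest, ScanParams(min_support=1),
                            individuals=manifest.select("EUR"))
        assert mats["1"].nonzero_bins() == [(30, 90, pytest.approx(0.5))]


class TestPopulationDifference:
    def _matrix(self, values, **kw):
        base = dict(chromosome="17", cohort_size=10)
        base.update(kw)
        return FrequencyMatrix(values=np.array(values, dtype=float), **base)

    def test_identical_matrices_give_zero(self):
        m = self._matrix([[0.2, 0.0], [0.1, 0.5]])
        assert np.all(population_difference(m, m).values == 0)

    def test_sign_convention_a_minus_b(self):
        a = self._matrix([[0.2]])
        b = self._matrix([[0.0]])
        assert population_difference(a, b).values[0, 0] == pytest.approx(0.2)

    def test_per_population_denominators(self):
        # 5 of 25 vs 10 of 100 -> 0.20 - 0.10 = 0.10
        a = self._matrix([[5 / 25]], cohort_size=25)
        b = self._matrix([[10 / 100]], cohort_size=100)
        assert population_difference(a, b).values[0, 0] == pytest.approx(0.10)

    def test_shapes_padded_to_union(self):
        a = self._matrix([[0.1, 0.2]])
        b = self._matrix([[0.3], [0.4]])
        diff = population_difference(a, b)
        assert diff.values.shape == (2, 2)
        assert diff.values[0, 0] == pytest.approx(-0.2)
        assert diff.values[1, 0] == pytest.approx(-0.4)
        assert diff.values[0, 1] == pytest.approx(0.2)

    def test_mismatched_chromosome_or_scale_rejected(self):
        a = self._matrix([[0.1]])
        with pytest.raises(ValidationError):
            population_difference(a, self._matrix([[0.1]], chromosome="5"))
        with pytest.raises(ValidationError):
            population_difference(a, self._matrix([[0.1]], tlen_scale=1000))

    def test_difference_bounded_in_minus_one_one(self):
        a = self._matrix([[1.0, 0.0]])
        b = self._matrix([[0.0, 1.0]])
        diff = population_difference(a, b).values
        assert diff.min() >= -1 and diff.max() <= 1


class TestHeatmap:
    @staticmethod
    def _cell_centroid(tmp_path, name, row, col):
        """Pixel centroid of the single highlighted cell, found by diffing
        against an all-zero render of the same geometry."""
        from PIL import Image

        def _render(values, fname):
            matrix = FrequencyMatrix(chromosome="1", values=values, cohort_size=10)
            return np.asarray(
                Image.open(render_heatmap(matrix, tmp_path / fname)).convert("RGB"),
                dtype=int,
            )

        values = np.zeros((3, 5))
        values[row, col] = 0.4
        img = _render(values, f"{name}.png")
        background = _render(np.zeros((3, 5)), f"{name}.bg.png")
        delta = np.abs(img - background).sum(axis=2)
        ys, xs = np.nonzero(delta > 30)
        assert len(ys), "no highlighted cell found"
        return ys.mean(), xs.mean()

    def test_single_nonzero_cell_lands_at_expected_row_and_col(self, tmp_path):
        # origin is upper-left: larger row -> lower on the image,
        # larger column -> further right
        y_a, x_a = self._cell_centroid(tmp_path, "a", row=1, col=3)
        y_b, x_b = self._cell_centroid(tmp_path, "b", row=2, col=1)
        assert y_a < y_b  # row 1 renders above row 2
        assert x_a > x_b  # column 3 renders right of column 1

    def test_all_zero_matrix_renders_uniform_background(self, tmp_path):
        matrix = FrequencyMatrix(chromosome="1", values=np.zeros((4, 4)), cohort_size=5)
        path = render_heatmap(matrix, tmp_path / "z.png")
        assert path.exists() and path.stat().st_size > 0

    def test_log_and_linear_share_geometry(self, tmp_path):
        values = np.zeros((3, 3))
        values[2, 1] = 0.7
        matrix = FrequencyMatrix(chromosome="1", values=values, cohort_size=10)
        from PIL import Image

        a = np.asarray(Image.open(render_heatmap(matrix, tmp_path / "log.png", True)).convert("L"))
        b = np.asarray(Image.open(render_heatmap(matrix, tmp_path / "lin.png", False)).convert("L"))
        assert a.shape == b.shape
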