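"""study_io: count reconstruction, parsing, and the bundled fixture."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpmeta import (
    ControlSource,
    Ethnicity,
    GenotypeCounts,
    ParseError,
    Study,
    StudyCollection,
    ValidationError,
    bundled_fixture,
    parse_study_table,
    reconstruct_counts,
    write_study_table,
)

# ---------------------------------------------------------------------------
# oracles


def enumerate_minimax_triples(n, freqs):
    """Brute force: all integer triples summing to n that minimise the
    maximum absolute deviation from n*freq."""
    best, best_dev = [], None
    for gg in range(n + 1):
        for ga in range(n + 1 - gg):
            aa = n - gg - ga
            dev = max(
                abs(gg - n * freqs[0]),
                abs(ga - n * freqs[1]),
                abs(aa - n * freqs[2]),
            )
            if best_dev is None or dev < best_dev - 1e-12:
                best, best_dev = [(gg, ga, aa)], dev
            elif abs(dev - best_dev) < 1e-12:
                best.append((gg, ga, aa))
    return best


# ---------------------------------------------------------------------------
# GenotypeCounts


class TestGenotypeCounts:
    def test_total(self):
        assert GenotypeCounts(1, 2, 3).total == 6

    @pytest.mark.parametrize("bad", [(-1, 0, 5), (0, 0, 0)])
    def test_invalid(self, bad):
        with pytest.raises(ValidationError):
            GenotypeCounts(*bad)

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            GenotypeCounts(1.5, 2, 3)


# ---------------------------------------------------------------------------
# reconstruct_counts


class TestReconstructCounts:
    def test_exact_products(self):
        assert reconstruct_counts(100, (0.25, 0.50, 0.25)).as_tuple() == (25, 50, 25)

    def test_case_row_rounding(self):
        # frozen from the enumeration oracle: unique minimax triple
        expected = enumerate_minimax_triples(160, (0.400, 0.444, 0.156))
        assert expected == [(64, 71, 25)]
        assert reconstruct_counts(160, (0.400, 0.444, 0.156)).as_tuple() == (64, 71, 25)

    def test_control_row_rounding(self):
        expected = enumerate_minimax_triples(76, (0.158, 0.487, 0.355))
        assert expected == [(12, 37, 27)]
        assert reconstruct_counts(76, (0.158, 0.487, 0.355)).as_tuple() == (12, 37, 27)

    def test_sum_outside_tolerance(self):
        with pytest.raises(ValidationError, match="sum"):
            reconstruct_counts(100, (0.4, 0.4, 0.1))

    def test_offending_row_named(self):
        with pytest.raises(ValidationError, match="RowX"):
            reconstruct_counts(100, (0.4, 0.4, 0.1), label="RowX")

    def test_negative_n(self):
        with pytest.raises(ValidationError):
            reconstruct_counts(-5, (0.25, 0.5, 0.25))

    def test_proportion_out_of_unit_interval(self):
        with pytest.raises(ValidationError):
            reconstruct_counts(100, (1.2, -0.2, 0.0))

    @given(
        n=st.integers(min_value=1, max_value=2000),
        raw=st.tuples(
            st.floats(0.001, 1.0), st.floats(0.001, 1.0), st.floats(0.001, 1.0)
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_sums_exactly_to_n(self, n, raw):
        total = sum(raw)
        freqs = tuple(x / total for x in raw)
        counts = reconstruct_counts(n, freqs)
        assert counts.total == n

    @given(
        n=st.integers(min_value=1, max_value=60),
        raw=st.tuples(
            st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0)
        ),
    )
    @settings(max_examples=60, deadline=None)
    def test_minimax_against_enumeration(self, n, raw):
        total = sum(raw)
        freqs = tuple(x / total for x in raw)
        got = reconstruct_counts(n, freqs).as_tuple()
        winners = enumerate_minimax_triples(n, freqs)
        got_dev = max(abs(g - n * f) for g, f in zip(got, freqs))
        best_dev = max(abs(w - n * f) for w, f in zip(winners[0], freqs))
        assert got_dev <= best_dev + 1e-9


# ---------------------------------------------------------------------------
# parsing


COUNT_HEADER = (
    "study,year,ethnicity,source,n_case,n_control,"
    "case_GG,case_GA,case_AA,ctrl_GG,ctrl_GA,ctrl_AA"
)
FREQ_HEADER = (
    "study,year,ethnicity,source,n_case,n_control,"
    "case_fGG,case_fGA,case_fAA,ctrl_fGG,ctrl_fGA,ctrl_fAA"
)


class TestParseStudyTable:
    def test_single_count_row_passthrough(self):
        text = COUNT_HEADER + "\nA 2011,2011,Asian,Hospital,160,320,64,71,25,141,151,28\n"
        coll = parse_study_table(io.StringIO(text))
        assert len(coll) == 1
        assert coll[0].cases.as_tuple() == (64, 71, 25)
        assert coll[0].controls.as_tuple() == (141, 151, 28)

    def test_frequency_mode_reconstructs(self):
        text = (
            FREQ_HEADER
            + "\nA,2011,Asian,Hospital,160,320,0.400,0.444,0.156,0.441,0.472,0.088\n"
        )
        coll = parse_study_table(io.StringIO(text))
        assert coll[0].cases.as_tuple() == (64, 71, 25)
        assert coll[0].controls.total == 320

    def test_tab_delimiter_autodetected(self):
        text = (
            COUNT_HEADER.replace(",", "\t")
            + "\nA\t2011\tAsian\tHospital\t160\t320\t64\t71\t25\t141\t151\t28\n"
        )
        coll = parse_study_table(io.StringIO(text))
        assert len(coll) == 1

    def test_missing_column_named(self):
        text = "study,year,ethnicity,n_case,n_control\nA,2011,Asian,10,10\n"
        with pytest.raises(ParseError, match="source"):
            parse_study_table(io.StringIO(text))

    def test_duplicate_label(self):
        row = "A,2011,Asian,Hospital,160,320,64,71,25,141,151,28"
        text = COUNT_HEADER + f"\n{row}\n{row}\n"
        with pytest.raises(ValidationError, match="duplicate"):
            parse_study_table(io.StringIO(text))

    def test_bad_proportion_sum(self):
        text = (
            FREQ_HEADER
            + "\nA,2011,Asian,Hospital,160,320,0.4,0.4,0.1,0.441,0.472,0.088\n"
        )
        with pytest.raises(ValidationError, match="sum"):
            parse_study_table(io.StringIO(text))

    def test_mixed_counts_and_freqs_in_one_arm(self):
        header = (
            "study,year,ethnicity,source,n_case,n_control,"
            "case_GG,case_fGA,case_fAA,ctrl_GG,ctrl_GA,ctrl_AA"
        )
        text = header + "\nA,2011,Asian,Hospital,160,320,64,0.444,0.156,141,151,28\n"
        with pytest.raises(ValidationError, match="mixed"):
            parse_study_table(io.StringIO(text))

    def test_count_sum_must_match_declared_n(self):
        text = COUNT_HEADER + "\nA,2011,Asian,Hospital,999,320,64,71,25,141,151,28\n"
        with pytest.raises(ValidationError, match="declared"):
            parse_study_table(io.StringIO(text))

    def test_unknown_stratum_is_error(self):
        text = COUNT_HEADER + "\nA,2011,Martian,Hospital,160,320,64,71,25,141,151,28\n"
        with pytest.raises(ValidationError, match="ethnicity"):
            parse_study_table(io.StringIO(text))

    def test_case_insensitive_strata(self):
        text = COUNT_HEADER + "\nA,2011,asian,population-based,160,320,64,71,25,141,151,28\n"
        coll = parse_study_table(io.StringIO(text))
        assert coll[0].ethnicity is Ethnicity.ASIAN
        assert coll[0].control_source is ControlSource.POPULATION


class TestRoundTrip:
    def test_fixture_roundtrip(self, fixture_collection):
        buf = io.StringIO()
        write_study_table(fixture_collection, buf)
        reparsed = parse_study_table(io.StringIO(buf.getvalue()))
        assert reparsed.labels == fixture_collection.labels
        for a, b in zip(reparsed, fixture_collection):
            assert a.cases == b.cases
            assert a.controls == b.controls
            assert a.ethnicity == b.ethnicity
            assert a.control_source == b.control_source


# ---------------------------------------------------------------------------
# bundled fixture


# printed per-study genotype proportions (case, control) for the 7 studies
FIXTURE_PROPORTIONS = {
    "Bao 2011": ((0.400, 0.444, 0.156), (0.441, 0.472, 0.088)),
    "Wang 2010": ((0.443, 0.454, 0.103), (0.528, 0.398, 0.074)),
    "Pinto 2009": ((0.285, 0.479, 0.236), (0.280, 0.460, 0.260)),
    "Liu 2009": ((0.446, 0.464, 0.089), (0.474, 0.443, 0.082)),
    "Costa 2007": ((0.284, 0.492, 0.223), (0.230, 0.467, 0.304)),
    "Vauleon 2007": ((0.211, 0.488, 0.301), (0.145, 0.561, 0.294)),
    "Bhowmick 2004": ((0.357, 0.381, 0.262), (0.158, 0.487, 0.355)),
}


class TestBundledFixture:
    def test_seven_studies(self, fixture_collection):
        assert len(fixture_collection) == 7

    def test_totals(self, fixture_collection):
        assert fixture_collection.total_cases == 1613
        assert fixture_collection.total_controls == 2267

    def test_strata_counts(self, fixture_collection):
        eth = [s.ethnicity for s in fixture_collection]
        src = [s.control_source for s in fixture_collection]
        assert eth.count(Ethnicity.ASIAN) == 3
        assert eth.count(Ethnicity.CAUCASIAN) == 4
        assert src.count(ControlSource.HOSPITAL) == 5
        assert src.count(ControlSource.POPULATION) == 2

    def test_wang_controls_reconstruction(self, fixture_collection):
        expected = reconstruct_counts(693, (0.528, 0.398, 0.074))
        assert expected.as_tuple() == (366, 276, 51)
        assert fixture_collection["Wang 2010"].controls.as_tuple() == (366, 276, 51)

    @pytest.mark.parametrize("label", list(FIXTURE_PROPORTIONS))
    def test_proportions_reproduced(self, fixture_collection, label):
        # reconstructed counts / n must reproduce each printed proportion
        study = fixture_collection[label]
        case_f, ctrl_f = FIXTURE_PROPORTIONS[label]
        for counts, printed in [(study.cases, case_f), (study.controls, ctrl_f)]:
            n = counts.total
            for got, want in zip(counts.proportions(), printed):
                assert got == pytest.approx(want, abs=0.0005 + 0.5 / n)

    def test_fixture_matches_reconstruction(self, fixture_collection):
        # bundled counts are exactly what reconstruct_counts would produce
        for label, (case_f, ctrl_f) in FIXTURE_PROPORTIONS.items():
            s = fixture_collection[label]
            assert s.cases == reconstruct_counts(s.n_case, case_f)
            assert s.controls == reconstruct_counts(s.n_control, ctrl_f)


# ---------------------------------------------------------------------------
# collection plumbing


class TestStudyCollection:
    def _study(self, label, eth=Ethnicity.ASIAN):
        return Study(
            label=label,
            ethnicity=eth,
            control_source=ControlSource.HOSPITAL,
            cases=GenotypeCounts(10, 10, 10),
            controls=GenotypeCounts(10, 10, 10),
        )

    def test_unique_labels_enforced(self):
        with pytest.raises(ValidationError):
            StudyCollection(studies=(self._study("A"), self._study("A")))

    def test_drop(self):
        coll = StudyCollection(studies=(self._study("A"), self._study("B")))
        assert coll.drop("A").labels == ("B",)

    def test_partition_order_of_first_appearance(self):
        coll = StudyCollection(
            studies=(
                self._study("A", Ethnicity.CAUCASIAN),
                self._study("B", Ethnicity.ASIAN),
                self._study("C", Ethnicity.CAUCASIAN),
            )
        )
        parts = coll.partition("ethnicity")
        assert [name for name, _ in parts] == ["Caucasian", "Asian"]
        assert parts[0][1].labels == ("A", "C")
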