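import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from predblp.motifs import (
    MotifPattern,
    _dig_from_counts,
    dig_score,
    discover_motifs,
    enumerate_patterns,
    format_pattern,
    iter_pattern_space,
    matches,
    mtf_features,
    parse_pattern,
)
from predblp.seqio import ProteinRecord
from predblp.simulate import PlantedMotif, SimulationSpec, generate
from tests.conftest import toy_dataset


class TestPatternGrammar:
    @pytest.mark.parametrize(
        "text, literals, gaps",
        [
            ("L-S-GR", ("L", "S", "G", "R"), (1, 1, 0)),
            ("EHH", ("E", "H", "H"), (0, 0)),
            ("G-T-G-P", ("G", "T", "G", "P"), (1, 1, 1)),
            ("A-A", ("A", "A"), (1,)),
            ("DGW", ("D", "G", "W"), (0, 0)),
        ],
    )
    def test_parse(self, text, literals, gaps):
        pattern = parse_pattern(text)
        assert pattern.literals == literals
        assert pattern.gaps == gaps

    motif_text = st.builds(
        lambda lits, gaps: "".join(
            [lits[0]] + ["-" * g + l for g, l in zip(gaps, lits[1:])]
        ),
        st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=3, max_size=4),
        st.lists(st.integers(0, 1), min_size=3, max_size=3),
    )

    @given(text=motif_text)
    def test_roundtrip(self, text):
        assert format_pattern(parse_pattern(text)) == text

    @pytest.mark.parametrize(
        "bad", ["", "A", "AB", "ABCDE", "A--B", "A-1", "a-b", "AXB-"]
    )
    def test_rejects(self, bad):
        with pytest.raises(ValueError):
            parse_pattern(bad)

    def test_span(self):
        assert parse_pattern("L-S-GR").span == 6
        assert parse_pattern("EHH").span == 3


class TestMatches:
    @pytest.mark.parametrize(
        "pattern, sequence, expected",
        [
            ("A-A", "ACA", True),
            ("A-A", "AAG", False),
            ("EHH", "GGEHHGG", True),
            ("EHH", "GGEHGHG", False),
            ("G-T-G-P", "XGATCGAP".replace("X", "W"), True),
            ("A-A", "AC", False),  # shorter than span
        ],
    )
    def test_examples(self, pattern, sequence, expected):
        assert matches(parse_pattern(pattern), sequence) is expected


class TestEnumerate:
    def test_planted_trivially_found(self):
        data = toy_dataset(["ACAGGGGGGG", "AGAGGGGGGG", "ADAGGGGGGG"], ["GGGGGGGGGG"])
        found = {p.format() for p in enumerate_patterns(data.positives(), 0.1)}
        assert "A-A" in found

    def test_absent_pattern_not_yielded(self):
        data = toy_dataset(["ACAGGGGGGG"], ["GGGGGGGGGG"])
        found = {p.format() for p in enumerate_patterns(data.positives(), 0.1)}
        assert "W-W" not in found

    def test_k2_space_is_400(self):
        patterns = list(iter_pattern_space(2))
        assert len(patterns) == 400
        assert len({p.format() for p in patterns}) == 400
        assert all(p.gaps == (1,) for p in patterns)

    def test_frequency_is_presence_not_occurrence(self):
        # one sequence with many hits still counts once: presence frequency
        # is 1/2 = 0.5, which does not exceed a strict threshold of 0.5
        data = toy_dataset(["ACAACAACAA", "GGGGGGGGGG"], ["GGGGGGGGGG"])
        found = {p.format() for p in enumerate_patterns(data.positives(), 0.5)}
        assert "A-A" not in found


def _presence_dataset(n_pos, n_neg, a, b):
    """a positives / b negatives contain the probe pattern W-W."""
    with_pattern = "WCWGGGGGGG"
    without = "GGGGGGGGGG"
    pos = [with_pattern] * a + [without] * (n_pos - a)
    neg = [with_pattern] * b + [without] * (n_neg - b)
    return toy_dataset(pos, neg)


def _entropy_oracle(labels_by_group):
    """Independent brute-force conditional entropy from explicit groups."""
    n = sum(len(g) for g in labels_by_group)
    h = 0.0
    for group in labels_by_group:
        if not group:
            continue
        p1 = sum(group) / len(group)
        for p in (p1, 1 - p1):
            if p > 0:
                h -= (len(group) / n) * p * math.log2(p)
    return h


def _dig_oracle(n_pos, n_neg, a, b):
    pooled = [1] * n_pos + [0] * n_neg
    h0 = _entropy_oracle([pooled])
    ig_b = h0 - _entropy_oracle([[1] * a, [1] * (n_pos - a) + [0] * n_neg])
    ig_n = h0 - _entropy_oracle([[0] * b, [1] * n_pos + [0] * (n_neg - b)])
    return ig_b - ig_n


class TestDIG:
    probe = parse_pattern("W-W")

    def test_perfectly_discriminative(self):
        data = _presence_dataset(4, 4, 4, 0)
        assert dig_score(self.probe, data.positives(), data.negatives()) == (
            pytest.approx(1.0)
        )

    def test_absent_everywhere(self):
        data = _presence_dataset(4, 4, 0, 0)
        assert dig_score(self.probe, data.positives(), data.negatives()) == 0.0

    def test_symmetric_pattern_scores_zero(self):
        data = _presence_dataset(4, 4, 4, 4)
        assert dig_score(self.probe, data.positives(), data.negatives()) == (
            pytest.approx(0.0)
        )

    def test_matches_oracle_small(self):
        for n_pos, n_neg, a, b in [(3, 5, 2, 1), (4, 4, 3, 2), (2, 6, 1, 5)]:
            data = _presence_dataset(n_pos, n_neg, a, b)
            assert dig_score(
                self.probe, data.positives(), data.negatives()
            ) == pytest.approx(_dig_oracle(n_pos, n_neg, a, b))

    def test_monotone_in_positive_frequency(self):
        n = 100
        for b in (0, 10, 40):
            scores = [_dig_from_counts(n, n, a, b) for a in range(0, n + 1, 5)]
            assert all(x < y + 1e-12 for x, y in zip(scores, scores[1:]))

    def test_empty_class_rejected(self):
        data = _presence_dataset(3, 3, 1, 1)
        with pytest.raises(ValueError):
            dig_score(self.probe, data.positives(), toy_dataset([], []))


class TestDiscover:
    def test_planted_motif_ranks_first(self):
        spec = SimulationSpec(
            n_pos=60, n_neg=60, length_range=(100, 140),
            planted_motifs=[PlantedMotif("EHH", 0.60, 0.02)], seed=42,
        )
        data = generate(spec)
        catalog = discover_motifs(data.positives(), data.negatives())
        assert catalog.entries[0].pattern.format() == "EHH"
        assert len(catalog) == 10  # default top-k

    def test_sorted_descending_with_lexicographic_ties(self):
        spec = SimulationSpec(n_pos=40, n_neg=40, seed=7)
        data = generate(spec)
        catalog = discover_motifs(data.positives(), data.negatives())
        keys = [(-e.dig, e.pattern.format()) for e in catalog]
        assert keys == sorted(keys)

    def test_threshold_filters_everything(self):
        data = toy_dataset(
            ["ACDEFGHIKL", "MNPQRSTVWY"], ["ACDEFGHIKL", "MNPQRSTVWY"]
        )
        with pytest.warns(UserWarning, match="candidate motifs"):
            catalog = discover_motifs(
                data.positives(), data.negatives(), threshold_T=0.99
            )
        assert len(catalog) == 0

    def test_deterministic(self):
        spec = SimulationSpec(n_pos=30, n_neg=30, seed=3)
        data = generate(spec)
        first = discover_motifs(data.positives(), data.negatives()).to_frame()
        second = discover_motifs(data.positives(), data.negatives()).to_frame()
        assert first.equals(second)

    def test_catalog_tsv_roundtrip(self, tmp_path):
        spec = SimulationSpec(
            n_pos=30, n_neg=30,
            planted_motifs=[PlantedMotif("DGW", 0.8, 0.0)], seed=5,
        )
        data = generate(spec)
        catalog = discover_motifs(data.positives(), data.negatives())
        path = tmp_path / "catalog.tsv"
        catalog.to_tsv(path)
        from predblp.motifs import MotifCatalog

        back = MotifCatalog.from_tsv(path)
        assert [e.pattern for e in back] == [e.pattern for e in catalog]
        np.testing.assert_allclose(
            back.to_frame()[["dig", "freq_pos", "freq_neg"]],
            catalog.to_frame()[["dig", "freq_pos", "freq_neg"]],
            rtol=1e-9,
        )


class TestMTFBlock:
    def test_binary_presence_vector(self):
        pos = ["GGEHHGGGGG", "AAEHHAAAAA", "EHHGGGGGGG"]
        neg = ["GGGGGGGGGG", "AAAAAAAAAA", "CCCCCCCCCC"]
        data = toy_dataset(pos, neg)
        catalog = discover_motifs(data.positives(), data.negatives(), top_k=5)
        record = ProteinRecord("q", "TTEHHTTTTT")
        names, values = mtf_features(record, catalog)
        assert len(values) == len(catalog)
        assert set(np.unique(values)) <= {0.0, 1.0}
        expected = [
            1.0 if matches(e.pattern, record.sequence) else 0.0 for e in catalog
        ]
        assert list(values) == expected

    def test_no_overlap_gives_zero_vector(self):
        pos = ["GGEHHGGGGG", "AAEHHAAAAA", "EHHGGGGGGG"]
        neg = ["CCCCCCCCCC", "DDDDDDDDDD", "FFFFFFFFFF"]
        data = toy_dataset(pos, neg)
        catalog = discover_motifs(data.positives(), data.negatives(), top_k=3)
        _, values = mtf_features(ProteinrecordSafe("q"), catalog)
        assert not values.any()


def ProteinrecordSafe(name):
    # a sequence sharing no residues with the catalogs above
    return ProteinRecord(name, "KLKLKLKLKL")
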