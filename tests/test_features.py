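import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sirnakit import (
    FeatureElement,
    FeatureSetSpec,
    FeatureVectorizer,
    ValidationError,
    build_feature_vector,
    count_ngram,
    enumerate_ngram_features,
    enumerate_single_features,
    enumerate_thermo_features,
    select_features,
)
from sirnakit.features import _bulk_pearson

from conftest import random_sequences


def naive_count(seq: str, sub: str) -> int:
    return sum(seq[i:].startswith(sub) for i in range(len(seq)))


class TestCountNgram:
    def test_overlapping_worked_example(self):
        assert count_ngram("AGGAG", "AG") == 2

    def test_absent_and_overlap(self):
        assert count_ngram("AGGAG", "CC") == 0
        assert count_ngram("AAAA", "AA") == 3

    @given(
        st.text(alphabet="ACGU", min_size=5, max_size=19),
        st.text(alphabet="ACGU", min_size=2, max_size=5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_naive_scan(self, seq, sub):
        assert count_ngram(seq, sub) == naive_count(seq, sub)

    @pytest.mark.parametrize("sub", ["A", "AAAAAA", "AX"])
    def test_invalid_subword_rejected(self, sub):
        with pytest.raises(ValidationError):
            count_ngram("ACGUACGU", sub)


class TestEnumeration:
    def test_single_universe_is_76(self):
        seqs = random_sequences(60, 0)
        y = np.random.default_rng(0).uniform(0, 100, 60)
        elems = enumerate_single_features(seqs, y)
        assert len(elems) <= 76
        assert all(e.kind == "single" for e in elems)

    def test_ngram_universe_bound(self):
        seqs = random_sequences(200, 1)
        y = np.random.default_rng(1).uniform(0, 100, 200)
        elems = enumerate_ngram_features(seqs, y)
        assert len(elems) <= 4**2 + 4**3 + 4**4 + 4**5  # 1360

    def test_planted_ngram_ranks_first(self):
        seqs = random_sequences(200, 2)
        y = np.clip(
            [20.0 * count_ngram(s, "GG") + 10.0 for s in seqs], 0, 100
        )
        elems = enumerate_ngram_features(seqs, y)
        best = max(elems, key=lambda e: abs(e.r_train))
        assert best.key == "ngram:GG"

    def test_planted_position_has_smallest_p(self, balanced_pos1_dataset):
        elems = enumerate_single_features(
            balanced_pos1_dataset.sequences, balanced_pos1_dataset.efficacies
        )
        best = min(elems, key=lambda e: e.p_value)
        assert best.key in ("pos1:A", "pos1:G")

    def test_constant_subword_dropped_with_warning(self):
        # identical sequences: every subword has constant frequency
        seqs = ["ACGUACGUACGUACGUACG"] * 6
        y = [10.0, 20, 30, 70, 80, 90]
        with pytest.warns(UserWarning, match="constant-frequency"):
            elems = enumerate_ngram_features(seqs, y)
        assert elems == []

    def test_thermo_elements_always_21(self, small_random_dataset):
        elems = enumerate_thermo_features(
            small_random_dataset.sequences, small_random_dataset.efficacies
        )
        assert len(elems) == 21
        keys = {e.key for e in elems}
        assert {"wholeG", "dH", "dS", "stack:1-2", "stack:18-19"} <= keys

    def test_bulk_pearson_matches_scipy(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 6))
        X[:, 3] = rng.integers(0, 3, 40)  # discrete column
        y = rng.normal(size=40)
        r, p, valid = _bulk_pearson(X, y)
        assert valid.all()
        for j in range(6):
            r_ref, p_ref = stats.pearsonr(X[:, j], y)
            assert r[j] == pytest.approx(r_ref, abs=1e-12)
            assert p[j] == pytest.approx(p_ref, rel=1e-9)


def _pool():
    """A candidate pool with hand-set r/p values."""
    mk = FeatureElement
    return [
        mk("single", "pos1:A", 0.30, 1e-5),
        mk("single", "pos2:C", 0.11, 1e-4),
        mk("single", "pos3:G", -0.09, 1e-6),
        mk("single", "pos4:U", 0.50, 0.01),  # not significant
        mk("ngram", "ngram:AG", 0.095, 1e-5),
        mk("ngram", "ngram:GG", -0.20, 1e-7),
        mk("thermo", "wholeG", -0.02, 0.8),  # thermo always kept
    ]


class TestSelection:
    def test_unrestricted_keeps_all_significant(self):
        spec = select_features(_pool(), None, None, name="open")
        keys = [e.key for e in spec.elements]
        assert "pos4:U" not in keys  # p >= 0.001
        assert "wholeG" in keys
        assert len(spec) == 6

    def test_matches_brute_force_filter(self):
        ts, tn = 0.10, 0.09
        spec = select_features(_pool(), ts, tn)
        expected = sorted(
            e.key
            for e in _pool()
            if e.kind == "thermo"
            or (
                e.p_value < 1e-3
                and abs(e.r_train) > (ts if e.kind == "single" else tn)
            )
        )
        assert sorted(e.key for e in spec.elements) == expected

    def test_thresholds_are_strict(self):
        spec = select_features(_pool(), 0.11, 0.095)
        keys = [e.key for e in spec.elements]
        assert "pos2:C" not in keys  # |r| == threshold -> excluded
        assert "ngram:AG" not in keys

    def test_monotone_shrinkage(self):
        sizes = []
        for ts, tn in [(None, None), (0.10, 0.09), (0.12, 0.10), (0.13, 0.12)]:
            sizes.append(len(select_features(_pool(), ts, tn)))
        assert sizes == sorted(sizes, reverse=True)

    def test_element_order_deterministic(self):
        spec = select_features(_pool()[::-1], None, None)
        kinds = [e.kind for e in spec.elements]
        assert kinds == sorted(kinds, key=["single", "ngram", "thermo"].index)
        singles = [e.key for e in spec.elements if e.kind == "single"]
        assert singles == sorted(singles)

    def test_empty_selection_errors(self):
        pool = [FeatureElement("single", "pos1:A", 0.01, 0.5)]
        with pytest.raises(ValidationError, match="relax"):
            select_features(pool, 0.9, 0.9)

    def test_spec_serialization_roundtrip(self, tmp_path):
        spec = select_features(_pool(), 0.10, 0.09, name="F85-like")
        p = tmp_path / "spec.json"
        spec.save(p)
        assert FeatureSetSpec.load(p) == spec


class TestFeatureVector:
    def test_width_and_semantics(self):
        spec = FeatureSetSpec(
            "toy",
            (
                FeatureElement("single", "pos1:A", 0.5, 1e-5),
                FeatureElement("ngram", "ngram:AG", 0.3, 1e-5),
                FeatureElement("thermo", "wholeG", -0.2, 1e-5),
            ),
        )
        seq = "AGGAG" + "C" * 14
        v = build_feature_vector(seq, spec)
        assert v.shape == (3,)
        assert v[0] == 1.0  # A at position 1 matched
        assert v[1] == count_ngram(seq, "AG") == 2
        from sirnakit import whole_dG

        assert v[2] == pytest.approx(whole_dG(seq))
        v2 = build_feature_vector("C" * 19, spec)
        assert v2[0] == 0.0 and v2[1] == 0.0  # unmatched indicator is 0

    def test_vectorizer_end_to_end(self):
        seqs = random_sequences(80, 6)
        gc = np.array([s.count("G") + s.count("C") for s in seqs])
        y = np.clip(30 + 3 * gc + np.random.default_rng(6).normal(0, 3, 80), 0, 100)
        fv = FeatureVectorizer.standard("F85").fit(seqs, y)
        X = fv.transform(seqs[:5])
        assert X.shape == (5, len(fv.spec_))
        assert fv.spec_.threshold_single == 0.10
        with pytest.raises(ValidationError, match="unknown method"):
            FeatureVectorizer.standard("F999")
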