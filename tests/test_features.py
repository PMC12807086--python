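"""Normalization, 7-feature extraction, windowing and CpG candidate scans."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylformer.features import (
    build_window_set,
    extract_windows,
    featurize_samples,
    find_cpg_candidates,
    normalize_read,
    one_hot,
)
from methylformer.io import Event, LabeledSite


def _read(n_events, read_id="r1", chrom="chr1", start=0, rng=None, base="C"):
    rng = rng or np.random.default_rng(0)
    return [
        Event(read_id, chrom, "+", start + i, base, rng.normal(80, 10, size=5))
        for i in range(n_events)
    ]


class TestNormalizeRead:
    def test_constant_read_maps_to_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="MAD = 0"):
            out = normalize_read([np.full(4, 3.7), np.full(2, 3.7)])
        for arr in out:
            np.testing.assert_array_equal(arr, 0.0)

    def test_output_clipped_to_range(self):
        out = normalize_read([np.array([0.0, 10.0] * 50), np.array([0.0, 1e9])])
        pooled = np.concatenate(out)
        assert pooled.min() >= -5.0 and pooled.max() <= 5.0

    def test_median_mad_standardization_against_direct_recompute(self):
        """On N(80, 10) samples the output is ~N(0, 1) and matches the
        median/MAD formula recomputed directly on the pooled sample."""
        rng = np.random.default_rng(42)
        samples = rng.normal(80, 10, size=10_000)
        out = np.concatenate(normalize_read([samples]))
        med = np.median(samples)
        mad = np.median(np.abs(samples - med))
        expected = np.clip((samples - med) / (1.4826 * mad), -5, 5)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert abs(out.mean()) < 0.05
        assert abs(expected.std() - 1.0) < 0.1

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(1)
        once = normalize_read([rng.normal(0, 1, size=5_000)])
        twice = normalize_read(once)
        np.testing.assert_allclose(np.concatenate(twice), np.concatenate(once), atol=0.05)


class TestOneHot:
    def test_paper_order(self):
        np.testing.assert_array_equal(one_hot("C"), [0, 1, 0, 0])
        np.testing.assert_array_equal(one_hot("A"), [1, 0, 0, 0])
        np.testing.assert_array_equal(one_hot("G"), [0, 0, 1, 0])
        np.testing.assert_array_equal(one_hot("T"), [0, 0, 0, 1])

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            one_hot("N")

    @given(st.sampled_from("ACGT"))
    def test_exactly_one_bit(self, base):
        vec = one_hot(base)
        assert vec.sum() == 1.0 and set(np.unique(vec)) <= {0.0, 1.0}


class TestFeaturize:
    def test_mean_sd_count(self):
        feats = featurize_samples(np.array([1.0, 2.0, 3.0]), "C")
        assert feats[0] == pytest.approx(2.0)
        assert feats[1] == pytest.approx(0.8165, abs=1e-4)  # population sd
        assert feats[2] == 3.0
        np.testing.assert_array_equal(feats[3:], [0, 1, 0, 0])

    def test_single_sample(self):
        feats = featurize_samples(np.array([0.0]), "T")
        assert feats[0] == 0.0 and feats[1] == 0.0 and feats[2] == 1.0
        np.testing.assert_array_equal(feats[3:], [0, 0, 0, 1])

    def test_symmetric_pair(self):
        feats = featurize_samples(np.array([-5.0, 5.0]), "G")
        assert feats[0] == 0.0 and feats[1] == 5.0 and feats[2] == 2.0

    def test_empty_samples_error(self):
        with pytest.raises(ValueError):
            featurize_samples(np.array([]), "A")

    def test_brute_force_recompute_on_random_events(self):
        """f_m, f_sd, f_l agree with direct mean / sqrt(sum sq dev / n) /
        count on 1000 random events to 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            samples = rng.normal(0, 2, size=n)
            base = "ACGT"[rng.integers(4)]
            feats = featurize_samples(samples, base)
            mean = sum(samples) / n
            sd = (sum((x - mean) ** 2 for x in samples) / n) ** 0.5
            assert abs(feats[0] - mean) < 1e-9
            assert abs(feats[1] - sd) < 1e-9
            assert feats[2] == n


class TestExtractWindows:
    def test_exact_fit(self):
        events = _read(21)
        windows, skipped = extract_windows(events, [10], w=21)
        assert len(windows) == 1 and skipped == 0
        assert windows[0].matrix.shape == (21, 7)
        assert windows[0].center[3] == 10

    def test_edge_candidate_skipped(self):
        windows, skipped = extract_windows(_read(21), [5], w=21)
        assert windows == [] and skipped == 1

    def test_interior_count_matches_index_range_oracle(self):
        events = _read(100)
        windows, skipped = extract_windows(events, range(100), w=21)
        assert len(windows) == 80  # indices 10..89
        assert skipped == 20
        assert [w.center[3] for w in windows] == list(range(10, 90))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(_read(30), [15], w=20)

    def test_labels_attached(self):
        windows, _ = extract_windows(_read(21), [10], w=21, labels={10: 1})
        assert windows[0].label == 1

    @given(st.integers(min_value=1, max_value=60), st.integers(min_value=0, max_value=4))
    def test_window_count_oracle_and_row_invariants(self, n_events, half_w):
        w = 2 * half_w + 1
        events = _read(max(n_events, 1))
        windows, skipped = extract_windows(events, range(len(events)), w=w)
        expected = max(0, len(events) - 2 * (w // 2))
        assert len(windows) == expected
        assert skipped == len(events) - expected
        for win in windows:
            assert win.matrix.shape == (w, 7)
            np.testing.assert_array_equal(win.matrix[:, 3:].sum(axis=1), 1.0)


class TestCpGCandidates:
    def test_forward(self):
        assert find_cpg_candidates("ACGT") == [1]
        assert find_cpg_candidates("CGCG") == [0, 2]  # overlapping motifs
        assert find_cpg_candidates("AAAA") == []

    def test_both_strands_matches_reverse_complement_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        got = find_cpg_candidates(seq, "both")
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        minus = {
            len(seq) - 1 - p for p in range(len(rc) - 1) if rc[p : p + 2] == "CG"
        }
        expected = sorted(
            [(p, "+") for p in range(len(seq) - 1) if seq[p : p + 2] == "CG"]
            + [(p, "-") for p in minus]
        )
        assert got == expected

    def test_both_strands_small_example(self):
        assert find_cpg_candidates("ACGT", "both") == [(1, "+"), (2, "-")]


def test_build_window_set_with_labels():
    events = {"r1": _read(41)}
    labels = [LabeledSite("r1", "chr1", "+", pos, pos % 2) for pos in (5, 20, 30)]
    ws = build_window_set(events, w=21, labels=labels)
    assert len(ws) == 2  # pos 5 is too close to the read start
    assert ws.n_edge_skipped == 1
    assert list(ws.index["ref_pos"]) == [20, 30]
    np.testing.assert_array_equal(ws.y, [0, 0])
    assert ws.X.shape == (2, 21, 7)
    assert len(ws.groups) == 2
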