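"""Template matching, match extraction, label bookkeeping and the store."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ddkit.behaviour import (
    DEFAULT_THRESHOLD,
    LabelSet,
    MatchResult,
    Template,
    TemplateStore,
    boost,
    extract_matches,
    resample,
    sliding_similarity,
)
from ddkit.simulate import motif_waveform, planted_motif_series


def brute_force_ncc(x, t):
    L = len(t)
    tz = t - t.mean()
    tn = np.linalg.norm(tz)
    out = np.empty(len(x) - L + 1)
    for i in range(len(out)):
        w = x[i : i + L]
        wz = w - w.mean()
        d = np.linalg.norm(wz) * tn
        out[i] = 0.0 if d == 0 else (wz @ tz) / d
    return (out + 1.0) / 2.0 * 100.0


class TestResample:
    def test_half_rate_halves_length(self):
        assert len(resample(np.arange(100.0), 1, 2)) == 50

    def test_equal_factors_identity(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_array_equal(resample(x, 3, 3), x)

    def test_sine_round_trip_within_one_percent_rms(self):
        x = np.sin(2 * np.pi * np.arange(200) / 40)
        back = resample(resample(x, 2, 1), 1, 2)
        assert len(back) == len(x)
        rms = np.sqrt(np.mean((back - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert rms < 0.01

    def test_too_short_output_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            resample(np.arange(2.0), 1, 2)

    def test_factors_validated(self):
        with pytest.raises(ValueError):
            resample(np.arange(10.0), 0, 1)


class TestSlidingSimilarity:
    def test_self_match_is_100_percent(self, rng):
        x = rng.normal(size=400)
        tpl = Template("t", {"ch": x[50:110].copy()})
        sim = sliding_similarity({"ch": x}, tpl)
        assert sim[50] == pytest.approx(100.0, abs=1e-9)
        assert len(sim) == 400 - 60 + 1

    def test_amplitude_and_offset_invariance(self, rng):
        x = rng.normal(size=300)
        seg = x[40:100].copy()
        x[40:100] = 3.0 * seg + 2.0
        sim = sliding_similarity({"ch": x}, Template("t", {"ch": seg}))
        assert sim[40] == pytest.approx(100.0, abs=1e-9)

    def test_fft_equals_brute_force(self, rng):
        for n, L in ((10, 4), (100, 13), (1000, 40)):
            x = rng.normal(size=n)
            t = rng.normal(size=L)
            fast = sliding_similarity({"ch": x}, Template("t", {"ch": t}))
            np.testing.assert_allclose(fast, brute_force_ncc(x, t), atol=1e-10)

    def test_zero_variance_window_scores_zero(self):
        x = np.concatenate([np.zeros(30), np.sin(np.arange(30))])
        sim = sliding_similarity({"ch": x}, Template("t", {"ch": np.sin(np.arange(10))}))
        assert sim[0] == 0.0

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sliding_similarity({"ch": np.arange(20.0)}, Template("t", {"ch": np.ones(5)}))

    def test_missing_channel_and_short_series(self, rng):
        tpl = Template("t", {"ch": rng.normal(size=10)})
        with pytest.raises(ValueError, match="lacks"):
            sliding_similarity({"other": np.zeros(20)}, tpl)
        with pytest.raises(ValueError, match="shorter"):
            sliding_similarity({"ch": np.zeros(5)}, tpl)

    def test_multichannel_is_mean_of_per_channel(self, rng):
        x = {"a": rng.normal(size=200), "b": rng.normal(size=200)}
        ta, tb = rng.normal(size=20), rng.normal(size=20)
        joint = sliding_similarity(x, Template("t", {"a": ta, "b": tb}))
        sa = sliding_similarity(x, Template("t", {"a": ta}))
        sb = sliding_similarity(x, Template("t", {"b": tb}))
        np.testing.assert_allclose(joint, (sa + sb) / 2.0, atol=1e-9)

    def test_unnormalized_mode_is_raw_correlation(self, rng):
        x = rng.normal(size=100)
        t = rng.normal(size=9)
        raw = sliding_similarity({"ch": x}, Template("t", {"ch": t}), normalized=False)
        direct = np.array([x[i : i + 9] @ t for i in range(92)])
        np.testing.assert_allclose(raw, direct, atol=1e-10)

    def test_affine_series_transform_invariance(self, rng):
        x = rng.normal(size=300)
        tpl = Template("t", {"ch": rng.normal(size=25)})
        a = sliding_similarity({"ch": x}, tpl)
        b = sliding_similarity({"ch": 4.2 * x - 1.7}, tpl)
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestExtractMatches:
    def test_threshold_100_returns_only_exact_matches(self, rng):
        x = rng.normal(size=200)
        tpl = Template("t", {"ch": x[30:60].copy()})
        sim = sliding_similarity({"ch": x}, tpl)
        matches = extract_matches(np.round(sim, 9), 100.0, 30)
        assert [m.start for m in matches] == [30]

    def test_threshold_zero_bounded_by_suppression_geometry(self, rng):
        n, L = 200, 30
        sim = rng.uniform(0, 100, n - L + 1)
        matches = extract_matches(sim, 0.0, L)
        starts = [m.start for m in matches]
        assert len(matches) <= n // L + 1
        for a, b in zip(starts, starts[1:]):
            assert b - a >= L  # no overlap after suppression

    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_never_adds_matches(self, seed):
        rng = np.random.default_rng(seed)
        sim = rng.uniform(0, 100, 150)
        counts = [len(extract_matches(sim, th, 10)) for th in (0, 25, 50, 75, 100)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_tie_resolves_to_earliest_start(self):
        sim = np.zeros(20)
        sim[[3, 5]] = 90.0
        matches = extract_matches(sim, 50.0, 10)
        assert [m.start for m in matches] == [3]

    def test_planted_motif_benchmark(self):
        """20 motifs at 6 dB SNR in white noise: perfect recall and precision
        at the default threshold, starts within +/-2 samples."""
        x, starts = planted_motif_series(seed=7)
        tpl = Template("m", {"ch": motif_waveform()})
        sim = sliding_similarity({"ch": x}, tpl)
        matches = extract_matches(sim, DEFAULT_THRESHOLD, tpl.length)
        found = np.array([m.start for m in matches])
        assert len(found) == len(starts)
        assert all(np.abs(found - s).min() <= 2 for s in starts)


class TestBoost:
    def test_single_template_matches_extract(self, rng):
        x, starts = planted_motif_series(seed=3, n_instances=5)
        tpl = Template("m", {"ch": motif_waveform()})
        sim = sliding_similarity({"ch": x}, tpl)
        direct = extract_matches(sim, DEFAULT_THRESHOLD, tpl.length, template="m")
        boosted = boost([tpl], {"ch": x}, DEFAULT_THRESHOLD)
        assert [(m.start, m.similarity) for m in boosted] == [(m.start, m.similarity) for m in direct]

    def test_duplicate_template_idempotent(self):
        x, _ = planted_motif_series(seed=3, n_instances=5)
        tpl = Template("m", {"ch": motif_waveform()})
        one = boost([tpl], {"ch": x}, DEFAULT_THRESHOLD)
        two = boost([tpl, tpl], {"ch": x}, DEFAULT_THRESHOLD)
        assert [(m.start, m.similarity) for m in one] == [(m.start, m.similarity) for m in two]

    def test_two_motif_families_both_recovered(self, rng):
        m1 = motif_waveform(61, "dive")
        m2 = motif_waveform(61, "shake")
        x = rng.normal(0, 0.18, 4000)
        s1, s2 = [300, 1200, 2500], [700, 1800, 3300]
        for s in s1:
            x[s : s + 61] += m1
        for s in s2:
            x[s : s + 61] += m2
        t1 = Template("dive", {"ch": m1})
        t2 = Template("shake", {"ch": m2})
        both = boost([t1, t2], {"ch": x}, DEFAULT_THRESHOLD)
        found = sorted(m.start for m in both)
        assert len(found) == 6
        assert all(min(abs(f - s) for f in found) <= 2 for s in s1 + s2)
        only1 = boost([t1], {"ch": x}, DEFAULT_THRESHOLD)
        assert len(both) >= len(only1)


class TestLabelSet:
    def pending_set(self):
        labels = LabelSet()
        labels.add_class("dive")
        labels.add_pending(
            [MatchResult(10, 5, 95.0), MatchResult(30, 5, 90.0), MatchResult(50, 5, 88.0)]
        )
        return labels

    def test_accept_all_empties_pending(self):
        labels = self.pending_set()
        labels.accept_all(1)
        assert labels.pending == []
        assert [iv.start for iv in labels.intervals] == [10, 30, 50]

    def test_reject_region_removes_overlapping(self):
        labels = self.pending_set()
        dropped = labels.reject_region(28, 36)
        assert dropped == 1
        assert [m.start for m in labels.pending] == [10, 50]

    def test_rejected_not_resurrected_by_rerun(self):
        labels = self.pending_set()
        labels.reject([1])
        added = labels.add_pending([MatchResult(30, 5, 90.0)])
        assert added == 0
        assert [m.start for m in labels.pending] == [10, 50]

    def test_manual_label_overrides_rejection(self):
        labels = self.pending_set()
        labels.reject_region(28, 36)
        labels.manual_label(30, 35, 1)
        assert any(iv.start == 30 and iv.provenance == "manual" for iv in labels.intervals)

    def test_adjacent_same_class_intervals_merge(self):
        labels = LabelSet()
        labels.add_class("walk")
        labels.manual_label(10, 20, 1)
        labels.manual_label(20, 30, 1)
        assert [(iv.start, iv.end) for iv in labels.intervals] == [(10, 30)]

    def test_conflicting_class_overlap_rejected(self):
        labels = LabelSet()
        labels.add_class("walk")
        labels.add_class("rest")
        labels.manual_label(10, 20, 1)
        with pytest.raises(ValueError, match="overlaps"):
            labels.manual_label(15, 25, 2)

    def test_unknown_ids_rejected(self):
        labels = self.pending_set()
        with pytest.raises(KeyError):
            labels.accept([99], 1)
        with pytest.raises(KeyError):
            labels.accept([0], 42)
        with pytest.raises(KeyError):
            labels.reject([99])

    def test_behaviour_codes(self):
        labels = LabelSet()
        labels.add_class("walk")
        labels.add_class("rest")
        labels.manual_label(2, 4, 1)
        labels.manual_label(6, 8, 2)
        np.testing.assert_array_equal(labels.behaviour_codes(10), [0, 0, 1, 1, 0, 0, 2, 2, 0, 0])
        with pytest.raises(ValueError, match="exceeds"):
            labels.behaviour_codes(5)


class TestTemplateStore:
    def test_save_query_round_trip(self, tmp_path, rng):
        store = TemplateStore(tmp_path / "store")
        tpl = Template("dive", {"ax": rng.normal(size=30), "az": rng.normal(size=30)}, animal="turtle-1")
        store.store(tpl)
        (back,) = store.query("turtle-1", "dive")
        for ch in tpl.channels:
            np.testing.assert_array_equal(back.waveform[ch], tpl.waveform[ch])
        assert back.animal == "turtle-1"

    def test_unknown_animal_empty(self, tmp_path):
        assert TemplateStore(tmp_path / "store").query("condor-9") == []

    def test_query_animal_lists_all_behaviours(self, tmp_path, rng):
        store = TemplateStore(tmp_path / "store")
        store.store(Template("dive", {"ax": rng.normal(size=10)}, animal="turtle-1"))
        store.store(Template("surface", {"ax": rng.normal(size=12)}, animal="turtle-1"))
        names = sorted(t.name for t in store.query("turtle-1"))
        assert names == ["dive", "surface"]

    def test_unknown_behaviour_raises(self, tmp_path, rng):
        store = TemplateStore(tmp_path / "store")
        store.store(Template("dive", {"ax": rng.normal(size=10)}, animal="turtle-1"))
        with pytest.raises(KeyError, match="no template"):
            store.query("turtle-1", "moonwalk")

    def test_reopened_store_persists(self, tmp_path, rng):
        root = tmp_path / "store"
        TemplateStore(root).store(Template("dive", {"ax": rng.normal(size=10)}, animal="t"))
        assert len(TemplateStore(root).query("t")) == 1


class TestTemplateValidation:
    def test_length_and_channel_consistency(self):
        with pytest.raises(ValueError, match="same length"):
            Template("t", {"a": np.zeros(5), "b": np.zeros(6)})
        with pytest.raises(ValueError, match="at least 2"):
            Template("t", {"a": np.zeros(1)})
        with pytest.raises(ValueError, match="positive"):
            Template("t", {"a": np.zeros(5)}, interp=0)
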