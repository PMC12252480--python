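import numpy as np
import pandas as pd
import pytest

from systoseg import pipeline
from systoseg.intervals import (
    clinical_flags,
    compute_intervals,
    normalize_intervals,
    pair_beats,
    summarize,
)


def _pcg_df(onsets, peaks, s2s, edge=None):
    n = len(peaks)
    return pd.DataFrame({
        "window_id": 0, "beat": range(n),
        "s1_onset_t": onsets, "s1_peak_t": peaks, "s2_peak_t": s2s,
        "edge": edge if edge is not None else [False] * n,
    })


def _ecg_df(qs, rs, ss):
    n = len(rs)
    return pd.DataFrame({"window_id": 0, "beat": range(n),
                         "q_t": qs, "r_t": rs, "s_t": ss})


class TestPairing:
    def test_q_pairs_with_following_onset(self):
        paired = pair_beats(_pcg_df([1.074], [1.089], [1.333]),
                            _ecg_df([1.000], [1.040], [1.072]))
        assert len(paired) == 1

    def test_distant_onset_left_unpaired(self):
        paired = pair_beats(_pcg_df([1.400], [1.415], [1.650]),
                            _ecg_df([1.000], [1.040], [1.072]))
        assert paired.empty

    def test_order_invariance(self):
        onsets = [1.07, 1.77, 2.47]
        peaks = [1.09, 1.79, 2.49]
        s2s = [1.33, 2.03, 2.73]
        qs = [1.00, 1.70, 2.40]
        rs = [1.04, 1.74, 2.44]
        ss = [1.07, 1.77, 2.47]
        ordered = pair_beats(_pcg_df(onsets, peaks, s2s),
                             _ecg_df(qs, rs, ss))
        perm = [2, 0, 1]
        shuffled = pair_beats(
            _pcg_df([onsets[i] for i in perm], [peaks[i] for i in perm],
                    [s2s[i] for i in perm]),
            _ecg_df([qs[i] for i in perm], [rs[i] for i in perm],
                    [ss[i] for i in perm]),
        )
        pd.testing.assert_frame_equal(ordered, shuffled)

    def test_rr_from_consecutive_paired_r(self):
        paired = pair_beats(
            _pcg_df([1.07, 1.77], [1.09, 1.79], [1.33, 2.03]),
            _ecg_df([1.00, 1.70], [1.04, 1.74], [1.07, 1.77]))
        assert paired["rr_ms"].iloc[0] == pytest.approx(700.0)
        assert np.isnan(paired["rr_ms"].iloc[1])


class TestComputeIntervals:
    def test_reference_beat_arithmetic(self):
        paired = pair_beats(_pcg_df([1.074], [1.089], [1.333]),
                            _ecg_df([1.000], [1.040], [1.072]))
        bi = compute_intervals(paired)
        row = bi.iloc[0]
        assert row["emat_ms"] == pytest.approx(74.0)
        assert row["pep_ms"] == pytest.approx(89.0)
        assert row["lvet_ms"] == pytest.approx(244.0)
        assert row["lvst_ms"] == pytest.approx(259.0)

    def test_missing_s2_propagates(self):
        paired = pair_beats(_pcg_df([1.074], [1.089], [np.nan]),
                            _ecg_df([1.000], [1.040], [1.072]))
        row = compute_intervals(paired).iloc[0]
        assert np.isnan(row["lvet_ms"]) and np.isnan(row["lvst_ms"])
        assert row["emat_ms"] == pytest.approx(74.0)
        assert row["pep_ms"] == pytest.approx(89.0)

    def test_systolic_identity_is_exact(self, default_train):
        pair, _ = default_train
        beats, _, _ = pipeline.extract_intervals(
            *pipeline.segment_recording(pair)[:2])
        full = beats.dropna(subset=["emat_ms", "pep_ms", "lvet_ms", "lvst_ms"])
        lhs = full["lvst_ms"] - full["lvet_ms"]
        rhs = full["pep_ms"] - full["emat_ms"]
        assert np.abs(lhs - rhs).max() < 1e-9


class TestNormalisation:
    def _one_beat(self):
        paired = pair_beats(
            _pcg_df([1.074, 2.07], [1.089, 2.09], [1.333, 2.33]),
            _ecg_df([1.000, 2.0], [1.040, 2.04], [1.072, 2.07]))
        return compute_intervals(paired)

    def test_fraction_of_rr(self):
        bi = self._one_beat()
        bi.loc[0, "emat_ms"] = 100.0
        bi.loc[0, "rr_ms"] = 1000.0
        out = normalize_intervals(bi)
        assert out["emat_pct"].iloc[0] == pytest.approx(0.10)

    def test_pep_over_lvet(self):
        out = normalize_intervals(self._one_beat())
        assert out["pep_over_lvet"].iloc[0] == pytest.approx(89.0 / 244.0)

    def test_inverse_identity(self):
        out = normalize_intervals(self._one_beat())
        row = out.iloc[0]
        for name in ("emat", "pep", "lvet", "lvst"):
            assert row[f"{name}_pct"] * row["rr_ms"] == pytest.approx(
                row[f"{name}_ms"])


class TestSummaries:
    def _frame(self, values, col="emat_ms"):
        df = pd.DataFrame({col: values})
        df["edge"] = False
        return df

    def test_basic_statistics(self):
        s = summarize(self._frame([10.0, 20.0, 30.0]))
        st = s["emat_ms"]
        assert st["mean"] == 20.0 and st["median"] == 20.0
        assert st["sd"] == pytest.approx(10.0)

    def test_linear_interpolation_iqr(self):
        s = summarize(self._frame([1.0, 2.0, 3.0, 4.0]))
        assert s["emat_ms"]["iqr"] == pytest.approx(1.5)

    def test_single_value_sd_missing(self):
        s = summarize(self._frame([42.0]))
        assert s["emat_ms"]["mean"] == 42.0
        assert np.isnan(s["emat_ms"]["sd"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        vals = list(rng.normal(80, 10, 25))
        a = summarize(self._frame(vals))["emat_ms"]
        b = summarize(self._frame(vals[::-1]))["emat_ms"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_edge_beats_excluded(self):
        df = self._frame([10.0, 20.0, 1000.0])
        df.loc[2, "edge"] = True
        assert summarize(df)["emat_ms"]["n"] == 2


class TestClinicalFlags:
    def _summary(self, emat=74.35, emat_pct=0.104, lvst=258.6):
        df = pd.DataFrame({
            "emat_ms": [emat], "lvst_ms": [lvst], "emat_pct": [emat_pct],
            "edge": [False],
        })
        return summarize(df)

    def test_normal_subject_unflagged(self):
        flags = clinical_flags(self._summary())
        assert flags.emat_ge_104ms is False
        assert flags.emat_pct_gt_12_1 is False
        assert flags.emat_pct_gt_13_8 is False
        assert flags.emat_over_lvst_ge_0_40 is False

    def test_emat_threshold_is_closed(self):
        flags = clinical_flags(self._summary(emat=104.0))
        assert flags.emat_ge_104ms is True

    def test_emat_lvst_ratio(self):
        flags = clinical_flags(self._summary(emat=120.0, lvst=280.0))
        assert flags.emat_over_lvst_ge_0_40 is True

    def test_missing_inputs_undetermined(self):
        df = pd.DataFrame({"lvet_ms": [200.0], "edge": [False]})
        flags = clinical_flags(summarize(df))
        assert flags.emat_ge_104ms is None
        assert flags.emat_over_lvst_ge_0_40 is None


def test_default_profile_means_inside_typical_ranges(default_train):
    """Pipeline means on the default synthetic profile must fall inside the
    published typical physiological ranges for a resting adult."""
    pair, _ = default_train
    _, summary, _ = pipeline.extract_intervals(
        *pipeline.segment_recording(pair)[:2])
    for name, (lo, hi) in {
        "emat_ms": (50, 120), "pep_ms": (50, 120),
        "lvet_ms": (150, 350), "lvst_ms": (150, 350),
    }.items():
        assert lo <= summary.mean(name) <= hi, name
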