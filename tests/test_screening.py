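"""Peak-table screening: detection rate, CV, relative content, joins."""

import logging

import numpy as np
import pandas as pd
import pytest

from aromalip import screening as scr


def brute_force_screen(table: pd.DataFrame, min_rate=0.5, max_cv=0.30):
    """Independent per-compound recomputation with plain Python loops."""
    kept = {}
    for name in table.index:
        vals = [v for v in table.loc[name] if not np.isnan(v)]
        rate = len(vals) / table.shape[1]
        if not rate > min_rate:
            continue
        mean = sum(vals) / len(vals)
        if len(vals) < 2:
            continue
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        if not sd / mean < max_cv:
            continue
        kept[name] = mean
    total = sum(kept.values())
    return {n: 100.0 * m / total for n, m in kept.items()}


class TestDetectionRateFilter:
    def test_counts_and_strictness(self, simple_peaks):
        kept, report = scr.detection_rate_filter(simple_peaks)
        # 4/4 and 3/4 pass; 2/4 is exactly 0.5 and excluded; 1/4 excluded
        assert list(kept.index) == ["hexanal", "nonanal", "spiky"]
        assert report.loc["halfseen", "detection_rate"] == 0.5
        assert not report.loc["halfseen", "retained"]
        assert report.loc["hexanal", "detection_rate"] == 1.0

    def test_inclusive_keeps_boundary(self, simple_peaks):
        kept, _ = scr.detection_rate_filter(simple_peaks, inclusive=True)
        assert "halfseen" in kept.index

    def test_empty_result_warns_not_raises(self, simple_peaks, caplog):
        with caplog.at_level(logging.WARNING, logger="aromalip"):
            kept, _ = scr.detection_rate_filter(simple_peaks, min_rate=1.0)
        assert len(kept) == 0
        assert "removed every compound" in caplog.text


class TestCvFilter:
    def test_zero_variance_retained(self):
        t = pd.DataFrame([[10.0, 10.0, 10.0, 10.0]], index=["flat"])
        kept, report = scr.cv_filter(t)
        assert list(kept.index) == ["flat"]
        assert report.loc["flat", "cv"] == 0.0

    def test_known_cv_values(self):
        t = pd.DataFrame(
            [[1.0, 1.0, 1.0, 100.0], [90.0, 100.0, 110.0, np.nan]],
            index=["spiky", "steady"],
        )
        kept, report = scr.cv_filter(t)
        # spiky: mean 25.75, sd 49.5 -> cv ~1.92, removed
        assert list(kept.index) == ["steady"]
        assert report.loc["steady", "cv"] == pytest.approx(0.1)
        assert report.loc["spiky", "cv"] == pytest.approx(1.9223, abs=1e-4)

    def test_single_replicate_cv_undefined_removed(self, caplog):
        t = pd.DataFrame([[7.0, np.nan, np.nan, np.nan]], index=["lonely"])
        with caplog.at_level(logging.WARNING, logger="aromalip"):
            kept, report = scr.cv_filter(t)
        assert len(kept) == 0
        assert np.isnan(report.loc["lonely", "cv"])
        assert "undefined" in caplog.text

    def test_boundary_strictness(self):
        # sd/mean exactly 0.30: sd = 30, mean = 100
        vals = [70.0, 100.0, 130.0]
        sd = np.std(vals, ddof=1)
        t = pd.DataFrame([np.array(vals) * 30 / sd * (100 / 100)],
                         index=["edge"])
        mean = t.iloc[0].mean()
        t.iloc[0] += 100 - mean  # shift so cv == sd/mean exactly 0.30
        cv = t.iloc[0].std(ddof=1) / t.iloc[0].mean()
        assert cv == pytest.approx(0.30, abs=1e-12)
        kept, _ = scr.cv_filter(t, max_cv=cv)
        assert len(kept) == 0
        kept, _ = scr.cv_filter(t, max_cv=cv, inclusive=True)
        assert len(kept) == 1


class TestRelativeContent:
    def test_single_compound_is_100(self):
        t = pd.DataFrame([[5.0, 5.0]], index=["only"])
        out = scr.relative_content(t)
        assert out["c_percent"].iloc[0] == 100.0

    def test_proportionality_and_sum(self):
        t = pd.DataFrame([[3.0, 3.0], [1.0, 1.0]], index=["a", "b"])
        out = scr.relative_content(t)
        assert list(out["c_percent"]) == [75.0, 25.0]
        assert out["c_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self, simple_peaks):
        kept, _ = scr.detection_rate_filter(simple_peaks)
        a = scr.relative_content(kept)
        b = scr.relative_content(kept * 1000.0)
        np.testing.assert_allclose(a["c_percent"], b["c_percent"])

    def test_all_missing_compound_raises(self):
        t = pd.DataFrame([[1.0, 1.0], [np.nan, np.nan]], index=["a", "gone"])
        with pytest.raises(ValueError, match="gone"):
            scr.relative_content(t)


class TestScreeningProperties:
    def test_filter_order_commutative_and_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 21))
            areas = rng.lognormal(3, 1.5, size=(n, 4))
            drop = rng.random((n, 4)) < rng.uniform(0, 0.6)
            areas[drop] = np.nan
            t = pd.DataFrame(areas, index=[f"c{i:02d}" for i in range(n)])
            t1, _ = scr.detection_rate_filter(t)
            t1, _ = scr.cv_filter(t1)
            t2, _ = scr.cv_filter(t)
            t2, _ = scr.detection_rate_filter(t2)
            assert list(t1.index) == list(t2.index)
            expected = brute_force_screen(t)
            assert set(t1.index) == set(expected)
            if len(t1):
                got = scr.relative_content(t1).set_index("compound")
                for name, cpct in expected.items():
                    assert got.loc[name, "c_percent"] == pytest.approx(cpct)

    def test_column_permutation_invariance(self, simple_peaks):
        shuffled = simple_peaks[["rep_3", "rep_1", "rep_4", "rep_2"]]
        a = scr.detection_stats(simple_peaks)
        b = scr.detection_stats(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestJoinThresholds:
    def test_inner_join_drops_unannotated(self):
        screened = pd.DataFrame({
            "compound": ["hexanal", "unknown_x"],
            "c_percent": [60.0, 40.0],
        })
        db = pd.DataFrame({
            "compound": ["Hexanal"], "threshold_ug_per_kg": [4.0],
            "chemical_class": ["aldehyde"], "descriptor": [""],
        })
        annotated, dropped = scr.join_thresholds(screened, db)
        assert list(annotated["compound"]) == ["hexanal"]
        assert annotated["threshold"].iloc[0] == 4.0
        assert dropped == ["unknown_x"]
        # C% not renormalized after the drop
        assert annotated["c_percent"].iloc[0] == 60.0

    def test_synonym_matching(self):
        screened = pd.DataFrame({
            "compound": ["Butanoic acid, ethyl ester"], "c_percent": [1.0],
        })
        db = pd.DataFrame({
            "compound": ["ethyl butyrate"], "threshold_ug_per_kg": [0.1],
            "chemical_class": ["ester"], "descriptor": [""],
        })
        annotated, dropped = scr.join_thresholds(screened, db)
        assert len(annotated) == 1 and not dropped

    def test_duplicate_db_entry_raises(self):
        screened = pd.DataFrame({"compound": ["hexanal"], "c_percent": [1.0]})
        db = pd.DataFrame({
            "compound": ["hexanal", "HEXANAL"],
            "threshold_ug_per_kg": [4.0, 5.0],
            "chemical_class": ["aldehyde"] * 2, "descriptor": ["", ""],
        })
        with pytest.raises(ValueError, match="hexanal"):
            scr.join_thresholds(screened, db)

    def test_empty_db(self):
        screened = pd.DataFrame({"compound": ["hexanal"], "c_percent": [1.0]})
        db = pd.DataFrame({
            "compound": [], "threshold_ug_per_kg": [],
            "chemical_class": [], "descriptor": [],
        })
        annotated, dropped = scr.join_thresholds(screened, db)
        assert len(annotated) == 0
        assert dropped == ["hexanal"]


class TestKovatsRI:
    @pytest.mark.parametrize("t, expected", [
        (10.0, 1000.0),     # on the C10 alkane
        (11.0, 1050.0),     # midway C10-C11
        (10.5, 1025.0),     # quarter-way
    ])
    def test_interpolation(self, t, expected):
        ladder = {9: 8.0, 10: 10.0, 11: 12.0}
        assert scr.kovats_ri(t, ladder) == pytest.approx(expected)

    def test_unbracketed_raises_with_hint(self):
        with pytest.raises(ValueError, match="C9.*C11"):
            scr.kovats_ri(99.0, {9: 8.0, 10: 10.0, 11: 12.0})

    def test_non_monotone_ladder_raises(self):
        with pytest.raises(ValueError, match="increase"):
            scr.kovats_ri(9.0, {9: 8.0, 10: 7.0})
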