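import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from petsrtm import (
    BPTable,
    ChallengeStudy,
    delta_bp,
    delta_delta_bp,
    paired_t_two_tailed,
    unpaired_t_one_tailed,
    summarize_challenge,
    load_clinical_bp_table,
)

pos = st.floats(min_value=0.05, max_value=10.0, allow_nan=False)


class TestDeltaBP:
    @pytest.mark.parametrize(
        "base,post,expected",
        [
            (2.15, 1.77, 17.674),  # subject 1, putamen: 100*(1-1.77/2.15)
            (2.0, 1.0, 50.0),
            (1.3, 1.3, 0.0),
            (2.12, 2.20, -3.7736),  # post-challenge increase gives negative dBP
        ],
    )
    def test_percent_change(self, base, post, expected):
        assert delta_bp(base, post) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            delta_bp(0.0, 1.0)
        with pytest.raises(ValueError):
            delta_bp(-0.5, 1.0)

    def test_vectorised(self):
        out = delta_bp([2.0, 4.0], [1.0, 3.0])
        assert np.allclose(out, [50.0, 25.0])

    @settings(deadline=None, derandomize=True)
    @given(base=pos, post=pos, c=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, base, post, c):
        assert delta_bp(c * base, c * post) == pytest.approx(
            delta_bp(base, post), rel=1e-9, abs=1e-9
        )


class TestDeltaDeltaBP:
    @pytest.mark.parametrize(
        "da,dt,expected",
        [
            (17.674, 13.023, 26.316),  # subject 1, putamen, from the three scans
            (20.0, 20.0, 0.0),
            (20.0, 0.0, 100.0),
            (-5.0, -10.0, -100.0),
        ],
    )
    def test_attenuation(self, da, dt, expected):
        assert delta_delta_bp(da, dt) == pytest.approx(expected, abs=1e-3)

    def test_zero_challenge_effect_is_flagged_missing(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            out = delta_delta_bp(0.0, 5.0)
        assert np.isnan(out)

    @settings(deadline=None, derandomize=True)
    @given(b=pos, a=pos, t=pos)
    def test_consistency_with_bp_ratios(self, b, a, t):
        """ddBP from the two dBPs equals 100*(1 - (1-t/b)/(1-a/b)) algebraically."""
        da = delta_bp(b, a)
        if da == 0:
            return
        dt = delta_bp(b, t)
        expected = 100.0 * (1.0 - (1.0 - t / b) / (1.0 - a / b))
        assert delta_delta_bp(da, dt) == pytest.approx(expected, rel=1e-9, abs=1e-6)


class TestPairedT:
    def test_identical_pairs(self):
        r = paired_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == (0.0, 2, 1.0)

    def test_known_differences(self):
        # differences (1,2,3,4): t = 2.5/(sd/2), df = 3
        r = paired_t_two_tailed([2.0, 4.0, 6.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        assert r.statistic == pytest.approx(3.873, abs=1e-3)
        assert r.df == 3
        assert r.pvalue == pytest.approx(0.0305, abs=5e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        ours = paired_t_two_tailed(x, y)
        ref = stats.ttest_rel(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_nonzero_mean(self):
        r = paired_t_two_tailed([2.0, 2.0], [1.0, 1.0])
        assert r.pvalue == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t_two_tailed([1.0], [2.0])


class TestUnpairedOneTailedT:
    def test_identical_groups(self):
        r = unpaired_t_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(0.5)

    def test_separation_limit(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.0, 1e-6, 5)
        hi = 1.0 + rng.normal(0.0, 1e-6, 5)
        assert unpaired_t_one_tailed(lo, hi).pvalue < 1e-12

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=5), rng.normal(0.5, 1.0, size=7)
        ours = unpaired_t_one_tailed(a, b)
        ref = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-12)
        assert ours.df == a.size + b.size - 2

    def test_welch_option_matches_scipy(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=5), rng.normal(0.5, 3.0, size=7)
        ours = unpaired_t_one_tailed(a, b, welch=True)
        ref = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-2)


class TestBPTable:
    def test_unknown_labels_are_errors(self):
        df = pd.DataFrame(
            {
                "subject_id": [1],
                "dose_group": ["20 mg"],
                "scan": ["baseline"],
                "region": ["Thalamus"],
                "bp_nd": [1.0],
            }
        )
        with pytest.raises(ValueError, match="region"):
            BPTable(df)

    def test_duplicate_records_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": [1, 1],
                "dose_group": ["20 mg"] * 2,
                "scan": ["baseline"] * 2,
                "region": ["Pu"] * 2,
                "bp_nd": [1.0, 1.1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            BPTable(df)

    def test_bp_below_minus_one_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": [1],
                "dose_group": ["none"],
                "scan": ["baseline"],
                "region": ["Pu"],
                "bp_nd": [-1.5],
            }
        )
        with pytest.raises(ValueError, match="-1"):
            BPTable(df)


def _zero_variance_table():
    """Every subject shows exactly a 20% challenge effect and 50% attenuation."""
    rows = []
    for s in range(1, 5):
        group = "20 mg" if s <= 2 else "40 mg"
        for region in ("Pu", "VSt"):
            base = 2.0
            for scan, bp in [("baseline", base), ("amph", 1.6), ("amph_tak", 1.8)]:
                rows.append((s, group, scan, region, bp))
    return BPTable(
        pd.DataFrame(rows, columns=["subject_id", "dose_group", "scan", "region", "bp_nd"])
    )


class TestChallengeStudy:
    def test_clinical_group_means(self):
        """Per-subject-first aggregation reproduces the published striatal
        challenge effect (21.6% in putamen over all ten subjects)."""
        res = summarize_challenge(load_clinical_bp_table(), grouping="by_dose")
        f = res.summary_frame.set_index(["region", "group"])
        assert f.loc[("Pu", "all"), "dbp_amph_mean"] == pytest.approx(21.6, abs=0.05)
        assert f.loc[("Pu", "all"), "dbp_amph_sd"] == pytest.approx(5.1, abs=0.2)
        assert f.loc[("Pu", "40 mg"), "ddbp_mean"] == pytest.approx(36.4, abs=0.5)
        assert (f["n"].loc[pd.IndexSlice[:, "all"]] == 10).all()

    def test_zero_variance_summary_is_exact(self):
        res = summarize_challenge(_zero_variance_table(), grouping="by_dose")
        f = res.summary_frame
        assert np.allclose(f["dbp_amph_mean"], 20.0)
        assert np.allclose(f["ddbp_mean"], 50.0)

    def test_missing_amph_tak_degrades_gracefully(self):
        table = _zero_variance_table()
        df = table.frame[table.frame["scan"] != "amph_tak"]
        with pytest.warns(RuntimeWarning, match="amph_tak"):
            res = ChallengeStudy.from_dataframe(df).fit()
        assert res.summary_frame["ddbp_mean"].isna().all()
        assert np.allclose(res.summary_frame["dbp_amph_mean"], 20.0)

    def test_subject_without_baseline_excluded_with_warning(self):
        table = _zero_variance_table()
        df = table.frame[
            ~((table.frame["subject_id"] == 1) & (table.frame["scan"] == "baseline"))
        ]
        with pytest.warns(RuntimeWarning, match="baseline"):
            res = ChallengeStudy.from_dataframe(df).fit()
        f = res.summary_frame.set_index(["region", "group"])
        assert f.loc[("Pu", "all"), "n"] == 3

    def test_significance_pattern_of_clinical_table(self):
        """Challenge reduces binding in every region (paired two-tailed
        p < 0.05); the putamen attenuation is dose dependent (one-tailed
        p < 0.01)."""
        res = summarize_challenge(load_clinical_bp_table(), grouping="by_dose")
        tests = res.tests.set_index("region")
        assert (tests["p_amph_vs_baseline"] < 0.05).all()
        assert tests.loc["Pu", "p_dose_effect"] < 0.01
        assert tests.loc["GP", "p_dose_effect"] < 0.01
        # attenuation significant in the a priori striatal regions
        assert tests.loc["Pu", "p_attenuation"] < 0.05
        assert tests.loc["VSt", "p_attenuation"] < 0.05

    def test_summary_text_renders(self):
        res = summarize_challenge(_zero_variance_table())
        text = res.summary()
        assert "Pu" in text and "dBP_amph" in text
        assert "mean (SD)" in text

    def test_grouping_all_has_no_dose_rows(self):
        res = summarize_challenge(_zero_variance_table(), grouping="all")
        assert set(res.summary_frame["group"]) == {"all"}
        assert "p_dose_effect" not in res.tests.columns
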