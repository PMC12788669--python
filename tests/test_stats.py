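"""Paired t-tests, p-value bands, one-way ANOVA.

The published comparison tables (five folds each) are re-derived from their
printed mean-difference and SD columns; rows whose printed rounding is
self-consistent reproduce to +-0.005, the remainder to +-0.05.
"""

import numpy as np
import pytest
from scipy import stats as sps

from dbmca.stats import (
    one_way_anova,
    p_band,
    paired_ci,
    paired_t_from_folds,
    paired_t_from_summary,
)

# (mean_diff, sd_diff, printed_t, printed_band, self_consistent)
EXPERIMENT_1_ROWS = {
    "CNN-Image": (0.0048, 0.0411, 0.261, ">0.10", True),
    "CNN-Mask": (0.278, 0.0415, 14.964, "<0.01", False),
    "DNN-Image": (0.2313, 0.0227, 22.767, "<0.01", False),
    "DNN-Mask": (0.0372, 0.016, 5.193, "<0.01", False),
    "SVM-Image": (0.0633, 0.0626, 2.262, "<0.10", True),
    "SVM-Mask": (0.1792, 0.0391, 10.249, "<0.01", True),
}
EXPERIMENT_2_ROWS = {
    "CNN-Image": (-0.0084, 0.0143, -1.314, ">0.10", True),
    "CNN-Mask": (0.1604, 0.0692, 5.187, "<0.01", True),
    "DNN-Image": (0.1578, 0.0806, 4.378, "<0.02", True),
    "DNN-Mask": (0.0652, 0.0071, 20.502, "<0.01", False),
    "SVM-Image": (0.0457, 0.0437, 2.339, "<0.10", True),
    "SVM-Mask": (0.1459, 0.0319, 10.223, "<0.01", True),
}


class TestPairedFromSummary:
    @pytest.mark.parametrize("rows", [EXPERIMENT_1_ROWS, EXPERIMENT_2_ROWS],
                             ids=["exp1", "exp2"])
    def test_reproduces_published_t_statistics(self, rows):
        for name, (md, sd, t_printed, band, consistent) in rows.items():
            c = paired_t_from_summary(md, sd, 5)
            tol = 0.005 if consistent else 0.05
            assert c.t == pytest.approx(t_printed, abs=tol), name
            assert c.df == 4

    def test_band_assignment_matches_tables(self):
        for rows in (EXPERIMENT_1_ROWS, EXPERIMENT_2_ROWS):
            for name, (md, sd, _, band, _) in rows.items():
                c = paired_t_from_summary(md, sd, 5)
                assert c.p_band == band, name

    def test_zero_difference(self):
        c = paired_t_from_summary(0.0, 0.05, 5)
        assert c.t == 0.0 and c.p_two_sided == 1.0

    def test_degenerate_zero_sd(self):
        c = paired_t_from_summary(0.01, 0.0, 5)
        assert np.isinf(c.t) and c.degenerate

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            paired_t_from_summary(0.1, 0.1, 1)

    def test_confidence_interval_matches_published(self):
        # the published 95% CI for the top-line comparison: [-4.63%, 5.59%]
        lo, hi = paired_ci(0.0048, 0.0411, 5)
        assert lo == pytest.approx(-0.0463, abs=0.01)
        assert hi == pytest.approx(0.0559, abs=0.01)


class TestPairedFromFolds:
    def test_identical_vectors(self):
        c = paired_t_from_folds([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert c.t == 0.0 and c.mean_diff == 0.0

    def test_constant_shift_is_degenerate(self):
        a = np.array([0.9, 0.8, 0.85, 0.95, 0.9])
        c = paired_t_from_folds(a, a - 0.01)
        assert c.degenerate and np.isinf(c.t)

    def test_matches_hand_arithmetic_and_scipy(self):
        a = np.array([0.9, 0.8, 0.85, 0.95, 0.9])
        b = np.array([0.85, 0.75, 0.8, 0.9, 0.88])
        d = a - b
        c = paired_t_from_folds(a, b)
        assert c.mean_diff == pytest.approx(d.mean(), abs=1e-15)
        assert c.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-15)
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert c.t == pytest.approx(t_ref, abs=1e-12)
        assert c.p_two_sided == pytest.approx(p_ref, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(5), rng.random(5)
        assert paired_t_from_folds(a, b).t == pytest.approx(
            -paired_t_from_folds(b, a).t, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_from_folds([1, 2, 3], [1, 2])


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        # {1,2,3} vs {2,3,4}: SSB=1.5, SSW=4 -> F = 1.5/(4/4) = 1.5
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert res.df_between == 1 and res.df_within == 4

    def test_identical_groups_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(8), rng.random(6) + 0.2
        res = one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [1, 2]])


class TestPBand:
    @pytest.mark.parametrize("p,band", [
        (0.005, "<0.01"), (0.015, "<0.02"), (0.05, "<0.10"), (0.5, ">0.10"),
        (0.0, "<0.01"), (1.0, ">0.10"),
    ])
    def test_examples(self, p, band):
        assert p_band(p) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_band(1.2)
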