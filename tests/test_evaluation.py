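import numpy as np
import pandas as pd
import pytest

from octavd.evaluation import (
    ConfusionCounts,
    aggregate_performance,
    auc_from_sens_spec,
    bland_altman,
    compare_methods,
    confusion_counts,
    icc_absolute_agreement,
    image_metrics,
    regression_r2,
)
from octavd.raster_io import BinaryMask


# ---------------------------------------------------------------- oracles

def anova_mean_squares_oracle(x):
    """Two-way ANOVA mean squares via explicit per-cell loops."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    row_means = [x[i].sum() / k for i in range(n)]
    col_means = [x[:, j].sum() / n for j in range(k)]
    ssr = sum(k * (rm - grand) ** 2 for rm in row_means)
    ssc = sum(n * (cm - grand) ** 2 for cm in col_means)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_a1_oracle(x):
    n, k = x.shape
    msr, msc, mse = anova_mean_squares_oracle(x)
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def icc_c1_oracle(x):
    """Consistency ICC (rater bias ignored), for contrast with A,1."""
    k = x.shape[1]
    msr, _, mse = anova_mean_squares_oracle(x)
    return (msr - mse) / (msr + (k - 1) * mse)


# -------------------------------------------------------------- confusion

class TestConfusion:
    def test_identity_has_no_errors(self, rng):
        m = BinaryMask(rng.random((20, 20)) > 0.5)
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == m.flow.sum()

    def test_complement_has_no_agreement(self, rng):
        m = BinaryMask(rng.random((20, 20)) > 0.5)
        c = confusion_counts(BinaryMask(~m.flow), m)
        assert c.tp == 0 and c.tn == 0

    def test_enumerated_4x4_fixture(self):
        pred = np.zeros((4, 4), bool)
        gold = np.zeros((4, 4), bool)
        pred.ravel()[[0, 1, 2, 3, 4, 5]] = True  # 6 foreground
        gold.ravel()[[0, 1, 2, 3, 6]] = True  # 5 foreground, overlap 4
        c = confusion_counts(BinaryMask(pred), BinaryMask(gold))
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 2, 1, 9)

    def test_valid_region_restriction(self, rng):
        pred = BinaryMask(rng.random((10, 10)) > 0.5)
        gold = BinaryMask(rng.random((10, 10)) > 0.5)
        valid = rng.random((10, 10)) > 0.4
        c = confusion_counts(pred, gold, valid)
        assert c.total == valid.sum()

    def test_conservation_on_random_masks(self, rng):
        for _ in range(20):
            pred = BinaryMask(rng.random((15, 15)) > rng.random())
            gold = BinaryMask(rng.random((15, 15)) > rng.random())
            assert confusion_counts(pred, gold).total == 225

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(BinaryMask(np.zeros((4, 4), bool)), BinaryMask(np.zeros((5, 5), bool)))


class TestImageMetrics:
    def test_fixture_arithmetic(self):
        m = image_metrics(ConfusionCounts(tp=4, fp=2, fn=1, tn=9))
        assert m.sensitivity == pytest.approx(80.0)
        assert m.specificity == pytest.approx(81.818, abs=1e-3)
        assert m.accuracy == pytest.approx(81.25)

    def test_perfect_mask(self):
        m = image_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=90))
        assert m == (100.0, 100.0, 100.0)

    def test_zero_sensitivity(self):
        assert image_metrics(ConfusionCounts(0, 0, 5, 5)).sensitivity == 0.0

    def test_empty_flow_class_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = image_metrics(ConfusionCounts(0, 2, 0, 8))
        assert np.isnan(m.sensitivity)


class TestAuc:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(79.0, 86.1, 0.826), (72.6, 87.2, 0.799), (100.0, 100.0, 1.0), (0.0, 0.0, 0.0)],
    )
    def test_values(self, sens, spec, expected):
        assert auc_from_sens_spec(sens, spec) == pytest.approx(expected, abs=5e-4)

    def test_range_check(self):
        with pytest.raises(ValueError):
            auc_from_sens_spec(120, 50)


class TestAggregate:
    def test_identical_images_zero_width_ci(self):
        summary = aggregate_performance([(80.0, 90.0, 85.0)] * 5)
        assert summary.mean_accuracy == 85.0
        assert summary.accuracy_sd == 0.0
        assert summary.ci_low == summary.ci_high == 85.0

    def test_two_image_mean(self):
        s = aggregate_performance([(70, 90, 80), (80, 90, 90)])
        assert s.mean_accuracy == 85.0

    def test_fourteen_images_match_brute_force(self, rng):
        rows = [tuple(rng.uniform(50, 100, 3)) for _ in range(14)]
        s = aggregate_performance(rows)
        accs = [r[2] for r in rows]
        assert s.mean_accuracy == pytest.approx(sum(accs) / 14)
        mean = sum(accs) / 14
        sd = (sum((a - mean) ** 2 for a in accs) / 13) ** 0.5
        assert s.accuracy_sd == pytest.approx(sd)
        assert s.ci_low <= s.mean_accuracy <= s.ci_high
        assert s.auc == pytest.approx(
            auc_from_sens_spec(sum(r[0] for r in rows) / 14, sum(r[1] for r in rows) / 14)
        )

    def test_undefined_rows_dropped_with_warning(self):
        rows = [(80.0, 90.0, 85.0), (np.nan, 90.0, 50.0), (82.0, 88.0, 86.0)]
        with pytest.warns(UserWarning, match="dropping"):
            s = aggregate_performance(rows)
        assert s.n_images == 2

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            aggregate_performance([(80, 90, 85)])


# -------------------------------------------------------------------- icc

class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        r = icc_absolute_agreement(x)
        assert r.icc == 1.0 and r.passes_gate
        assert r.ci_low == r.ci_high == 1.0

    def test_rater_shift_hurts_absolute_more_than_consistency(self, rng):
        x = rng.normal(30, 8, (8, 1)) + rng.normal(0, 2, (8, 3))
        x[:, 2] += 40  # one rater reads high by a constant
        absolute = icc_absolute_agreement(x).icc
        assert absolute < icc_c1_oracle(x)

    def test_seeded_6x3_matches_anova_oracle(self, rng):
        x = rng.normal(30, 5, (6, 3)) + rng.normal(0, 2, (6, 1))
        assert icc_absolute_agreement(x).icc == pytest.approx(icc_a1_oracle(x), abs=1e-9)

    def test_hundred_seeded_matrices_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            k = int(rng.integers(2, 5))
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, rng.uniform(0.1, 3), (n, 1))
            assert icc_absolute_agreement(x).icc == pytest.approx(icc_a1_oracle(x), abs=1e-9)

    def test_matches_pingouin_with_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(3):
            x = rng.normal(30, 5, (8, 3)) + rng.normal(0, 2, (8, 1))
            df = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(8), 3),
                    "r": np.tile(np.arange(3), 8),
                    "s": x.ravel(),
                }
            )
            row = pg.intraclass_corr(df, "t", "r", "s").query("Type == 'ICC(A,1)'").iloc[0]
            mine = icc_absolute_agreement(x)
            assert mine.icc == pytest.approx(row["ICC"], abs=1e-9)
            assert mine.ci_low == pytest.approx(row["CI95"][0], abs=0.01)
            assert mine.ci_high == pytest.approx(row["CI95"][1], abs=0.01)

    def test_gate_boundary_inclusive(self):
        # engineered so MSR = 14, MSC = MSE = 2, hence ICC = 12/16 = 0.75
        x = np.array([[2.0, -2.0], [1.0, 1.0], [3.0, 3.0], [6.0, 6.0]])
        r = icc_absolute_agreement(x)
        assert r.icc == 0.75
        assert r.passes_gate

    def test_gate_consistent_with_estimate(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, (6, 3)) + rng.normal(0, rng.uniform(0.5, 3), (6, 1))
            r = icc_absolute_agreement(x)
            assert r.passes_gate == (r.icc >= 0.750)
            assert r.ci_low <= r.icc <= r.ci_high

    def test_zero_variance_degenerate(self):
        r = icc_absolute_agreement(np.full((4, 3), 7.0))
        assert r.degenerate and not r.passes_gate

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ----------------------------------------------------------- bland-altman

class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([(3.0, 3.0), (7.0, 7.0)])
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_symmetric_differences(self):
        ba = bland_altman([(1.0, 0.0), (0.0, 1.0)])
        sd = np.std([1.0, -1.0], ddof=1)
        assert ba.bias == 0.0
        assert ba.loa_high == pytest.approx(1.96 * sd)
        assert ba.loa_low == pytest.approx(-1.96 * sd)

    def test_constant_offset(self):
        ba = bland_altman([(8.0, 3.0), (12.0, 7.0), (4.0, -1.0)])
        assert ba.bias == 5.0 and ba.loa_low == 5.0 and ba.loa_high == 5.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])


class TestRegression:
    def test_perfect_line(self):
        slope, intercept, r2 = regression_r2([1, 2, 3, 4], [1, 2, 3, 4])
        assert (slope, intercept, r2) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(1.0))

    def test_independent_noise(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        assert regression_r2(x, y)[2] < 0.01

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 10, 5)
        y = 2.5 * x - 1 + rng.normal(0, 0.5, 5)
        slope, intercept, r2 = regression_r2(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        b = sxy / sxx
        a = y.mean() - b * x.mean()
        ss_res = ((y - (a + b * x)) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(b)
        assert intercept == pytest.approx(a)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            regression_r2([2, 2, 2], [1, 2, 3])


# --------------------------------------------------------------- pipeline

def test_compare_methods_small_battery(small_phantom):
    from octavd.methods import builtin_registry, get_method
    from octavd.synthetic import PhantomParams, generate_phantom

    phantoms = [small_phantom] + [
        generate_phantom(PhantomParams(size=(120, 120), vessel_count=5, seed=s, target_vd=v))
        for s, v in [(21, 30.0), (22, 38.0)]
    ]
    registry = [get_method("Mean Global Threshold"), get_method("Phansalkar Local Threshold")]
    df = compare_methods([p.image for p in phantoms], [p.truth for p in phantoms], registry, seed=0)
    assert list(df["method"]) == [s.name for s in registry]
    assert df["mean_vd"].between(0, 100).all()
    assert (df["reliable"] == (df["icc"] >= 0.750)).all()
    assert "gold_vd_mean" in df.attrs
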