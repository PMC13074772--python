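"""Agreement statistics: ANOVA oracle equivalence, formula identities,
classification bands, and simulation calibration of the ICC machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinecm import (
    RatingTable,
    ReliabilityDesign,
    SampleSizeSpec,
    bland_altman,
    classify_correlation,
    classify_icc,
    error_sd_for_target_icc,
    icc_absolute_agreement,
    mdc_from_icc,
    rmse,
    sample_size_icc,
    sem_from_icc,
    simulate_rating_table,
    spearman,
)


def icc_ak_oracle(values):
    """From-scratch two-way ANOVA decomposition with plain loops, then the
    absolute-agreement average-measures formula with the same degenerate
    rule (non-positive denominator -> NaN) and lower clip at -1."""
    n = len(values)
    k = len(values[0])
    grand = sum(sum(row) for row in values) / (n * k)
    row_means = [sum(row) / k for row in values]
    col_means = [sum(values[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row_means) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col_means) / (k - 1)
    sse = sum(
        (values[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom <= 1e-12 * max(abs(msr), abs(msc), abs(mse), 1e-300):
        return float("nan")
    return max((msr - mse) / denom, -1.0)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        vals = np.column_stack([np.arange(5.0), np.arange(5.0)])
        est = icc_absolute_agreement(RatingTable(values=vals))
        assert est.icc == 1.0
        assert est.sem == 0.0 and est.mdc == 0.0
        assert est.label == "excellent"

    def test_small_table_matches_hand_anova(self):
        vals = [[9, 8], [1, 2], [8, 6], [2, 4]]
        est = icc_absolute_agreement(RatingTable(values=np.asarray(vals, float)))
        assert est.icc == pytest.approx(icc_ak_oracle(vals), abs=1e-10)

    def test_exhaustive_two_column_oracle_equivalence(self):
        # all 2-column tables with n <= 5 subjects and entries in {0, 1, 2}
        for n in range(2, 6):
            for flat in itertools.product((0.0, 1.0, 2.0), repeat=2 * n):
                vals = [list(flat[2 * i : 2 * i + 2]) for i in range(n)]
                expected = icc_ak_oracle(vals)
                est = icc_absolute_agreement(RatingTable(values=np.asarray(vals)))
                if math.isnan(expected):
                    assert est.degenerate and math.isnan(est.icc)
                else:
                    assert est.icc == pytest.approx(expected, abs=1e-10), vals

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        subj = rng.normal(10, 4, 15)[:, None]
        vals = subj + np.array([0.0, 0.5, -0.3]) + rng.normal(0, 1.5, (15, 3))
        est = icc_absolute_agreement(RatingTable(values=vals))
        df = pd.DataFrame({
            "s": np.repeat(np.arange(15), 3),
            "r": np.tile(np.arange(3), 15),
            "y": vals.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        row = ref[ref.Type == "ICC(A,k)"].iloc[0]
        assert est.icc == pytest.approx(row.ICC, abs=1e-12)
        assert est.p_value == pytest.approx(row.pval, rel=1e-9)
        assert est.ci_low == pytest.approx(row.CI95[0], abs=0.01)
        assert est.ci_high == pytest.approx(row.CI95[1], abs=0.01)

    def test_degenerate_table_flagged(self):
        vals = np.full((4, 2), 3.0)
        est = icc_absolute_agreement(RatingTable(values=vals))
        assert est.degenerate and math.isnan(est.icc)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            RatingTable(values=np.zeros((1, 2)))
        with pytest.raises(ValueError):
            RatingTable(values=np.zeros((3, 1)))

    def test_type_i_error_rate(self):
        # no subject signal: the one-sided F test at alpha = 0.05 should
        # reject in about 5% of replicates
        seeds = np.random.SeedSequence(7).generate_state(2000)
        rej = sum(
            icc_absolute_agreement(
                simulate_rating_table(
                    ReliabilityDesign(n_subjects=22, k_measurements=2,
                                      subject_sd=0.0, error_sd=1.0, seed=int(s))
                )
            ).p_value
            < 0.05
            for s in seeds
        )
        assert 0.04 <= rej / 2000 <= 0.06

    def test_ci_coverage(self):
        # 95% CI covers the true average-measures ICC 0.7 in 93-97% of reps
        err = error_sd_for_target_icc(0.7, 1.0, 2)
        seeds = np.random.SeedSequence(10).generate_state(2000)
        cov = 0
        for s in seeds:
            est = icc_absolute_agreement(
                simulate_rating_table(
                    ReliabilityDesign(n_subjects=32, k_measurements=2,
                                      subject_sd=1.0, error_sd=err, seed=int(s))
                )
            )
            cov += est.ci_low <= 0.7 <= est.ci_high
        assert 0.93 <= cov / 2000 <= 0.97

    def test_consistency_form_available(self, rng):
        vals = rng.normal(0, 3, 10)[:, None] + rng.normal(0, 1, (10, 2))
        msr_est = icc_absolute_agreement(RatingTable(values=vals), consistency=True)
        assert msr_est.form == "C,k"
        assert -1.0 <= msr_est.icc <= 1.0


class TestSemMdc:
    def test_reference_row_values(self):
        # ICC 0.60 with SD 1.9 deg: SEM 1.20, MDC 3.33 at z = 1.96
        assert round(sem_from_icc(0.60, 1.9), 2) == 1.20
        assert 3.33 <= round(mdc_from_icc(0.60, 1.9), 2) <= 3.34

    def test_limits(self):
        assert sem_from_icc(1.0, 7.7) == 0.0
        assert sem_from_icc(0.0, 3.3) == 3.3
        assert mdc_from_icc(1.0, 5.0) == 0.0

    def test_invalid_icc_rejected(self):
        with pytest.raises(ValueError):
            sem_from_icc(1.1, 1.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.floats(-1.0, 1.0, allow_nan=False),
        st.floats(0.0, 50.0, allow_nan=False),
        st.floats(0.1, 4.0, allow_nan=False),
    )
    def test_mdc_is_z_sqrt2_sem(self, icc, sd, z):
        assert mdc_from_icc(icc, sd, z) == pytest.approx(
            z * math.sqrt(2) * sem_from_icc(icc, sd), abs=1e-12
        )


def spearman_rank_oracle(x, y):
    """Explicit midrank computation + Pearson correlation of the ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        up = spearman(x, np.exp(x))
        assert up.rho == pytest.approx(1.0, abs=1e-12)
        assert up.label == "very_high"
        down = spearman(x, -(x**3))
        assert down.rho == pytest.approx(-1.0, abs=1e-12)

    def test_tied_data_matches_rank_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0]
        res = spearman(x, y)
        assert res.rho == pytest.approx(spearman_rank_oracle(x, y), abs=1e-12)

    def test_constant_input_degenerate(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate and math.isnan(res.rho)

    def test_permutation_p_value_reasonable(self, rng):
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0, 0.3, 12)
        res_t = spearman(x, y, method="t")
        res_p = spearman(x, y, method="permutation", n_permutations=2000, seed=0)
        assert res_p.rho == res_t.rho
        assert res_p.p_value < 0.05


class TestRmseBlandAltman:
    def test_rmse_examples(self):
        a = np.arange(6.0)
        assert rmse(a, a) == 0.0
        assert rmse(a, a - 2.5) == 2.5
        d = np.array([1.0, -1.0, 3.0, -3.0])
        assert rmse(d, np.zeros(4)) == pytest.approx(math.sqrt(5), abs=1e-12)

    def test_identical_pairs(self):
        a = np.arange(5.0)
        ba = bland_altman(a, a)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_two_point_closed_form(self):
        ba = bland_altman(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert ba.bias == 0.0
        assert ba.loa_high == pytest.approx(1.96 * math.sqrt(2), abs=1e-12)
        assert ba.loa_low == pytest.approx(-1.96 * math.sqrt(2), abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(-50, 50, width=32), st.floats(-50, 50, width=32)),
            min_size=2,
            max_size=30,
        )
    )
    def test_midpoint_identity(self, pairs):
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        ba = bland_altman(x, y)
        assert (ba.loa_low + ba.loa_high) / 2 == pytest.approx(ba.bias, abs=1e-9)
        assert ba.loa_high - ba.bias == pytest.approx(1.96 * ba.sd_diff, abs=1e-9)


class TestSampleSize:
    def test_design_point_80_power(self):
        n, n_infl = sample_size_icc(rho1=0.5, rho0=0.0, k=2, power=0.80, alpha=0.05)
        assert n == 22
        assert n_infl == 22

    def test_higher_power_higher_reliability(self):
        n, _ = sample_size_icc(rho1=0.6, rho0=0.0, k=2, power=0.90, alpha=0.05)
        assert n == 19

    def test_inflation(self):
        _, n_infl = sample_size_icc(rho1=0.5, k=2, power=0.80, inflation=0.25)
        assert n_infl == math.ceil(22 / 0.75)

    def test_monotone_in_effect_size(self):
        sizes = [sample_size_icc(rho1=r)[0] for r in (0.3, 0.4, 0.5, 0.6, 0.7)]
        assert all(b < a for a, b in zip(sizes, sizes[1:]))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(rho1=0.2, rho0=0.5)


class TestClassification:
    @pytest.mark.parametrize("rho,label", [
        (0.97, "very_high"), (0.90, "very_high"), (0.89, "high"), (0.70, "high"),
        (0.51, "moderate"), (0.30, "low"), (-0.45, "low"), (0.1, "insignificant"),
    ])
    def test_correlation_bands(self, rho, label):
        assert classify_correlation(rho) == label

    @pytest.mark.parametrize("icc,label", [
        (0.93, "excellent"), (0.75, "excellent"), (0.74, "moderate"),
        (0.40, "moderate"), (0.39, "poor"), (-0.2, "poor"),
    ])
    def test_icc_bands(self, icc, label):
        assert classify_icc(icc) == label
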