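"""Agreement statistics: consensus levels, MAE, ICC, Bland-Altman, acceptance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cobbmri.errors import UnavailableLevelError, UnsupportedConfigurationError
from cobbmri.reader_agreement import (
    MeasurementSet,
    acceptance_simulation,
    bland_altman,
    consensus_level,
    icc,
    icc_band,
    level_agreement_table,
    mae,
)

ORDER = ["L1", "L2", "L3", "L4", "L5"]


class TestConsensusLevel:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            (["L4", "L4", "L4"], "L4"),
            (["L3", "L4", "L5"], "L4"),   # three distinct: the middle one
            (["L2", "L2", "L5"], "L2"),   # median, not the outlier
            (["L3", "L3", "L4"], "L3"),
            (["L5", "L1", "L3", "L3", "L2"], "L3"),
        ],
    )
    def test_median_under_craniocaudal_order(self, levels, expected):
        assert consensus_level(levels, ORDER) == expected

    @pytest.mark.parametrize("levels", [["L1", "L2"], ["L1", "L2", "L3", "L4"]])
    def test_even_panels_refused(self, levels):
        with pytest.raises(UnsupportedConfigurationError):
            consensus_level(levels, ORDER)


class TestMAE:
    def test_identical_vectors_give_zero(self):
        assert mae([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == (0.0, 0.0)

    def test_population_sd_convention(self):
        m, sd = mae([0.0, 0.0], [1.0, 3.0])
        assert (m, sd) == (2.0, 1.0)

    def test_sample_sd_available_via_ddof(self):
        _, sd = mae([0.0, 0.0], [1.0, 3.0], ddof=1)
        assert sd == pytest.approx(math.sqrt(2))

    def test_half_normal_expectation_for_gaussian_noise(self):
        rng = np.random.default_rng(12)
        sigma = 2.0
        a = rng.normal(0, sigma, 20000)
        m, _ = mae(a, np.zeros_like(a))
        assert m == pytest.approx(sigma * math.sqrt(2 / math.pi), abs=0.05)


def hand_icc21(table):
    """Independent oracle: explicit two-way ANOVA mean-squares decomposition
    followed by the Shrout & Fleiss ICC(2,1) formula, written with plain
    loops (no shared code with the implementation)."""
    n = len(table)
    k = len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


SIX_BY_THREE = [
    [12.0, 14.5, 13.0],
    [20.0, 22.5, 21.0],
    [8.0, 7.5, 9.5],
    [30.0, 28.0, 31.5],
    [15.0, 16.0, 14.0],
    [25.5, 24.0, 27.0],
]


class TestICC:
    def test_matches_hand_anova_oracle_to_1e10(self):
        result = icc(np.array(SIX_BY_THREE))
        assert abs(result.estimate - hand_icc21(SIX_BY_THREE)) < 1e-10

    def test_matches_pingouin_estimate_and_ci(self):
        pg = pytest.importorskip("pingouin")
        x = np.array(SIX_BY_THREE)
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(6), 3),
                "rater": np.tile(["a", "b", "c"], 6),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="case", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        mine = icc(x)
        assert mine.estimate == pytest.approx(float(row["ICC"]), abs=1e-10)
        assert mine.ci95 == pytest.approx(tuple(row["CI95"]), abs=5e-3)

    def test_perfect_agreement_is_one(self):
        col = np.array([[10.0], [20.0], [5.0], [30.0], [12.0]])
        result = icc(np.repeat(col, 3, axis=1))
        assert result.estimate == 1.0
        assert result.band == "excellent"

    def test_pure_noise_is_near_zero_with_ci_covering_zero(self):
        rng = np.random.default_rng(3)
        result = icc(rng.normal(0, 1, (40, 3)))
        assert result.estimate < 0.25
        assert result.ci95[0] <= 0.05

    def test_case_and_rater_permutation_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(15, 8, (10, 1)) + rng.normal(0, 2, (10, 4))
        base = icc(x).estimate
        assert icc(x[rng.permutation(10)]).estimate == pytest.approx(base, abs=1e-12)
        assert icc(x[:, rng.permutation(4)]).estimate == pytest.approx(base, abs=1e-12)

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(15, 8, (10, 1)) + rng.normal(0, 2, (10, 3))
        assert icc(3.7 * x).estimate == pytest.approx(icc(x).estimate, abs=1e-12)

    def test_rater_offset_decreases_absolute_agreement(self):
        rng = np.random.default_rng(10)
        x = rng.normal(15, 8, (20, 1)) + rng.normal(0, 1, (20, 3))
        shifted = x + np.array([0.0, 4.0, -4.0])
        assert icc(shifted).estimate < icc(x).estimate

    def test_negative_estimates_clipped_and_flagged(self):
        # anti-correlated raters force a negative raw ICC
        x = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0], [4.0, -4.0], [5.0, -5.0]])
        result = icc(x)
        assert result.estimate == 0.0 and result.clipped and result.raw_estimate < 0

    def test_missing_cells_rejected(self):
        x = np.ones((6, 3))
        x[2, 1] = np.nan
        with pytest.raises(ValueError):
            icc(x)

    def test_band_cutpoints(self):
        assert icc_band(0.49) == "poor"
        assert icc_band(0.50) == "moderate"
        assert icc_band(0.75) == "good"
        assert icc_band(0.90) == "excellent"


class TestBlandAltman:
    def test_identical_vectors(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.bias, res.loa_lower, res.loa_upper) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([10.0, 12.0, 15.0])
        res = bland_altman(a + 3.0, a)
        assert res.bias == pytest.approx(3.0)
        assert res.loa_lower == pytest.approx(3.0)
        assert res.loa_upper == pytest.approx(3.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(15, 5, 50), rng.normal(15, 5, 50)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.bias == pytest.approx(-ba.bias)
        assert ab.loa_upper - ab.bias == pytest.approx(ba.loa_upper - ba.bias)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(44)
        mu, sigma, n = 3.2, 2.0, 150
        b = rng.normal(15, 8, n)
        a = b + rng.normal(mu, sigma, n)
        res = bland_altman(a, b)
        se_limit = sigma * math.sqrt(3 / n)  # approx SE of a limit of agreement
        assert res.bias == pytest.approx(mu, abs=4 * sigma / math.sqrt(n))
        assert res.loa_upper == pytest.approx(mu + 1.96 * sigma, abs=4 * se_limit)
        assert res.loa_lower == pytest.approx(mu - 1.96 * sigma, abs=4 * se_limit)

    def test_plot_written(self, tmp_path):
        rng = np.random.default_rng(5)
        a, b = rng.normal(15, 5, 30), rng.normal(15, 5, 30)
        out = tmp_path / "ba.png"
        bland_altman(a, b, plot=out)
        assert out.exists() and out.stat().st_size > 0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


def mset(rows):
    return MeasurementSet(pd.DataFrame(rows, columns=["case", "source", "top", "bottom", "angle"]))


class TestMeasurementSet:
    def test_duplicate_rows_rejected(self):
        with pytest.raises(ValueError):
            mset([("c1", "r1", "L2", "L4", 10.0), ("c1", "r1", "L2", "L4", 11.0)])

    def test_negative_angles_rejected(self):
        with pytest.raises(ValueError):
            mset([("c1", "r1", "L2", "L4", -1.0)])

    def test_csv_round_trip(self, tmp_path):
        ms = mset([("c1", "r1", "L2", "L4", 10.0), ("c2", "r1", "L3", "L5", 8.0)])
        path = tmp_path / "m.csv"
        ms.to_csv(path)
        assert MeasurementSet.from_csv(path).data.equals(ms.data)


class TestAcceptanceSimulation:
    def test_identical_measurements_fully_accepted(self):
        man = mset([("c1", "r1", "L2", "L4", 10.0), ("c2", "r1", "L2", "L4", 20.0)])
        auto = mset([("c1", "alg", "L2", "L4", 10.0), ("c2", "alg", "L2", "L4", 20.0)])
        res = acceptance_simulation(man, auto)
        assert res.fraction_accepted == 1.0 and not res.rejected

    def test_exact_5_degree_difference_is_rejected(self):
        man = mset([("c1", "r1", "L2", "L4", 15.0)])
        auto = mset([("c1", "alg", "L2", "L4", 10.0)])
        res = acceptance_simulation(man, auto, tolerance=5.0)
        assert res.fraction_accepted == 0.0  # strict "less than"

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(6)
        man = mset([(f"c{i}", "r1", "L2", "L4", 10.0 + rng.normal(0, 3)) for i in range(60)])
        auto = mset([(f"c{i}", "alg", "L2", "L4", 10.0) for i in range(60)])
        fracs = [acceptance_simulation(man, auto, tolerance=t).fraction_accepted
                 for t in (1.0, 3.0, 5.0, 8.0)]
        assert fracs == sorted(fracs)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(7)
        sigma, n = 2.0, 2000
        man = mset(
            [(f"c{i}", "r1", "L2", "L4", max(0.0, 15.0 + rng.normal(0, sigma)))
             for i in range(n)]
        )
        auto = mset([(f"c{i}", "alg", "L2", "L4", 15.0) for i in range(n)])
        res = acceptance_simulation(man, auto, tolerance=5.0)
        expected = 2 * stats.norm.cdf(5.0 / sigma) - 1
        assert res.fraction_accepted == pytest.approx(expected, abs=0.01)

    def test_missing_levels_raise(self):
        man = mset([("c1", "r1", "L2", "L4", 10.0)])
        auto = mset([("c1", "alg", "L3", "L4", 10.0)])
        with pytest.raises(UnavailableLevelError):
            acceptance_simulation(man, auto)


class TestLevelAgreementTable:
    def test_identical_levels_all_in_same_bucket(self):
        man = mset([("c1", "r1", "L2", "L4", 10.0), ("c2", "r1", "L1", "L3", 12.0)])
        ref = mset([("c1", "alg", "L2", "L4", 11.0), ("c2", "alg", "L1", "L3", 12.5)])
        table = level_agreement_table(man, ref, ORDER)
        assert table.loc["r1", "same_level"] == 1.0

    def test_combined_top_and_bottom_distance(self):
        man = mset(
            [
                ("c1", "r1", "L1", "L4", 10.0),  # top off by one -> one_level
                ("c2", "r1", "L1", "L3", 10.0),  # top and bottom off by one -> two_levels
                ("c3", "r1", "L1", "L1", 10.0),  # off by 1 + 3 -> more_than_two
                ("c4", "r1", "L2", "L4", 10.0),  # exact
            ]
        )
        ref = mset([(f"c{i}", "alg", "L2", "L4", 10.0) for i in range(1, 5)])
        table = level_agreement_table(man, ref, ORDER)
        assert table.loc["r1", "same_level"] == 0.25
        assert table.loc["r1", "one_level"] == 0.25
        assert table.loc["r1", "two_levels"] == 0.25
        assert table.loc["r1", "more_than_two"] == 0.25

    def test_unmatched_cases_listed(self):
        man = mset([("c1", "r1", "L2", "L4", 10.0), ("cX", "r1", "L2", "L4", 10.0)])
        ref = mset([("c1", "alg", "L2", "L4", 10.0)])
        with pytest.raises(ValueError, match="cX"):
            level_agreement_table(man, ref, ORDER)


class TestEndToEndReliability:
    """On simulated single-curve phantoms the qualitative reliability picture
    of the clinical validation reproduces: excellent reader-reader agreement
    and excellent reader-vs-algorithm agreement at matched levels."""

    def test_both_iccs_exceed_excellent_threshold(self, scheme):
        from cobbmri.cobb_core import cobb_at_levels
        from cobbmri.phantom import PhantomConfig, generate_phantom, simulate_readers
        from cobbmri.pipeline import measure_volume

        rng = np.random.default_rng(321)
        n = 30
        truths, results = [], []
        for _ in range(n):
            cfg = PhantomConfig.smooth_c_curve(
                max_cobb_deg=float(rng.uniform(5.0, 40.0)),
                plateau_fractions=tuple(rng.uniform(0.05, 0.25, 2)),
                direction=1 if rng.random() < 0.5 else -1,
                spacing=(1.2, 1.2, 1.2),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, truth = generate_phantom(cfg)
            truths.append(truth)
            results.append(measure_volume(vol, scheme))
        readers = simulate_readers(truths, n_readers=3, angle_noise_sd=2.5,
                                   level_error_prob=0.0, seed=17)
        cases = [f"case{i:03d}" for i in range(n)]
        matrix = np.array(
            [
                [float(readers[(readers["case"] == c)
                               & (readers["source"] == f"reader{k}")]["angle"].iloc[0])
                 for k in (1, 2, 3)]
                for c in cases
            ]
        )
        assert icc(matrix).estimate > 0.9
        manual, auto = [], []
        for rec in readers.itertuples(index=False):
            i = cases.index(rec.case)
            manual.append(float(rec.angle))
            auto.append(cobb_at_levels(results[i].table, rec.top, rec.bottom).angle)
        assert icc(np.column_stack([manual, auto])).estimate > 0.9
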