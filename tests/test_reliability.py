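import numpy as np
import pandas as pd
import pytest

import motionshare as ms
from motionshare.reliability import (
    icc_sem_roundtrip,
    minimal_difference,
    repeatability_report,
    sem_percent_of_mean,
)


def brute_force_anova(y):
    """Definition-level sums of squares, plain Python loops."""
    n, k = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def brute_force_icc_a1(y):
    n, k = y.shape
    msr, msc, mse = brute_force_anova(y)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestAnovaOracle:
    def test_integer_6x2_matrix(self):
        y = np.array([[3, 4], [5, 5], [2, 2], [8, 7], [6, 9], [4, 3]], dtype=float)
        m = ms.ObservationMatrix(y)
        a = ms.two_way_anova(m)
        msr, msc, mse = brute_force_anova(y)
        assert a.ms_subjects == pytest.approx(msr, abs=1e-10)
        assert a.ms_raters == pytest.approx(msc, abs=1e-10)
        assert a.ms_error == pytest.approx(mse, abs=1e-10)
        res = ms.icc_two_way_random_single(m)
        assert res.icc == pytest.approx(brute_force_icc_a1(y), abs=1e-10)

    @pytest.mark.parametrize("shape", [(6, 2), (8, 2), (10, 3), (7, 4)])
    def test_random_matrices(self, shape, rng):
        y = rng.normal(0, 1, size=shape) + rng.normal(0, 1, size=(shape[0], 1))
        res = ms.icc_two_way_random_single(ms.ObservationMatrix(y))
        assert res.icc == pytest.approx(brute_force_icc_a1(y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, size=(12, 3)) + rng.normal(0, 1, size=(12, 1))
        res = ms.icc_two_way_random_single(ms.ObservationMatrix(y))
        res_c = ms.icc_two_way_random_single(ms.ObservationMatrix(y), form="consistency")
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "y": y.ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
        table = table.set_index("Type")
        assert res.icc == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert res_c.icc == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        lo, hi = table.loc["ICC(A,1)", "CI95"]
        assert res.ci95[0] == pytest.approx(lo, abs=5e-3)
        assert res.ci95[1] == pytest.approx(hi, abs=5e-3)


class TestIcc:
    def test_identical_columns_icc_one(self, rng):
        col = rng.normal(0, 1, size=10)
        m = ms.ObservationMatrix(np.column_stack([col, col]))
        res = ms.icc_two_way_random_single(m)
        assert res.icc == pytest.approx(1.0)
        assert res.sem == pytest.approx(0.0, abs=1e-12)
        assert res.md == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_icc_near_zero(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, size=(3000, 2))
        res = ms.icc_two_way_random_single(ms.ObservationMatrix(y))
        assert abs(res.icc) < 0.05

    def test_constant_matrix_flagged_not_crashing(self):
        m = ms.ObservationMatrix(np.full((5, 2), 3.7))
        res = ms.icc_two_way_random_single(m)
        assert res.undefined
        assert np.isnan(res.icc)
        assert res.category is None

    def test_ci_brackets_estimate(self, rng):
        y = rng.normal(0, 0.03, size=(30, 2)) + rng.normal(0, 0.09, size=(30, 1))
        res = ms.icc_two_way_random_single(ms.ObservationMatrix(y))
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_shift_and_scale_invariance(self, rng):
        y = rng.normal(0, 1, size=(15, 2)) + rng.normal(0, 2, size=(15, 1))
        base = ms.icc_two_way_random_single(ms.ObservationMatrix(y))
        moved = ms.icc_two_way_random_single(ms.ObservationMatrix(y * 3.0 + 10.0))
        assert moved.icc == pytest.approx(base.icc, abs=1e-10)
        assert moved.sem == pytest.approx(base.sem * 3.0, abs=1e-10)
        assert moved.md == pytest.approx(base.md * 3.0, abs=1e-10)

    def test_ci_coverage_light(self):
        # 400-replicate smoke version of the coverage property
        model = ms.ObserverModel(between_subject_sd=0.08, error_sd=0.03, mean=0.2)
        root = np.random.SeedSequence(17)
        hits = 0
        for ss in root.spawn(400):
            m, _ = ms.generate_observation_matrix(model, 30, 2, seed=ss)
            res = ms.icc_two_way_random_single(m)
            hits += res.ci95[0] <= model.population_icc <= res.ci95[1]
        assert 0.91 <= hits / 400 <= 0.99

    def test_unknown_form_raises(self, rng):
        m = ms.ObservationMatrix(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            ms.icc_two_way_random_single(m, form="nope")


class TestSem:
    def test_duplicate_columns_sem_zero(self, rng):
        col = rng.normal(0, 1, size=8)
        a = ms.two_way_anova(ms.ObservationMatrix(np.column_stack([col, col])))
        assert ms.sem_from_anova(a) == pytest.approx(0.0, abs=1e-12)

    def test_sd_icc_roundtrip_printed_values(self):
        # SEM = SD * sqrt(1 - ICC) inverted: 1 - (0.024/0.09)^2 ~ 0.93
        icc = icc_sem_roundtrip(sem=0.024, pooled_sd=0.09)
        assert round(icc, 2) == 0.93
        assert icc_sem_roundtrip(0.029, 0.09) == pytest.approx(0.8962, abs=1e-4)

    def test_sd_icc_method(self, rng):
        y = rng.normal(0, 1, size=(20, 2)) + rng.normal(0, 1, size=(20, 1))
        m = ms.ObservationMatrix(y)
        res = ms.icc_two_way_random_single(m)
        sem2 = ms.sem_from_anova(res.anova, method="sd_icc", icc=res.icc)
        assert sem2 == pytest.approx(res.anova.pooled_sd * np.sqrt(1 - res.icc))

    def test_parameter_recovery(self):
        # mean estimated SEM ~ generating error SD, bias < 5% at n=30, k=2
        model = ms.ObserverModel(between_subject_sd=0.09, error_sd=0.02)
        root = np.random.SeedSequence(31)
        sems = []
        for ss in root.spawn(500):
            m, _ = ms.generate_observation_matrix(model, 30, 2, seed=ss)
            sems.append(ms.icc_two_way_random_single(m).sem)
        assert np.mean(sems) == pytest.approx(0.02, rel=0.05)

    def test_bad_method_raises(self, rng):
        a = ms.two_way_anova(ms.ObservationMatrix(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError):
            ms.sem_from_anova(a, method="bogus")


class TestMinimalDifference:
    @pytest.mark.parametrize(
        "sem,expected", [(0.024, 0.067), (0.020, 0.055), (0.0, 0.0)]
    )
    def test_printed_values(self, sem, expected):
        assert round(minimal_difference(sem), 3) == expected

    def test_formula_exact(self):
        sem = 0.1234
        assert minimal_difference(sem) == pytest.approx(sem * 1.96 * np.sqrt(2), abs=1e-15)

    def test_negative_sem_raises(self):
        with pytest.raises(ValueError):
            minimal_difference(-0.1)


class TestCategorize:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.90, "substantial"),
            (0.93, "substantial"),
            (0.78, "moderate"),
            (0.55, "fair"),
            (0.11, "slight"),
            (0.40, "slight"),
            (0.41, "fair"),
            (0.60, "fair"),
            (0.61, "moderate"),
            (0.80, "moderate"),
            (0.81, "substantial"),
            (1.00, "substantial"),
            (0.10, "below-slight"),
            (-0.30, "below-slight"),
        ],
    )
    def test_bands(self, icc, label):
        assert ms.categorize_icc(icc) == label

    def test_above_one_raises(self):
        with pytest.raises(ValueError):
            ms.categorize_icc(1.01)


class TestReport:
    @staticmethod
    def make_readings(rng, n=12, raters=("AxB", "DT1", "DT2"), error=0.02):
        rows = []
        true = {"MSI": rng.normal(0.24, 0.09, size=n), "MSV": rng.normal(0.07, 0.03, size=n)}
        for biom, vals in true.items():
            for j, rater in enumerate(raters):
                for i in range(n):
                    rows.append(
                        {
                            "subject": f"S{i:02d}",
                            "rater": rater,
                            "biomarker": biom,
                            "value": vals[i] + rng.normal(0, error),
                        }
                    )
        return pd.DataFrame(rows)

    def test_report_structure(self, rng, tmp_path):
        readings = self.make_readings(rng)
        pairs = {"intra": ("DT1", "DT2"), "inter": ("AxB", "DT1")}
        rep = repeatability_report(readings, pairs=pairs, outdir=tmp_path)
        assert set(rep["results"]) == {
            ("MSI", "intra"),
            ("MSI", "inter"),
            ("MSV", "intra"),
            ("MSV", "inter"),
        }
        assert (tmp_path / "report.md").exists()
        assert (tmp_path / "repeatability.csv").exists()
        assert (tmp_path / "scatter_MSI_intra.png").exists()
        summary = rep["summary"]
        assert set(summary["rater"]) == {"AxB", "DT1", "DT2"}

    def test_identical_reading_sets(self, rng):
        readings = self.make_readings(rng, error=0.0)
        rep = repeatability_report(readings, pairs={"intra": ("DT1", "DT2")})
        for res in rep["results"].values():
            assert res.icc == pytest.approx(1.0)
            assert res.sem == pytest.approx(0.0, abs=1e-12)
            assert res.md == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_subjects_raise(self, rng):
        readings = self.make_readings(rng)
        readings = readings.drop(
            readings[(readings.rater == "DT2") & (readings.subject == "S00")].index
        )
        with pytest.raises(ValueError, match="mismatched"):
            repeatability_report(readings, pairs={"intra": ("DT1", "DT2")})

    def test_sem_percent_example(self):
        assert round(sem_percent_of_mean(0.024, 0.24)) == 10
        assert round(sem_percent_of_mean(0.029, 0.24)) == 12

    def test_calibrated_simulation_recovers_icc(self):
        # cohorts with between 0.0867 / error 0.024 -> mean ICC ~ 0.93 population
        model = ms.ObserverModel(between_subject_sd=0.0867, error_sd=0.024, mean=0.24)
        root = np.random.SeedSequence(8)
        iccs = [
            ms.icc_two_way_random_single(
                ms.generate_observation_matrix(model, 30, 2, seed=ss)[0]
            ).icc
            for ss in root.spawn(300)
        ]
        assert np.mean(iccs) == pytest.approx(model.population_icc, abs=0.015)
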