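import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2

from remission_rank.config import StudyConfig
from remission_rank.datatypes import CohortTable, GenotypeMatrix
from remission_rank.gwas import (CHI2_1_MEDIAN, genomic_lambda, hwe_exact_p,
                                 logistic_snp_scan, qc_filter)


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent full-enumeration oracle: probability of each
    heterozygote count from the exact multinomial/hypergeometric form,
    p = sum of P(config) over configs no more probable than observed."""
    # P(h) = n!/(a! h! b!) * 2^h * na! (2n-na)! / (2n)!
    from math import factorial

    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def P(h):
        a = (na - h) // 2
        b = n - a - h
        return (factorial(n) // (factorial(a) * factorial(h) * factorial(b))
                * 2 ** h * factorial(na) * factorial(2 * n - na)
                / factorial(2 * n))

    hs = list(range(na % 2, min(na, 2 * n - na) + 1, 2))
    ps = {h: P(h) for h in hs}
    p_obs = ps[n_ab]
    return sum(p for p in ps.values() if p <= p_obs * (1 + 1e-12))


class TestHweExact:
    def test_hardy_weinberg_mode_has_p_one(self):
        # (25, 50, 25) is the modal configuration for 50/50 alleles
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_strongly_rejected(self):
        assert hwe_exact_p(50, 0, 50) < 1e-4

    @pytest.mark.parametrize("counts", [
        (5, 10, 5), (2, 3, 15), (0, 10, 10), (7, 1, 12), (20, 0, 1),
        (3, 14, 3), (0, 0, 25),
    ])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9)


def _make_cohort(gm, y, age=None, sex=None):
    n = gm.n_samples
    rng = np.random.default_rng(0)
    data = pd.DataFrame({
        "remission": y,
        "age": rng.normal(50, 8, n) if age is None else age,
        "male_sex": rng.integers(0, 2, n).astype(float) if sex is None
        else sex,
    }, index=gm.sample_ids)
    return CohortTable(data, dichotomous=("male_sex",),
                       continuous=("age",))


class TestQcFilter:
    def test_monomorphic_snp_excluded(self):
        rng = np.random.default_rng(1)
        dosage = np.column_stack([np.zeros(60),
                                  np.tile([0.0, 1.0, 2.0, 1.0], 15)])
        gm = GenotypeMatrix([f"s{i}" for i in range(60)],
                            ["mono", "ok"], dosage)
        cohort = _make_cohort(gm, rng.integers(0, 2, 60))
        filtered, _, report = qc_filter(gm, cohort, StudyConfig())
        assert "mono" not in filtered.snp_ids
        row = report[report["item"] == "mono"].iloc[0]
        assert row["reason"] == "low_maf"

    def test_sample_filter_applied_before_snp_filters(self):
        """A sample with >10% missing genotypes is removed first, and
        SNP statistics are computed on the survivors."""
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, (40, 10)).astype(float)
        dosage[0, :5] = np.nan  # 50% missing for sample 0
        gm = GenotypeMatrix([f"s{i}" for i in range(40)],
                            [f"v{j}" for j in range(10)], dosage)
        cohort = _make_cohort(gm, rng.integers(0, 2, 40))
        filtered, cohort_f, report = qc_filter(gm, cohort, StudyConfig())
        assert "s0" not in filtered.sample_ids
        assert "s0" not in cohort_f.sample_ids
        kinds = report.set_index("item")["kind"]
        assert kinds["s0"] == "sample"

    def test_hwe_violating_snp_excluded(self):
        # 30/0/30: total heterozygote deficit
        col = np.r_[np.zeros(30), np.full(30, 2.0)]
        ok = np.tile([0.0, 1.0, 2.0, 1.0], 15)
        gm = GenotypeMatrix([f"s{i}" for i in range(60)], ["bad", "good"],
                            np.column_stack([col, ok]))
        cohort = _make_cohort(gm, np.r_[np.zeros(30), np.ones(30)])
        filtered, _, report = qc_filter(gm, cohort, StudyConfig())
        assert "bad" not in filtered.snp_ids
        assert report.set_index("item").loc["bad", "reason"] == "hwe_deviation"

    def test_everything_filtered_is_an_error(self):
        gm = GenotypeMatrix(["s1", "s2", "s3", "s4"], ["mono"],
                            np.zeros((4, 1)))
        cohort = _make_cohort(gm, np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="no SNPs survive"):
            qc_filter(gm, cohort, StudyConfig())


def irls_logistic_oracle(X, y, tol=1e-12, max_iter=200):
    """Hand-rolled iteratively-reweighted least squares for logistic
    regression; independent of the statsmodels fitting path."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        z = eta + (y - mu) / np.clip(w, 1e-10, None)
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(X.T @ (X * (expit(X @ beta)
                                    * (1 - expit(X @ beta)))[:, None]))
    return beta, np.sqrt(np.diag(cov))


class TestLogisticScan:
    @pytest.fixture
    def fixture12(self):
        g = np.array([2, 1, 1, 0, 0, 0, 0, 0, 0, 2, 1, 2], dtype=float)
        age = np.array([59, 57, 45, 41, 46, 50, 34, 48, 41, 45, 46, 48],
                       dtype=float)
        sex = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 1, 1], dtype=float)
        gm = GenotypeMatrix([f"s{i}" for i in range(12)], ["snp1"],
                            g[:, None])
        cohort = _make_cohort(gm, y, age=age, sex=sex)
        return gm, cohort, g, age, sex, y

    def test_beta_matches_irls_oracle(self, fixture12):
        gm, cohort, g, age, sex, y = fixture12
        scan = logistic_snp_scan(gm, cohort)
        X = np.column_stack([np.ones(12), g, age, sex])
        beta, se = irls_logistic_oracle(X, y)
        assert scan.loc["snp1", "beta"] == pytest.approx(beta[1], abs=1e-6)
        assert scan.loc["snp1", "se"] == pytest.approx(se[1], rel=1e-4)
        assert scan.loc["snp1", "odds_ratio"] == pytest.approx(
            np.exp(beta[1]), rel=1e-5)

    def test_allele_flip_equivariance(self, fixture12):
        """Recoding dosage g -> 2-g negates beta and preserves p."""
        gm, cohort, g, *_ = fixture12
        flipped = GenotypeMatrix(gm.sample_ids, ["snp1"],
                                 (2.0 - g)[:, None])
        a = logistic_snp_scan(gm, cohort)
        b = logistic_snp_scan(flipped, cohort)
        assert a.loc["snp1", "beta"] == pytest.approx(
            -b.loc["snp1", "beta"], abs=1e-6)
        assert a.loc["snp1", "p_wald"] == pytest.approx(
            b.loc["snp1", "p_wald"], rel=1e-6)

    def test_separated_snp_flagged_unstable(self):
        g = np.r_[np.zeros(10), np.full(10, 2.0)]
        y = np.r_[np.zeros(10), np.ones(10)]
        gm = GenotypeMatrix([f"s{i}" for i in range(20)], ["sep"],
                            g[:, None])
        scan = logistic_snp_scan(gm, _make_cohort(gm, y))
        assert scan.loc["sep", "qc_status"] == "unstable_fit"
        assert np.isnan(scan.loc["sep", "p_wald"])

    def test_missing_dosage_dropped_listwise(self, fixture12):
        gm, cohort, g, age, sex, y = fixture12
        g2 = g.copy()
        g2[3] = np.nan
        gm2 = GenotypeMatrix(gm.sample_ids, ["snp1"], g2[:, None])
        scan = logistic_snp_scan(gm2, cohort)
        assert scan.loc["snp1", "n_used"] == 11


class TestGenomicLambda:
    def test_all_median_p_gives_unit_lambda(self):
        lam, _ = genomic_lambda(np.full(99, 0.5))
        assert lam == pytest.approx(1.0)

    def test_doubled_chi2_gives_lambda_two(self):
        p = chi2.sf(2 * CHI2_1_MEDIAN, 1)
        lam, _ = genomic_lambda(np.full(50, p))
        assert lam == pytest.approx(2.0, rel=1e-9)

    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(12)
        lam, qq = genomic_lambda(rng.random(10_000))
        assert 0.95 < lam < 1.05
        assert len(qq) == 10_000
        # expected axis is sorted descending, observed matched
        assert qq["expected_neglog10_p"].is_monotonic_decreasing

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            genomic_lambda([np.nan])
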