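"""Quality control and the single-SNP covariate-adjusted logistic scan.

QC removes samples with a high missing-genotype rate first, then SNPs
failing minor-allele-frequency, Hardy-Weinberg (exact test) or
missingness filters.  Each surviving SNP is tested with
``remission ~ dosage + age + sex`` by maximum likelihood under the
additive (multiplicative-odds) model; the dosage Wald p-value is the
association score.  A genomic inflation factor near 1 over a null panel
is the calibration diagnostic.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import StudyConfig
from .datatypes import CohortTable, GenotypeMatrix

#: median of the chi-square(1) distribution, the null expectation of the
#: median association statistic.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

DEFAULT_COVARIATES = ("age", "male_sex")


def hwe_exact_p(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Full enumeration over all heterozygote counts compatible with the
    observed allele counts; the p-value sums the probabilities of every
    configuration no more probable than the observed one (no mid-p).
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    # heterozygote count must share parity with the minor-allele count
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    if len(hets) == 0:
        return 1.0
    from scipy.special import gammaln

    def logprob(h):
        a = (n_minor - h) // 2          # minor homozygotes
        b = (2 * n - n_minor - h) // 2  # major homozygotes
        return (gammaln(n + 1) - gammaln(a + 1) - gammaln(h + 1)
                - gammaln(b + 1) + h * math.log(2)
                + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
                - gammaln(2 * n + 1))

    lp = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _snp_stats(col: np.ndarray) -> tuple:
    """(maf, missing_rate, hwe_p) for one dosage column."""
    miss = np.isnan(col)
    obs = col[~miss]
    missing_rate = miss.mean() if len(col) else 1.0
    if len(obs) == 0:
        return 0.0, missing_rate, 1.0
    freq = obs.sum() / (2 * len(obs))
    maf = min(freq, 1 - freq)
    counts = [(obs == 2).sum(), (obs == 1).sum(), (obs == 0).sum()]
    if freq > 0.5:  # column happens to count the major allele
        counts = counts[::-1]
    hwe = hwe_exact_p(*[int(c) for c in counts])
    return float(maf), float(missing_rate), hwe


def qc_filter(genotypes: GenotypeMatrix, cohort: CohortTable,
              config: StudyConfig | None = None):
    """Apply the standard association-scan quality-control filters.

    Samples with missing-genotype rate above ``sample_miss_max`` are
    removed first; SNP statistics are then computed on the surviving
    samples and SNPs failing MAF / HWE / missingness thresholds are
    dropped.  Returns (filtered GenotypeMatrix, filtered CohortTable,
    report DataFrame listing every exclusion with its reason).
    """
    config = config or StudyConfig()
    exclusions = []

    sample_miss = np.isnan(genotypes.dosage).mean(axis=1)
    keep_samples = sample_miss <= config.sample_miss_max
    for sid, rate in zip(np.asarray(genotypes.sample_ids)[~keep_samples],
                         sample_miss[~keep_samples]):
        exclusions.append({"item": sid, "kind": "sample",
                           "reason": "sample_missingness", "value": rate})
    kept_ids = [s for s, k in zip(genotypes.sample_ids, keep_samples) if k]
    gm = genotypes.subset(sample_ids=kept_ids)

    keep_snps = []
    snp_report = {}
    for j, snp in enumerate(gm.snp_ids):
        maf, miss, hwe = _snp_stats(gm.dosage[:, j])
        snp_report[snp] = (maf, miss, hwe)
        if miss > config.snp_miss_max:
            exclusions.append({"item": snp, "kind": "snp",
                               "reason": "snp_missingness", "value": miss})
        elif maf < config.maf_min:
            exclusions.append({"item": snp, "kind": "snp",
                               "reason": "low_maf", "value": maf})
        elif hwe < config.hwe_p_min:
            exclusions.append({"item": snp, "kind": "snp",
                               "reason": "hwe_deviation", "value": hwe})
        else:
            keep_snps.append(snp)
    if not keep_snps:
        raise ValueError("no SNPs survive QC")
    gm = gm.subset(snp_ids=keep_snps)
    cohort_f = cohort.subset(kept_ids)
    report = pd.DataFrame(exclusions,
                          columns=["item", "kind", "reason", "value"])
    report.attrs["snp_stats"] = snp_report
    return gm, cohort_f, report


def logistic_snp_scan(genotypes: GenotypeMatrix, cohort: CohortTable,
                      covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Per-SNP logistic regression of remission on minor-allele dosage.

    Rows with a missing dosage or covariate are dropped per fit
    (listwise within SNP).  Returns one row per SNP: beta, se,
    odds_ratio, 95% CI, p_wald, maf, hwe_p, snp_missing_rate and
    qc_status ('ok' or 'unstable_fit'; unstable fits carry no values).
    """
    y_all = cohort.remission.reindex(genotypes.sample_ids).to_numpy(float)
    cov = cohort.data.reindex(genotypes.sample_ids)[list(covariates)] \
        .to_numpy(float)
    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        g = genotypes.dosage[:, j]
        maf, miss, hwe = _snp_stats(g)
        ok = ~np.isnan(g) & ~np.isnan(y_all) & ~np.isnan(cov).any(axis=1)
        rec = {"snp_id": snp, "maf": maf, "hwe_p": hwe,
               "snp_missing_rate": miss, "n_used": int(ok.sum())}
        X = np.column_stack([np.ones(ok.sum()), g[ok], cov[ok]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y_all[ok], X).fit(disp=0, maxiter=100)
            beta, se = fit.params[1], fit.bse[1]
            if not (fit.mle_retvals.get("converged", False)
                    and np.isfinite(beta) and np.isfinite(se) and se < 1e3):
                raise RuntimeError("unstable")
            rec.update(beta=float(beta), se=float(se),
                       odds_ratio=float(np.exp(beta)),
                       ci95_low=float(np.exp(beta - 1.96 * se)),
                       ci95_high=float(np.exp(beta + 1.96 * se)),
                       p_wald=float(2 * stats.norm.sf(abs(beta) / se)),
                       qc_status="ok")
        except Exception:
            rec.update(beta=np.nan, se=np.nan, odds_ratio=np.nan,
                       ci95_low=np.nan, ci95_high=np.nan, p_wald=np.nan,
                       qc_status="unstable_fit")
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("snp_id")
    return out[["beta", "se", "odds_ratio", "ci95_low", "ci95_high",
                "p_wald", "maf", "hwe_p", "snp_missing_rate", "n_used",
                "qc_status"]]


def genomic_lambda(p_values) -> tuple:
    """Genomic inflation factor and QQ-plot points.

    λ = median observed chi-square(1) quantile / null median (~0.455).
    Returns (lambda, DataFrame of expected vs observed -log10 p).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no valid p-values")
    chi2_obs = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    lam = float(np.median(chi2_obs) / CHI2_1_MEDIAN)
    n = len(p)
    # both axes descending: smallest expected/observed p first
    obs = np.sort(-np.log10(np.clip(p, 1e-300, 1.0)))[::-1]
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"expected_neglog10_p": exp,
                       "observed_neglog10_p": obs})
    return lam, qq
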