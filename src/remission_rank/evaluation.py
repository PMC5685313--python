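"""Model evaluation: ROC/AUC, confusion at the 0.5 cutoff, NRI/IDI
reclassification metrics, negative controls and the 8-group patient
breakdown comparing the clinical-only and clinical+SNP models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC (tie-corrected)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(np.asarray(labels),
                              np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def confusion_at(scores, labels, cutoff: float = 0.5) -> dict:
    """Accuracy / sensitivity / specificity with score >= cutoff
    classified as remitter (boundary inclusive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = len(labels)
    return {"accuracy": (tp + tn) / n,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn, "n": n}


@dataclass
class ReclassResult:
    estimate: float
    z: float
    p_value: float
    method: str


def _ztest(est: float, se: float, method: str) -> ReclassResult:
    if se == 0:
        return ReclassResult(est, np.inf if est else 0.0,
                             0.0 if est else 1.0, method)
    z = est / se
    return ReclassResult(est, float(z), float(2 * stats.norm.sf(abs(z))),
                         method)


def reclassification_metrics(scores_old, scores_new, labels,
                             cutoffs=(0.5,)) -> dict:
    """Categorical NRI, continuous NRI and IDI with asymptotic z-tests.

    Categorical NRI counts moves across the cutoff categories;
    continuous NRI counts any score increase/decrease.
    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)];
    IDI = (mean Δscore | events) - (mean Δscore | nonevents).
    Standard errors follow the usual asymptotic formulas:
    se(NRI) = sqrt(Σ_group (p_up + p_down - (p_up - p_down)^2) / n_group)
    and se(IDI) = sqrt(var(Δ|events)/n_e + var(Δ|nonevents)/n_ne).
    """
    old = np.asarray(scores_old, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("scores_old, scores_new and labels must be paired")

    edges = np.concatenate([[-np.inf], np.sort(np.asarray(cutoffs, float)),
                            [np.inf]])
    cat_old = np.digitize(old, edges[1:-1], right=False)
    cat_new = np.digitize(new, edges[1:-1], right=False)

    out = {}
    for name, up, down in [
        ("nri_categorical", cat_new > cat_old, cat_new < cat_old),
        ("nri_continuous", new > old, new < old),
    ]:
        ev, ne = y == 1, y == 0
        pu_e, pd_e = up[ev].mean(), down[ev].mean()
        pu_n, pd_n = up[ne].mean(), down[ne].mean()
        est = (pu_e - pd_e) + (pd_n - pu_n)
        se = np.sqrt((pu_e + pd_e - (pu_e - pd_e) ** 2) / ev.sum()
                     + (pu_n + pd_n - (pd_n - pu_n) ** 2) / ne.sum())
        out[name] = _ztest(float(est), float(se), name)

    d = new - old
    ev, ne = y == 1, y == 0
    idi = d[ev].mean() - d[ne].mean()
    se = np.sqrt(d[ev].var(ddof=1) / ev.sum() + d[ne].var(ddof=1) / ne.sum()
                 ) if ev.sum() > 1 and ne.sum() > 1 else 0.0
    out["idi"] = _ztest(float(idi), float(se), "idi")
    return out


def discrimination_slope(scores, labels) -> float:
    """Mean score among events minus mean score among nonevents; the
    IDI equals the difference of discrimination slopes."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    return float(scores[y == 1].mean() - scores[y == 0].mean())


BREAKDOWN_GROUPS = [
    ("remitter", True, True), ("remitter", True, False),
    ("remitter", False, True), ("remitter", False, False),
    ("nonremitter", True, True), ("nonremitter", True, False),
    ("nonremitter", False, True), ("nonremitter", False, False),
]


def patient_breakdown(scores_clinical, scores_full, labels,
                      cutoff: float = 0.5) -> tuple:
    """Cross-classify patients by correctness under each model.

    Returns (8-group count table indexed by
    (true class, clinical-correct, full-correct), per-patient
    score-shift table with old/new scores and group labels).  The
    'rescued' groups are the clinically misclassified patients that
    the SNP-augmented model fixes.
    """
    old = np.asarray(scores_clinical, dtype=float)
    new = np.asarray(scores_full, dtype=float)
    y = np.asarray(labels).astype(int)
    ok_old = (old >= cutoff).astype(int) == y
    ok_new = (new >= cutoff).astype(int) == y
    rows = []
    for cls, o, nw in BREAKDOWN_GROUPS:
        mask = (y == (1 if cls == "remitter" else 0)) & (ok_old == o) \
            & (ok_new == nw)
        rows.append({"true_class": cls, "clinical_correct": o,
                     "full_correct": nw, "count": int(mask.sum())})
    counts = pd.DataFrame(rows).set_index(
        ["true_class", "clinical_correct", "full_correct"])
    shift = pd.DataFrame({
        "label": y, "score_clinical": old, "score_full": new,
        "clinical_correct": ok_old, "full_correct": ok_new})
    return counts, shift


def evaluation_report(scores, labels, cutoff: float = 0.5) -> dict:
    """AUC plus confusion-derived metrics at the classification cutoff."""
    return {"auc": roc_auc(scores, labels),
            **confusion_at(scores, labels, cutoff)}


def repeated_split_auc(cohort, genotypes, features, config=None,
                       n_splits: int = 1000, seed: int = 0,
                       eval_cohort=None) -> dict:
    """Mean and s.d. of the cross-validated AUC over repeated splits.

    Each repetition draws a fresh stratified outer split, trains one
    model per fold and pools the out-of-fold scores.  When
    ``eval_cohort`` is given (e.g. the redundant patients held out of
    the reduced set), models are trained on ``cohort`` but evaluated
    on the extra cohort instead of out-of-fold rows.
    """
    from .ann import encode, encoded_rows, predict_score, train_ann
    from .config import StudyConfig
    from .selection import make_nested_splits

    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_splits):
        split_seed = int(rng.integers(2 ** 31))
        plan = make_nested_splits(cohort.remission, config, seed=split_seed)
        scores_parts, labels_parts = [], []
        for o in range(config.outer_folds):
            tr, te = plan.outer_split(o)
            X_tr, y_tr, enc = encode(cohort, genotypes, features, tr)
            model = train_ann(X_tr, y_tr, config,
                              seed=int(rng.integers(2 ** 31)))
            target = eval_cohort if eval_cohort is not None else cohort
            ids = target.sample_ids if eval_cohort is not None else te
            X_te, y_te = encoded_rows(target, genotypes, enc, ids)
            scores_parts.append(pd.Series(predict_score(model, X_te),
                                          index=X_te.index))
            labels_parts.append(y_te)
        if eval_cohort is not None:
            # average the five fold models' scores on the fixed eval set
            s = pd.concat(scores_parts, axis=1).mean(axis=1)
            aucs.append(roc_auc(s, labels_parts[0]))
        else:
            aucs.append(roc_auc(pd.concat(scores_parts),
                                pd.concat(labels_parts)))
    arr = np.asarray(aucs)
    return {"auc_mean": float(arr.mean()), "auc_sd": float(arr.std(ddof=1)),
            "n_splits": n_splits}


def random_snp_control(cohort, genotypes, clinical_features, final_snps,
                       candidate_pool, plan, config=None,
                       n_draws: int = 1000, seed: int = 0,
                       draw_size: int | None = None) -> pd.DataFrame:
    """AUC distribution for random SNP sets of the final set's size.

    Each draw samples ``len(final_snps)`` SNPs (or ``draw_size`` when
    given) from the candidate pool excluding the final SNPs, trains the
    outer-fold models with clinical features + drawn SNPs and records
    the pooled out-of-fold AUC.
    """
    from .selection import outer_fold_models

    pool = [s for s in candidate_pool if s not in set(final_snps)]
    k = draw_size if draw_size is not None else max(len(final_snps), 1)
    if len(pool) < k:
        raise ValueError("candidate pool smaller than the draw size")
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_draws):
        drawn = list(rng.choice(pool, size=k, replace=False))
        _, scores, labels = outer_fold_models(
            cohort, genotypes, list(clinical_features) + drawn, plan, config)
        rows.append({"draw": d, "auc": roc_auc(scores, labels),
                     "snps": "|".join(drawn)})
    return pd.DataFrame(rows).set_index("draw")


def permuted_label_auc(cohort, genotypes, features, config=None,
                       seed: int = 0) -> float:
    """Cross-validated AUC after permuting the remission labels; a
    leak-free pipeline scores near 0.5."""
    from .datatypes import CohortTable
    from .selection import make_nested_splits, outer_fold_models
    from .config import StudyConfig

    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    data["remission"] = rng.permutation(data["remission"].to_numpy())
    permuted = CohortTable(data, cohort.dichotomous, cohort.continuous)
    plan = make_nested_splits(permuted.remission, config,
                              seed=int(rng.integers(2 ** 31)))
    _, scores, labels = outer_fold_models(permuted, genotypes, features,
                                          plan, config)
    return roc_auc(scores, labels)
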