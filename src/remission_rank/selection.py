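"""Nested cross-validated sequential forward feature selection.

Geometry: 5 outer folds; within each outer training set, 5 inner folds
repeated 5 times — 125 selection runs in total, each run performing a
full forward selection on its inner train/test split.  Nonremitters
are stratified equally across folds.  Features are accepted while the
inner-test AUC improves by at least ``delta_auc``; exact ties are
resolved by a seeded uniform draw.  The procedure runs first over
clinical features alone; the finalized clinical set then becomes the
fixed base on top of which candidate SNPs are forward-selected.

Finalization: a feature enters the final set when selected at least
once in every outer fold and at least X times over all runs (X = 45
for clinical features, 5 for SNPs at the default 125-run geometry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ann import AnnModel, encode, encoded_rows, train_ann
from .config import StudyConfig
from .datatypes import CohortTable, GenotypeMatrix
from .evaluation import roc_auc

log = logging.getLogger(__name__)


@dataclass
class SplitRun:
    outer: int
    repeat: int
    inner: int
    outer_train: list
    outer_test: list
    inner_train: list
    inner_test: list
    seed: int  # substream seed for this run's tie-breaks and inits


@dataclass
class SplitPlan:
    runs: list
    outer_assignments: dict  # sample_id -> outer fold
    seed: int
    config: StudyConfig

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def outer_split(self, o: int) -> tuple:
        r = next(r for r in self.runs if r.outer == o)
        return r.outer_train, r.outer_test


def _derived_seed(master: int, *key) -> int:
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_nested_splits(labels: pd.Series, config: StudyConfig | None = None,
                       seed: int = 0) -> SplitPlan:
    """Stratified outer folds and repeated stratified inner folds.

    ``labels`` is a 0/1 Series indexed by sample id.  Deterministic
    given the seed; per-run substreams are derived from
    (seed, outer, repeat, inner) so runs are order-independent.
    """
    config = config or StudyConfig()
    ids = np.asarray(labels.index)
    y = labels.to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < config.outer_folds:
        raise ValueError("minority class smaller than the outer fold count")

    outer = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                            random_state=_derived_seed(seed, 0))
    runs, assignments = [], {}
    for o, (tr, te) in enumerate(outer.split(ids, y)):
        outer_train, outer_test = ids[tr].tolist(), ids[te].tolist()
        for sid in outer_test:
            assignments[sid] = o
        y_tr = y[tr]
        for r in range(config.inner_repeats):
            inner = StratifiedKFold(
                n_splits=config.inner_folds, shuffle=True,
                random_state=_derived_seed(seed, 1, o, r))
            for i, (itr, ite) in enumerate(inner.split(tr, y_tr)):
                runs.append(SplitRun(
                    outer=o, repeat=r, inner=i,
                    outer_train=outer_train, outer_test=outer_test,
                    inner_train=ids[tr][itr].tolist(),
                    inner_test=ids[tr][ite].tolist(),
                    seed=_derived_seed(seed, 2, o, r, i)))
    return SplitPlan(runs=runs, outer_assignments=assignments, seed=seed,
                     config=config)


@dataclass
class SelectionRecord:
    outer: int
    repeat: int
    inner: int
    selected: list
    auc_trajectory: list  # starting AUC then AUC after each acceptance
    tie_draws: int = 0


class FeatureWorkspace:
    """Pre-transformed feature columns for one train/test split.

    Numerically identical to :func:`remission_rank.ann.encode` followed
    by ``encoder.transform`` on the test rows, but computed with bare
    numpy so the inner forward-selection loop avoids per-fit DataFrame
    construction.  Standardization statistics are recomputed per
    feature subset on the subset's complete-case TRAIN rows, exactly
    as the reference encoder does.
    """

    def __init__(self, cohort: CohortTable, genotypes: GenotypeMatrix | None,
                 features, train_ids, test_ids):
        self.features = list(features)
        self.index = {f: j for j, f in enumerate(self.features)}
        geno = genotypes.to_frame() if genotypes is not None else None
        cols, self.kinds = [], []
        for f in self.features:
            if f in cohort.covariates:
                col = cohort.data[f].to_numpy(dtype=float)
                kind = cohort.covariate_kind(f)
            elif geno is not None and f in geno.columns:
                col = geno[f].reindex(cohort.data.index).to_numpy(dtype=float)
                kind = "snp"
            else:
                raise KeyError(f"feature {f!r} is neither a covariate nor a SNP")
            if kind == "dichotomous":
                col = np.where(np.isnan(col), np.nan,
                               np.where(col > 0.5, 0.95, 0.05))
            elif kind == "continuous":
                if (col[~np.isnan(col)] <= 0).any():
                    raise ValueError(
                        f"continuous feature {f!r} has nonpositive values; "
                        "configure an offset before the log transform")
                col = np.log(col)
            cols.append(col)
            self.kinds.append(kind)
        self.values = np.column_stack(cols) if cols else np.empty((len(cohort.data), 0))
        self.y = cohort.remission.to_numpy(float)
        pos = {s: i for i, s in enumerate(cohort.sample_ids)}
        self.train_pos = np.array([pos[s] for s in train_ids], dtype=int)
        self.test_pos = np.array([pos[s] for s in test_ids], dtype=int)

    def encoded(self, feature_subset) -> tuple:
        """(X_train, y_train, X_test, y_test) for the complete-case rows."""
        js = [self.index[f] for f in feature_subset]
        sub = self.values[:, js]
        ok = ~np.isnan(sub).any(axis=1)
        tr = self.train_pos[ok[self.train_pos]]
        te = self.test_pos[ok[self.test_pos]]
        X_tr, X_te = sub[tr].copy(), sub[te].copy()
        for c, j in enumerate(js):
            if self.kinds[j] == "continuous":
                mu = X_tr[:, c].mean()
                sd = X_tr[:, c].std(ddof=0)
                sd = sd if sd > 0 else 1.0
                X_tr[:, c] = (X_tr[:, c] - mu) / sd
                X_te[:, c] = (X_te[:, c] - mu) / sd
        return X_tr, self.y[tr], X_te, self.y[te]


def _ws_fit_and_auc(ws: FeatureWorkspace, features, config, train_seed):
    """Train on the workspace's train rows, return (test AUC or None, model)."""
    from .ann import predict_score_array, train_ann_array

    X_tr, y_tr, X_te, y_te = ws.encoded(features)
    if len(X_tr) == 0 or len(set(y_tr)) < 2:
        return None, None
    model = train_ann_array(X_tr, y_tr, list(features), config,
                            seed=train_seed)
    if len(X_te) == 0 or len(set(y_te)) < 2:
        return None, model
    return roc_auc(predict_score_array(model, X_te), y_te), model


def _fit_and_auc(cohort, genotypes, features, train_ids, test_ids,
                 config, train_seed):
    """Train on train_ids, return (inner-test AUC or None, model)."""
    X_tr, y_tr, enc = encode(cohort, genotypes, features, train_ids)
    if len(set(y_tr)) < 2 or len(X_tr) == 0:
        return None, None
    model = train_ann(X_tr, y_tr, config, seed=train_seed)
    X_te, y_te = encoded_rows(cohort, genotypes, enc, test_ids)
    if len(set(y_te)) < 2 or len(X_te) == 0:
        return None, model
    from .ann import predict_score
    return roc_auc(predict_score(model, X_te), y_te), model


def forward_select(candidate_features, base_features, train_ids, test_ids,
                   cohort: CohortTable, genotypes: GenotypeMatrix | None,
                   config: StudyConfig, rng: np.random.Generator,
                   run_key: tuple = (0, 0, 0)) -> SelectionRecord:
    """One sequential forward selection on a single train/test split.

    Starting point: chance AUC 0.5 for an empty base, otherwise the
    AUC of the base-features model.  Each step trains one model per
    remaining candidate (same seeded init within the step, so
    candidates differ only by the added feature), accepts the best if
    it improves the current AUC by at least ``delta_auc``, breaking
    exact ties by a uniform draw, and stops otherwise.
    """
    candidates = [c for c in candidate_features if c not in set(base_features)]
    ws = FeatureWorkspace(cohort, genotypes,
                          list(base_features) + candidates,
                          train_ids, test_ids)
    selected: list = []
    tie_draws = 0
    if base_features:
        base_seed = int(rng.integers(2 ** 31))
        current, _ = _ws_fit_and_auc(ws, list(base_features), config,
                                     base_seed)
        if current is None:
            log.warning("run %s: base model untrainable", (run_key,))
            return SelectionRecord(*run_key, selected=[],
                                   auc_trajectory=[], tie_draws=0)
    else:
        current = 0.5
    trajectory = [current]

    while candidates:
        step_seed = int(rng.integers(2 ** 31))
        aucs = []
        for c in candidates:
            auc, _ = _ws_fit_and_auc(
                ws, list(base_features) + selected + [c], config, step_seed)
            aucs.append(-np.inf if auc is None else auc)
        best = max(aucs)
        if not (best >= current + config.delta_auc):
            break
        winners = [c for c, a in zip(candidates, aucs)
                   if abs(a - best) < 1e-12]
        if len(winners) > 1:
            tie_draws += 1
            choice = winners[int(rng.integers(len(winners)))]
        else:
            choice = winners[0]
        selected.append(choice)
        candidates.remove(choice)
        current = best
        trajectory.append(current)
    return SelectionRecord(*run_key, selected=selected,
                           auc_trajectory=trajectory, tie_draws=tie_draws)


def run_selection_phase(candidate_features, base_features,
                        cohort: CohortTable, genotypes: GenotypeMatrix | None,
                        plan: SplitPlan, config: StudyConfig) -> list:
    """Forward selection on every scheduled run of the plan."""
    records = []
    for run in plan.runs:
        rng = np.random.default_rng(run.seed)
        records.append(forward_select(
            candidate_features, base_features, run.inner_train,
            run.inner_test, cohort, genotypes, config, rng,
            run_key=(run.outer, run.repeat, run.inner)))
    return records


def finalize_features(records, config: StudyConfig, phase: str
                      ) -> pd.DataFrame:
    """Aggregate selection counts and apply the inclusion rule.

    Returns one row per ever-selected feature: total count, per-outer
    counts, and the final ``included`` flag.
    """
    if phase not in ("clinical", "snp"):
        raise ValueError("phase must be 'clinical' or 'snp'")
    outers = sorted({r.outer for r in records})
    if len(outers) < config.outer_folds:
        raise ValueError(f"records cover outer folds {outers}, "
                         f"expected {config.outer_folds}")
    min_total = (config.min_total_clinical if phase == "clinical"
                 else config.min_total_snp)
    counts: dict = {}
    for rec in records:
        for f in rec.selected:
            per = counts.setdefault(f, dict.fromkeys(outers, 0))
            per[rec.outer] += 1
    rows = []
    for f, per in sorted(counts.items()):
        total = sum(per.values())
        rows.append({"feature": f, "phase": phase, "total_count": total,
                     **{f"outer_{o}": per[o] for o in outers},
                     "included": (total >= min_total
                                  and all(per[o] >= config.min_per_outer
                                          for o in outers))})
    cols = (["feature", "phase", "total_count"]
            + [f"outer_{o}" for o in outers] + ["included"])
    return pd.DataFrame(rows, columns=cols).set_index("feature")


@dataclass
class TwoPhaseResult:
    plan: SplitPlan
    clinical_records: list
    clinical_table: pd.DataFrame
    snp_records: list
    snp_table: pd.DataFrame

    @property
    def clinical_features(self) -> list:
        return self.clinical_table.index[self.clinical_table.included].tolist()

    @property
    def snp_features(self) -> list:
        return self.snp_table.index[self.snp_table.included].tolist()


def run_two_phase_selection(cohort: CohortTable,
                            genotypes: GenotypeMatrix | None,
                            clinical_candidates, snp_candidates,
                            config: StudyConfig | None = None,
                            seed: int = 0) -> TwoPhaseResult:
    """Clinical phase, finalization, then SNP phase on the fixed base."""
    config = config or StudyConfig()
    plan = make_nested_splits(cohort.remission, config, seed=seed)
    clin_records = run_selection_phase(clinical_candidates, [], cohort,
                                       genotypes, plan, config)
    clin_table = finalize_features(clin_records, config, "clinical")
    base = clin_table.index[clin_table.included].tolist()
    if config.snp_phase_mode == "single":
        snp_records = _single_snp_phase(snp_candidates, base, cohort,
                                        genotypes, plan, config)
    else:
        snp_records = run_selection_phase(snp_candidates, base, cohort,
                                          genotypes, plan, config)
    snp_table = finalize_features(snp_records, config, "snp")
    return TwoPhaseResult(plan=plan, clinical_records=clin_records,
                          clinical_table=clin_table,
                          snp_records=snp_records, snp_table=snp_table)


def _single_snp_phase(snp_candidates, base, cohort, genotypes, plan, config):
    """Alternative SNP phase: each run accepts at most the single best SNP."""
    records = []
    one_step = StudyConfig(**{**config.to_dict()})
    for run in plan.runs:
        rng = np.random.default_rng(run.seed)
        rec = forward_select(snp_candidates, base, run.inner_train,
                             run.inner_test, cohort, genotypes, one_step,
                             rng, run_key=(run.outer, run.repeat, run.inner))
        rec.selected = rec.selected[:1]
        rec.auc_trajectory = rec.auc_trajectory[:2]
        records.append(rec)
    return records


def outer_fold_models(cohort: CohortTable, genotypes: GenotypeMatrix | None,
                      features, plan: SplitPlan,
                      config: StudyConfig | None = None) -> tuple:
    """Train one model per outer fold on the final feature set.

    Each model is fitted on its outer-training rows and scored on its
    held-out outer-test rows; the concatenated out-of-fold scores give
    the cross-validated performance estimate.  Returns
    (models, scores Series, labels Series).
    """
    from .ann import predict_score

    config = config or StudyConfig()
    models, score_parts, label_parts = [], [], []
    for o in sorted({r.outer for r in plan.runs}):
        train_ids, test_ids = plan.outer_split(o)
        X_tr, y_tr, enc = encode(cohort, genotypes, features, train_ids)
        model = train_ann(X_tr, y_tr, config,
                          seed=_derived_seed(plan.seed, 3, o))
        models.append(model)
        X_te, y_te = encoded_rows(cohort, genotypes, enc, test_ids)
        score_parts.append(pd.Series(predict_score(model, X_te),
                                     index=X_te.index))
        label_parts.append(y_te)
    return models, pd.concat(score_parts), pd.concat(label_parts)
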