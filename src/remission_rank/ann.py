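"""Feature encoding and the single-hidden-layer classification network.

The classifier is a feed-forward network with one hidden layer of three
logistic units and a logistic output, trained by minimizing the summed
cross-entropy plus a quadratic weight-decay penalty (decay parameter 1)
over all parameters with a quasi-Newton batch optimizer — the batch
equivalent of the classic back-propagation fit, and deterministic given
the initialization seed.  Weight decay on such a small cohort is the
main guard against overtraining.

Encoding conventions: dichotomous covariates map to {0.05, 0.95},
continuous covariates are log-transformed and standardized with the
TRAIN split's mean and s.d. (applied unchanged to test rows), SNPs stay
as additive minor-allele counts {0, 1, 2}.  Only complete cases for the
listed features are used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .config import StudyConfig
from .datatypes import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

DICHOTOMOUS_LOW, DICHOTOMOUS_HIGH = 0.05, 0.95


@dataclass
class Encoder:
    """Feature -> model-input transform anchored on a training split."""

    features: list
    kinds: dict                  # feature -> 'dichotomous'|'continuous'|'snp'
    train_mean: dict = field(default_factory=dict)
    train_sd: dict = field(default_factory=dict)

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Encode complete-case rows of ``raw`` (columns = features)."""
        raw = raw[self.features]
        complete = raw.dropna()
        n_dropped = len(raw) - len(complete)
        if n_dropped:
            log.debug("dropped %d incomplete rows", n_dropped)
        out = {}
        for f in self.features:
            x = complete[f].to_numpy(dtype=float)
            kind = self.kinds[f]
            if kind == "dichotomous":
                out[f] = np.where(x > 0.5, DICHOTOMOUS_HIGH, DICHOTOMOUS_LOW)
            elif kind == "continuous":
                if (x <= 0).any():
                    raise ValueError(
                        f"continuous feature {f!r} has nonpositive values; "
                        "configure an offset before the log transform")
                sd = self.train_sd[f]
                out[f] = (np.log(x) - self.train_mean[f]) / (sd if sd > 0 else 1.0)
            else:  # snp dosage
                out[f] = x
        return pd.DataFrame(out, index=complete.index)


def _raw_feature_frame(cohort: CohortTable, genotypes: GenotypeMatrix | None,
                       features) -> tuple:
    frames, kinds = {}, {}
    geno = genotypes.to_frame() if genotypes is not None else None
    for f in features:
        if f in cohort.covariates:
            frames[f] = cohort.data[f]
            kinds[f] = cohort.covariate_kind(f)
        elif geno is not None and f in geno.columns:
            frames[f] = geno[f].reindex(cohort.data.index)
            kinds[f] = "snp"
        else:
            raise KeyError(f"feature {f!r} is neither a covariate nor a SNP")
    return pd.DataFrame(frames, index=cohort.data.index), kinds


def encode(cohort: CohortTable, genotypes: GenotypeMatrix | None,
           features, train_ids) -> tuple:
    """Fit the encoder on the training rows.

    Returns (X_train, y_train, encoder); standardization statistics come
    from the complete-case training rows only, so applying
    ``encoder.transform`` to test rows never uses test information.
    """
    if not features:
        raise ValueError("empty feature list")
    raw, kinds = _raw_feature_frame(cohort, genotypes, features)
    enc = Encoder(features=list(features), kinds=kinds)
    train_raw = raw.loc[list(train_ids)].dropna()
    for f in features:
        if kinds[f] == "continuous":
            x = train_raw[f].to_numpy(dtype=float)
            if (x <= 0).any():
                raise ValueError(
                    f"continuous feature {f!r} has nonpositive values; "
                    "configure an offset before the log transform")
            lx = np.log(x)
            enc.train_mean[f] = float(lx.mean())
            enc.train_sd[f] = float(lx.std(ddof=0))
    X_train = enc.transform(raw.loc[list(train_ids)])
    y_train = cohort.remission.loc[X_train.index]
    return X_train, y_train, enc


def encoded_rows(cohort: CohortTable, genotypes: GenotypeMatrix | None,
                 encoder: Encoder, ids) -> tuple:
    """Apply a fitted encoder to arbitrary rows (e.g. a test split)."""
    raw, _ = _raw_feature_frame(cohort, genotypes, encoder.features)
    X = encoder.transform(raw.loc[list(ids)])
    return X, cohort.remission.loc[X.index]


@dataclass
class AnnModel:
    """One-hidden-layer network weights plus training metadata."""

    features: list
    w_in: np.ndarray    # (n_features, hidden)
    b_hidden: np.ndarray
    w_out: np.ndarray   # (hidden,)
    b_out: float
    weight_decay: float
    max_iterations: int
    seed: int
    converged: bool = True
    n_iter: int = 0

    @property
    def hidden_units(self) -> int:
        return self.w_in.shape[1]

    def to_text(self, path) -> None:
        Path(path).write_text(json.dumps({
            "features": self.features,
            "w_in": self.w_in.tolist(), "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(), "b_out": self.b_out,
            "weight_decay": self.weight_decay,
            "max_iterations": self.max_iterations, "seed": self.seed,
            "converged": self.converged, "n_iter": self.n_iter}, indent=1))

    @classmethod
    def from_text(cls, path) -> "AnnModel":
        d = json.loads(Path(path).read_text())
        return cls(features=d["features"], w_in=np.array(d["w_in"]),
                   b_hidden=np.array(d["b_hidden"]),
                   w_out=np.array(d["w_out"]), b_out=float(d["b_out"]),
                   weight_decay=d["weight_decay"],
                   max_iterations=d["max_iterations"], seed=d["seed"],
                   converged=d["converged"], n_iter=d["n_iter"])


def _unpack(theta, f, h):
    i = f * h
    w_in = theta[:i].reshape(f, h)
    b_h = theta[i:i + h]
    w_out = theta[i + h:i + 2 * h]
    b_out = theta[i + 2 * h]
    return w_in, b_h, w_out, b_out


def _loss_grad_numpy(theta, Xv, yv, lam, f, h):
    w_in, b_h, w_out, b_out = _unpack(theta, f, h)
    z = expit(Xv @ w_in + b_h)
    p = expit(z @ w_out + b_out)
    eps = 1e-12
    ce = -(yv * np.log(p + eps) + (1 - yv) * np.log(1 - p + eps)).sum()
    loss = ce + lam * (theta ** 2).sum()
    d_out = p - yv
    g_w_out = z.T @ d_out + 2 * lam * w_out
    g_b_out = d_out.sum() + 2 * lam * b_out
    d_hidden = d_out[:, None] * w_out[None, :] * z * (1 - z)
    g_w_in = Xv.T @ d_hidden + 2 * lam * w_in
    g_b_h = d_hidden.sum(axis=0) + 2 * lam * b_h
    grad = np.concatenate([g_w_in.ravel(), g_b_h, g_w_out,
                           np.array([g_b_out])])
    return loss, grad


try:  # compiled hot path; the numpy route is the readable reference
    import numba as _nb

    @_nb.njit(cache=True, fastmath=False)
    def _loss_grad_jit(theta, Xv, yv, lam, f, h):  # pragma: no cover
        n = Xv.shape[0]
        w_in = np.ascontiguousarray(theta[:f * h]).reshape(f, h)
        b_h = theta[f * h:f * h + h]
        w_out = theta[f * h + h:f * h + 2 * h]
        b_out = theta[f * h + 2 * h]
        grad = np.zeros_like(theta)
        g_w_in = grad[:f * h].reshape(f, h)
        loss = 0.0
        g_b_out = 0.0
        for i in range(n):
            z = np.empty(h)
            out_lin = b_out
            for j in range(h):
                a = b_h[j]
                for k in range(f):
                    a += Xv[i, k] * w_in[k, j]
                zj = 1.0 / (1.0 + np.exp(-a))
                z[j] = zj
                out_lin += zj * w_out[j]
            p = 1.0 / (1.0 + np.exp(-out_lin))
            eps = 1e-12
            loss += -(yv[i] * np.log(p + eps)
                      + (1.0 - yv[i]) * np.log(1.0 - p + eps))
            d = p - yv[i]
            g_b_out += d
            for j in range(h):
                grad[f * h + h + j] += z[j] * d
                dh = d * w_out[j] * z[j] * (1.0 - z[j])
                grad[f * h + j] += dh
                for k in range(f):
                    g_w_in[k, j] += Xv[i, k] * dh
        for t in range(theta.size):
            loss += lam * theta[t] * theta[t]
            grad[t] += 2.0 * lam * theta[t]
        grad[f * h + 2 * h] += g_b_out
        return loss, grad

    def _loss_grad(theta, Xv, yv, lam, f, h):
        return _loss_grad_jit(theta, Xv, yv, lam, f, h)
except ImportError:  # pragma: no cover
    _loss_grad = _loss_grad_numpy


def train_ann(X, y, config: StudyConfig | None = None, seed: int = 0
              ) -> AnnModel:
    """Fit the network by penalized maximum likelihood.

    Minimizes  sum cross-entropy + decay * sum(theta^2)  over all
    parameters (weights and biases) with L-BFGS-B, starting from
    seeded uniform(-0.5, 0.5) weights.  Deterministic given
    (data, seed).
    """
    X = pd.DataFrame(X)
    return train_ann_array(X.to_numpy(dtype=float), np.asarray(y, float),
                           list(X.columns), config, seed)


def train_ann_array(Xv: np.ndarray, yv: np.ndarray, features,
                    config: StudyConfig | None = None, seed: int = 0
                    ) -> AnnModel:
    """`train_ann` on bare arrays; the hot path of forward selection."""
    config = config or StudyConfig()
    features = list(features)
    if np.isnan(Xv).any():
        raise ValueError("design matrix contains missing values")
    classes = set(np.unique(yv))
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    const = [f for f, s in zip(features, Xv.std(axis=0)) if s == 0]
    if const:
        log.debug("constant columns in design matrix: %s", const)

    n, f = Xv.shape
    h = config.hidden_units
    lam = float(config.weight_decay)
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-0.5, 0.5, size=f * h + 2 * h + 1)

    Xc = np.ascontiguousarray(Xv, dtype=float)
    yc = np.ascontiguousarray(yv, dtype=float)
    res = minimize(_loss_grad, theta0, args=(Xc, yc, lam, f, h),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": config.max_iterations})
    w_in, b_h, w_out, b_out = _unpack(res.x, f, h)
    return AnnModel(features=features, w_in=w_in, b_hidden=b_h,
                    w_out=w_out, b_out=float(b_out),
                    weight_decay=lam, max_iterations=config.max_iterations,
                    seed=seed, converged=bool(res.success),
                    n_iter=int(res.nit))


def predict_score(model: AnnModel, X) -> np.ndarray:
    """Network output in [0, 1]; higher = more remitter-like."""
    X = pd.DataFrame(X)
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    Xv = X[model.features].to_numpy(dtype=float)
    return predict_score_array(model, Xv)


def predict_score_array(model: AnnModel, Xv: np.ndarray) -> np.ndarray:
    """`predict_score` on a bare array already in model feature order."""
    z = expit(Xv @ model.w_in + model.b_hidden)
    return expit(z @ model.w_out + model.b_out)


def olden_importance(models) -> pd.DataFrame:
    """Signed connection-weight importance, averaged across models.

    Per model, importance(feature) = sum over hidden units of
    (input->hidden weight) x (hidden->output weight); each model is
    scaled so max |importance| = 1 before averaging.  Positive values
    mean high values / more minor alleles push the score toward
    remission.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    feats = models[0].features
    if any(m.features != feats for m in models):
        raise ValueError("models have inconsistent feature lists")
    per_model = []
    for m in models:
        raw = m.w_in @ m.w_out
        peak = np.abs(raw).max()
        per_model.append(raw / peak if peak > 0 else raw)
    arr = np.vstack(per_model)
    return pd.DataFrame({"importance": arr.mean(axis=0),
                         "importance_sd": arr.std(axis=0, ddof=0)},
                        index=pd.Index(feats, name="feature"))


def raw_connection_weights(model: AnnModel) -> pd.Series:
    """Unscaled per-feature connection-weight products of one model."""
    return pd.Series(model.w_in @ model.w_out, index=model.features)
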