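"""Connectome-style prediction of a behavioral score from directed flow.

Two-step procedure.  Step 1 (done upstream, :func:`flowgc.group.step1_select`)
keeps edges whose average p-value across subjects clears a threshold.  Step 2
runs leave-one-subject-out cross-validation: within each fold, scores are
residualized on age and sex, every candidate edge's F-values are correlated
with the adjusted scores, edges passing p < p_step2 are split by correlation
sign, and per-sign simple regressions

    y_hat(+-) = b0(+-) + b1(+-) * sum of the subject's selected F values

are fit on the training subjects and applied to the holdout.  The final
model takes the union of fold-wise edge sets per sign (an edge selected with
conflicting signs keeps the sign of its full-sample correlation) and refits
the per-sign betas once on all training subjects.  Out-of-sample application
freezes everything: covariate coefficients, edge sets and betas.

Exposed both as functions and as :class:`CpmRegressor`, a scikit-learn
estimator over a subjects x edges feature matrix.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DimensionError, ValidationError
from .group import GroupFlowStack


# ---------------------------------------------------------------------------
# covariate handling
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CovariateModel:
    """Frozen OLS of score on intercept + covariates, reusable on new subjects."""

    columns: tuple[str, ...]
    coef: np.ndarray            # aligned with (intercept, *columns)

    def adjust(self, scores: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
        """Residualize new scores with the training coefficients (no refit)."""
        X = _covariate_design(covariates, self.columns)
        return np.asarray(scores, dtype=float) - X @ self.coef


def encode_sex(values) -> np.ndarray:
    v = pd.Series(values)
    if v.dtype == object:
        return v.map({"male": 1.0, "female": 0.0}).to_numpy()
    return v.astype(float).to_numpy()


def _covariate_design(covariates: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    for c in columns:
        cols.append(encode_sex(covariates[c]) if c == "sex" else covariates[c].to_numpy(float))
    return np.column_stack(cols)


def residualize_scores(behavior: pd.DataFrame,
                       covariate_columns: Sequence[str] = ("age", "sex")
                       ) -> tuple[np.ndarray, CovariateModel]:
    """OLS-residualize scores on the covariates; return residuals + frozen model.

    Constant covariates are dropped with a warning (their effect is absorbed
    by the intercept).  Held-out subjects must be adjusted with the returned
    model, never refit.
    """
    if len(behavior) < 3:
        raise ValidationError("need at least three subjects to residualize")
    kept = []
    for c in covariate_columns:
        vals = encode_sex(behavior[c]) if c == "sex" else behavior[c].to_numpy(float)
        if np.ptp(vals) == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
        else:
            kept.append(c)
    X = _covariate_design(behavior, kept)
    y = behavior["score"].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    model = CovariateModel(columns=tuple(kept), coef=coef)
    return y - X @ coef, model


# ---------------------------------------------------------------------------
# edge-wise correlation screening
# ---------------------------------------------------------------------------

def _column_pearson(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of every feature column against y.

    Zero-variance columns get r = 0, p = 1 (they can never be selected).
    """
    K = F.shape[0]
    Fc = F - F.mean(axis=0)
    yc = y - y.mean()
    ss_f = (Fc ** 2).sum(axis=0)
    ss_y = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Fc.T @ yc) / np.sqrt(ss_f * ss_y)
    dead = ~np.isfinite(r)
    r[dead] = 0.0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((K - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=K - 2)
    p[dead] = 1.0
    return r, p


def step2_select(features: np.ndarray, adjusted_scores: np.ndarray,
                 p_thresh: float = 0.005) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of positively / negatively score-correlated edges.

    Selection is strict (p < p_thresh); the sign split over selected edges is
    exhaustive and disjoint.
    """
    if features.shape[0] < 10:
        raise ValidationError("edge screening needs at least ten subjects")
    r, p = _column_pearson(np.asarray(features, float), np.asarray(adjusted_scores, float))
    sel = p < p_thresh
    return np.flatnonzero(sel & (r > 0)), np.flatnonzero(sel & (r < 0))


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CpmModel:
    """Frozen union-edge prediction model, applied unchanged to new subjects.

    Per sign s in {+, -}: ``edges`` is the union indicator over feature
    columns and ``beta`` the (intercept, slope) of the summed-feature
    regression; ``beta`` is None when the union for that sign is empty.
    """

    n_features: int
    positive_edges: np.ndarray        # int index array into feature columns
    negative_edges: np.ndarray
    beta_pos: tuple[float, float] | None
    beta_neg: tuple[float, float] | None
    covariate_model: CovariateModel
    alpha_step1: float | None
    p_step2: float

    def __post_init__(self):
        if np.intersect1d(self.positive_edges, self.negative_edges).size:
            raise ValidationError("positive and negative edge sets must be disjoint")

    def summed_feature(self, features: np.ndarray, sign: str) -> np.ndarray:
        idx = self.positive_edges if sign == "positive" else self.negative_edges
        if features.shape[1] != self.n_features:
            raise DimensionError(
                f"feature matrix has {features.shape[1]} columns, model expects {self.n_features}"
            )
        return features[:, idx].sum(axis=1)

    def predict(self, features: np.ndarray, sign: str = "positive") -> np.ndarray:
        beta = self.beta_pos if sign == "positive" else self.beta_neg
        if beta is None:
            raise ValidationError(f"{sign} model unavailable (empty edge union)")
        b0, b1 = beta
        return b0 + b1 * self.summed_feature(features, sign)


@dataclasses.dataclass
class PredictionResult:
    """Predicted vs adjusted-observed scores with association statistics."""

    predicted: np.ndarray
    observed: np.ndarray
    r: float
    p_parametric: float
    n_edges_pos: int
    n_edges_neg: int
    p_permutation: float | None = None


def _fit_simple(y: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    if np.ptp(s) == 0:
        return float(y.mean()), 0.0
    sm, ym = s.mean(), y.mean()
    b1 = float(((s - sm) @ (y - ym)) / ((s - sm) @ (s - sm)))
    return float(ym - b1 * sm), b1


def _corr_result(predicted: np.ndarray, observed: np.ndarray,
                 n_pos: int, n_neg: int) -> PredictionResult:
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(predicted, observed)
    return PredictionResult(predicted=predicted, observed=observed, r=float(r),
                            p_parametric=float(p), n_edges_pos=n_pos, n_edges_neg=n_neg)


# ---------------------------------------------------------------------------
# LOOCV, union map, out-of-sample application
# ---------------------------------------------------------------------------

def _nonconstant_covariates(behavior: pd.DataFrame,
                            columns: Sequence[str] = ("age", "sex")) -> tuple[str, ...]:
    kept = []
    for c in columns:
        vals = encode_sex(behavior[c]) if c == "sex" else behavior[c].to_numpy(float)
        if np.ptp(vals) > 0:
            kept.append(c)
    return tuple(kept)


def _loocv_core(features: np.ndarray, y_raw: np.ndarray, cov_design: np.ndarray,
                p_step2: float):
    """Numpy-only fold loop shared by :func:`loocv` and the permutation path.

    Each fold fits the covariate regression, screens edges and fits the
    per-sign summed-feature regressions on the K-1 training rows; the holdout
    row is adjusted and predicted with those frozen fold coefficients.
    """
    K = features.shape[0]
    pred = {"positive": np.empty(K), "negative": np.empty(K)}
    observed = np.empty(K)
    fold_sets: list[dict[str, np.ndarray]] = []
    n_empty = {"positive": 0, "negative": 0}
    idx_all = np.arange(K)
    for k in range(K):
        tr = idx_all != k
        Xk, yk = cov_design[tr], y_raw[tr]
        beta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ beta
        observed[k] = y_raw[k] - cov_design[k] @ beta
        r, p = _column_pearson(features[tr], resid)
        sel = p < p_step2
        pos = np.flatnonzero(sel & (r > 0))
        neg = np.flatnonzero(sel & (r < 0))
        fold_sets.append({"positive": pos, "negative": neg})
        for sign, idx in (("positive", pos), ("negative", neg)):
            if idx.size == 0:
                pred[sign][k] = resid.mean()
                n_empty[sign] += 1
                continue
            s_train = features[tr][:, idx].sum(axis=1)
            b0, b1 = _fit_simple(resid, s_train)
            pred[sign][k] = b0 + b1 * features[k, idx].sum()
    return pred, observed, fold_sets, n_empty


def loocv(features: np.ndarray, behavior: pd.DataFrame, p_step2: float = 0.005
          ) -> dict:
    """Leave-one-subject-out predictions with per-fold edge selection.

    Every fold residualizes scores, screens edges and fits the per-sign
    regressions on the K-1 training subjects only; the holdout contributes
    nothing to its own prediction path.  A fold selecting no edges of a sign
    predicts that fold's training mean (counted in ``n_empty``).
    """
    features = np.asarray(features, dtype=float)
    K = features.shape[0]
    if K < 20:
        raise ValidationError("LOOCV needs at least 20 subjects")
    if len(behavior) != K:
        raise DimensionError("behavior table does not match feature rows")
    kept = _nonconstant_covariates(behavior)
    design = _covariate_design(behavior, kept)
    y_raw = behavior["score"].to_numpy(float)
    pred, observed, fold_sets, n_empty = _loocv_core(features, y_raw, design, p_step2)
    out = {"fold_sets": fold_sets, "observed": observed, "n_empty": n_empty}
    n_pos = max(len(fs["positive"]) for fs in fold_sets)
    n_neg = max(len(fs["negative"]) for fs in fold_sets)
    for sign in ("positive", "negative"):
        out[sign] = _corr_result(pred[sign], observed, n_pos=n_pos, n_neg=n_neg)
    return out


def union_weight_map(fold_sets: Sequence[dict[str, np.ndarray]], features: np.ndarray,
                     behavior: pd.DataFrame, p_step2: float = 0.005,
                     alpha_step1: float | None = None) -> CpmModel:
    """Union of fold-wise edge sets, sign conflicts resolved by full-sample r.

    The per-sign betas and the covariate model are refit once on the full
    training sample; the result is the frozen weight map applied to unseen
    subjects.
    """
    features = np.asarray(features, dtype=float)
    pos_union = set()
    neg_union = set()
    for fs in fold_sets:
        pos_union.update(fs["positive"].tolist())
        neg_union.update(fs["negative"].tolist())
    resid, cov_model = residualize_scores(behavior)
    conflicts = pos_union & neg_union
    if conflicts:
        r_full, _ = _column_pearson(features, resid)
        pos_union -= {e for e in conflicts if r_full[e] < 0}
        neg_union -= {e for e in conflicts if r_full[e] >= 0}
    pos = np.array(sorted(pos_union), dtype=int)
    neg = np.array(sorted(neg_union), dtype=int)
    betas = {}
    for sign, idx in (("positive", pos), ("negative", neg)):
        if idx.size == 0:
            betas[sign] = None
            continue
        s = features[:, idx].sum(axis=1)
        betas[sign] = _fit_simple(resid, s)
    return CpmModel(
        n_features=features.shape[1], positive_edges=pos, negative_edges=neg,
        beta_pos=betas["positive"], beta_neg=betas["negative"],
        covariate_model=cov_model, alpha_step1=alpha_step1, p_step2=p_step2,
    )


def predict_oos(model: CpmModel, features_test: np.ndarray,
                behavior_test: pd.DataFrame, sign: str = "positive"
                ) -> PredictionResult:
    """Apply the frozen model to held-out subjects; no refitting anywhere."""
    features_test = np.asarray(features_test, dtype=float)
    predicted = model.predict(features_test, sign=sign)
    observed = model.covariate_model.adjust(
        behavior_test["score"].to_numpy(float), behavior_test
    )
    return _corr_result(predicted, observed,
                        n_pos=len(model.positive_edges), n_neg=len(model.negative_edges))


def permutation_test(eval_fn: Callable[[np.ndarray], float], scores: np.ndarray,
                     observed_r: float, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for a prediction statistic.

    ``eval_fn`` reruns the full fitting procedure on a permuted score vector
    and returns its r; the p-value uses the add-one estimator
    (1 + #{perm r >= observed r}) / (n_perm + 1), never exactly zero.
    """
    if n_perm < 100:
        raise ValidationError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    count = 0
    for _ in range(n_perm):
        r = eval_fn(rng.permutation(scores))
        if r >= observed_r:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# feature extraction from flow stacks
# ---------------------------------------------------------------------------

def edge_features(stack: GroupFlowStack, mask: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x edges matrix of F-values over the masked (selected) edges.

    Returns the feature matrix and an [E, 2] array of 0-based (source,
    target) indices aligned with the feature columns.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (stack.n_nodes, stack.n_nodes):
        raise DimensionError("mask does not match stack dimensions")
    idx = np.argwhere(mask)
    return stack.f_stack[:, mask], idx


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class CpmRegressor(RegressorMixin, BaseEstimator):
    """LOOCV-screened summed-edge regressor over a subjects x edges matrix.

    Parameters
    ----------
    p_step2 : float
        Strict per-edge correlation threshold used inside every fold.
    sign : {"positive", "negative"}
        Which single-sign model :meth:`predict` applies.
    alpha_step1 : float or None
        Recorded provenance of the upstream average-p mask (not applied here;
        the feature matrix is assumed already restricted to that mask).

    Attributes
    ----------
    model_ : CpmModel
        Frozen union weight map refit on the full training sample.
    loocv_ : dict
        Per-sign LOOCV :class:`PredictionResult` plus fold edge sets.
    """

    def __init__(self, p_step2: float = 0.005, sign: str = "positive",
                 alpha_step1: float | None = None):
        self.p_step2 = p_step2
        self.sign = sign
        self.alpha_step1 = alpha_step1

    def fit(self, X, y=None, behavior: pd.DataFrame | None = None):
        """Run LOOCV on the training sample and freeze the union model.

        ``behavior`` supplies score/age/sex; if omitted, a minimal table is
        built from ``y`` with no covariates beyond the intercept.
        """
        X = np.asarray(X, dtype=float)
        if behavior is None:
            if y is None:
                raise ValidationError("either y or a behavior table is required")
            behavior = pd.DataFrame(
                {"subject_id": [f"s{i}" for i in range(len(y))],
                 "score": np.asarray(y, float),
                 "age": np.zeros(len(y)), "sex": ["female"] * len(y),
                 "head_motion": np.zeros(len(y))}
            )
        self.loocv_ = loocv(X, behavior, p_step2=self.p_step2)
        self.model_ = union_weight_map(self.loocv_["fold_sets"], X, behavior,
                                       p_step2=self.p_step2, alpha_step1=self.alpha_step1)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, float), sign=self.sign)

    def evaluate(self, X, behavior: pd.DataFrame, sign: str | None = None
                 ) -> PredictionResult:
        """Out-of-sample evaluation against covariate-adjusted observed scores."""
        check_is_fitted(self, "model_")
        return predict_oos(self.model_, X, behavior, sign=sign or self.sign)
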