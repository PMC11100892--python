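"""Parsimonious diagnostic classifier for occult sarcoidosis.

The modeling task: predict whether a granuloma-remote, inflammation(-)
parenchymal segment comes from a sarcoid or a control heart, using only
markers suitable for quantitative multiplex immunofluorescence, and end with
a panel small enough (<= 7 markers) to transfer to an IF assay.

Pipeline: candidate curation (consistent direction vs every control
subgroup) -> stratified train/test split -> L1-penalized logistic
regression for feature screening -> backward stepwise elimination driven by
leave-one-out cross-validated accuracy -> final logistic model with a
classification cut-point chosen by the Liu criterion (maximizing
sensitivity x specificity) -> held-out evaluation.

Scaling statistics, feature selection and the cut-point are all derived
from the training side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import CONTROL_CLASSES, CS_CLASSES, NormalizedMatrix, SegmentAnnotation
from .errors import AnalysisError
from .panel import ProbePanel


@dataclass
class ClassifierConfig:
    """Settings for panel derivation. ``lasso_penalty`` is the L1 weight
    lambda in ``(1/n) sum loss + lambda * ||beta||_1``."""

    seed: int
    candidate_features: list[str] | None = None
    lasso_penalty: float = 0.001
    max_features: int = 7
    train_fraction: float = 0.67
    split_mode: str = "roi_level"  # or "donor_grouped"
    cv_folds_lasso: int = 4
    stratum: str = "full_roi"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise AnalysisError("train_fraction must be in (0, 1)")
        if self.max_features < 1:
            raise AnalysisError("max_features must be >= 1")
        if self.lasso_penalty <= 0:
            raise AnalysisError("lasso_penalty must be > 0")
        if self.split_mode not in ("roi_level", "donor_grouped"):
            raise AnalysisError("split_mode must be 'roi_level' or 'donor_grouped'")


@dataclass
class LogisticModel:
    """Frozen logistic model with its training-side scaler."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    intercept: float

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.mean) / self.sd
        return 1.0 / (1.0 + np.exp(-(Z @ self.coef + self.intercept)))

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.coef, index=self.features)


@dataclass
class ClassifierReport:
    """Everything the derivation produced, training and held-out metrics included."""

    model: LogisticModel
    cutpoint: float
    candidates: list[str]
    lasso_features: list[str]
    stepwise_trace: pd.DataFrame
    train_metrics: dict
    test_metrics: dict
    perigranuloma_metrics: dict
    split: dict = field(default_factory=dict)

    def coefficient_table(self) -> pd.DataFrame:
        rows = [{"feature": "(intercept)", "coefficient": self.model.intercept}]
        rows += [{"feature": f, "coefficient": c}
                 for f, c in self.model.coefficients.items()]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "selected_features": self.model.features,
            "coefficients": {f: float(c) for f, c in self.model.coefficients.items()},
            "intercept": float(self.model.intercept),
            "liu_cutpoint": float(self.cutpoint),
            "n_candidates": len(self.candidates),
            "train_metrics": self.train_metrics,
            "test_metrics": self.test_metrics,
            "perigranuloma_metrics": self.perigranuloma_metrics,
            "split": self.split,
        }


# ---------------------------------------------------------------------------
# candidate curation and splitting
# ---------------------------------------------------------------------------

def _modeling_segments(ann: SegmentAnnotation, stratum: str) -> tuple[pd.Index, pd.Series]:
    t = ann.table
    cs = t["cohort_class"].isin(CS_CLASSES)
    remote = t["region_class"] == "granuloma_remote"
    in_stratum = t["compartment"] == stratum
    mask = remote & in_stratum & (cs & ~t["infiltrate"] | ~cs)
    ids = t.index[mask]
    labels = cs[mask].astype(int)
    return ids, labels


def prefilter_candidates(matrix: NormalizedMatrix, ann: SegmentAnnotation,
                         panel: ProbePanel, stratum: str = "full_roi") -> list[str]:
    """IF-suitable probes consistently shifted versus every control subgroup.

    A probe qualifies if the sign of (mean in bland sarcoid segments - mean
    in subgroup segments) agrees across all three control subgroups; a
    deliberately heterogeneous control population makes this a strong
    specificity filter. Deterministic; an empty subgroup is an error naming
    it.
    """
    ids, labels = _modeling_segments(ann, stratum)
    t = ann.table.loc[ids]
    cs_ids = ids[labels.to_numpy() == 1]
    if len(cs_ids) == 0:
        raise AnalysisError("no bland granuloma-remote sarcoid segments available")
    sub_ids = {}
    for sub in CONTROL_CLASSES:
        sub_ids[sub] = t.index[t["cohort_class"] == sub]
        if len(sub_ids[sub]) == 0:
            raise AnalysisError(f"control subgroup {sub!r} has no segments")
    cs_mean = matrix.values[list(cs_ids)].mean(axis=1)
    kept = []
    suitable = set(panel.if_suitable)
    for probe in matrix.probes:
        if probe not in suitable:
            continue
        diffs = [cs_mean[probe] - matrix.values.loc[probe, list(sub_ids[s])].mean()
                 for s in CONTROL_CLASSES]
        if all(d > 0 for d in diffs) or all(d < 0 for d in diffs):
            kept.append(probe)
    return kept


def split_train_test(labels: pd.Series, config: ClassifierConfig,
                     donors: pd.Series | None = None) -> tuple[list[str], list[str]]:
    """Stratified, seeded train/test split of segment ids.

    ``roi_level`` splits segments directly within each class (one donor may
    straddle both sides); ``donor_grouped`` keeps each donor's segments on
    one side, filling the training side donor by donor per class.
    """
    rng = np.random.default_rng(config.seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(labels.unique()):
        ids = np.asarray(labels.index[labels == cls])
        if len(ids) < 2:
            raise AnalysisError(f"class {cls} has fewer than 2 segments")
        if config.split_mode == "roi_level":
            perm = rng.permutation(len(ids))
            n_train = int(round(config.train_fraction * len(ids)))
            n_train = min(max(n_train, 1), len(ids) - 1)
            train += list(ids[perm[:n_train]])
            test += list(ids[perm[n_train:]])
        else:
            if donors is None:
                raise AnalysisError("donor_grouped split requires donor ids")
            cls_donors = donors.loc[ids]
            uniq = rng.permutation(cls_donors.unique())
            target = config.train_fraction * len(ids)
            picked: list[str] = []
            n_acc = 0
            for d in uniq:
                d_ids = list(cls_donors.index[cls_donors == d])
                if n_acc < target:
                    picked += d_ids
                    n_acc += len(d_ids)
            if n_acc == len(ids):  # keep at least one donor on the test side
                last = uniq[-1]
                drop = set(cls_donors.index[cls_donors == last])
                picked = [i for i in picked if i not in drop]
            train += picked
            test += [i for i in ids if i not in set(picked)]
    for side, name in ((train, "train"), (test, "test")):
        side_classes = set(labels.loc[side])
        if side_classes != set(labels.unique()):
            raise AnalysisError(f"class missing from {name} side after split")
    return train, test


# ---------------------------------------------------------------------------
# fitting primitives
# ---------------------------------------------------------------------------

_RIDGE = 1e-6  # tiny L2 stabilizer: keeps IRLS finite under perfect separation


def _irls_logistic(Z: np.ndarray, y: np.ndarray, ridge: float = _RIDGE,
                   max_iter: int = 50, tol: float = 1e-10, w0: np.ndarray | None = None):
    """Newton/IRLS logistic regression returning (coef, intercept)."""
    n, k = Z.shape
    X1 = np.column_stack([np.ones(n), Z])
    w = np.zeros(k + 1) if w0 is None else w0.copy()
    pen = ridge * np.eye(k + 1)
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(X1 @ w, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p) + 1e-12
        grad = X1.T @ (y - p) - pen @ w
        H = (X1 * W[:, None]).T @ X1 + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        w = w + step
        if np.abs(step).max() < tol:
            break
    return w[1:], w[0]


def _loocv_scores(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Out-of-fold predicted probabilities under leave-one-out CV.

    Each fold's Newton solve warm-starts from the full-data fit (exact —
    Newton still iterates to the same tolerance, just from a close point).
    """
    n = Z.shape[0]
    out = np.empty(n)
    idx = np.arange(n)
    coef_full, b0_full = _irls_logistic(Z, y)
    w_full = np.concatenate([[b0_full], coef_full])
    for i in range(n):
        mask = idx != i
        coef, b0 = _irls_logistic(Z[mask], y[mask], w0=w_full)
        eta = np.clip(Z[i] @ coef + b0, -30, 30)
        out[i] = 1.0 / (1.0 + np.exp(-eta))
    return out


def _auroc(scores: np.ndarray, y: np.ndarray) -> float:
    if len(set(y)) < 2:
        return np.nan
    return float(roc_auc_score(y, scores))


def lasso_select(X: pd.DataFrame, y, lasso_penalty: float = 0.001,
                 cv_folds: int = 4, seed: int = 0) -> tuple[list[str], dict]:
    """L1-penalized logistic screening; returns (features, cv_report).

    ``X`` must already be z-scored on the training data. The penalty maps
    to scikit-learn's ``C = 1 / (n * lambda)``. The folds do not choose the
    penalty — they only report cross-validated performance at it.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    C = 1.0 / (n * lasso_penalty)
    model = LogisticRegression(penalty="l1", C=C, solver="saga", max_iter=20000,
                               tol=1e-8, random_state=0)
    model.fit(X.to_numpy(dtype=float), y)
    coefs = model.coef_[0]
    selected = [f for f, c in zip(X.columns, coefs) if c != 0.0]
    if not selected:
        raise AnalysisError(
            f"no feature survives the L1 penalty {lasso_penalty}; try a smaller penalty")

    folds = min(cv_folds, np.bincount(y).min())
    cv_acc = []
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y):
            m = LogisticRegression(penalty="l1", C=C, solver="saga", max_iter=20000,
                                   tol=1e-8, random_state=0)
            m.fit(X.to_numpy(dtype=float)[tr], y[tr])
            cv_acc.append(float((m.predict(X.to_numpy(dtype=float)[te]) == y[te]).mean()))
    report = {"cv_accuracy": float(np.mean(cv_acc)) if cv_acc else np.nan,
              "n_folds": folds, "n_selected": len(selected)}
    return selected, report


def backward_stepwise_loocv(X: pd.DataFrame, y, features: list[str],
                            max_features: int = 7):
    """Backward stepwise elimination scored by LOOCV accuracy.

    At each step the feature whose removal yields the highest LOOCV
    accuracy is dropped (ties break by higher LOOCV AUROC, then by removing
    the alphabetically first name). Elimination is forced while more than
    ``max_features`` remain; below that it continues only while a removal
    strictly improves LOOCV accuracy — on ties the larger panel is kept,
    since with redundant informative markers an indifferent tie-chain would
    otherwise collapse the panel to a minimal subset. Returns
    ``(final features, fitted LogisticModel on X, trace)``.
    """
    y = np.asarray(y, dtype=int)
    current = list(features)
    if not current:
        raise AnalysisError("backward stepwise needs at least one feature")

    def loocv_metrics(feats: list[str]) -> tuple[float, float]:
        scores = _loocv_scores(X[feats].to_numpy(dtype=float), y)
        return float(((scores >= 0.5).astype(int) == y).mean()), _auroc(scores, y)

    acc, auc = loocv_metrics(current)
    trace: list[dict] = []  # one row per removal
    step = 0
    while len(current) > 1:
        options = []
        for f in sorted(current):
            feats = [g for g in current if g != f]
            a, u = loocv_metrics(feats)
            options.append((a, u if np.isfinite(u) else -1.0, f))
        best_a = max(o[0] for o in options)
        tied = [o for o in options if o[0] == best_a]
        best_u = max(o[1] for o in tied)
        removed = sorted(o[2] for o in tied if o[1] == best_u)[0]
        if len(current) <= max_features and best_a <= acc:
            break
        current = [g for g in current if g != removed]
        acc, auc = best_a, dict((o[2], o[1]) for o in options)[removed]
        step += 1
        trace.append({"step": step, "removed": removed, "n_features": len(current),
                      "loocv_accuracy": acc, "loocv_auroc": auc})
        if len(current) == 1:
            break

    coef, b0 = _irls_logistic(X[current].to_numpy(dtype=float), y)
    model = LogisticModel(features=current, mean=np.zeros(len(current)),
                          sd=np.ones(len(current)), coef=coef, intercept=b0)
    trace_df = pd.DataFrame(trace, columns=["step", "removed", "n_features",
                                            "loocv_accuracy", "loocv_auroc"])
    return current, model, trace_df


def liu_cutpoint(scores, labels) -> float:
    """Threshold maximizing sensitivity x specificity (Liu criterion).

    Candidates are the midpoints between adjacent distinct scores (a single
    distinct score is its own candidate); a score >= threshold predicts the
    positive class; ties resolve to the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise AnalysisError("Liu cut-point needs both classes present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    pos, neg = labels == 1, labels == 0
    best_thr, best_prod = None, -1.0
    for thr in cands:
        pred = scores >= thr
        se = pred[pos].mean()
        sp = (~pred[neg]).mean()
        prod = se * sp
        if prod > best_prod + 1e-15:
            best_prod, best_thr = prod, float(thr)
    return best_thr


def _confusion_metrics(pred: np.ndarray, y: np.ndarray) -> dict:
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())

    def safe(a, b):  # 0/0 -> 0.0 by convention (degenerate confusion cells)
        return a / b if b else 0.0

    return {"accuracy": safe(tp + tn, len(y)), "sensitivity": safe(tp, tp + fn),
            "specificity": safe(tn, tn + fp), "ppv": safe(tp, tp + fp),
            "npv": safe(tn, tn + fn), "tp": tp, "tn": tn, "fp": fp, "fn": fn}


def evaluate(model: LogisticModel, cutpoint: float, X_test: pd.DataFrame, y_test) -> dict:
    """All six held-out metrics at the frozen cut-point (AUROC is rank-based)."""
    y = np.asarray(y_test, dtype=int)
    if len(y) == 0:
        raise AnalysisError("empty test set")
    scores = model.predict_proba(X_test)
    metrics = _confusion_metrics(scores >= cutpoint, y)
    metrics["auroc"] = _auroc(scores, y)
    metrics["n"] = len(y)
    return metrics


def evaluate_perigranuloma(model: LogisticModel, cutpoint: float,
                           matrix: NormalizedMatrix, ann: SegmentAnnotation,
                           stratum: str = "full_roi") -> dict:
    """Apply the frozen model to inflammation(-) peri-granuloma sarcoid segments.

    All such segments are truly sarcoid, so the report is the fraction
    called sarcoid (accuracy) plus counts; an empty stratum is skipped with
    a notice in the returned record.
    """
    t = ann.table
    cs = t["cohort_class"].isin(CS_CLASSES)
    mask = cs & (t["region_class"] == "peri_granuloma") & ~t["infiltrate"] \
        & (t["compartment"] == stratum)
    ids = [s for s in t.index[mask] if s in matrix.values.columns]
    if not ids:
        return {"evaluated": False, "note": "no inflammation(-) peri-granuloma segments"}
    X = matrix.values.loc[model.features, ids].T
    scores = model.predict_proba(X)
    called = scores >= cutpoint
    return {"evaluated": True, "n": len(ids), "n_correct": int(called.sum()),
            "accuracy": float(called.mean())}


# ---------------------------------------------------------------------------
# end-to-end derivation
# ---------------------------------------------------------------------------

def train_classifier(matrix: NormalizedMatrix, ann: SegmentAnnotation,
                     panel: ProbePanel, config: ClassifierConfig) -> ClassifierReport:
    """Derive and evaluate the parsimonious diagnostic panel."""
    ids, labels = _modeling_segments(ann, config.stratum)
    ids = pd.Index([s for s in ids if s in matrix.values.columns])
    labels = labels.loc[ids]
    candidates = config.candidate_features or prefilter_candidates(
        matrix, ann, panel, stratum=config.stratum)
    if not candidates:
        raise AnalysisError("no candidate features survive the consistency prefilter")

    donors = ann.table.loc[ids, "donor_id"]
    train_ids, test_ids = split_train_test(labels, config, donors=donors)
    X_all = matrix.values.loc[candidates, list(ids)].T  # segments x features
    y_train = labels.loc[train_ids].to_numpy()
    y_test = labels.loc[test_ids].to_numpy()

    # scaler fit on the training side only
    mean = X_all.loc[train_ids].mean(axis=0).to_numpy()
    sd = X_all.loc[train_ids].std(axis=0, ddof=0).to_numpy()
    sd = np.where(sd > 0, sd, 1.0)
    Z_train = (X_all.loc[train_ids] - mean) / sd

    lasso_feats, lasso_report = lasso_select(Z_train, y_train,
                                             lasso_penalty=config.lasso_penalty,
                                             cv_folds=config.cv_folds_lasso,
                                             seed=config.seed)
    final_feats, z_model, trace = backward_stepwise_loocv(
        Z_train, y_train, lasso_feats, max_features=config.max_features)

    # fold the training scaler into the frozen model (raw-scale inputs)
    pos = [candidates.index(f) for f in final_feats]
    model = LogisticModel(features=final_feats, mean=mean[pos], sd=sd[pos],
                          coef=z_model.coef, intercept=z_model.intercept)

    loocv_scores = _loocv_scores(Z_train[final_feats].to_numpy(dtype=float), y_train)
    cutpoint = liu_cutpoint(loocv_scores, y_train)
    train_metrics = _confusion_metrics(loocv_scores >= cutpoint, y_train)
    train_metrics["auroc"] = _auroc(loocv_scores, y_train)
    train_metrics["n"] = len(y_train)
    train_metrics.update({f"lasso_{k}": v for k, v in lasso_report.items()})

    test_metrics = evaluate(model, cutpoint, X_all.loc[test_ids], y_test)
    peri = evaluate_perigranuloma(model, cutpoint, matrix, ann, stratum=config.stratum)

    return ClassifierReport(
        model=model, cutpoint=cutpoint, candidates=list(candidates),
        lasso_features=lasso_feats, stepwise_trace=trace,
        train_metrics=train_metrics, test_metrics=test_metrics,
        perigranuloma_metrics=peri,
        split={"mode": config.split_mode, "n_train": len(train_ids),
               "n_test": len(test_ids), "seed": config.seed},
    )
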