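"""Diagnostic panel derivation: oracles for each step and leakage guards."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import sarcospace as ss
from sarcospace.classifier import (
    ClassifierConfig,
    LogisticModel,
    _irls_logistic,
    backward_stepwise_loocv,
    evaluate,
    lasso_select,
    liu_cutpoint,
    prefilter_candidates,
    split_train_test,
)
from sarcospace.errors import AnalysisError
from sarcospace.simulate import EffectSpec


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------

def _prefilter_dataset(seed=0, n_consistent=20, n_inconsistent=20):
    """Bland remote segments: CS + three control subgroups; the consistent
    probes are shifted the same way vs all subgroups, inconsistent ones flip
    sign for one subgroup."""
    rng = np.random.default_rng(seed)
    groups = [("cs_biopsy", 30), ("control_nicm", 10), ("control_nf", 10), ("control_txp", 10)]
    probes = [f"c{i}" for i in range(n_consistent)] + [f"x{i}" for i in range(n_inconsistent)]
    rows, cols = [], {}
    k = 0
    for cls, n in groups:
        for _ in range(n):
            aoi = f"S{k}"
            rows.append({"aoi_id": aoi, "roi_id": f"R{k}", "donor_id": f"D{k}",
                         "cohort_class": cls, "region_class": "granuloma_remote",
                         "compartment": "full_roi", "infiltrate": False,
                         "nuclei_count": 100, "surface_area": 5000.0,
                         "binding_density": 1.0, "background_signal": 1.0})
            v = np.zeros(len(probes))
            if cls.startswith("cs"):
                v[:n_consistent] = 2.0          # consistently higher in CS
                v[n_consistent:] = 2.0
            elif cls == "control_nf":
                v[n_consistent:] = 5.0          # flips the sign for one subgroup
            cols[aoi] = v + rng.normal(0, 0.01, len(probes))
            k += 1
    panel = ss.ProbePanel(pd.DataFrame({
        "probe_id": probes, "category": "t",
        "myocyte_expressed": False, "if_suitable": True,
        "contamination_marker": [True] * 8 + [False] * (len(probes) - 8)}))
    mat = ss.NormalizedMatrix(pd.DataFrame(cols, index=probes))
    return mat, ss.SegmentAnnotation(pd.DataFrame(rows)), panel


def test_prefilter_keeps_exactly_the_consistent_probes():
    mat, ann, panel = _prefilter_dataset()
    kept = prefilter_candidates(mat, ann, panel)
    assert set(kept) == {f"c{i}" for i in range(20)}


def test_prefilter_requires_all_control_subgroups():
    mat, ann, panel = _prefilter_dataset()
    keep = ann.table.index[ann.table["cohort_class"] != "control_txp"]
    with pytest.raises(AnalysisError, match="control_txp"):
        prefilter_candidates(mat.subset_segments(keep), ann.subset(keep), panel)


def test_prefilter_excludes_not_if_suitable():
    mat, ann, panel = _prefilter_dataset()
    panel.table.loc["c0", "if_suitable"] = False
    kept = prefilter_candidates(mat, ann, panel)
    assert "c0" not in kept


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def _labels(n1, n0):
    idx = [f"S{i}" for i in range(n1 + n0)]
    return pd.Series([1] * n1 + [0] * n0, index=idx)


def test_split_154_segments_at_0_67_gives_103_51():
    labels = _labels(88, 66)
    train, test = split_train_test(labels, ClassifierConfig(seed=0))
    assert len(train) == 103 and len(test) == 51


def test_split_reproducible_and_stratified():
    labels = _labels(40, 20)
    cfg = ClassifierConfig(seed=5)
    t1 = split_train_test(labels, cfg)
    t2 = split_train_test(labels, cfg)
    assert t1 == t2
    train, test = t1
    assert 0 < labels.loc[train].mean() < 1 and 0 < labels.loc[test].mean() < 1


def test_donor_grouped_split_keeps_donors_together():
    labels = _labels(30, 30)
    donors = pd.Series([f"D{i // 5}" for i in range(60)], index=labels.index)
    cfg = ClassifierConfig(seed=2, split_mode="donor_grouped")
    train, test = split_train_test(labels, cfg, donors=donors)
    assert set(donors.loc[train]) & set(donors.loc[test]) == set()


# ---------------------------------------------------------------------------
# lasso
# ---------------------------------------------------------------------------

def _screening_data(seed=0, n=80, k=10):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"f{i}" for i in range(k)])
    y = (X["f0"] + 0.2 * rng.normal(size=n) > 0).astype(int).to_numpy()
    Xz = (X - X.mean()) / X.std(ddof=0)
    return Xz, y


def test_lasso_selects_the_separating_feature():
    Xz, y = _screening_data()
    feats, _ = lasso_select(Xz, y, lasso_penalty=0.05)
    assert "f0" in feats and len(feats) <= 4


def test_lasso_huge_penalty_errors():
    Xz, y = _screening_data()
    with pytest.raises(AnalysisError, match="penalty"):
        lasso_select(Xz, y, lasso_penalty=100.0)


def test_lasso_coefficients_match_proximal_gradient_oracle():
    """Independent check: ISTA (proximal gradient) on the same objective
    (1/n) sum log-loss + lambda * ||w||_1 reaches the same solution."""
    Xz, y = _screening_data(seed=3, n=60, k=5)
    lam = 0.02
    from sklearn.linear_model import LogisticRegression

    skl = LogisticRegression(penalty="l1", C=1.0 / (len(y) * lam),
                             solver="saga", max_iter=20000, tol=1e-10)
    skl.fit(Xz.to_numpy(), y)

    # ISTA oracle
    X1 = Xz.to_numpy()
    n = len(y)
    w = np.zeros(X1.shape[1])
    b = 0.0
    step = 0.5
    for _ in range(20000):
        eta = X1 @ w + b
        p = 1 / (1 + np.exp(-eta))
        gw = X1.T @ (p - y) / n
        gb = (p - y).mean()
        w_new = w - step * gw
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        b_new = b - step * gb
        if max(np.abs(w_new - w).max(), abs(b_new - b)) < 1e-12:
            w, b = w_new, b_new
            break
        w, b = w_new, b_new
    np.testing.assert_allclose(skl.coef_[0], w, atol=2e-3)
    assert {f for f, c in zip(Xz.columns, w) if c != 0} == \
           {f for f, c in zip(Xz.columns, skl.coef_[0]) if c != 0}


# ---------------------------------------------------------------------------
# stepwise
# ---------------------------------------------------------------------------

def test_stepwise_single_feature_unchanged():
    Xz, y = _screening_data(seed=4, k=3)
    final, model, trace = backward_stepwise_loocv(Xz, y, ["f0"], max_features=7)
    assert final == ["f0"] and len(trace) == 0


def test_stepwise_trace_length_matches_removals():
    Xz, y = _screening_data(seed=5, k=8)
    feats = list(Xz.columns)
    final, _, trace = backward_stepwise_loocv(Xz, y, feats, max_features=3)
    assert len(trace) == len(feats) - len(final)
    assert len(final) <= 3


def test_stepwise_retains_informative_features():
    """3 informative among 10: at least 2 survive in most replicates."""
    wins = 0
    n_reps = 20
    for seed in range(n_reps):
        rng = np.random.default_rng(seed)
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        signal = X["f0"] + X["f1"] - X["f2"]
        y = (signal + 0.5 * rng.normal(size=n) > 0).astype(int).to_numpy()
        Xz = (X - X.mean()) / X.std(ddof=0)
        final, _, _ = backward_stepwise_loocv(Xz, y, list(X.columns), max_features=4)
        wins += len({"f0", "f1", "f2"} & set(final)) >= 2
    assert wins >= 0.9 * n_reps


# ---------------------------------------------------------------------------
# Liu cut-point and evaluation
# ---------------------------------------------------------------------------

def brute_force_liu(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    cands = [(uniq[0])] if len(uniq) == 1 else list((uniq[:-1] + uniq[1:]) / 2)
    best, best_thr = -1, None
    for thr in cands:
        pred = scores >= thr
        se = pred[labels == 1].mean()
        sp = (~pred)[labels == 0].mean()
        if se * sp > best + 1e-15:
            best, best_thr = se * sp, thr
    return best_thr


def test_liu_perfect_separation_returns_midpoint():
    thr = liu_cutpoint([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert thr == pytest.approx(0.5)


def test_liu_matches_exhaustive_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(4, 200)
        scores = rng.uniform(size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert liu_cutpoint(scores, labels) == pytest.approx(brute_force_liu(scores, labels))


def test_liu_identical_scores_boundary():
    assert liu_cutpoint([0.5, 0.5, 0.5], [0, 1, 1]) == 0.5


def test_liu_single_class_errors():
    with pytest.raises(AnalysisError):
        liu_cutpoint([0.2, 0.8], [1, 1])


def _toy_model(features):
    return LogisticModel(features=features, mean=np.zeros(len(features)),
                         sd=np.ones(len(features)), coef=np.ones(len(features)),
                         intercept=0.0)


def test_evaluate_perfect_predictions():
    model = _toy_model(["f"])
    X = pd.DataFrame({"f": [-5.0, -4.0, 4.0, 5.0]})
    m = evaluate(model, 0.5, X, [0, 0, 1, 1])
    for key in ("accuracy", "auroc", "sensitivity", "specificity", "ppv", "npv"):
        assert m[key] == 1.0


def test_auroc_equals_mann_whitney_u_statistic():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(1)
    model = _toy_model(["f"])
    X = pd.DataFrame({"f": rng.normal(size=100)})
    y = rng.integers(0, 2, 100)
    m = evaluate(model, 0.5, X, y)
    scores = model.predict_proba(X)
    u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
    assert m["auroc"] == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))


def test_irls_matches_sklearn_unpenalized():
    from sklearn.linear_model import LogisticRegression

    Xz, y = _screening_data(seed=7, n=100, k=3)
    # moderate noise so the optimum is interior (no separation)
    rng = np.random.default_rng(7)
    y = np.where(rng.uniform(size=len(y)) < 0.15, 1 - y, y)
    coef, b0 = _irls_logistic(Xz.to_numpy(), y)
    skl = LogisticRegression(penalty=None, max_iter=2000)
    skl.fit(Xz.to_numpy(), y)
    np.testing.assert_allclose(coef, skl.coef_[0], atol=1e-3)
    assert b0 == pytest.approx(skl.intercept_[0], abs=1e-3)


# ---------------------------------------------------------------------------
# end to end and leakage
# ---------------------------------------------------------------------------

def _classifier_cohort(seed, null=False):
    cfg = ss.default_study_config(seed=seed)
    if null:
        cfg = replace(cfg, effects=EffectSpec(
            compartment_offsets=cfg.effects.compartment_offsets))
    return ss.simulate_cohort(cfg)


def test_train_classifier_end_to_end():
    m, ann, panel, _ = _classifier_cohort(seed=42)
    report = ss.train_classifier(ss.quantile_normalize(m), ann, panel,
                                 ClassifierConfig(seed=0))
    assert 1 <= len(report.model.features) <= 7
    assert 0 <= report.test_metrics["auroc"] <= 1
    assert report.split["n_train"] + report.split["n_test"] == \
        report.train_metrics["n"] + report.test_metrics["n"]
    assert report.perigranuloma_metrics["evaluated"]


def test_scaler_and_selection_ignore_test_side():
    """Corrupting the held-out segments must not change the fitted model."""
    m, ann, panel, _ = _classifier_cohort(seed=43)
    norm = ss.quantile_normalize(m)
    cfg = ClassifierConfig(seed=1)
    report1 = ss.train_classifier(norm, ann, panel, cfg)

    from sarcospace.classifier import _modeling_segments
    ids, labels = _modeling_segments(ann, "full_roi")
    train_ids, test_ids = split_train_test(labels.loc[ids], cfg,
                                           donors=ann.table.loc[ids, "donor_id"])
    corrupted = norm.values.copy()
    corrupted[test_ids] = corrupted[test_ids] + 37.0
    report2 = ss.train_classifier(ss.NormalizedMatrix(corrupted), ann, panel, cfg)
    assert report1.model.features == report2.model.features
    np.testing.assert_allclose(report1.model.coef, report2.model.coef)
    assert report1.cutpoint == report2.cutpoint


def test_perigranuloma_empty_stratum_not_evaluated():
    m, ann, panel, _ = _classifier_cohort(seed=44)
    norm = ss.quantile_normalize(m)
    keep = ann.table.index[ann.table["region_class"] != "peri_granuloma"]
    report = ss.train_classifier(norm.subset_segments(keep), ann.subset(keep),
                                 panel, ClassifierConfig(seed=0))
    assert report.perigranuloma_metrics["evaluated"] is False
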