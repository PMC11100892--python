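"""QC filtering and normalization: hand-computed oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sarcospace as ss
from sarcospace.errors import AnalysisError
from sarcospace.qc import QCThresholds
from conftest import make_annotation


def _matrix(arr, probes=None, segs=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    segs = segs or [f"S{j}" for j in range(arr.shape[1])]
    return ss.CountMatrix(pd.DataFrame(arr, index=probes, columns=segs))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_all_pass_is_identity():
    m = _matrix(np.ones((3, 4)))
    ann = make_annotation(4)
    out, out_ann, report = ss.filter_segments(m, ann, QCThresholds())
    assert report.n_flagged == 0
    pd.testing.assert_frame_equal(out.values, m.values)


def test_qc_low_nuclei_flagged_with_reason():
    m = _matrix(np.ones((3, 4)))
    ann = make_annotation(4)
    ann.table.loc["S2", "nuclei_count"] = 5
    out, out_ann, report = ss.filter_segments(m, ann, QCThresholds(min_nuclei=20))
    flagged = report.table[~report.table["passed"]]
    assert list(flagged["aoi_id"]) == ["S2"]
    assert flagged.iloc[0]["failed_criteria"] == "nuclei"
    assert "S2" not in out.segments


def test_qc_three_planted_failures_of_distinct_kinds():
    m = _matrix(np.ones((3, 6)))
    ann = make_annotation(6)
    ann.table.loc["S1", "nuclei_count"] = 2
    ann.table.loc["S3", "surface_area"] = 10.0
    ann.table.loc["S5", "binding_density"] = 9.0
    _, _, report = ss.filter_segments(m, ann)
    flagged = report.table[~report.table["passed"]].set_index("aoi_id")
    assert set(flagged.index) == {"S1", "S3", "S5"}
    assert flagged.loc["S1", "failed_criteria"] == "nuclei"
    assert flagged.loc["S3", "failed_criteria"] == "area"
    assert flagged.loc["S5", "failed_criteria"] == "binding_density"
    assert report.counts_per_criterion == {"nuclei": 1, "area": 1,
                                           "binding_density": 1, "background": 0}


def test_qc_idempotent(cohort):
    m, ann, _, _ = cohort
    m1, a1, r1 = ss.filter_segments(m, ann)
    m2, a2, r2 = ss.filter_segments(m1, a1)
    assert r2.n_flagged == 0
    assert m1.segments == m2.segments


def test_qc_removing_everything_errors():
    m = _matrix(np.ones((2, 3)))
    ann = make_annotation(3)
    with pytest.raises(AnalysisError, match="every segment"):
        ss.filter_segments(m, ann, QCThresholds(min_nuclei=10_000))


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _prelog(norm):
    return (2.0 ** norm.values.to_numpy()) - 1.0


def test_quantile_hand_example():
    """Segments [1,2,3] and [4,5,6] both become [2.5, 3.5, 4.5] pre-log."""
    m = _matrix([[1, 4], [2, 5], [3, 6]])
    out = _prelog(ss.quantile_normalize(m))
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out, expected, atol=1e-9)


def test_quantile_identity_on_identical_segments():
    m = _matrix([[3, 3], [1, 1], [7, 7]])
    out = _prelog(ss.quantile_normalize(m))
    np.testing.assert_allclose(out, m.values.to_numpy(), atol=1e-9)


def test_quantile_tie_handling():
    """Tied values receive the mean of the reference values their ranks span."""
    m = _matrix([[1, 10], [1, 20], [5, 30]])
    out = _prelog(ss.quantile_normalize(m))
    ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])  # [5.5, 10.5, 17.5]
    np.testing.assert_allclose(out[:, 1], ref, atol=1e-9)
    np.testing.assert_allclose(out[:2, 0], [(5.5 + 10.5) / 2] * 2, atol=1e-9)
    np.testing.assert_allclose(out[2, 0], 17.5, atol=1e-9)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(2, 6))
def test_quantile_shared_sorted_multiset(seed, p, s):
    """Post-normalization every segment carries one common sorted value vector."""
    rng = np.random.default_rng(seed)
    m = _matrix(rng.integers(0, 50, (p, s)).astype(float))
    out = _prelog(ss.quantile_normalize(m))
    cols = np.sort(out, axis=0)
    # ties may redistribute mass within a column, but sums and untied columns agree
    np.testing.assert_allclose(cols.sum(axis=0), cols.sum(axis=0)[0] * np.ones(s), atol=1e-8)
    untied = [j for j in range(s) if len(np.unique(m.values.to_numpy()[:, j])) == p]
    for j in untied[1:]:
        np.testing.assert_allclose(cols[:, j], cols[:, untied[0]], atol=1e-8)


def test_quantile_single_segment_errors():
    with pytest.raises(AnalysisError):
        ss.quantile_normalize(_matrix([[1.0], [2.0]]))


# ---------------------------------------------------------------------------
# other strategies
# ---------------------------------------------------------------------------

def test_library_size_identity_for_equal_totals():
    m = _matrix([[1, 2], [3, 2]])  # totals equal (4, 4)
    out = (2.0 ** ss.normalize(m, "library_size").values.to_numpy()) - 1.0
    np.testing.assert_allclose(out, m.values.to_numpy(), atol=1e-9)


def test_housekeeping_identity_when_housekeeper_constant():
    m = _matrix([[5, 5], [1, 9]], probes=["hk", "x"])
    out = (2.0 ** ss.normalize(m, "housekeeping", housekeepers=["hk"]).values.to_numpy()) - 1.0
    np.testing.assert_allclose(out, m.values.to_numpy(), atol=1e-9)


def test_background_subtraction_floors_at_zero():
    m = _matrix([[3.0], [8.0]])
    out = (2.0 ** ss.normalize(m, "background", negative_control=5.0).values.to_numpy()) - 1.0
    np.testing.assert_allclose(out[:, 0], [0.0, 3.0], atol=1e-9)


def test_missing_method_inputs_error():
    m = _matrix([[1, 2], [3, 4]])
    with pytest.raises(AnalysisError):
        ss.normalize(m, "housekeeping")
    with pytest.raises(AnalysisError):
        ss.normalize(m, "background")


# ---------------------------------------------------------------------------
# strategy evaluation
# ---------------------------------------------------------------------------

def _biased_dataset(seed=0, n_probes=60, n_per_arm=30):
    """Counts identical across arms except a nonlinear distortion of the
    sarcoid segments that a single scale factor cannot undo: after
    library-size scaling low- and high-abundance probes are shifted in
    opposite directions (intensity-dependent bias), while quantile
    normalization restores the common distribution."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(2, 10, n_probes)
    cols, labels = [], []
    for arm in (0, 1):
        for i in range(n_per_arm):
            lam = 2.0 ** (base + rng.normal(0, 0.1, n_probes))
            counts = rng.poisson(lam).astype(float)
            if arm == 1:
                counts = counts ** 0.85
            cols.append(counts)
            labels.append(arm)
    probes = [f"p{i}" for i in range(n_probes)]
    segs = [f"S{j}" for j in range(len(cols))]
    m = ss.CountMatrix(pd.DataFrame(np.column_stack(cols), index=probes, columns=segs))
    ann = make_annotation(len(cols))
    ann.table["cohort_class"] = ["control_nf" if a == 0 else "cs_biopsy" for a in labels]
    return m, ann


def test_evaluation_prefers_quantile_under_intensity_bias():
    m, ann = _biased_dataset()
    table, winner = ss.evaluate_normalizations(m, ann,
                                               methods=["quantile", "library_size"],
                                               negative_control=1.0)
    assert winner == "quantile"
    row_q = table.set_index("method").loc["quantile"]
    row_l = table.set_index("method").loc["library_size"]
    assert row_q["abs_correlation"] < row_l["abs_correlation"]


def test_evaluation_invariant_to_segment_order():
    m, ann = _biased_dataset(seed=3)
    perm = np.random.default_rng(1).permutation(len(ann))
    ids = [ann.aoi_ids[i] for i in perm]
    m2 = m.subset_segments(ids)
    ann2 = ann.subset(ids)
    t1, w1 = ss.evaluate_normalizations(m, ann, methods=["quantile", "library_size"])
    t2, w2 = ss.evaluate_normalizations(m2, ann2, methods=["quantile", "library_size"])
    assert w1 == w2
    pd.testing.assert_frame_equal(t1, t2)


def test_evaluation_no_significant_probes_convention():
    rng = np.random.default_rng(5)
    m = _matrix(np.tile(rng.uniform(10, 20, 8)[:, None], (1, 8)))
    ann = make_annotation(8)
    ann.table.loc[ann.table.index[:4], "cohort_class"] = "control_nf"
    table, _ = ss.evaluate_normalizations(m, ann, methods=["quantile"])
    row = table.iloc[0]
    assert row["n_significant"] == 0 and row["symmetry"] == 0.0
    assert row["note"] == "no significant probes"
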