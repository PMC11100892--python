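"""Normalization strategies and the data-driven strategy selection criterion.

Quantile normalization forces every segment to share one common value
distribution by rank; alternatives are total-signal (library size) scaling,
housekeeping-probe scaling, and background subtraction. Competing strategies
are scored on sarcoid-vs-control behaviour: a good normalization should show
(i) low absolute correlation between a probe's mean expression and its
differential-expression p-value (no intensity-dependent bias) and (ii)
significant probes split symmetrically between the two conditions (no global
shift toward either condition). Strategies are ranked lexicographically on
the two metrics, lower being better.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountMatrix, NormalizedMatrix, SegmentAnnotation, is_sarcoid
from .errors import AnalysisError

METHODS = ("quantile", "library_size", "housekeeping", "background")


def _log2p1(values: pd.DataFrame) -> NormalizedMatrix:
    return NormalizedMatrix(np.log2(values + 1.0))


def quantile_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Quantile-normalize segments, then log2(v + 1).

    The reference distribution is the across-segment mean of sorted value
    vectors; every segment's sorted vector becomes the reference. Ties
    within a segment receive the mean of the reference values their rank
    range spans, so the result is invariant to segment order.
    """
    values = counts.values
    if values.shape[1] < 2:
        raise AnalysisError("quantile normalization requires at least 2 segments")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        rmin = stats.rankdata(col, method="min").astype(int)
        rmax = stats.rankdata(col, method="max").astype(int)
        # mean of the reference values spanned by each (possibly tied) rank range
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return _log2p1(pd.DataFrame(out, index=values.index, columns=values.columns))


def normalize(counts: CountMatrix, method: str, housekeepers: list[str] | None = None,
              negative_control: float | None = None) -> NormalizedMatrix:
    """Normalize raw counts with the chosen strategy; output is log2(v + 1)."""
    if method not in METHODS:
        raise AnalysisError(f"unknown normalization method {method!r}; choose from {METHODS}")
    values = counts.values
    if method == "quantile":
        return quantile_normalize(counts)
    if method == "library_size":
        totals = values.sum(axis=0)
        if (totals == 0).any():
            raise AnalysisError("library_size normalization: a segment has zero total signal")
        scaled = values * (totals.mean() / totals)
        return _log2p1(scaled)
    if method == "housekeeping":
        if not housekeepers:
            raise AnalysisError("housekeeping normalization requires a designated probe subset")
        missing = [p for p in housekeepers if p not in values.index]
        if missing:
            raise AnalysisError(f"housekeeping probes absent from matrix: {missing}")
        # geometric mean computed on v+1 so zero counts stay defined
        geo = np.exp(np.log(values.loc[housekeepers] + 1.0).mean(axis=0))
        scaled = values * (geo.mean() / geo)
        return _log2p1(scaled)
    # background
    if negative_control is None:
        raise AnalysisError("background normalization requires a negative-control estimate")
    floored = (values - float(negative_control)).clip(lower=0.0)
    return _log2p1(floored)


def evaluate_normalizations(counts: CountMatrix, ann: SegmentAnnotation,
                            methods: list[str] | None = None, alpha: float = 0.05,
                            housekeepers: list[str] | None = None,
                            negative_control: float | None = None):
    """Score and rank normalization strategies; returns (table, winner).

    For each method the per-probe mean normalized expression and the Welch
    two-sample p-value (sarcoid vs control, on log values) are computed;
    the score is (|Spearman rho(mean, p)|, |fraction of significant probes
    higher in sarcoid - 0.5|), ranked lexicographically, ties broken by
    method name. A method with no significant probes gets symmetry 0 and is
    noted in the table.
    """
    methods = list(methods) if methods is not None else list(METHODS)
    sarcoid_mask = is_sarcoid(ann.table["cohort_class"]).to_numpy()
    if sarcoid_mask.sum() < 2 or (~sarcoid_mask).sum() < 2:
        raise AnalysisError("evaluation needs >=2 sarcoid and >=2 control segments")

    rows = []
    for method in methods:
        norm = normalize(counts, method, housekeepers=housekeepers,
                         negative_control=negative_control)
        arr = norm.values.to_numpy()
        mean_expr = arr.mean(axis=1)
        sarc, ctrl = arr[:, sarcoid_mask], arr[:, ~sarcoid_mask]
        pvals = stats.ttest_ind(sarc, ctrl, axis=1, equal_var=False).pvalue
        rho = stats.spearmanr(mean_expr, pvals).statistic
        abs_corr = float(abs(rho)) if np.isfinite(rho) else 0.0
        sig = pvals < alpha
        n_sig = int(sig.sum())
        if n_sig == 0:
            symmetry, note = 0.0, "no significant probes"
        else:
            frac_up = float((sarc.mean(axis=1) > ctrl.mean(axis=1))[sig].mean())
            symmetry, note = abs(frac_up - 0.5), ""
        rows.append({"method": method, "abs_correlation": abs_corr,
                     "symmetry": symmetry, "n_significant": n_sig, "note": note})

    table = pd.DataFrame(rows).sort_values(
        ["abs_correlation", "symmetry", "method"], kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    winner = str(table.iloc[0]["method"])
    return table, winner
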