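"""Granuloma heterogeneity statistics.

Three complementary views of how variable granulomas are, within and
between tissue samples:

* per-probe variance of log2 expression across granuloma ROIs versus across
  non-granuloma parenchymal ROIs, with the fraction of probes where the
  granuloma variance is strictly higher;
* intra-sample versus inter-sample coefficient of variation (COV, linear
  scale) of each probe across the granuloma ROIs of samples contributing at
  least two granulomas;
* a PCA nearest-neighbor statistic: the fraction of granuloma ROIs (from
  multi-granuloma samples) whose nearest neighbor in principal-component
  space belongs to a *different* sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import NormalizedMatrix, SegmentAnnotation
from .errors import AnalysisError


def _granuloma_segments(ann: SegmentAnnotation) -> pd.Index:
    t = ann.table
    return t.index[(t["region_class"] == "granuloma") & (t["compartment"] == "full_roi")]


def _parenchyma_segments(ann: SegmentAnnotation) -> pd.Index:
    t = ann.table
    parenchymal = t["region_class"].isin(("peri_granuloma", "granuloma_remote"))
    return t.index[parenchymal & (t["compartment"] == "full_roi")]


def variance_comparison(matrix: NormalizedMatrix, ann: SegmentAnnotation,
                        top_k: int = 10):
    """Per-probe variance in granuloma vs parenchymal ROIs.

    Returns ``(table, fraction_granuloma_higher, top_k_probes)`` where the
    fraction uses a strict comparison (ties are recorded but not counted)
    and ``top_k_probes`` lists the probes with the highest granuloma
    variance.
    """
    gran = _granuloma_segments(ann)
    par = _parenchyma_segments(ann)
    if len(gran) < 2 or len(par) < 2:
        raise AnalysisError("variance comparison needs >=2 segments in each ROI group")
    g = matrix.values[list(gran)].to_numpy()
    p = matrix.values[list(par)].to_numpy()
    var_g = g.var(axis=1, ddof=1)
    var_p = p.var(axis=1, ddof=1)
    table = pd.DataFrame({
        "probe_id": matrix.probes,
        "var_granuloma": var_g,
        "var_parenchyma": var_p,
        "granuloma_higher": var_g > var_p,
        "tie": var_g == var_p,
    })
    fraction = float(table["granuloma_higher"].mean())
    top = list(table.sort_values("var_granuloma", ascending=False, kind="mergesort")
               .head(top_k)["probe_id"])
    return table, fraction, top


def cov_intra_inter(matrix: NormalizedMatrix, ann: SegmentAnnotation):
    """Intra- vs inter-sample COV of each probe across granuloma ROIs.

    Restricted to samples (donors) contributing >= 2 granuloma ROIs. COV is
    computed on linear-scale values (2^log2 - shifted values are already
    log2(v+1), so linear values are 2^x - 1). The intra COV is sd/mean of a
    probe across one sample's granulomas; the inter COV is sd/mean across
    all samples' granuloma means. Returns ``(table, counts_per_sample)``
    where the counts give, per sample, the number of probes whose intra COV
    strictly exceeds the inter COV.
    """
    gran = _granuloma_segments(ann)
    donors = ann.table.loc[gran, "donor_id"]
    multi = [d for d, k in donors.value_counts().items() if k >= 2]
    if not multi:
        warnings.warn("no sample contributes >= 2 granuloma ROIs; COV table is empty")
        return pd.DataFrame(columns=["donor_id", "probe_id", "cov_intra", "cov_inter"]), {}

    linear = (2.0 ** matrix.values[list(gran)]) - 1.0
    sample_means = {d: linear.loc[:, donors[donors == d].index].mean(axis=1) for d in multi}
    between = pd.DataFrame(sample_means)
    inter = between.std(axis=1, ddof=1) / between.mean(axis=1)

    rows = []
    counts: dict[str, int] = {}
    for d in multi:
        segs = donors[donors == d].index
        vals = linear.loc[:, segs]
        intra = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        exceed = int((intra > inter).sum())
        counts[d] = exceed
        rows.append(pd.DataFrame({
            "donor_id": d, "probe_id": matrix.probes,
            "cov_intra": intra.to_numpy(), "cov_inter": inter.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True), counts


def pca_nearest_neighbor(matrix: NormalizedMatrix, ann: SegmentAnnotation,
                         n_components: int = 2):
    """Fraction of granuloma ROIs whose PCA nearest neighbor is cross-sample.

    Only granuloma ROIs of multi-granuloma samples enter the statistic
    (singleton-sample ROIs have no possible same-sample neighbor); the PCA
    itself is fit on all granuloma ROIs, z-scored per probe. The principal
    component signs are fixed so each component's largest-magnitude loading
    is positive, making results bit-reproducible on identical input.
    Returns ``(fraction, neighbor_table)``.
    """
    gran = _granuloma_segments(ann)
    donors = ann.table.loc[gran, "donor_id"]
    if len(gran) < 2 or donors.nunique() < 2:
        raise AnalysisError("PCA nearest-neighbor needs >=2 granuloma ROIs from >=2 samples")
    X = matrix.values[list(gran)].to_numpy().T  # ROIs x probes
    sd = X.std(axis=0, ddof=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k = min(n_components, min(X.shape) - 1)
    if k < n_components:
        warnings.warn(f"reducing PCA components from {n_components} to {k}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component is positive
    for j in range(k):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1.0

    ids = list(gran)
    d2 = ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    table = pd.DataFrame({
        "aoi_id": ids,
        "donor_id": donors.to_numpy(),
        "neighbor_aoi_id": [ids[j] for j in nn],
        "neighbor_donor_id": [donors.iloc[j] for j in nn],
        "distance": np.sqrt(d2[np.arange(len(ids)), nn]),
    })
    table["cross_sample"] = table["donor_id"] != table["neighbor_donor_id"]
    multi = donors.value_counts()
    eligible = table["donor_id"].map(multi) >= 2
    if not eligible.any():
        raise AnalysisError("no multi-granuloma samples for nearest-neighbor statistic")
    fraction = float(table.loc[eligible, "cross_sample"].mean())
    table["eligible"] = eligible.to_numpy()
    return fraction, table
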