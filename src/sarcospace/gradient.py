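"""Ordinal distance-gradient testing.

Parenchymal segments are assigned an ordinal distance class relative to
granulomatous inflammation: inflammation(-) peri-granuloma regions are class
1, inflammation(-) granuloma-remote regions class 2, and control regions
class 3. For every probe a proportional-odds cumulative-logit model is fit
with the probe's z-scored expression as the single predictor, and the Wald
p-value of the expression coefficient tests whether expression carries
information about distance from inflammation.

The fit treats segments as independent (no donor effect) — an assumption,
documented as a limitation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .data import CS_CLASSES, NormalizedMatrix, SegmentAnnotation
from .errors import AnalysisError
from .de import adjust_pvalues


def assign_distance_classes(ann: SegmentAnnotation, stratum: str = "full_roi") -> pd.Series:
    """Ordinal class per eligible segment: 1 = peri, 2 = remote, 3 = control."""
    t = ann.table
    cs = t["cohort_class"].isin(CS_CLASSES)
    in_stratum = t["compartment"] == stratum
    bland = ~t["infiltrate"]
    cls = pd.Series(np.nan, index=t.index)
    cls[cs & bland & (t["region_class"] == "peri_granuloma") & in_stratum] = 1
    cls[cs & bland & (t["region_class"] == "granuloma_remote") & in_stratum] = 2
    cls[~cs & (t["region_class"] == "granuloma_remote") & in_stratum] = 3
    return cls.dropna().astype(int)


def ordinal_gradient_test(matrix: NormalizedMatrix, ann: SegmentAnnotation,
                          stratum: str = "full_roi", min_class_size: int = 3) -> pd.DataFrame:
    """Per-probe proportional-odds regression of distance class on expression.

    Returns one row per probe with the odds ratio per SD of expression, the
    Wald p-value, its BH adjustment, the direction of the gradient, and the
    per-class segment counts. Classes with fewer than ``min_class_size``
    segments are excluded with a warning; fewer than two surviving classes
    is an error.
    """
    classes = assign_distance_classes(ann, stratum)
    counts = classes.value_counts()
    small = [int(c) for c in counts.index[counts < min_class_size]]
    if small:
        warnings.warn(f"distance classes {small} have fewer than {min_class_size} "
                      "segments and are excluded")
        classes = classes[~classes.isin(small)]
    if classes.nunique() < 2:
        raise AnalysisError("ordinal gradient test needs at least two distance classes")

    seg_ids = [s for s in classes.index if s in matrix.values.columns]
    classes = classes.loc[seg_ids]
    endog = classes.to_numpy()
    n_per_class = {f"n_class_{k}": int((endog == k).sum()) for k in sorted(set(endog))}

    rows = []
    for probe in matrix.probes:
        y = matrix.values.loc[probe, seg_ids].to_numpy(dtype=float)
        sd = y.std(ddof=1)
        if sd == 0:
            rows.append({"probe_id": probe, "odds_ratio": np.nan, "p_value": np.nan,
                         "direction": "flat", **n_per_class})
            continue
        z = (y - y.mean()) / sd
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = OrderedModel(endog, z[:, None], distr="logit").fit(
                    method="bfgs", disp=False, maxiter=200)
            coef = float(fit.params[0])
            p = float(fit.pvalues[0])
            if not fit.mle_retvals.get("converged", True):
                coef, p = np.nan, np.nan
        except Exception:
            coef, p = np.nan, np.nan
        direction = ("increasing" if coef > 0 else "decreasing" if coef < 0 else "flat") \
            if np.isfinite(coef) else "na"
        rows.append({"probe_id": probe, "odds_ratio": float(np.exp(coef)) if np.isfinite(coef) else np.nan,
                     "p_value": p, "direction": direction, **n_per_class})

    result = pd.DataFrame(rows)
    result["p_adjusted"] = adjust_pvalues(result["p_value"].to_numpy())
    front = ["probe_id", "odds_ratio", "p_value", "p_adjusted", "direction"]
    return result[front + [c for c in result.columns if c not in front]]
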