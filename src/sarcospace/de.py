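"""Per-probe mixed-model differential expression with exhaustive model selection.

Every probe's log-normalized expression is modeled with a donor random
intercept and up to four fixed covariates derived from the annotation:

``sarcoid``
    donor carries a clinical sarcoidosis diagnosis;
``infiltrate``
    the segment's ROI shows non-granulomatous inflammatory infiltration;
``explant``
    the tissue came from an explant (advanced disease) rather than a biopsy;
``distance``
    ordinal distance from the nearest granuloma, coded 0 (granuloma) /
    1 (peri-granuloma) / 2 (granuloma-remote); control and vascular-bed
    segments, which have no granuloma in the section, are coded 2 when a
    contrast includes them.

Model selection fits every subset of the fixed terms (the random intercept
always stays) and compares each reduced model to the full model with a
likelihood-ratio test; the selected model is the smallest subset whose LRT
against the full model is non-significant — i.e. the most parsimonious model
the data cannot distinguish from the full one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CS_CLASSES, NormalizedMatrix, SegmentAnnotation, is_sarcoid
from .errors import AnalysisError, ValidationError
from .mixedlm import MixedModelFit, fit_random_intercept
from .panel import ProbePanel

FIXED_TERMS = ("sarcoid", "infiltrate", "explant", "distance")

#: contrast name -> the model term whose coefficient is reported
CONTRAST_TERMS = {
    "stage": "explant",          # biopsy vs explant, within sarcoid donors
    "distance": "distance",      # peri-granuloma vs granuloma-remote
    "infiltrate": "infiltrate",  # infiltrate(+) vs infiltrate(-) parenchyma
    "cs_vs_control": "sarcoid",  # bland sarcoid parenchyma vs controls
}

_DISTANCE_CODE = {"granuloma": 0.0, "peri_granuloma": 1.0, "granuloma_remote": 2.0,
                  "vascular": 2.0}


@dataclass
class ModelSpec:
    """Fixed-term subset for one probe; the donor random intercept is implicit."""

    response: str
    fixed_terms: tuple[str, ...] = FIXED_TERMS
    grouping: str = "donor_id"

    def __post_init__(self) -> None:
        bad = set(self.fixed_terms) - set(FIXED_TERMS)
        if bad:
            raise ValidationError(f"unknown fixed terms {sorted(bad)}; allowed {FIXED_TERMS}")
        self.fixed_terms = tuple(t for t in FIXED_TERMS if t in self.fixed_terms)


def build_design(ann: SegmentAnnotation) -> pd.DataFrame:
    """Covariate table (sarcoid, infiltrate, explant, distance) per segment."""
    t = ann.table
    return pd.DataFrame({
        "sarcoid": is_sarcoid(t["cohort_class"]).astype(float),
        "infiltrate": t["infiltrate"].astype(float),
        "explant": (t["cohort_class"] == "cs_explant").astype(float),
        "distance": t["region_class"].map(_DISTANCE_CODE).astype(float),
    }, index=t.index)


def fit_mixed_model(y, design: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """ML fit of the probe's model; non-convergence is flagged, not raised."""
    X = design[list(spec.fixed_terms)]
    groups = design["__groups__"] if "__groups__" in design else None
    if groups is None:
        raise AnalysisError("design must carry a '__groups__' donor column")
    return fit_random_intercept(y, X, groups)


def attach_groups(design: pd.DataFrame, ann: SegmentAnnotation) -> pd.DataFrame:
    design = design.copy()
    design["__groups__"] = ann.table["donor_id"].to_numpy()
    return design


def select_model(y, design: pd.DataFrame, full_spec: ModelSpec,
                 protected: tuple[str, ...] = (), alpha: float = 0.05):
    """Exhaustive reduced-model search; returns (selected ModelSpec, LRT table).

    All subsets of the full fixed-term set that contain ``protected`` are
    fit; each is compared to the full model by a likelihood-ratio test with
    df equal to the number of dropped terms. The selected model is the
    smallest subset whose LRT p-value exceeds ``alpha`` (the reduction is
    not significantly worse); ties at the same size break by AIC, then by
    term-name order. If no reduction qualifies, the full model is kept.
    Non-converged candidates are skipped and flagged in the table.
    """
    full_terms = full_spec.fixed_terms
    bad = set(protected) - set(full_terms)
    if bad:
        raise AnalysisError(f"protected terms {sorted(bad)} not in the full model")
    full_fit = fit_mixed_model(y, design, full_spec)
    if not full_fit.converged:
        raise AnalysisError("full model did not converge")

    free = [t for t in full_terms if t not in protected]
    rows = []
    candidates = []
    for r in range(len(free) + 1):
        for drop in combinations(free, r):
            terms = tuple(t for t in full_terms if t not in drop)
            spec = ModelSpec(full_spec.response, terms)
            fit = full_fit if not drop else fit_mixed_model(y, design, spec)
            if not fit.converged:
                rows.append({"terms": ";".join(terms), "n_terms": len(terms),
                             "df_dropped": len(drop), "lrt_stat": np.nan,
                             "p_lrt": np.nan, "aic": np.nan, "converged": False})
                continue
            stat = 2.0 * (full_fit.llf - fit.llf)
            if np.isfinite(stat):
                assert stat >= -1e-6, "nested LRT statistic must be nonnegative"
                stat = max(stat, 0.0)
            p = 1.0 if not drop else float(stats.chi2.sf(stat, len(drop)))
            rows.append({"terms": ";".join(terms), "n_terms": len(terms),
                         "df_dropped": len(drop), "lrt_stat": stat, "p_lrt": p,
                         "aic": fit.aic, "converged": True})
            if p > alpha:
                candidates.append((len(terms), fit.aic, terms, spec))

    table = pd.DataFrame(rows)
    if candidates:
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        selected = candidates[0][3]
    else:
        selected = ModelSpec(full_spec.response, full_terms)
    table["selected"] = table["terms"] == ";".join(selected.fixed_terms)
    return selected, table


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def _contrast_subset(ann: SegmentAnnotation, contrast: str, stratum: str) -> pd.Index:
    t = ann.table
    in_stratum = t["compartment"] == stratum
    cs = t["cohort_class"].isin(CS_CLASSES)
    parenchyma = t["region_class"].isin(("peri_granuloma", "granuloma_remote"))
    if contrast in ("stage", "distance", "infiltrate"):
        mask = cs & parenchyma & in_stratum
    elif contrast == "cs_vs_control":
        bland_cs = cs & (t["region_class"] == "granuloma_remote") & ~t["infiltrate"]
        control = ~cs & (t["region_class"] == "granuloma_remote")
        mask = (bland_cs | control) & in_stratum
    else:
        raise ValidationError(f"unknown contrast {contrast!r}; known: {list(CONTRAST_TERMS)}")
    return t.index[mask]


def run_contrast(matrix: NormalizedMatrix, ann: SegmentAnnotation, panel: ProbePanel,
                 contrast: str, stratum: str = "full_roi", select: bool = True,
                 selection_alpha: float = 0.05) -> pd.DataFrame:
    """Differential expression for one contrast within one compartment stratum.

    Subsets segments per the contrast definition, fits the mixed model per
    probe with the contrast term always included (other applicable terms
    subject to exhaustive reduced-model selection when ``select`` is true),
    and BH-adjusts p-values within this (stratum, contrast) family. For the
    myocyte stratum the output is restricted to myocyte-expressed probes;
    contamination flags are assumed to have been applied to ``matrix``
    beforehand.
    """
    term = CONTRAST_TERMS.get(contrast)
    if term is None:
        raise ValidationError(f"unknown contrast {contrast!r}; known: {list(CONTRAST_TERMS)}")
    subset = _contrast_subset(ann, contrast, stratum)
    if len(subset) == 0:
        raise AnalysisError(f"no segments in stratum {stratum!r} for contrast {contrast!r}")
    sub_ann = ann.subset(subset)
    available = [s for s in subset if s in matrix.values.columns]
    if len(available) < len(subset):
        sub_ann = ann.subset(available)
    design = attach_groups(build_design(sub_ann), sub_ann)

    # terms that do not vary in this subset are inestimable and excluded
    varying = [t for t in FIXED_TERMS if design[t].nunique() > 1]
    if term not in varying:
        raise AnalysisError(f"contrast term {term!r} does not vary in the selected segments")
    full_terms = tuple(varying)

    probes = matrix.probes
    if stratum == "myocyte":
        myo = set(panel.myocyte_expressed)
        probes = [p for p in probes if p in myo]

    rows = []
    for probe in probes:
        y = matrix.values.loc[probe, sub_ann.table.index].to_numpy(dtype=float)
        try:
            if select and len(full_terms) > 1:
                spec, _ = select_model(y, design, ModelSpec(probe, full_terms),
                                       protected=(term,), alpha=selection_alpha)
            else:
                spec = ModelSpec(probe, full_terms)
            fit = fit_mixed_model(y, design, spec)
        except AnalysisError:
            fit = None
        if fit is None or not fit.converged:
            rows.append({"probe_id": probe, "stratum": stratum, "contrast": contrast,
                         "coefficient": np.nan, "std_error": np.nan, "p_value": np.nan,
                         "selected_terms": "", "n_segments": len(sub_ann), "converged": False})
            continue
        rows.append({"probe_id": probe, "stratum": stratum, "contrast": contrast,
                     "coefficient": float(fit.params[term]),
                     "std_error": float(fit.bse[term]),
                     "p_value": float(fit.pvalues[term]),
                     "selected_terms": ";".join(spec.fixed_terms),
                     "n_segments": len(sub_ann), "converged": True})

    result = pd.DataFrame(rows)
    result["p_adjusted"] = adjust_pvalues(result["p_value"].to_numpy())
    cols = ["probe_id", "stratum", "contrast", "coefficient", "std_error",
            "p_value", "p_adjusted", "selected_terms", "n_segments", "converged"]
    return result[cols].sort_values("p_value", kind="mergesort").reset_index(drop=True)
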