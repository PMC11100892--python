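"""Rank-percentile immune-marker scoring of myocyte segments.

Digital segmentation of parenchymal ROIs is imperfect: a nominal myocyte
segment can include unsegmented stroma, producing improbably high immune
marker signal. Each myocyte segment is scored by the fraction of a
designated immune-marker set found in the segment's top expression
percentile (a simplified rank-based gene-set score); segments whose score
exceeds a threshold are excluded from myocyte-level analyses while remaining
available to full-ROI analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import NormalizedMatrix, SegmentAnnotation
from .errors import AnalysisError
from .panel import ProbePanel


def contamination_score(segment_values: pd.Series, marker_set, percentile: float = 0.80) -> float:
    """Fraction of ``marker_set`` probes in the segment's top percentile.

    All probes in the segment are ranked ascending (ties get average rank);
    the top set is probes with rank strictly above ``percentile * P``. The
    score is rank-based, hence invariant to monotone transforms of the
    segment's values.
    """
    marker_set = list(marker_set)
    if not marker_set:
        raise AnalysisError("contamination_score: empty marker set")
    if not 0.0 < percentile < 1.0:
        raise AnalysisError("percentile must be in (0, 1)")
    missing = [m for m in marker_set if m not in segment_values.index]
    if missing:
        raise AnalysisError(f"marker probes absent from segment: {missing}")
    ranks = stats.rankdata(segment_values.to_numpy(), method="average")
    cutoff = percentile * len(segment_values)
    top = pd.Index(segment_values.index[ranks > cutoff])
    hits = sum(1 for m in marker_set if m in top)
    return hits / len(marker_set)


def flag_myocyte_segments(matrix: NormalizedMatrix, ann: SegmentAnnotation,
                          panel: ProbePanel, threshold: float = 0.2,
                          percentile: float = 0.80):
    """Score myocyte segments and drop contaminated ones.

    Returns ``(result_table, kept_myocyte_aoi_ids)``. Only segments with
    compartment ``myocyte`` are scored; a segment is dropped iff its score
    is strictly greater than ``threshold`` (with the default 8-marker set
    and threshold 0.2, one marker in the top set keeps the segment, two
    drop it). Dropped segments are excluded from the myocyte analysis view
    only — all other views keep them.
    """
    markers = panel.contamination_markers
    if not markers:
        raise AnalysisError("panel designates no contamination markers")
    myo = ann.table.index[ann.table["compartment"] == "myocyte"]
    rows = []
    for aoi in myo:
        seg = matrix.values[aoi]
        score = contamination_score(seg, markers, percentile=percentile)
        ranks = stats.rankdata(seg.to_numpy(), method="average")
        cutoff = percentile * len(seg)
        in_top = set(seg.index[ranks > cutoff])
        hits = [m for m in markers if m in in_top]
        rows.append({"aoi_id": aoi, "score": score, "dropped": score > threshold,
                     "marker_hits": ";".join(hits)})
    result = pd.DataFrame(rows, columns=["aoi_id", "score", "dropped", "marker_hits"])
    kept = list(result.loc[~result["dropped"], "aoi_id"]) if len(result) else []
    return result, kept
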