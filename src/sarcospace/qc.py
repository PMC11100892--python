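"""Segment-level quality control.

Segments (AOIs) are filtered on four covariates recorded by the profiling
instrument: nuclei count, surface area, binding density, and background
signal relative to a negative-control estimate. Thresholds are exposed and
echoed into the report; filtering is deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import CountMatrix, SegmentAnnotation
from .errors import AnalysisError


@dataclass
class QCThresholds:
    """Pass criteria for a segment. Defaults follow common DSP practice."""

    min_nuclei: int = 20
    min_area: float = 1600.0          # um^2
    binding_density_range: tuple[float, float] = (0.1, 2.25)
    max_background_ratio: float = 3.0
    negative_control_estimate: float = 1.0

    def __post_init__(self) -> None:
        low, high = self.binding_density_range
        if low >= high:
            raise AnalysisError("binding_density_range must satisfy low < high")
        if min(self.min_nuclei, self.min_area, low, self.max_background_ratio) < 0:
            raise AnalysisError("QC thresholds must be >= 0")


@dataclass
class QCReport:
    """Per-segment pass/fail flags and per-criterion failure counts."""

    table: pd.DataFrame          # aoi_id, passed, failed_criteria
    counts_per_criterion: dict[str, int]
    thresholds: QCThresholds

    @property
    def n_flagged(self) -> int:
        return int((~self.table["passed"]).sum())

    def as_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def threshold_comment(self) -> str:
        """One-line record of the thresholds applied, for report headers."""
        t = self.thresholds
        return (f"thresholds: min_nuclei={t.min_nuclei} min_area={t.min_area} "
                f"binding_density={t.binding_density_range} "
                f"max_background_ratio={t.max_background_ratio}")


_CRITERIA = ("nuclei", "area", "binding_density", "background")


def filter_segments(counts: CountMatrix, ann: SegmentAnnotation,
                    thresholds: QCThresholds | None = None):
    """Drop failing segments; returns (counts, annotation, QCReport).

    A segment fails if any criterion fails; the report lists every input
    segment with the named reasons. Removing all segments is an error
    rather than an empty result.
    """
    thresholds = thresholds or QCThresholds()
    t = ann.table
    low, high = thresholds.binding_density_range
    fails = {
        "nuclei": t["nuclei_count"] < thresholds.min_nuclei,
        "area": t["surface_area"] < thresholds.min_area,
        "binding_density": (t["binding_density"] < low) | (t["binding_density"] > high),
        "background": (t["background_signal"] / thresholds.negative_control_estimate)
                      > thresholds.max_background_ratio,
    }
    failed_lists = [
        ";".join(c for c in _CRITERIA if bool(fails[c].iloc[i]))
        for i in range(len(t))
    ]
    passed = ~pd.concat(fails, axis=1).any(axis=1)
    report = QCReport(
        table=pd.DataFrame({
            "aoi_id": t.index,
            "passed": passed.to_numpy(),
            "failed_criteria": failed_lists,
        }),
        counts_per_criterion={c: int(fails[c].sum()) for c in _CRITERIA},
        thresholds=thresholds,
    )
    keep = list(t.index[passed])
    if not keep:
        raise AnalysisError("QC thresholds removed every segment")
    return counts.subset_segments(keep), ann.subset(keep), report
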