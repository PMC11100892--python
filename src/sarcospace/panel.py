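"""Probe panel: probe identities and role flags.

A high-plex protein panel is described by one row per probe with a category
label and three boolean role flags:

``myocyte_expressed``
    the protein is known to be expressed by cardiomyocytes, so the probe is
    reportable for myocyte-compartment segments;
``if_suitable``
    the marker is suitable for quantitative multiplex immunofluorescence
    (cell-surface markers, cell-type-restricted enzymes and transcription
    factors), making it a candidate for diagnostic panel modeling;
``contamination_marker``
    the probe is an immune lineage marker used to score stromal
    contamination of myocyte segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

REQUIRED_COLUMNS = (
    "probe_id",
    "category",
    "myocyte_expressed",
    "if_suitable",
    "contamination_marker",
)

_FLAG_COLUMNS = ("myocyte_expressed", "if_suitable", "contamination_marker")


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, True: True, False: False, 1: True, 0: False,
    }
    out = series.map(lambda v: mapping.get(str(v).strip().lower(), None))
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ValidationError(f"column {name!r}: cannot interpret {bad!r} as boolean")
    return out.astype(bool)


@dataclass
class ProbePanel:
    """Validated probe panel table.

    ``table`` is indexed by ``probe_id`` and carries at least the category
    and flag columns; unknown extra columns are preserved as metadata.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        if "probe_id" in df.columns:
            df = df.set_index("probe_id")
        if df.index.name != "probe_id":
            df = df.copy()
            df.index.name = "probe_id"
        missing = [c for c in REQUIRED_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValidationError(f"panel is missing required columns: {missing}")
        if len(df) == 0:
            raise ValidationError("panel contains no probes")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate probe_id in panel: {dup}")
        if df.index.isna().any() or (df.index.astype(str) == "").any():
            raise ValidationError("panel contains empty probe_id")
        df = df.copy()
        for col in _FLAG_COLUMNS:
            df[col] = _coerce_bool(df[col], col)
        self.table = df

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    @property
    def contamination_markers(self) -> list[str]:
        return list(self.table.index[self.table["contamination_marker"]])

    @property
    def myocyte_expressed(self) -> list[str]:
        return list(self.table.index[self.table["myocyte_expressed"]])

    @property
    def if_suitable(self) -> list[str]:
        return list(self.table.index[self.table["if_suitable"]])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.table.index
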