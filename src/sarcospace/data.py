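"""Segment annotations, count matrices, and delimited-text I/O.

The three study inputs are plain delimited tables (TSV by default, CSV
accepted by extension): a probe panel, a probe-by-segment nonnegative count
matrix with probes as rows, and a per-segment (AOI) annotation table carrying
donor, ROI, cohort class, region class, compartment, infiltrate flag and the
four QC covariates. A YAML manifest names the three files so a dataset can be
passed around as one artifact.

Result tables are written as TSV with a leading ``#`` comment line recording
the tool version and, when available, a configuration hash; readers skip
comment lines, so every writer/reader pair is an identity on its table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .panel import ProbePanel

COHORT_CLASSES = ("cs_biopsy", "cs_explant", "control_nicm", "control_nf", "control_txp")
CS_CLASSES = ("cs_biopsy", "cs_explant")
CONTROL_CLASSES = ("control_nicm", "control_nf", "control_txp")
REGION_CLASSES = ("granuloma", "peri_granuloma", "granuloma_remote", "vascular")
COMPARTMENTS = ("full_roi", "myocyte", "stroma", "vascular")

ANNOTATION_COLUMNS = (
    "aoi_id",
    "roi_id",
    "donor_id",
    "cohort_class",
    "region_class",
    "compartment",
    "infiltrate",
    "nuclei_count",
    "surface_area",
    "binding_density",
    "background_signal",
)


def _sep_for(path: Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def is_sarcoid(cohort_class: pd.Series) -> pd.Series:
    """Boolean donor-level sarcoidosis indicator from the cohort class."""
    return cohort_class.isin(CS_CLASSES)


@dataclass
class SegmentAnnotation:
    """Validated per-segment annotation table, indexed by ``aoi_id``."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        if "aoi_id" in df.columns:
            df = df.set_index("aoi_id")
        df = df.copy()
        df.index.name = "aoi_id"
        missing = [c for c in ANNOTATION_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation is missing required columns: {missing}")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate aoi_id in annotation: {dup}")
        for col, allowed in (("cohort_class", COHORT_CLASSES),
                             ("region_class", REGION_CLASSES),
                             ("compartment", COMPARTMENTS)):
            bad = sorted(set(df[col].astype(str)) - set(allowed))
            if bad:
                raise ValidationError(f"unknown {col} value(s) {bad}; allowed: {list(allowed)}")
        from .panel import _coerce_bool  # shared coercion helper

        df["infiltrate"] = _coerce_bool(df["infiltrate"], "infiltrate")
        # granulomas are themselves inflammation; the infiltrate flag describes
        # non-granulomatous infiltration and never applies to granuloma ROIs
        if bool((df["infiltrate"] & (df["region_class"] == "granuloma")).any()):
            raise ValidationError("granuloma segments cannot carry infiltrate=true")
        for col in ("nuclei_count", "surface_area", "binding_density", "background_signal"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"annotation column {col!r} contains non-numeric values")
            if (vals < 0).any():
                raise ValidationError(f"annotation column {col!r} contains negative values")
            df[col] = vals
        self.table = df

    @property
    def aoi_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    def subset(self, aoi_ids) -> "SegmentAnnotation":
        return SegmentAnnotation(self.table.loc[list(aoi_ids)].copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountMatrix:
    """Probe x segment matrix of nonnegative counts (probes as rows)."""

    values: pd.DataFrame = field(repr=False)
    log_scale: bool = False

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise ValidationError("duplicate probe ids on matrix rows")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate segment ids on matrix columns")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("matrix contains non-finite values")
        if not self.log_scale and (arr < 0).any():
            raise ValidationError("count matrix contains negative values")
        df = df.astype(float)
        df.index.name = "probe_id"
        self.values = df

    @property
    def probes(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def segments(self) -> list[str]:
        return list(self.values.columns.astype(str))

    def subset_segments(self, aoi_ids) -> "CountMatrix":
        return CountMatrix(self.values[list(aoi_ids)].copy(), log_scale=self.log_scale)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class NormalizedMatrix(CountMatrix):
    """Probe x segment matrix of log2(normalized + 1) values."""

    def __init__(self, values: pd.DataFrame):
        super().__init__(values, log_scale=True)

    def subset_segments(self, aoi_ids) -> "NormalizedMatrix":
        return NormalizedMatrix(self.values[list(aoi_ids)].copy())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_panel(path) -> ProbePanel:
    """Read and validate a probe panel table (TSV/CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if df.empty and len(df.columns) <= 1:
        raise ValidationError(f"{path}: no probes")
    if "probe_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'probe_id'")
    if len(df) == 0:
        raise ValidationError(f"{path}: no probes")
    return ProbePanel(df)


def read_annotation(path) -> SegmentAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if "aoi_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'aoi_id'")
    return SegmentAnnotation(df)


def read_counts(path) -> CountMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", index_col=0)
    return CountMatrix(df)


def read_dataset(counts_path, annotation_path, panel: ProbePanel) -> tuple[CountMatrix, SegmentAnnotation]:
    """Read counts + annotation and align both against the panel.

    Probe rows must match the panel exactly (order is taken from the panel)
    and segment columns must match the annotation exactly; any segment or
    probe present on one side only is a hard error naming the offenders.
    """
    counts = read_counts(counts_path)
    ann = read_annotation(annotation_path)

    panel_probes = set(panel.probe_ids)
    matrix_probes = set(counts.probes)
    if panel_probes != matrix_probes:
        only_matrix = sorted(matrix_probes - panel_probes)
        only_panel = sorted(panel_probes - matrix_probes)
        raise ValidationError(
            f"probe axis mismatch: in counts but not panel {only_matrix[:10]}, "
            f"in panel but not counts {only_panel[:10]}"
        )
    ann_segments = set(ann.aoi_ids)
    matrix_segments = set(counts.segments)
    if ann_segments != matrix_segments:
        only_matrix = sorted(matrix_segments - ann_segments)
        only_ann = sorted(ann_segments - matrix_segments)
        raise ValidationError(
            f"segment axis mismatch: in counts but not annotation {only_matrix[:10]}, "
            f"in annotation but not counts {only_ann[:10]}"
        )
    aligned = counts.values.loc[panel.probe_ids, ann.aoi_ids]
    return CountMatrix(aligned), ann


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def config_hash(config) -> str:
    """Stable short hash of a configuration mapping (for provenance headers)."""
    blob = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header_comment(cfg_hash: str | None) -> str:
    tag = f" config={cfg_hash}" if cfg_hash else ""
    return f"# sarcospace v{__version__}{tag}\n"


def write_table(result, path, cfg_hash: str | None = None,
                extra_comments: list[str] | None = None) -> None:
    """Write a result table (DataFrame or wrapped matrix/annotation) as TSV.

    Output carries a ``#`` provenance comment line (plus any
    ``extra_comments``); ``read_table`` / ``read_counts`` /
    ``read_annotation`` skip them, so round-trips are exact (floating
    values to well below 1e-9).
    """
    path = Path(path)
    if isinstance(result, (CountMatrix, NormalizedMatrix)):
        df, index = result.values, True
    elif isinstance(result, (SegmentAnnotation, ProbePanel)):
        df, index = result.table.reset_index(), False
    elif isinstance(result, pd.DataFrame):
        df, index = result, False
    else:
        raise ValidationError(f"cannot write object of type {type(result).__name__}")
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(cfg_hash))
        for line in extra_comments or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=index, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_table`."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_manifest(out_dir, counts="counts.tsv", annotation="annotation.tsv",
                   panel="panel.tsv", extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    manifest = {"counts": counts, "annotation": annotation, "panel": panel}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_manifest_dataset(manifest_path) -> tuple[CountMatrix, SegmentAnnotation, ProbePanel]:
    """Load the (counts, annotation, panel) trio named by a YAML manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    for key in ("counts", "annotation", "panel"):
        if key not in manifest:
            raise ValidationError(f"manifest {manifest_path} lacks entry {key!r}")
        if not (base / manifest[key]).exists():
            raise ValidationError(f"manifest input file not found: {base / manifest[key]}")
    panel = read_panel(base / manifest["panel"])
    counts, ann = read_dataset(base / manifest["counts"], base / manifest["annotation"], panel)
    return counts, ann, panel
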