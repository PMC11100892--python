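"""Synthetic spatial-proteomics cohort generator with ground truth.

The generator emulates the statistical structure of an ROI/AOI digital
spatial profiling study of cardiac sarcoidosis: donors in five cohort
classes (sarcoid biopsy, sarcoid explant, and three control subgroups),
ROIs of four region classes (granuloma, peri-granuloma, granuloma-remote
parenchyma, large vascular bed), compartment AOIs within parenchymal ROIs
(full-ROI, myocyte, stroma), a donor random intercept, fixed effects for
sarcoid status / infiltrate / explant / distance-from-granuloma, and
stromal contamination of myocyte segments.

Generative model, per probe ``p`` and segment ``s`` of donor ``j``::

    mu_ps = baseline_p + d_j + beta-terms(covariates of s) + compartment offset
    d_j ~ Normal(0, donor_sd^2)
    count_ps ~ Poisson(2^(mu_ps + eps)),  eps ~ Normal(0, residual_sd^2)

Myocyte segments are mixed on the linear scale with the ROI's stroma
profile using a Beta-distributed contamination fraction ``c`` before the
Poisson draw, and full-ROI segments are area-weighted linear mixtures of
that ROI's compartment means. The ordinal distance covariate is coded
0 (granuloma) / 1 (peri-granuloma) / 2 (granuloma-remote) for sarcoid
donors; control segments carry no distance term.

All randomness flows from a single seeded generator. Stream order: donor
effects, then ROI/segment structure (infiltrate flags), then contamination
fractions (segment emission order), then per-segment log-normal noise, then
Poisson counts, then QC covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CONTROL_CLASSES,
    CS_CLASSES,
    CountMatrix,
    SegmentAnnotation,
    write_manifest,
    write_table,
)
from .errors import ValidationError
from .panel import ProbePanel

# ---------------------------------------------------------------------------
# the default 79-plex cardiac immune/stroma/pathway panel
# ---------------------------------------------------------------------------

# immune lineage markers used to score stromal contamination of myocyte AOIs
CONTAMINATION_MARKERS = ("CD68", "CTLA4", "CD3", "CD4", "PD-1", "CD8", "CD45", "CD20")

_PANEL_SPEC: list[tuple[str, str]] = [
    # (probe, category)
    ("CD68", "immune_lineage"), ("CTLA4", "checkpoint"), ("CD3", "immune_lineage"),
    ("CD4", "immune_lineage"), ("PD-1", "checkpoint"), ("CD8", "immune_lineage"),
    ("CD45", "immune_lineage"), ("CD20", "immune_lineage"),
    ("CD11c", "immune_lineage"), ("CD11b", "immune_lineage"), ("CD14", "immune_lineage"),
    ("CD163", "immune_lineage"), ("CD27", "immune_lineage"), ("CD34", "stroma_vascular"),
    ("CD40", "immune_activation"), ("CD40L", "immune_activation"), ("CD44", "immune_activation"),
    ("CD45RO", "immune_lineage"), ("CD56", "immune_lineage"), ("CD66b", "immune_lineage"),
    ("CD80", "immune_activation"), ("CD86", "immune_activation"), ("CD90", "stroma_vascular"),
    ("CD95", "apoptosis"), ("CD127", "immune_lineage"), ("CD25", "immune_lineage"),
    ("GZMA", "immune_activation"), ("GZMB", "immune_activation"), ("HLA-DR", "antigen_presentation"),
    ("Beta-2-microglobulin", "antigen_presentation"), ("FOXP3", "immune_lineage"),
    ("GITR", "immune_activation"), ("ICOS", "immune_activation"), ("IDO1", "immune_activation"),
    ("ARG1", "immune_activation"), ("BCL6", "immune_activation"), ("STING", "immune_activation"),
    ("PD-L1", "checkpoint"), ("PD-L2", "checkpoint"), ("Tim-3", "checkpoint"),
    ("LAG3", "checkpoint"), ("VISTA", "checkpoint"), ("4-1BB", "checkpoint"),
    ("OX40L", "checkpoint"),
    ("FAP-alpha", "stroma_vascular"), ("SMA", "stroma_vascular"), ("Fibronectin", "stroma_vascular"),
    ("Vimentin", "stroma_vascular"), ("CD31", "stroma_vascular"),
    ("Histone-H3", "proliferation"), ("Ki-67", "proliferation"),
    ("Desmin", "structural"), ("Alpha-Actinin", "structural"),
    ("BAD", "apoptosis"), ("BAX", "apoptosis"), ("BIM", "apoptosis"),
    ("BCL-XL", "apoptosis"), ("MCL1", "apoptosis"), ("p53", "apoptosis"),
    ("PARP", "apoptosis"), ("Cleaved-PARP", "apoptosis"), ("Cleaved-Caspase-9", "apoptosis"),
    ("MEK1", "mapk"), ("ERK1-2", "mapk"), ("Phospho-ERK1-2", "mapk"),
    ("p38-MAPK", "mapk"), ("Phospho-p38", "mapk"), ("JNK", "mapk"),
    ("Phospho-JNK", "mapk"), ("NF-kB-p65", "mapk"), ("STAT3", "mapk"),
    ("Phospho-STAT3", "mapk"),
    ("Pan-AKT", "pi3k_akt"), ("Phospho-AKT", "pi3k_akt"), ("S6", "pi3k_akt"),
    ("Phospho-S6", "pi3k_akt"), ("PTEN", "pi3k_akt"),
    ("Phospho-GSK3A", "pi3k_akt"), ("Phospho-GSK3B", "pi3k_akt"),
]

# pathway/apoptosis proteins are broadly expressed (incl. myocytes) but poorly
# suited to quantitative multiplex IF; surface markers/TFs are the reverse
_MYOCYTE_CATEGORIES = {"apoptosis", "mapk", "pi3k_akt", "structural", "proliferation"}
_MYOCYTE_EXTRA = {"CD44", "CD40", "HLA-DR", "Beta-2-microglobulin", "PD-L1",
                  "Fibronectin", "Vimentin", "STING"}
_NOT_IF_SUITABLE_CATEGORIES = {"apoptosis", "mapk", "pi3k_akt"}
_IF_SUITABLE_EXCEPTIONS = {"CD95"}  # surface death receptor, IF-stainable


def default_panel() -> ProbePanel:
    """The built-in 79-probe cardiac sarcoidosis study panel."""
    rows = []
    for probe, cat in _PANEL_SPEC:
        myo = cat in _MYOCYTE_CATEGORIES or probe in _MYOCYTE_EXTRA
        if_ok = cat not in _NOT_IF_SUITABLE_CATEGORIES or probe in _IF_SUITABLE_EXCEPTIONS
        rows.append({
            "probe_id": probe,
            "category": cat,
            "myocyte_expressed": myo,
            "if_suitable": if_ok,
            "contamination_marker": probe in CONTAMINATION_MARKERS,
        })
    return ProbePanel(pd.DataFrame(rows))


def _generic_panel(n_probes: int) -> ProbePanel:
    """Anonymous panel used when a non-79-probe simulation is requested."""
    ids = [f"P{i + 1:03d}" for i in range(n_probes)]
    n_mark = min(8, n_probes)
    rows = [{
        "probe_id": pid,
        "category": "synthetic",
        "myocyte_expressed": (i % 2 == 0),
        "if_suitable": (i % 4 != 3),
        "contamination_marker": i < n_mark,
    } for i, pid in enumerate(ids)]
    return ProbePanel(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Planted fixed effects, all in log2 units.

    ``sarcoid`` / ``infiltrate`` / ``explant`` map probe -> log2 fold change
    for the corresponding indicator covariate; ``gradient`` maps probe -> the
    per-distance-step slope; ``compartment_offsets`` maps
    ``(probe, compartment)`` -> log2 offset relative to the ROI core profile;
    ``granuloma_offsets`` maps probe -> log2 offset applied inside granuloma
    ROIs (granulomas are dense immune lesions, so immune lineage markers are
    boosted there by default).
    """

    sarcoid: dict[str, float] = field(default_factory=dict)
    infiltrate: dict[str, float] = field(default_factory=dict)
    explant: dict[str, float] = field(default_factory=dict)
    gradient: dict[str, float] = field(default_factory=dict)
    compartment_offsets: dict[tuple[str, str], float] = field(default_factory=dict)
    granuloma_offsets: dict[str, float] = field(default_factory=dict)

    def validate(self, probes: set[str]) -> None:
        for name, mapping in (("sarcoid", self.sarcoid), ("infiltrate", self.infiltrate),
                              ("explant", self.explant), ("gradient", self.gradient),
                              ("granuloma_offsets", self.granuloma_offsets)):
            unknown = set(mapping) - probes
            if unknown:
                raise ValidationError(f"effect set {name!r} references unknown probes: {sorted(unknown)[:5]}")
            if not all(np.isfinite(list(mapping.values()) or [0.0])):
                raise ValidationError(f"effect set {name!r} contains non-finite values")
        unknown = {p for p, _ in self.compartment_offsets} - probes
        if unknown:
            raise ValidationError(f"compartment_offsets reference unknown probes: {sorted(unknown)[:5]}")


@dataclass
class ContaminationSpec:
    """Stromal contamination of myocyte segments.

    The mixing fraction ``c`` of each myocyte segment is drawn from
    Beta(``beta_a``, ``beta_b``); ``marker_stroma_boost`` is a log2 offset
    added to the contamination-marker probes in stroma profiles, making
    contamination detectable by rank-based marker scoring.
    """

    beta_a: float = 1.0
    beta_b: float = 45.0
    marker_stroma_boost: float = 1.5

    def validate(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValidationError("contamination Beta parameters must be > 0")
        if self.marker_stroma_boost < 0:
            raise ValidationError("marker_stroma_boost must be >= 0")


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort. Seed is mandatory."""

    seed: int
    n_donors_per_class: dict[str, int] = field(default_factory=dict)
    rois_per_donor: dict[str, int] = field(default_factory=dict)
    compartments_per_roi: tuple[str, ...] = ("full_roi", "myocyte", "stroma")
    n_probes: int = 79
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    donor_sd: float = 0.5
    residual_sd: float = 0.5
    effects: EffectSpec = field(default_factory=EffectSpec)
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    # area weights of the myocyte/stroma/vascular compartments in a full-ROI
    # segment (a full-ROI profile incorporates all expression within the ROI)
    full_roi_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    # extra per-segment log2 SD inside granuloma ROIs (granulomas are far more
    # heterogeneous than bland parenchyma, within and between donors)
    granuloma_extra_sd: float = 0.5
    # donor-level spread of granuloma immune-offset intensity: granulomas of
    # one donor share an activation state ("age"), donors differ in it
    granuloma_donor_sd: float = 0.8
    infiltrate_rate: float = 0.2
    qc_low_nuclei_rate: float = 0.01

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("simulation seed is required")
        for name, val in (("baseline_log_sd", self.baseline_log_sd),
                          ("donor_sd", self.donor_sd),
                          ("residual_sd", self.residual_sd),
                          ("granuloma_extra_sd", self.granuloma_extra_sd)):
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(v < 0 for v in self.n_donors_per_class.values()):
            raise ValidationError("donor counts must be >= 0")
        if any(v < 0 for v in self.rois_per_donor.values()):
            raise ValidationError("ROI counts must be >= 0")
        if not 0 <= self.infiltrate_rate <= 1:
            raise ValidationError("infiltrate_rate must be in [0, 1]")
        self.contamination.validate()


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the generated cohort.

    ``latent_log2_mean`` holds the pre-noise log2 mean of every probe x
    segment cell (after compartment mixing); ``donor_effects`` the random
    intercepts; ``contamination_fraction`` the Beta draw per myocyte
    segment; ``qc_low_nuclei`` the segments planted as QC failures.
    """

    latent_log2_mean: pd.DataFrame
    donor_effects: pd.Series
    contamination_fraction: pd.Series
    qc_low_nuclei: list[str]
    effects: EffectSpec
    config: SimulationConfig


# ---------------------------------------------------------------------------
# default study configuration
# ---------------------------------------------------------------------------

def default_study_config(seed: int = 0) -> SimulationConfig:
    """Default synthetic cohort: the study design at roughly half scale.

    Five cohort classes (7 sarcoid biopsy, 12 sarcoid explant, 2+2+2
    controls), two granuloma / one peri-granuloma / three granuloma-remote /
    one vascular ROI per sarcoid donor, parenchymal ROIs segmented into
    full-ROI + myocyte + stroma AOIs, and the 79-probe panel — ~345 segments
    in total. Effect sizes follow the qualitative direction of the cardiac
    sarcoidosis findings the package models (Treg and MHC markers up in
    bland sarcoid parenchyma, immune effectors up with infiltrates, fibrosis
    markers up in explants, MHC/adhesion markers decaying with distance from
    granulomas).
    """
    panel = default_panel()
    effects = EffectSpec(
        sarcoid={
            "HLA-DR": 1.2, "FOXP3": 1.2, "CD25": 1.2, "GITR": 1.2, "CD34": 1.2,
            "Histone-H3": 1.2, "VISTA": 1.2, "CD56": 1.2,
            "CD45RO": -1.2, "PD-L2": -1.2, "CD95": -1.2,
            "Phospho-GSK3A": -1.2, "Phospho-GSK3B": -1.2,
        },
        infiltrate={p: 1.5 for p in ("CD3", "CD4", "CD8", "CD68", "CD163", "GZMA", "CD14", "CD45")},
        explant={
            "Tim-3": 1.0, "FAP-alpha": 1.0, "SMA": 1.0, "ICOS": 1.0, "CD127": 1.0, "CD20": 1.0,
            "VISTA": -1.0, "Histone-H3": -1.0, "MEK1": -1.0, "CD3": -1.0, "CD163": -1.0,
            "PD-L1": -1.0, "STING": -1.0,
        },
        gradient={
            # negative slope: expression decays as distance from granulomas grows
            "HLA-DR": -0.5, "Beta-2-microglobulin": -0.5, "CD11c": -0.5, "CD45RO": -0.5,
            "CD44": -0.5, "Fibronectin": -0.5, "ARG1": -0.5, "CD40": -0.5, "PD-L1": -0.5,
            "Tim-3": 0.3,
        },
        compartment_offsets=_default_compartment_offsets(panel),
        granuloma_offsets=_default_granuloma_offsets(panel),
    )
    return SimulationConfig(
        seed=seed,
        n_donors_per_class={"cs_biopsy": 7, "cs_explant": 12,
                            "control_nicm": 2, "control_nf": 2, "control_txp": 2},
        rois_per_donor={"granuloma": 2, "peri_granuloma": 1, "granuloma_remote": 3, "vascular": 1},
        compartments_per_roi=("full_roi", "myocyte", "stroma"),
        n_probes=79,
        effects=effects,
    )


def _default_compartment_offsets(panel: ProbePanel) -> dict[tuple[str, str], float]:
    offsets: dict[tuple[str, str], float] = {}
    cats = panel.table["category"]
    markers = set(panel.contamination_markers)
    for probe in panel.probe_ids:
        cat = cats[probe]
        if cat in ("immune_lineage", "immune_activation", "checkpoint", "antigen_presentation"):
            offsets[(probe, "stroma")] = 1.0
            offsets[(probe, "vascular")] = 0.5
            # dedicated immune-cell markers are essentially absent from true
            # myocyte tissue; broader immune-class probes are merely depleted
            offsets[(probe, "myocyte")] = -3.5 if probe in markers else -2.0
        elif cat == "structural":
            offsets[(probe, "myocyte")] = 2.0
            offsets[(probe, "stroma")] = -2.0
            offsets[(probe, "vascular")] = -1.0
        elif cat == "stroma_vascular":
            offsets[(probe, "stroma")] = 1.5
            offsets[(probe, "vascular")] = 1.5
            offsets[(probe, "myocyte")] = -1.0
    return offsets


def _default_granuloma_offsets(panel: ProbePanel) -> dict[str, float]:
    top = ("CD68", "HLA-DR", "CD11c", "CD45", "CD3", "IDO1", "CD44", "CD40", "CD66b", "BCL6")
    offsets = {p: 2.0 for p in top}
    cats = panel.table["category"]
    for probe in panel.probe_ids:
        if probe not in offsets and cats[probe] in ("immune_lineage", "immune_activation",
                                                    "checkpoint", "antigen_presentation"):
            offsets[probe] = 1.0
    return offsets


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_DISTANCE_STEP = {"granuloma": 0.0, "peri_granuloma": 1.0, "granuloma_remote": 2.0}


def simulate_cohort(config: SimulationConfig):
    """Generate a cohort: returns (CountMatrix, SegmentAnnotation, ProbePanel, GroundTruth).

    Identical (config, seed) pairs produce bit-identical output.
    """
    config.validate()
    panel = default_panel() if config.n_probes == 79 else _generic_panel(config.n_probes)
    probes = panel.probe_ids
    probe_set = set(probes)
    config.effects.validate(probe_set)

    cs_donors = sum(config.n_donors_per_class.get(c, 0) for c in CS_CLASSES)
    if config.effects.sarcoid and cs_donors == 0:
        raise ValidationError("sarcoid effects planted but no sarcoid donors configured")
    if config.effects.explant and config.n_donors_per_class.get("cs_explant", 0) == 0:
        raise ValidationError("explant effects planted but no cs_explant donors configured")
    total_donors = sum(config.n_donors_per_class.values())
    if total_donors == 0:
        raise ValidationError("no donors configured")

    rng = np.random.default_rng(config.seed)
    rng_donor, rng_struct, rng_contam, rng_noise, rng_counts, rng_qc = rng.spawn(6)

    # per-probe baselines are deterministic in the seed via rng_donor stream
    baseline = config.baseline_log_mean + config.baseline_log_sd * rng_donor.standard_normal(len(probes))
    base = pd.Series(baseline, index=probes)

    # donors and their random intercepts
    donors: list[tuple[str, str]] = []  # (donor_id, cohort_class)
    for cls in ("cs_biopsy", "cs_explant", "control_nicm", "control_nf", "control_txp"):
        for k in range(config.n_donors_per_class.get(cls, 0)):
            donors.append((f"{cls}_{k + 1:02d}", cls))
    d_eff = pd.Series(config.donor_sd * rng_donor.standard_normal(len(donors)),
                      index=[d for d, _ in donors])
    # per-donor multiplier on the granuloma immune offsets (shared by all
    # granulomas of one donor, so within-donor granulomas resemble each other)
    gran_intensity = pd.Series(
        1.0 + config.granuloma_donor_sd * rng_donor.standard_normal(len(donors)),
        index=[d for d, _ in donors])

    eff = config.effects
    vec = {name: np.array([mapping.get(p, 0.0) for p in probes])
           for name, mapping in (("sarcoid", eff.sarcoid), ("infiltrate", eff.infiltrate),
                                 ("explant", eff.explant), ("gradient", eff.gradient),
                                 ("granuloma", eff.granuloma_offsets))}
    comp_off = {c: np.array([eff.compartment_offsets.get((p, c), 0.0) for p in probes])
                for c in ("full_roi", "myocyte", "stroma", "vascular")}
    stroma_boost = np.array([config.contamination.marker_stroma_boost
                             if panel.table.loc[p, "contamination_marker"] else 0.0
                             for p in probes])
    w_m, w_s, w_v = config.full_roi_weights

    seg_rows: list[dict] = []
    latent_cols: list[np.ndarray] = []
    extra_sd: list[float] = []
    contam_frac: dict[str, float] = {}

    for donor_id, cls in donors:
        sarcoid = cls in CS_CLASSES
        explant = cls == "cs_explant"
        d_j = d_eff[donor_id]
        for region, n_rois in sorted(config.rois_per_donor.items()):
            if region not in _DISTANCE_STEP and region != "vascular":
                raise ValidationError(f"unknown region class in rois_per_donor: {region!r}")
            if not sarcoid and region in ("granuloma", "peri_granuloma"):
                continue  # controls have no granulomas, hence no granuloma-proximal regions
            for r in range(n_rois):
                roi_id = f"{donor_id}_{region}_{r + 1}"
                infiltrate = False
                if sarcoid and region in ("peri_granuloma", "granuloma_remote"):
                    infiltrate = bool(rng_struct.random() < config.infiltrate_rate)
                mu_core = (base.to_numpy() + d_j
                           + (vec["sarcoid"] if sarcoid else 0.0)
                           + (vec["infiltrate"] if infiltrate else 0.0)
                           + (vec["explant"] if explant else 0.0))
                if sarcoid and region in _DISTANCE_STEP:
                    mu_core = mu_core + vec["gradient"] * _DISTANCE_STEP[region]

                if region == "granuloma":
                    mu = mu_core + vec["granuloma"] * gran_intensity[donor_id] + comp_off["full_roi"]
                    _emit(seg_rows, latent_cols, extra_sd, roi_id, donor_id, cls, region,
                          "full_roi", infiltrate, mu, config.granuloma_extra_sd)
                elif region == "vascular":
                    mu = mu_core + comp_off["vascular"]
                    _emit(seg_rows, latent_cols, extra_sd, roi_id, donor_id, cls, region,
                          "vascular", infiltrate, mu, 0.0)
                else:
                    mu_myo = mu_core + comp_off["myocyte"]
                    mu_str = mu_core + comp_off["stroma"] + stroma_boost
                    mu_vas = mu_core + comp_off["vascular"]
                    lin = {"myocyte": 2.0 ** mu_myo, "stroma": 2.0 ** mu_str,
                           "vascular": 2.0 ** mu_vas}
                    for comp in config.compartments_per_roi:
                        if comp == "full_roi":
                            mu = np.log2(w_m * lin["myocyte"] + w_s * lin["stroma"]
                                         + w_v * lin["vascular"])
                        elif comp == "myocyte":
                            c = float(rng_contam.beta(config.contamination.beta_a,
                                                      config.contamination.beta_b))
                            mu = np.log2((1.0 - c) * lin["myocyte"] + c * lin["stroma"])
                            contam_frac[f"{roi_id}_{comp}"] = c
                        else:
                            mu = np.log2(lin[comp])
                        _emit(seg_rows, latent_cols, extra_sd, roi_id, donor_id, cls, region,
                              comp, infiltrate, mu, 0.0)

    if not seg_rows:
        raise ValidationError("configuration generates no segments")

    latent = np.column_stack(latent_cols)  # probes x segments
    seg_ids = [row["aoi_id"] for row in seg_rows]
    sd = np.sqrt(config.residual_sd ** 2 + np.asarray(extra_sd) ** 2)  # per segment
    eps = rng_noise.standard_normal(latent.shape) * sd[None, :]
    lam = 2.0 ** (latent + eps)
    counts = rng_counts.poisson(lam).astype(float)

    # QC covariates; a small fraction of segments is planted as low-nuclei failures
    n_seg = len(seg_rows)
    nuclei = rng_qc.poisson(250, n_seg)
    low = rng_qc.random(n_seg) < config.qc_low_nuclei_rate
    nuclei[low] = rng_qc.poisson(8, int(low.sum()))
    area = rng_qc.uniform(4000, 30000, n_seg)
    density = rng_qc.uniform(0.3, 2.0, n_seg)
    background = rng_qc.uniform(0.5, 2.0, n_seg)
    for i, row in enumerate(seg_rows):
        row.update(nuclei_count=int(nuclei[i]), surface_area=float(area[i]),
                   binding_density=float(density[i]), background_signal=float(background[i]))

    ann = SegmentAnnotation(pd.DataFrame(seg_rows))
    matrix = CountMatrix(pd.DataFrame(counts, index=probes, columns=seg_ids))
    truth = GroundTruth(
        latent_log2_mean=pd.DataFrame(latent, index=probes, columns=seg_ids),
        donor_effects=d_eff,
        contamination_fraction=pd.Series(contam_frac, dtype=float),
        qc_low_nuclei=[seg_ids[i] for i in np.flatnonzero(low)],
        effects=eff,
        config=config,
    )
    return matrix, ann, panel, truth


def _emit(seg_rows, latent_cols, extra_sd, roi_id, donor_id, cls, region, comp,
          infiltrate, mu, seg_extra_sd) -> None:
    seg_rows.append({
        "aoi_id": f"{roi_id}_{comp}", "roi_id": roi_id, "donor_id": donor_id,
        "cohort_class": cls, "region_class": region, "compartment": comp,
        "infiltrate": infiltrate,
    })
    latent_cols.append(mu)
    extra_sd.append(seg_extra_sd)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, out_dir) -> Path:
    """Simulate a cohort and write counts/annotation/panel plus a manifest.

    The ground truth is written alongside as ``truth.json`` (effect
    assignments, donor effects, contamination fractions); the latent mean
    matrix is written as ``latent.tsv``. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, ann, panel, truth = simulate_cohort(config)
    write_table(matrix, out_dir / "counts.tsv")
    write_table(ann, out_dir / "annotation.tsv")
    write_table(panel, out_dir / "panel.tsv")
    truth.latent_log2_mean.rename_axis("probe_id").to_csv(out_dir / "latent.tsv", sep="\t",
                                                          float_format="%.12g")

    import json

    truth_blob = {
        "seed": config.seed,
        "donor_effects": {k: float(v) for k, v in truth.donor_effects.items()},
        "contamination_fraction": {k: float(v) for k, v in truth.contamination_fraction.items()},
        "qc_low_nuclei": truth.qc_low_nuclei,
        "effects": {
            "sarcoid": truth.effects.sarcoid,
            "infiltrate": truth.effects.infiltrate,
            "explant": truth.effects.explant,
            "gradient": truth.effects.gradient,
            "granuloma_offsets": truth.effects.granuloma_offsets,
        },
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_blob, fh, indent=1, sort_keys=True)
    return write_manifest(out_dir, extra={"truth": "truth.json", "latent": "latent.tsv"})


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
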