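import numpy as np
import pandas as pd
import pytest

import sarcospace as ss
from sarcospace.simulate import default_panel


@pytest.fixture(scope="session")
def panel79() -> ss.ProbePanel:
    return default_panel()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across tests (seed 11)."""
    return ss.simulate_cohort(ss.default_study_config(seed=11))


@pytest.fixture(scope="session")
def normalized_cohort(cohort):
    matrix, ann, panel, truth = cohort
    return ss.quantile_normalize(matrix), ann, panel, truth


@pytest.fixture()
def tiny_panel() -> ss.ProbePanel:
    return ss.ProbePanel(pd.DataFrame({
        "probe_id": ["A", "B", "C", "D", "E"],
        "category": ["x", "x", "y", "y", "y"],
        "myocyte_expressed": [True, True, False, False, True],
        "if_suitable": [True, True, True, False, True],
        "contamination_marker": [False, False, True, True, False],
    }))


def make_annotation(n, donors=None, cohort_class="cs_biopsy", region="granuloma_remote",
                    compartment="full_roi", infiltrate=False, prefix="S"):
    """Minimal valid annotation frame for ad-hoc matrices."""
    ids = [f"{prefix}{i}" for i in range(n)]
    return ss.SegmentAnnotation(pd.DataFrame({
        "aoi_id": ids,
        "roi_id": [f"R{i}" for i in range(n)],
        "donor_id": donors if donors is not None else [f"D{i}" for i in range(n)],
        "cohort_class": cohort_class,
        "region_class": region,
        "compartment": compartment,
        "infiltrate": infiltrate,
        "nuclei_count": 100,
        "surface_area": 5000.0,
        "binding_density": 1.0,
        "background_signal": 1.0,
    }))
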