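import numpy as np
import pandas as pd
import pytest

from stereosyn.sampling import SamplingPlan
from stereosyn.study import ingest_table1
from stereosyn.tissue import compact_tissue_model


@pytest.fixture(scope="session")
def table1():
    """Typed per-animal summaries from the packaged individual-values table."""
    return ingest_table1()


@pytest.fixture(scope="session")
def control_summaries(table1):
    return [s for s in table1 if s.group == "control"]


@pytest.fixture(scope="session")
def stress_summaries(table1):
    return [s for s in table1 if s.group == "stress"]


@pytest.fixture()
def compact_model():
    """Single-band block used for estimator-recovery experiments."""
    return compact_tissue_model()


@pytest.fixture()
def compact_plan():
    return SamplingPlan(sections_per_animal=6, fields_per_layer_per_section=4)


def segment_row(x1, y1, x2, y2, type_="asymmetric", length_nm=None, perforated=False,
                object_id=0):
    """One profile-table row for a hand-placed trace segment."""
    if length_nm is None:
        length_nm = float(np.hypot(x2 - x1, y2 - y1) * 1000.0)
    return {
        "object_id": object_id,
        "type": type_,
        "layer": "III",
        "x_um": (x1 + x2) / 2,
        "y_um": (y1 + y2) / 2,
        "x1_um": x1,
        "y1_um": y1,
        "x2_um": x2,
        "y2_um": y2,
        "junction_length_nm": length_nm,
        "terminal_membrane_length_nm": 2.0 * length_nm,
        "radius_um": 0.0,
        "perforated": perforated,
    }


def profile_table(rows):
    return pd.DataFrame(rows)
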