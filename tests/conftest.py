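import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers module

from mavelayers.containers import FrequencyMatrix
from mavelayers.synthetic import LibraryDesign, generate_variant_library


@pytest.fixture(scope="session")
def tiny_design() -> LibraryDesign:
    """Three-codon template with a single-codon ROI (reference ATG)."""
    return LibraryDesign(roi_list=(("ROI1", 2, 2),), template_cds="GCTATGCAT")


@pytest.fixture(scope="session")
def tiny_library(tiny_design):
    return generate_variant_library(tiny_design)


@pytest.fixture
def small_sheet() -> pd.DataFrame:
    rows = []
    for readout in ("gDNA", "totalRNA"):
        for bio in (1, 2):
            for tech in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{readout}_b{bio}_t{tech}",
                        "readout": readout,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "batch": f"B{bio}",
                    }
                )
    return pd.DataFrame(rows)


def make_fm(values, columns, index=None, transform="raw_freq") -> FrequencyMatrix:
    values = np.asarray(values, dtype=float)
    index = index if index is not None else [f"v{i}" for i in range(values.shape[0])]
    return FrequencyMatrix(pd.DataFrame(values, index=index, columns=columns), transform)
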