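import numpy as np
import pandas as pd
import pytest

from longvol import SampleMetadata


def make_metadata(records, state_column="state", subject_column="subject",
                  numeric_columns=()):
    """Build SampleMetadata from a list of dicts keyed by 'sample-id'."""
    frame = pd.DataFrame(records).set_index("sample-id")
    types = {}
    for c in frame.columns:
        if c == state_column or c in numeric_columns or pd.api.types.is_numeric_dtype(frame[c]):
            types[c] = "numeric"
            frame[c] = pd.to_numeric(frame[c], errors="coerce")
        else:
            types[c] = "categorical"
    return SampleMetadata(frame, state_column, subject_column, types)


@pytest.fixture
def metadata_factory():
    return make_metadata


def random_cohort_frame(rng, n_subjects=20, states=(0, 1, 2, 3, 4), missing=0.0):
    """Random long-format records with optional per-observation missingness."""
    records = []
    for k in range(n_subjects):
        subject = f"S{k:03d}"
        for t in states:
            if rng.random() < missing:
                continue
            records.append(
                {
                    "sample-id": f"{subject}.{t}",
                    "subject": subject,
                    "state": float(t),
                    "value": float(rng.normal()),
                }
            )
    return records


def random_distance_matrix(rng, ids):
    n = len(ids)
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return ids, m
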