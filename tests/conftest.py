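import numpy as np
import pandas as pd
import pytest

from biotpscreen.feature_model import FeatureTable, SampleMetadata, SampleSheet

DOSES = (0.050, 0.49, 12.0, 62.0, 4550.0, 46540.0)


def make_sheet(doses=DOSES, replicates=12, n_controls=12, excluded=()):
    """Full-design sample sheet: len(doses) dose groups + positive and
    negative controls."""
    samples = []
    for di, dose in enumerate(doses):
        for r in range(replicates):
            sid = f"D{di + 1}_R{r + 1:02d}"
            samples.append(
                SampleMetadata(sid, "dose", dose, r + 1, excluded=sid in excluded)
            )
    for prefix, group in (("PC", "positive_control"), ("NC", "negative_control")):
        for r in range(n_controls):
            sid = f"{prefix}_R{r + 1:02d}"
            samples.append(
                SampleMetadata(sid, group, 0.0, r + 1, excluded=sid in excluded)
            )
    return SampleSheet(samples)


def make_table(feature_areas, masses=None, rts=None, sheet=None):
    """FeatureTable from {feature_id: {sample_id: area}}."""
    fids = list(feature_areas)
    masses = masses or {f: 200.0 + i for i, f in enumerate(fids)}
    rts = rts or {f: 1.0 for f in fids}
    meta = pd.DataFrame(
        {
            "neutral_mass": [masses[f] for f in fids],
            "rt_min": [rts[f] for f in fids],
        },
        index=pd.Index(fids, name="feature_id"),
    )
    columns = sheet.sample_ids if sheet is not None else None
    areas = pd.DataFrame(
        [feature_areas[f] for f in fids], index=meta.index, columns=columns, dtype=float
    )
    return FeatureTable(meta, areas)


@pytest.fixture(scope="session")
def sheet96():
    return make_sheet()


@pytest.fixture(scope="session")
def small_sheet():
    return make_sheet(doses=(1.0, 10.0, 100.0), replicates=3, n_controls=2)
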