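import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oligomir.locus import ArrayPanel, DifferentialMirSet, MirRecord
from oligomir.synthetic import SynthConfig


@pytest.fixture
def small_cfg():
    """Scaled-down study conditions for fast generator tests."""
    return dataclasses.replace(
        SynthConfig(seed=7),
        n_array_mirs=40,
        n_locus_mirs=8,
        n_diff=10,
        n_genes=300,
        n_pathways=9,
        pathway_size_range=(10, 20),
        n_probes=400,
        n_suppressed_per_mir=40,
        n_patients_per_group=12,
    )


@pytest.fixture
def toy_panel():
    """10-miR panel with 4 locus members (the closed-form oracle instance)."""
    records = []
    for i in range(10):
        if i < 4:
            records.append(
                MirRecord(f"m{i}", "chr14", 101_000_000 + i * 1000,
                          101_000_000 + i * 1000 + 80, "14q32")
            )
        else:
            records.append(MirRecord(f"m{i}", "chr2", 1_000 + i, 1_080 + i, ""))
    return ArrayPanel(records=tuple(records), name="toy")


def make_diff(mir_ids, label="test"):
    return DifferentialMirSet(dataset_label=label, mir_ids=frozenset(mir_ids))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
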