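import numpy as np
import pytest

from idscn.atlas import GMVTable, Region, RegionAtlas, SubjectRecord
from idscn.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def toy_atlas():
    """4 regions, pairs (1<->3) and (2<->4), one subnet, 1/2 left, 3/4 right."""
    return RegionAtlas(
        (
            Region(1, "L.a", "left", 3, "SMN"),
            Region(2, "L.b", "left", 4, "SMN"),
            Region(3, "R.a", "right", 1, "SMN"),
            Region(4, "R.b", "right", 2, "SMN"),
        )
    )


@pytest.fixture
def small_cohort():
    """Two-site, 20-region null cohort (no injected signal)."""
    cfg = SimulationConfig(
        n_regions=20,
        sites=("A", "B"),
        n_controls_per_site=(30, 30),
        n_patients_per_site=(10, 10),
        site_offsets=(0.0, 0.1),
        site_scales=(1.0, 1.05),
        seed=11,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


def make_manual_cohort(values, atlas, groups=None, sites=None, lesions=None):
    """Assemble a GMVTable from a raw value matrix with default metadata."""
    n = values.shape[0]
    groups = groups or ["control"] * n
    sites = sites or ["A"] * n
    rng = np.random.default_rng(0)
    subjects = []
    for i in range(n):
        lesion = "none" if groups[i] == "control" else (
            lesions[i] if lesions else "left")
        subjects.append(
            SubjectRecord(
                subject_id=f"s{i:03d}",
                group=groups[i],
                site=sites[i],
                age=float(50 + rng.uniform(-5, 5)),
                gender="M" if i % 2 else "F",
                tiv=float(1450 + rng.normal(0, 50)),
                lesion_side=lesion,
            )
        )
    return GMVTable(subjects, values, atlas)
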