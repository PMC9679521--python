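import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsrkit.discretization import fit_bins
from tsrkit.keys import pooled_geometry
from tsrkit.labeling import build_label_scheme
from tsrkit.synthetic_data import (
    PlantedTriple,
    SyntheticSpec,
    generate_hierarchy,
    generate_structure,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ungrouped():
    return build_label_scheme(grouping=False)


@pytest.fixture(scope="session")
def grouped():
    return build_label_scheme(grouping=True)


@pytest.fixture(scope="session")
def cys_triad_structure():
    """50-residue chain with a planted Cys triad at known geometry."""
    spec = SyntheticSpec(
        n_residues=50,
        seed=7,
        planted=(
            PlantedTriple(codes=("CYS", "CYS", "CYS"), positions=(20, 22, 25),
                          max_dist=8.0, theta=55.0),
        ),
    )
    structure, pdb_text = generate_structure(spec)
    return structure, pdb_text, spec


@pytest.fixture(scope="session")
def fitted_bins(cys_triad_structure, ungrouped):
    structure, _, _ = cys_triad_structure
    maxdist_values, theta_values = pooled_geometry([structure], ungrouped)
    return (
        fit_bins(theta_values, 29, variable="theta"),
        fit_bins(maxdist_values, 35, variable="maxdist"),
    )


@pytest.fixture(scope="session")
def no_cys_structure():
    """Structure whose label orders agree between the two schemes
    (no mixed-Cys triangles): His/Trp motifs on an Ala/Gly/Ser background."""
    spec = SyntheticSpec(
        n_residues=80,
        seed=3,
        planted=(
            PlantedTriple(("HIS", "HIS", "HIS"), (20, 22, 25), 8.0, 50.0),
            PlantedTriple(("TRP", "TRP", "TRP"), (50, 52, 55), 8.5, 60.0),
        ),
        composition={"ALA": 1.0, "GLY": 1.0, "SER": 1.0},
    )
    structure, _ = generate_structure(spec)
    return structure


@pytest.fixture(scope="session")
def small_hierarchy():
    """Compact hierarchy dataset for mining tests (2 classes x 2 members)."""
    return generate_hierarchy(
        n_classes=2, n_per_class=2, n_residues=60, seed=11,
        shared_motifs=(
            PlantedTriple(("MET", "MET", "MET"), (50, 52, 55), 9.0, 65.0),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
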