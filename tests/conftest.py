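import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hrpfkit import fixtures

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy64():
    return fixtures.make_toy_structure(64, seed=1)


@pytest.fixture(scope="session")
def noiseless_spec():
    return fixtures.SimulationSpec(seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_dataset(toy64, noiseless_spec):
    return fixtures.simulate_labeling(toy64, noiseless_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random proper rotation matrix from a normalized quaternion."""
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


def write_reactivity(spec, path):
    pd.DataFrame(
        {"restype": list(spec.reactivity), "reactivity": list(spec.reactivity.values())}
    ).to_csv(path, index=False)
    return str(path)


@pytest.fixture()
def pipeline_inputs(tmp_path, toy64, noiseless_spec, noiseless_dataset):
    """Noiseless labeling study written to disk, ready for run_pipeline."""
    from hrpfkit.topography import write_structures
    from hrpfkit.workbench import RunConfig

    paths = noiseless_dataset.write(tmp_path)
    decoys = fixtures.make_decoys(toy64, sigma=2.0, count=8, seed=3)
    write_structures([toy64] + [d for d, _ in decoys], tmp_path / "models.pdb")
    write_structures([toy64], tmp_path / "reference.pdb")
    reactivity = write_reactivity(noiseless_spec, tmp_path / "reactivity.csv")
    config = RunConfig(
        isotopologue_table=paths["isotopologues"],
        fragment_table=paths["fragments"],
        dose_table=paths["doses"],
        reactivity_table=reactivity,
        structures=str(tmp_path / "models.pdb"),
        reference_structure=str(tmp_path / "reference.pdb"),
        calibration_m=noiseless_spec.calibration_m,
        calibration_b=noiseless_spec.calibration_b,
        funnel_top_n=5,
    )
    return config, tmp_path
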