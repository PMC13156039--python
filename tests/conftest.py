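import warnings

import pytest

import drgcomm as dc

# the background-interval clamp warning fires constantly at desk scale
# (2,000-gene universes cannot fill 20 x 100 background draws) and is
# asserted explicitly where it matters
warnings.filterwarnings("ignore", message="background intervals hold as few")


@pytest.fixture(scope="session")
def desk_sim():
    """Full stated world at desk scale: 15 types, 8 timepoints, planted
    communication programs, ISG-like module, monocyte influx."""
    return dc.simulate_dataset(dc.default_config(seed=7))


@pytest.fixture(scope="session")
def null_desk():
    """Same roster with nothing planted: marker programs only."""
    return dc.simulate_dataset(dc.null_config(seed=7))


@pytest.fixture(scope="session")
def planted_small():
    """Compact planted world for interactome tests: 6 types, 2 timepoints."""
    cfg = dc.default_config(
        seed=1,
        n_cell_types=6,
        cells_per_type_per_timepoint=100,
        timepoints=(0.0, 0.5),
        n_genes=1500,
    )
    return dc.simulate_dataset(cfg)
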