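import numpy as np
import pytest

from cytopheno import synthetic
from cytopheno.synthetic import well_separated_preset


@pytest.fixture(scope="session")
def preset_small():
    """Small well-separated study: 6 models x 400 cells, 4 phenotypes."""
    templates, comps = well_separated_preset(6, 4, seed=11)
    table, truth = synthetic.simulate_cell_table(templates, comps, cells_per_model=400, seed=11)
    return templates, comps, table, truth


@pytest.fixture(scope="session")
def blobs3():
    """Three balanced, strongly separated human phenotypes (no stroma)."""
    templates = synthetic.make_templates(3, separation=12, seed=2, include_stroma=False)
    import pandas as pd

    comps = pd.DataFrame(
        [[1 / 3, 1 / 3, 1 / 3]], index=["M1"], columns=[t.phenotype_id for t in templates]
    )
    table, truth = synthetic.simulate_cell_table(templates, comps, cells_per_model=600, seed=2)
    return templates, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
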