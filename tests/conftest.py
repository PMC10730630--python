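import numpy as np
import pytest

import hcscreen as h


@pytest.fixture(scope="session")
def small_screen():
    """Tiny duplicate screen (2 plates, 200 conditions, 32 features) with truth."""
    cfg = h.ScreenSimConfig(n_plates=2, n_conditions=200, n_features=32, seed=11)
    table, layouts, truth = h.generate_feature_screen(cfg)
    return cfg, table, layouts, truth


@pytest.fixture(scope="session")
def aligned_screen(small_screen):
    cfg, table, layouts, truth = small_screen
    corrected = h.spatial_correct(table, layouts)
    aligned, stats = h.robust_z_align(corrected, layouts)
    return cfg, aligned, layouts, truth, stats


@pytest.fixture(scope="session")
def clean_layout():
    """One fully-populated 384-well layout, F=4, C=4."""
    wells = {
        h.WellAddress(r, c): (f"cond_{r}{c}", h.ControlRole.sample)
        for r in "ABCDEFGHIJKLMNOP"
        for c in range(1, 25)
    }
    return h.PlateLayout("P01", "R1", wells, fields_per_well=4, channels=4)


def make_table(values, plates=("P01",), replicates=("R1",), wells=None):
    """Feature table from a (n_rows, D) array with a simple synthetic index."""
    values = np.asarray(values, dtype=float)
    if wells is None:
        wells = [f"A{i + 1:02d}" for i in range(values.shape[0])]
    index = [(plates[0], replicates[0], w) for w in wells]
    return h.FeatureTable.from_array(values, index)
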