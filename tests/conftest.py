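import numpy as np
import pytest

from midaskit import synth
from midaskit.pipeline import matrix_from_fold_changes
from midaskit.quant import fold_change_table
from midaskit.stats import score_screen


@pytest.fixture(scope="session")
def preset_screen():
    """DHTKD1-like spiked scenario at default noise: table + truth + scenario."""
    scenario = synth.preset_dhtkd1_like(seed=2020)
    table, truth = synth.generate_screen(
        scenario.config,
        scenario.spikes,
        library=scenario.library,
        protein_ids=scenario.protein_ids,
    )
    return scenario, table, truth


@pytest.fixture(scope="session")
def preset_scored(preset_screen):
    """Fold changes + scored results for the preset screen."""
    _, table, _ = preset_screen
    fc = fold_change_table(table)
    results, corrected, report = score_screen(matrix_from_fold_changes(fc))
    return fc, results, corrected, report


@pytest.fixture(scope="session")
def null_screen():
    """One pure-null screen at the default generator conditions."""
    config = synth.GeneratorConfig(seed=11)
    table, truth = synth.generate_screen(config)
    return config, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
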