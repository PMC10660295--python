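import json
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fingerprint_pins():
    """Pinned fingerprint vectors for 24 drug-like molecules (regression
    reference for determinism across versions/processes)."""
    return json.loads((DATA_DIR / "fingerprint_pins.json").read_text())


@pytest.fixture(scope="session")
def drug_compounds():
    from pairsyn.synthetic import fixture_compounds

    return fixture_compounds()


@pytest.fixture(scope="session")
def small_screen():
    """A 20-compound, single-cell-line synthetic screen with replicate
    ceiling 0.9 — the shared small workload for pipeline tests."""
    from pairsyn.synthetic import SyntheticScenario, generate_screen

    scenario = SyntheticScenario.default(n_compounds=20, n_cell_lines=1, seed=7)
    return scenario, generate_screen(scenario)


@pytest.fixture()
def tiny_mlp_config():
    from pairsyn.models import MLPConfig

    return MLPConfig(hidden_width=64, epochs=30, batch_size=128, seed=0)
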