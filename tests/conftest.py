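import numpy as np
import pytest

import chromofrag as cf

# the worked urea example: four functional groups on one backbone
UREA_EXAMPLE = "CN(C)C(=O)NCCC1C=CC(Cl)C(Cl)C1"
ALLYLBENZENE = "C=CCc1ccccc1"
CYCLOPENTENE = "C1=CCCC1"


@pytest.fixture(scope="session")
def small_oracle():
    """200 molecules with context effects and observation noise."""
    spec = cf.OracleSpec(n=200, seed=42)
    records, truth = cf.generate_molecules(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def library_values():
    """Canonical capped SMILES -> base gap for the default library."""
    return {cf.canonical_smiles(s): g for s, g in cf.default_library()}
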