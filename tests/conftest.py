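import numpy as np
import pytest
from hypothesis import settings

from thermocat.io import CoordinateEnsemble

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def toy_reference():
    """Single-frame reference: 20-residue CA trace (chain A) + 6-atom sugar (chain S)."""
    rng = np.random.default_rng(1234)
    n_res = 20
    backbone = np.cumsum(rng.normal(0, 2.0, (n_res, 3)), axis=0)
    sugar = rng.normal(5.0, 1.0, (6, 3))
    return CoordinateEnsemble(
        coordinates=np.vstack([backbone, sugar])[None],
        atom_names=np.array(["CA"] * n_res + ["C1", "C2", "C3", "C4", "C5", "O5"]),
        residue_ids=np.array(list(range(1, n_res + 1)) + [100] * 6),
        residue_names=np.array(["ALA"] * n_res + ["GLC"] * 6),
        chain_ids=np.array(["A"] * n_res + ["S"] * 6),
    )


@pytest.fixture
def tetramer_reference():
    """Four identical 10-residue chains, for monomer-averaging paths."""
    rng = np.random.default_rng(7)
    chain = np.cumsum(rng.normal(0, 1.5, (10, 3)), axis=0)
    coords, chains, rids = [], [], []
    for i, ch in enumerate("ABCD"):
        coords.append(chain + np.array([20.0 * i, 0, 0]))
        chains += [ch] * 10
        rids += list(range(1, 11))
    return CoordinateEnsemble(
        coordinates=np.vstack(coords)[None],
        atom_names=np.array(["CA"] * 40),
        residue_ids=np.array(rids),
        residue_names=np.array(["GLY"] * 40),
        chain_ids=np.array(chains),
    )
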