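import numpy as np
import pytest

from bait2dtm import model_io, simulate
from bait2dtm.simulate import CTFParams


@pytest.fixture(scope="session")
def toy_model() -> model_io.AtomicModel:
    """Small two-chain random-walk polymer used across tests."""
    return simulate.synthetic_model(n_chains=2, n_residues=20, seed=3)


@pytest.fixture(scope="session")
def toy_volume(toy_model) -> simulate.DensityVolume:
    return simulate.simulate_volume(toy_model, pixel_size=1.0, box_size=48, extra_b=20.0)


@pytest.fixture(scope="session")
def ctf_12k() -> CTFParams:
    return CTFParams(defocus=12000.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


def pdb_atom(serial, name, resname, chain, resi, x, y, z, b=20.0, element=None, record="ATOM"):
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resi:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          {element:>2}"
    )
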