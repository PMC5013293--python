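import numpy as np
import pytest
from hypothesis import settings

from protofil import DimerFrame, make_protomer

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def constructed_dimer(
    twist_deg: float = 0.0,
    bend_deg: float = 0.0,
    rise_A: float = 44.0,
    n_residues: int = 60,
    seed: int = 0,
    noise_sigma: float = 0.0,
    noise_seed: int = 99,
) -> DimerFrame:
    """Dimer whose subunit B is subunit A rotated about the inter-centroid
    (+z) axis by twist, swung about +y by bend, and raised along +z."""
    a = make_protomer(n_residues=n_residues, seed=seed, marker_resseqs=())
    R = rot_z(twist_deg) @ rot_y(bend_deg)
    b = a.transformed(R, np.array([0.0, 0.0, rise_A]), label="B")
    if noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)

        def jitter(p, label):
            return p.transformed(np.eye(3), np.zeros(3), label=label)

        a = jitter(a, "A")
        b = jitter(b, "B")
        for prot in (a, b):
            for res in prot.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(scale=noise_sigma, size=3)
    return DimerFrame(0.0, a, b)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
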