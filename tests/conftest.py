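import numpy as np
import pytest

from tbmcore import synth
from tbmcore.structio import Residue, Structure

DATA = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def helix40():
    """A 40-residue ideal helix with side-chain stubs."""
    return synth.ideal_backbone(synth._sequence(40), "helix")


@pytest.fixture(scope="session")
def family():
    """Native + 4 good templates + 2 decoys with TM truth straddling 0.5."""
    spec = synth.SynthSpec(seed=11, target_length=48, n_templates=4, n_decoys=2)
    native, templates, tm_truth = synth.make_structures(spec)
    return spec, native, templates, tm_truth


def rigid_transform(structure, seed=0, angle_deg=73.0, shift=(4.0, -7.0, 2.5)):
    """Apply an arbitrary but reproducible rigid transform to a structure."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
    out = structure.copy()
    for res in out.residues:
        for name in res.atoms:
            res.atoms[name] = rot @ res.atoms[name] + np.asarray(shift)
    return out


def ca_structure(coords, sequence=None):
    """Build a CA-only Structure from an Nx3 array (for metric tests)."""
    coords = np.asarray(coords, dtype=float)
    seq = sequence or "A" * len(coords)
    residues = [Residue(i + 1, seq[i],
                        {"N": coords[i] + (0.0, 0.0, 1.0),
                         "CA": coords[i].copy(),
                         "C": coords[i] + (1.0, 0.0, 0.0)})
                for i in range(len(coords))]
    return Structure(residues)
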