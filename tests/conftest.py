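import numpy as np
import pytest

from fibrilkit import GeneratorSpec, make_fibril
from fibrilkit.model import AtomSite, FibrilModel, Layer, Residue


@pytest.fixture
def nine_layer_stack():
    """Noise-free 9-layer synthetic stack at the refined helical parameters."""
    return make_fibril(GeneratorSpec(n_layers=9, twist=-1.4, rise=4.8, seed=1))


@pytest.fixture
def six_layer_stack():
    """Six-layer stack, the MD system size."""
    return make_fibril(GeneratorSpec(n_layers=6, twist=-1.4, rise=4.8, seed=1))


def make_point_model(atom_specs, chain_id="A"):
    """Tiny hand-built model: atom_specs = [(name, element, resname, seq, xyz), ...]."""
    by_res = {}
    for i, (name, elem, resname, seq, xyz) in enumerate(atom_specs):
        by_res.setdefault((seq, resname), []).append(
            AtomSite(i + 1, name, elem, resname, seq, chain_id, np.array(xyz, float))
        )
    residues = [Residue(rn, sq, atoms) for (sq, rn), atoms in sorted(by_res.items())]
    layer = Layer(chain_id, residues, layer_index=0)
    return FibrilModel([layer])
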