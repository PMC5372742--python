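import pytest

from quefss.synth import GLU97GLN_BRIDGES, make_reference_set


@pytest.fixture(scope="session")
def refs():
    """Synthetic stand-in subfamily references."""
    return make_reference_set()


@pytest.fixture(scope="session")
def published_bridges():
    """The five crystallographic Cys55-Cys99 bridge geometries (subunits A-E
    of the B. subtilis QueF Glu97Gln structure) with their published
    dihedral strain energies in kJ/mol."""
    energies = {"A": 15.023, "B": 16.120, "C": 14.772, "D": 18.584, "E": 13.938}
    return {
        sub: {"chis": chis, "ss": ss, "energy": energies[sub]}
        for sub, (chis, ss) in GLU97GLN_BRIDGES.items()
    }
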