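import numpy as np
import pytest

from contactgrid.grids import GridSpec
from contactgrid.pdb_io import AtomSphere

_DEFAULT_NAMES = {"C": "CB", "N": "N", "O": "O", "S": "SG", "P": "P"}
_DEFAULT_RES = {"C": "ALA", "N": "ALA", "O": "ALA", "S": "CYS", "P": "UNL"}


def make_sphere(element="O", position=(0.0, 0.0, 0.0), radius=1.52, serial=1,
                seq=1, chain="A", name=None, residue_name=None, icode="",
                standard=True):
    """A bare AtomSphere for direct geometry calls."""
    return AtomSphere(
        serial=serial,
        name=name or _DEFAULT_NAMES.get(element, element),
        element=element,
        residue_name=residue_name or _DEFAULT_RES.get(element, "UNL"),
        residue_seq=seq,
        insertion_code=icode,
        chain_id=chain,
        model_index=1,
        position=np.asarray(position, dtype=float),
        vdw_radius=radius,
        is_standard_residue=standard,
    )


@pytest.fixture
def sphere():
    return make_sphere


@pytest.fixture
def bare_spec():
    """Default-precision grid with no solvent expansion (raw spheres)."""
    return GridSpec(solvent_radius=0.0)


@pytest.fixture
def bare_enhanced():
    return GridSpec.from_precision("enhanced", solvent_radius=0.0)
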