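import numpy as np
import pytest

from ligenergy.chem import TypedAtom
from ligenergy.forcefield import load_forcefield
from ligenergy.structure import Atom


@pytest.fixture(scope="session")
def ff():
    return load_forcefield()


def make_atom(name="C1", element="C", coords=(0.0, 0.0, 0.0), occupancy=1.0,
              adp=20.0, residue_name="LIG", residue_seq=1, chain_id="A",
              is_polymer=False, altloc="", serial=1):
    return Atom(serial=serial, name=name, element=element,
                coords=np.asarray(coords, float), occupancy=occupancy,
                adp=adp, altloc=altloc, residue_name=residue_name,
                residue_seq=residue_seq, icode="", chain_id=chain_id,
                is_polymer=is_polymer, is_water=False)


def make_typed(ff_type="C", charge=0.0, coords=(0.0, 0.0, 0.0),
               element=None, **kw):
    el = element or ("H" if ff_type in ("H", "HD", "HS") else ff_type[0])
    atom = make_atom(element=el, coords=coords)
    return TypedAtom(
        atom=atom, ff_type=ff_type, partial_charge=charge,
        is_polar_h=ff_type == "HD", is_donor_h=ff_type == "HD",
        is_acceptor=ff_type in ("OA", "NA", "SA"), **kw)


@pytest.fixture
def typed_factory():
    return make_typed


@pytest.fixture
def atom_factory():
    return make_atom
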