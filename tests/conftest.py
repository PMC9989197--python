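import numpy as np
import pytest

from abaffinity.complex_model import AbAgComplex, CDRId, Residue


def make_residue(chain="H", number=1, aa="A", ca=(0, 0, 0), side=(), icode=""):
    return Residue(chain_id=chain, number=number, aa=aa,
                   ca_coord=np.asarray(ca, dtype=float),
                   sidechain_coords=[np.asarray(s, dtype=float) for s in side],
                   icode=icode)


def make_complex(residues, roles=None, kd=None, cdr_map=None):
    c = AbAgComplex(
        id="test", residues=list(residues),
        chain_roles=roles or {"H": "heavy", "L": "light", "A": "antigen"},
        kd=kd)
    if cdr_map:
        c.cdr_map = dict(cdr_map)
    return c


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def worked_example_plan():
    """CDR-H3 contacts four epitope residues, each also contacted by at
    least two other CDRs; private L3 contacts on top."""
    from abaffinity.synthetic_data import ContactPlan
    return ContactPlan(
        shared_sites=[frozenset({CDRId.H3, CDRId.H1, CDRId.H2})] * 2
        + [frozenset({CDRId.H3, CDRId.L1, CDRId.L2})] * 2,
        private_contacts={CDRId.L3: 2},
    )
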