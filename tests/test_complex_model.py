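"""Domain model: side-chain reach, the contact criterion, interface
projection, and PDB ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abaffinity.complex_model import (
    CDRId,
    compute_contact_map,
    define_interface,
    in_contact,
    parse_complex,
    read_cdr_annotation,
    sidechain_length,
)
from abaffinity.synthetic_data import GeneratorConfig, complex_to_pdb, generate_complex

from conftest import make_complex, make_residue

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       1.000   1.500   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  TYR A   3       8.000   0.000   0.000  1.00  0.00           C
ATOM      6  OH  TYR A   3       8.000   6.000   0.000  1.00  0.00           O
ATOM      7  CA  LYS B   1       1.000   3.000   0.000  1.00  0.00           C
ATOM      8  CA  SER B   2       5.000   3.000   0.000  1.00  0.00           C
ATOM      9  CA  TRP B   3       9.000   3.000   0.000  1.00  0.00           C
HETATM   10  O   HOH B  90      50.000  50.000  50.000  1.00  0.00           O
END
"""


class TestSidechainLength:
    @pytest.mark.parametrize("side,expected", [
        ((), 0.0),                                       # glycine convention
        (((3, 0, 0),), 3.0),                             # single atom
        (((1.5, 0, 0), (0, 2.6, 0), (0, 0, 4.1)), 4.1),  # max over atoms
    ])
    def test_max_distance_to_ca(self, side, expected):
        r = make_residue(aa="G" if not side else "Y", ca=(0, 0, 0), side=side)
        assert sidechain_length(r) == pytest.approx(expected)


class TestInContact:
    def test_two_glycines_inside_threshold(self):
        a = make_residue(chain="H", aa="G", ca=(0, 0, 0))
        b = make_residue(chain="A", aa="G", ca=(3, 0, 0))
        assert in_contact(a, b)

    def test_boundary_is_strict(self):
        a = make_residue(chain="H", aa="G", ca=(0, 0, 0))
        b = make_residue(chain="A", aa="G", ca=(4.5, 0, 0))
        assert not in_contact(a, b)

    def test_symmetric_and_rigid_motion_invariant(self, rng):
        from scipy.spatial.transform import Rotation
        for _ in range(20):
            pa, pb = rng.normal(scale=4, size=(2, 3))
            sa = [pa + rng.normal(scale=2, size=3)]
            sb = [pb + rng.normal(scale=2, size=3)]
            a = make_residue(chain="H", aa="L", ca=pa, side=sa)
            b = make_residue(chain="A", aa="K", ca=pb, side=sb)
            assert in_contact(a, b) == in_contact(b, a)
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(scale=50, size=3)
            a2 = make_residue(chain="H", aa="L", ca=R @ pa + t,
                              side=[R @ s + t for s in sa])
            b2 = make_residue(chain="A", aa="K", ca=R @ pb + t,
                              side=[R @ s + t for s in sb])
            assert in_contact(a, b) == in_contact(a2, b2)


class TestInContactProperties:
    coords = st.tuples(st.floats(-50, 50), st.floats(-50, 50),
                       st.floats(-50, 50))

    @given(ca_a=coords, ca_b=coords, la=st.floats(0, 8), lb=st.floats(0, 8))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_and_threshold_arithmetic(self, ca_a, ca_b, la, lb):
        """Contact iff CA distance < la + lb + 4.5, symmetric."""
        a = make_residue("H", 1, "Y", ca=ca_a,
                         side=[np.add(ca_a, (la, 0, 0))] if la else [])
        b = make_residue("A", 1, "W", ca=ca_b,
                         side=[np.add(ca_b, (0, lb, 0))] if lb else [])
        d = float(np.linalg.norm(np.subtract(ca_a, ca_b)))
        assert in_contact(a, b) == (d < la + lb + 4.5)
        assert in_contact(a, b) == in_contact(b, a)


class TestContactMap:
    def test_separated_chains_yield_empty_map(self, rng):
        ab = [make_residue("H", i + 1, "A", ca=rng.normal(size=3))
              for i in range(5)]
        ag = [make_residue("A", i + 1, "A", ca=rng.normal(size=3) + 200)
              for i in range(5)]
        c = make_complex(ab + ag, roles={"H": "heavy", "A": "antigen"})
        assert len(compute_contact_map(c)) == 0

    def test_matches_bruteforce_on_random_complexes(self, rng):
        """KD-tree-pruned map equals the exhaustive pairwise oracle."""
        for _ in range(25):
            ab = [make_residue("H", i + 1, "V", ca=rng.uniform(0, 20, 3),
                               side=[rng.uniform(0, 20, 3)]) for i in range(8)]
            ag = [make_residue("A", i + 1, "S", ca=rng.uniform(0, 20, 3),
                               side=[rng.uniform(0, 20, 3)]) for i in range(8)]
            c = make_complex(ab + ag, roles={"H": "heavy", "A": "antigen"})
            got = {(a.key, b.key) for a, b in compute_contact_map(c).pairs}
            want = {(a.key, b.key) for a in ab for b in ag if in_contact(a, b)}
            assert got == want

    def test_planted_contact_count(self, worked_example_plan):
        c, truth = generate_complex(GeneratorConfig(seed=7), 0,
                                    worked_example_plan)
        m = compute_contact_map(c)
        assert len(m) == truth.n_contacts
        assert {(a.key, b.key) for a, b in m.pairs} == truth.contact_keys


class TestInterface:
    def test_empty_map_gives_empty_sets(self):
        from abaffinity.synthetic_data import ContactPlan
        c, _ = generate_complex(GeneratorConfig(seed=0), 0, plan=ContactPlan())
        iface = define_interface(c, compute_contact_map(c))
        assert not iface.epitope and not iface.paratope
        assert all(not s for s in iface.cdr_epitopes.values())

    def test_single_h3_contact(self):
        h3 = make_residue("H", 95, "F", ca=(0, 0, 0))
        ag = make_residue("A", 1, "W", ca=(2, 0, 0))
        fw = make_residue("H", 5, "A", ca=(100, 0, 0))
        c = make_complex([h3, ag, fw], roles={"H": "heavy", "A": "antigen"},
                         cdr_map={h3: CDRId.H3})
        iface = define_interface(c, compute_contact_map(c))
        assert iface.epitope == {ag}
        assert iface.cdr_epitopes[CDRId.H3] == {ag}
        assert all(not iface.cdr_epitopes[x] for x in CDRId if x != CDRId.H3)

    def test_framework_contacts_in_paratope_but_no_cdr_epitope(self):
        from abaffinity.synthetic_data import ContactPlan
        plan = ContactPlan(framework_contacts=2)
        c, truth = generate_complex(GeneratorConfig(seed=1), 0, plan)
        m = compute_contact_map(c)
        iface = define_interface(c, m)
        assert {r.key for r in iface.paratope} == truth.paratope_keys
        assert all(not s for s in iface.cdr_epitopes.values())

    def test_projection_sizes_and_cdr_union(self, rng):
        from abaffinity.synthetic_data import ContactPlan
        for seed in range(10):
            c, _ = generate_complex(
                GeneratorConfig(seed=seed), 0,
                ContactPlan.random(np.random.default_rng(seed)))
            m = compute_contact_map(c)
            iface = define_interface(c, m)
            assert len(iface.epitope) <= len(m)
            assert len(iface.paratope) <= len(m)
            union = set().union(*iface.cdr_epitopes.values())
            assert union <= iface.epitope


class TestParseComplex:
    def test_minimal_pdb(self):
        c = parse_complex(MINIMAL_PDB, {"A": "heavy", "B": "antigen"})
        assert len(c.residues) == 6  # water excluded
        tyr = next(r for r in c.residues if r.aa == "Y")
        assert sidechain_length(tyr) == pytest.approx(6.0)
        gly = next(r for r in c.residues if r.aa == "G")
        assert gly.sidechain_coords == []

    def test_missing_chain_role_raises(self):
        with pytest.raises(ValueError, match="chain role unresolved"):
            parse_complex(MINIMAL_PDB, {"A": "heavy", "Z": "antigen"})

    def test_roundtrip_preserves_coordinates(self):
        cfg = GeneratorConfig(seed=11)
        c, _ = generate_complex(cfg, 0)
        c2 = parse_complex(complex_to_pdb(c),
                           {"H": "heavy", "L": "light", "A": "antigen"})
        orig = {r.key: r for r in c.residues}
        assert set(orig) == {r.key for r in c2.residues}
        for r in c2.residues:
            # PDB fixed-width precision
            assert np.allclose(r.ca_coord, orig[r.key].ca_coord, atol=1e-3)
            assert orig[r.key].aa == r.aa

    def test_cdr_annotation_override(self):
        table = read_cdr_annotation("A\t1\t2\tH3\n")
        c = parse_complex(MINIMAL_PDB, {"A": "heavy", "B": "antigen"},
                          cdr_annotation=table)
        cdr_numbers = {r.number for r in c.cdr_map}
        assert cdr_numbers == {1, 2}
        assert set(c.cdr_map.values()) == {CDRId.H3}
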