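"""Domain model for antibody-antigen complexes.

Residue-level representation of a complex with role-assigned chains
(heavy / light / antigen), CDR annotation on Chothia numbering, the
side-chain-reach contact criterion, and the epitope / paratope interface
derived from it.

A pair of residues is considered potentially interacting when the
distance between their alpha carbons is less than the sum of their
side-chain lengths plus an interaction distance (default 4.5 Å), where
the side-chain length of a residue is the distance from its CA to its
furthest side-chain heavy atom.  Glycine, having no side-chain heavy
atoms, has length 0.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AA_ALPHABET",
    "CDRId",
    "Residue",
    "AbAgComplex",
    "ContactMap",
    "InterfaceDefinition",
    "DEFAULT_CDR_BOUNDARIES",
    "DEFAULT_INTERACTION_DISTANCE",
    "parse_complex",
    "read_cdr_annotation",
    "sidechain_length",
    "in_contact",
    "compute_contact_map",
    "define_interface",
]

#: One-letter codes of the 20 standard amino acids, alphabetical.
AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Contact-criterion interaction distance in Å.
DEFAULT_INTERACTION_DISTANCE = 4.5


class CDRId(str, Enum):
    """The six complementarity-determining regions."""

    H1 = "H1"
    H2 = "H2"
    H3 = "H3"
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: North CDR boundaries expressed in Chothia positions, inclusive.
#: Overridable via the ``cdr_annotation`` argument of :func:`parse_complex`.
DEFAULT_CDR_BOUNDARIES: dict[CDRId, tuple[int, int]] = {
    CDRId.H1: (23, 35),
    CDRId.H2: (50, 58),
    CDRId.H3: (93, 102),
    CDRId.L1: (24, 34),
    CDRId.L2: (49, 56),
    CDRId.L3: (89, 97),
}


@dataclass(eq=False)
class Residue:
    """One amino-acid residue.

    Identity semantics (``eq=False``): two Residue objects are equal only
    if they are the same object, which makes residues usable as dict /
    set members within a single complex.  Cross-object comparison goes
    through :attr:`key`.
    """

    chain_id: str
    number: int
    aa: str
    ca_coord: np.ndarray
    sidechain_coords: list[np.ndarray] = field(default_factory=list)
    icode: str = ""

    def __post_init__(self) -> None:
        if self.aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino acid {self.aa!r}")
        self.ca_coord = np.asarray(self.ca_coord, dtype=float)
        if self.ca_coord.shape != (3,) or not np.all(np.isfinite(self.ca_coord)):
            raise ValueError("ca_coord must be a finite 3-vector")
        self.sidechain_coords = [np.asarray(c, dtype=float) for c in self.sidechain_coords]

    @property
    def key(self) -> tuple[str, int, str]:
        """Positional identity: (chain_id, Chothia number, insertion code)."""
        return (self.chain_id, self.number, self.icode)


@dataclass
class AbAgComplex:
    """A role-annotated antibody-antigen complex."""

    id: str
    residues: list[Residue]
    chain_roles: dict[str, str]  # chain_id -> heavy | light | antigen
    cdr_map: dict[Residue, CDRId] = field(default_factory=dict)
    kd: Optional[float] = None
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        roles = set(self.chain_roles.values())
        if "antigen" not in roles:
            raise ValueError("complex must contain at least one antigen chain")
        if "heavy" not in roles:
            raise ValueError("complex must contain a heavy chain")
        if self.kd is not None and not self.kd > 0:
            raise ValueError("kd must be a positive molar concentration")
        for r in self.cdr_map:
            if self.chain_roles.get(r.chain_id) == "antigen":
                raise ValueError("cdr_map keys must lie on antibody chains")

    # -- chain helpers -------------------------------------------------
    def role_of(self, residue: Residue) -> str:
        return self.chain_roles[residue.chain_id]

    @property
    def antibody_residues(self) -> list[Residue]:
        return [r for r in self.residues if self.role_of(r) in ("heavy", "light")]

    @property
    def antigen_residues(self) -> list[Residue]:
        return [r for r in self.residues if self.role_of(r) == "antigen"]

    @property
    def has_light_chain(self) -> bool:
        return "light" in self.chain_roles.values()

    def chain_sequence(self, role: str) -> str:
        """Concatenated one-letter sequence of the first chain with `role`,
        in residue-number order."""
        for cid, r in self.chain_roles.items():
            if r == role:
                res = sorted(
                    (x for x in self.residues if x.chain_id == cid),
                    key=lambda x: (x.number, x.icode),
                )
                return "".join(x.aa for x in res)
        raise KeyError(f"no chain with role {role!r}")


@dataclass
class ContactMap:
    """Antibody×antigen residue pairs satisfying the contact criterion.

    The first element of every pair is on an antibody chain, the second
    on an antigen chain.
    """

    pairs: set[tuple[Residue, Residue]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def antibody_residues(self) -> set[Residue]:
        return {a for a, _ in self.pairs}

    @property
    def antigen_residues(self) -> set[Residue]:
        return {b for _, b in self.pairs}

    def partners_of(self, residue: Residue) -> list[Residue]:
        """Cross-interface contact partners of an interface residue."""
        out = [b for a, b in self.pairs if a is residue]
        out.extend(a for a, b in self.pairs if b is residue)
        return out


@dataclass
class InterfaceDefinition:
    """Epitope / paratope projections of a contact map, plus the antigen
    residues contacted by each CDR."""

    epitope: set[Residue]
    paratope: set[Residue]
    cdr_epitopes: dict[CDRId, set[Residue]]


# ---------------------------------------------------------------------------
# geometry

def sidechain_length(r: Residue) -> float:
    """Distance from CA to the furthest side-chain heavy atom (Å).

    0.0 when the residue has no side-chain heavy atoms (glycine).
    """
    if not r.sidechain_coords:
        return 0.0
    sc = np.asarray(r.sidechain_coords)
    return float(np.sqrt(((sc - r.ca_coord) ** 2).sum(axis=1)).max())


def in_contact(a: Residue, b: Residue,
               interaction_distance: float = DEFAULT_INTERACTION_DISTANCE) -> bool:
    """Contact criterion: CA-CA distance strictly less than the combined
    side-chain lengths plus the interaction distance."""
    d = float(np.linalg.norm(a.ca_coord - b.ca_coord))
    return d < sidechain_length(a) + sidechain_length(b) + interaction_distance


def compute_contact_map(c: AbAgComplex,
                        interaction_distance: float = DEFAULT_INTERACTION_DISTANCE,
                        ) -> ContactMap:
    """All antibody×antigen residue pairs in contact.

    Candidate pairs are pruned with a KD-tree on CA coordinates using the
    largest possible threshold, then checked exactly, so the result is
    identical to the exhaustive pairwise computation.
    """
    ab = c.antibody_residues
    ag = c.antigen_residues
    pairs: set[tuple[Residue, Residue]] = set()
    if not ab or not ag:
        return ContactMap(pairs)
    ab_len = np.array([sidechain_length(r) for r in ab])
    ag_len = np.array([sidechain_length(r) for r in ag])
    radius = ab_len.max() + ag_len.max() + interaction_distance
    tree = cKDTree(np.array([r.ca_coord for r in ag]))
    ab_xyz = np.array([r.ca_coord for r in ab])
    for i, hits in enumerate(tree.query_ball_point(ab_xyz, radius)):
        for j in hits:
            d = float(np.linalg.norm(ab_xyz[i] - ag[j].ca_coord))
            if d < ab_len[i] + ag_len[j] + interaction_distance:
                pairs.add((ab[i], ag[j]))
    return ContactMap(pairs)


def define_interface(c: AbAgComplex, m: ContactMap) -> InterfaceDefinition:
    """Project a contact map onto epitope / paratope and per-CDR epitopes.

    Framework (non-CDR) antibody contacts appear in the paratope but in
    no CDR-epitope.
    """
    cdr_epitopes: dict[CDRId, set[Residue]] = {cdr: set() for cdr in CDRId}
    for a, b in m.pairs:
        cdr = c.cdr_map.get(a)
        if cdr is not None:
            cdr_epitopes[cdr].add(b)
    return InterfaceDefinition(
        epitope=m.antigen_residues,
        paratope=m.antibody_residues,
        cdr_epitopes=cdr_epitopes,
    )


# ---------------------------------------------------------------------------
# PDB ingestion

def read_cdr_annotation(path_or_text: str) -> dict[str, list[tuple[int, int, CDRId]]]:
    """Read a CDR-boundary TSV (chain_id, start, end, cdr_id; Chothia
    positions, inclusive).  Accepts a path or the raw text itself."""
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = path_or_text
    table: dict[str, list[tuple[int, int, CDRId]]] = {}
    for line in text.strip().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("chain_id"):
            continue
        chain, start, end, cdr = line.split("\t")
        table.setdefault(chain, []).append((int(start), int(end), CDRId(cdr)))
    return table


def _assign_cdrs(
    complex_: AbAgComplex,
    annotation: Optional[Mapping[str, Sequence[tuple[int, int, CDRId]]]] = None,
) -> None:
    """Populate cdr_map from an explicit boundary table, or from the
    built-in North/Chothia boundary constants by chain role."""
    cdr_map: dict[Residue, CDRId] = {}
    for r in complex_.residues:
        role = complex_.chain_roles[r.chain_id]
        if role == "antigen":
            continue
        if annotation is not None and r.chain_id in annotation:
            for start, end, cdr in annotation[r.chain_id]:
                if start <= r.number <= end:
                    cdr_map[r] = cdr
                    break
        else:
            prefix = "H" if role == "heavy" else "L"
            for cdr, (start, end) in DEFAULT_CDR_BOUNDARIES.items():
                if cdr.value[0] == prefix and start <= r.number <= end:
                    cdr_map[r] = cdr
                    break
    complex_.cdr_map = cdr_map


def parse_complex(
    pdb_text: str,
    roles: Mapping[str, str],
    cdr_annotation: Optional[Mapping[str, Sequence[tuple[int, int, CDRId]]]] = None,
    *,
    complex_id: str = "complex",
    kd: Optional[float] = None,
    resolution: Optional[float] = None,
) -> AbAgComplex:
    """Build an :class:`AbAgComplex` from PDB-format text.

    Waters, heteroatoms and non-standard residues are excluded (the
    latter with a warning); a retained residue lacking a CA atom is an
    error.  Alternate locations keep the highest-occupancy conformer
    (first on tie), which Biopython's parser already does.

    Parameters
    ----------
    roles
        chain_id -> one of ``heavy`` / ``light`` / ``antigen``; every
        listed chain must be present in the file.
    cdr_annotation
        Optional explicit per-chain CDR boundary table (see
        :func:`read_cdr_annotation`); when absent, the built-in
        North-over-Chothia boundary constants are applied to antibody
        chains.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(complex_id, io.StringIO(pdb_text))
    model = next(iter(structure))
    chains = {ch.id: ch for ch in model}
    missing = set(roles) - set(chains)
    if missing:
        raise ValueError(f"chain role unresolved: {sorted(missing)}")

    residues: list[Residue] = []
    skipped = 0
    for cid in roles:
        for res in chains[cid]:
            hetflag, resseq, icode = res.id
            if hetflag != " ":  # water / ligand / modified residue
                continue
            aa = THREE_TO_ONE.get(res.get_resname())
            if aa is None:
                skipped += 1
                continue
            atoms = {a.get_name(): a for a in res if a.element != "H"}
            if "CA" not in atoms:
                raise ValueError(
                    f"incomplete residue: {cid}{resseq}{icode.strip()} has no CA"
                )
            side = [np.array(a.get_coord(), dtype=float)
                    for name, a in atoms.items() if name not in BACKBONE_ATOMS]
            residues.append(Residue(
                chain_id=cid, number=resseq, aa=aa,
                ca_coord=np.array(atoms["CA"].get_coord(), dtype=float),
                sidechain_coords=side, icode=icode.strip(),
            ))
    if skipped:
        warnings.warn(f"{complex_id}: skipped {skipped} non-standard residue(s)")

    complex_ = AbAgComplex(
        id=complex_id, residues=residues, chain_roles=dict(roles),
        kd=kd, resolution=resolution,
    )
    _assign_cdrs(complex_, cdr_annotation)
    return complex_
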