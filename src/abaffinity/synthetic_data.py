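"""Synthetic antibody-antigen complexes with known ground truth.

The generator builds toy three-chain complexes (heavy, light, antigen)
whose interface realizes a *contact plan* exactly under the
side-chain-reach contact criterion, so every downstream feature can be
checked against generator bookkeeping:

* Each planned epitope *site* is one antigen residue placed on a widely
  spaced grid (40 Å pitch — far beyond any contact threshold).
* For every CDR listed at a site, one residue of that CDR is placed
  4.0 Å from the site's CA, comfortably inside the contact threshold
  even for two glycines (0 + 0 + 4.5 Å), so each (CDR, site) incidence
  contributes exactly one contact pair and nothing else.
* Framework residues, unused CDR padding and non-epitope antigen
  residues sit on remote shelves, > 100 Å from everything they must not
  touch.

Residues carry a CA plus a single pseudo side-chain atom at a fixed
distance (glycine: none), which keeps the contact criterion analytic.
Affinity labels are planted through a logistic model on chosen features
with configurable effect size and noise, and KD values are drawn
consistent with the label on a log-normal spread of about five orders
of magnitude around the 1 nM class boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .complex_model import (
    AA_ALPHABET,
    ONE_TO_THREE,
    AbAgComplex,
    CDRId,
    ContactMap,
    DEFAULT_CDR_BOUNDARIES,
    Residue,
)

__all__ = [
    "ContactPlan",
    "GeneratorConfig",
    "GroundTruth",
    "generate_complex",
    "generate_dataset",
    "generate_reference_set",
    "generate_homolog_families",
    "plant_affinity",
    "synthetic_classification_table",
    "complex_to_pdb",
]

_SITE_PITCH = 40.0       # Å between epitope sites
_CONTACT_DIST = 4.0      # Å from CDR residue CA to its site CA
_FAR_SHELF = 150.0       # z-offset of non-interacting residues

_WINDOW_SIZE = {
    cdr: hi - lo + 1 for cdr, (lo, hi) in DEFAULT_CDR_BOUNDARIES.items()
}


@dataclass
class ContactPlan:
    """Planned interface: shared multi-CDR sites plus private contacts.

    ``shared_sites`` lists epitope sites each contacted by the given set
    of CDRs; ``private_contacts`` adds per-CDR sites contacted by that
    CDR alone; ``framework_contacts`` adds sites contacted by one
    framework (non-CDR) heavy-chain residue each.
    """

    shared_sites: list[frozenset[CDRId]] = field(default_factory=list)
    private_contacts: dict[CDRId, int] = field(default_factory=dict)
    framework_contacts: int = 0

    def __post_init__(self) -> None:
        self.shared_sites = [frozenset(s) for s in self.shared_sites]
        for s in self.shared_sites:
            if not s:
                raise ValueError("infeasible plan: empty shared site")
        for cdr, n in self.private_contacts.items():
            if n < 0:
                raise ValueError("infeasible plan: negative private contacts")
        for cdr in CDRId:
            need = self.cdr_residue_demand(cdr)
            if need > _WINDOW_SIZE[cdr]:
                raise ValueError(
                    f"infeasible plan: CDR {cdr.value} needs {need} contact "
                    f"residues but its window holds {_WINDOW_SIZE[cdr]}"
                )

    def cdr_residue_demand(self, cdr: CDRId) -> int:
        return (sum(1 for s in self.shared_sites if cdr in s)
                + self.private_contacts.get(cdr, 0))

    # -- ground-truth bookkeeping -------------------------------------
    @property
    def contacts_per_cdr(self) -> dict[CDRId, int]:
        return {c: self.cdr_residue_demand(c) for c in CDRId}

    @property
    def multivalency_per_cdr(self) -> dict[CDRId, int]:
        """Epitope sites of each CDR that at least two additional CDRs
        also contact."""
        return {
            c: sum(1 for s in self.shared_sites if c in s and len(s) >= 3)
            for c in CDRId
        }

    @property
    def n_sites(self) -> int:
        return (len(self.shared_sites)
                + sum(self.private_contacts.values())
                + self.framework_contacts)

    @property
    def n_contacts(self) -> int:
        return (sum(len(s) for s in self.shared_sites)
                + sum(self.private_contacts.values())
                + self.framework_contacts)

    @classmethod
    def random(cls, rng: np.random.Generator,
               max_shared: int = 6, max_private: int = 3,
               max_framework: int = 1) -> "ContactPlan":
        """A feasible random plan (rejection-free by construction)."""
        cdrs = list(CDRId)
        demand = {c: 0 for c in CDRId}
        shared: list[frozenset[CDRId]] = []
        for _ in range(int(rng.integers(0, max_shared + 1))):
            size = int(rng.integers(2, 7))
            members = frozenset(
                rng.choice(len(cdrs), size=size, replace=False).tolist())
            members = frozenset(cdrs[i] for i in members)
            if any(demand[c] + 1 > _WINDOW_SIZE[c] for c in members):
                continue
            for c in members:
                demand[c] += 1
            shared.append(members)
        private = {}
        for c in CDRId:
            room = _WINDOW_SIZE[c] - demand[c]
            private[c] = int(rng.integers(0, min(max_private, room) + 1))
        return cls(shared_sites=shared, private_contacts=private,
                   framework_contacts=int(rng.integers(0, max_framework + 1)))


@dataclass
class GroundTruth:
    """What the generator planted, keyed positionally for comparison
    with pipeline output."""

    complex_id: str
    contacts_per_cdr: dict[CDRId, int]
    multivalency_per_cdr: dict[CDRId, int]
    n_contacts: int
    contact_keys: set[tuple[tuple[str, int, str], tuple[str, int, str]]]
    epitope_keys: set[tuple[str, int, str]]
    paratope_keys: set[tuple[str, int, str]]


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark."""

    n_complexes: int = 142           # size of the curated classification set
    n_framework: int = 10            # framework residues per antibody chain
    n_extra_antigen: int = 10        # non-epitope antigen residues
    sidechain_len: float = 1.0       # Å; pseudo side-chain atom distance
    pad_cdrs: bool = True            # fill CDR windows with remote residues
    composition: Optional[dict[str, float]] = None  # aa -> weight
    effect_spec: tuple = (("H3_multivalent", 2.0), ("H1_multivalent", 2.0))
    noise_scale: float = 1.0         # logistic label noise
    seed: int = 0


def _aa_sampler(cfg: GeneratorConfig):
    aas = list(AA_ALPHABET)
    if cfg.composition:
        w = np.array([cfg.composition.get(a, 0.0) for a in aas], dtype=float)
    else:
        w = np.ones(len(aas))
    w = w / w.sum()
    return aas, w


def _pseudo_sidechain(ca: np.ndarray, aa: str, length: float) -> list[np.ndarray]:
    if aa == "G" or length <= 0:
        return []
    return [ca + np.array([0.0, 0.0, length])]


def generate_complex(
    cfg: GeneratorConfig,
    index: int,
    plan: Optional[ContactPlan] = None,
) -> tuple[AbAgComplex, GroundTruth]:
    """Build one complex realizing ``plan`` exactly (a random feasible
    plan is drawn from the per-complex seed when none is given)."""
    rng = np.random.default_rng((cfg.seed, index))
    if plan is None:
        plan = ContactPlan.random(rng)
    aas, w = _aa_sampler(cfg)

    def draw_aa() -> str:
        return aas[int(rng.choice(len(aas), p=w))]

    residues: list[Residue] = []
    contact_keys = set()
    epitope_keys = set()
    paratope_keys = set()

    # epitope sites along x at z=0
    site_specs: list[tuple[np.ndarray, list]] = []
    si = 0
    for members in plan.shared_sites:
        site_specs.append((np.array([si * _SITE_PITCH, 0.0, 0.0]),
                           sorted(members, key=lambda c: c.value)))
        si += 1
    for cdr in CDRId:
        for _ in range(plan.private_contacts.get(cdr, 0)):
            site_specs.append((np.array([si * _SITE_PITCH, 0.0, 0.0]), [cdr]))
            si += 1
    for _ in range(plan.framework_contacts):
        site_specs.append((np.array([si * _SITE_PITCH, 0.0, 0.0]), ["framework"]))
        si += 1

    # antigen chain: one residue per site, then remote extras
    ag_num = 0
    site_ag: list[Residue] = []
    for pos, _ in site_specs:
        ag_num += 1
        aa = draw_aa()
        r = Residue("A", ag_num, aa, pos,
                    _pseudo_sidechain(pos, aa, cfg.sidechain_len))
        residues.append(r)
        site_ag.append(r)
        epitope_keys.add(r.key)
    for j in range(cfg.n_extra_antigen):
        ag_num += 1
        pos = np.array([j * 10.0, 200.0, 0.0])
        aa = draw_aa()
        residues.append(Residue("A", ag_num, aa, pos,
                                _pseudo_sidechain(pos, aa, cfg.sidechain_len)))

    # antibody CDR residues: those with a planned contact hover over
    # their site; numbering is sequential within the CDR window
    cdr_slots: dict[CDRId, int] = {c: DEFAULT_CDR_BOUNDARIES[c][0] for c in CDRId}
    fw_heavy_num = 0
    cdr_residues: dict[CDRId, list[Residue]] = {c: [] for c in CDRId}

    for (pos, members), ag_res in zip(site_specs, site_ag):
        for k, member in enumerate(members):
            # spread incidences on a cone over the site
            alpha = 2 * np.pi * k / max(len(members), 1)
            offset = _CONTACT_DIST * np.array([
                0.5 * np.cos(alpha), 0.5 * np.sin(alpha),
                np.sqrt(1 - 0.25)])
            ca = pos + offset
            aa = draw_aa()
            side = _pseudo_sidechain(ca, aa, cfg.sidechain_len)
            if member == "framework":
                fw_heavy_num += 1
                r = Residue("H", fw_heavy_num, aa, ca, side)
            else:
                chain = "H" if member.value[0] == "H" else "L"
                num = cdr_slots[member]
                cdr_slots[member] = num + 1
                r = Residue(chain, num, aa, ca, side)
                cdr_residues[member].append(r)
            residues.append(r)
            contact_keys.add((r.key, ag_res.key))
            paratope_keys.add(r.key)

    # CDR padding and framework shelves, far from every site
    shelf_x = 0.0
    if cfg.pad_cdrs:
        for cdr in CDRId:
            lo, hi = DEFAULT_CDR_BOUNDARIES[cdr]
            chain = "H" if cdr.value[0] == "H" else "L"
            for num in range(cdr_slots[cdr], hi + 1):
                pos = np.array([shelf_x, 0.0, _FAR_SHELF])
                shelf_x += 10.0
                aa = draw_aa()
                r = Residue(chain, num, aa, pos,
                            _pseudo_sidechain(pos, aa, cfg.sidechain_len))
                residues.append(r)
                cdr_residues[cdr].append(r)
    for chain in ("H", "L"):
        start = fw_heavy_num if chain == "H" else 0
        for j in range(start, cfg.n_framework):
            pos = np.array([shelf_x, 100.0, _FAR_SHELF])
            shelf_x += 10.0
            aa = draw_aa()
            residues.append(Residue(chain, j + 1, aa, pos,
                                    _pseudo_sidechain(pos, aa, cfg.sidechain_len)))

    complex_ = AbAgComplex(
        id=f"synth_{index:04d}",
        residues=residues,
        chain_roles={"H": "heavy", "L": "light", "A": "antigen"},
    )
    from .complex_model import _assign_cdrs
    _assign_cdrs(complex_)

    truth = GroundTruth(
        complex_id=complex_.id,
        contacts_per_cdr=plan.contacts_per_cdr,
        multivalency_per_cdr=plan.multivalency_per_cdr,
        n_contacts=plan.n_contacts,
        contact_keys=contact_keys,
        epitope_keys=epitope_keys,
        paratope_keys=paratope_keys,
    )
    return complex_, truth


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[AbAgComplex], list[GroundTruth]]:
    """Generate ``cfg.n_complexes`` complexes with per-complex random
    plans (deterministic in ``cfg.seed``).  Affinities are planted
    afterwards with :func:`plant_affinity` on the assembled feature
    table."""
    complexes, truths = [], []
    for i in range(cfg.n_complexes):
        c, t = generate_complex(cfg, i)
        complexes.append(c)
        truths.append(t)
    return complexes, truths


# ---------------------------------------------------------------------------
# affinity planting

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def plant_affinity(
    features: pd.DataFrame,
    effect_spec: Iterable[tuple[str, float]],
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Plant a logistic affinity relationship on named features.

    The named features are standardized over the table, combined
    linearly, and turned into a high-affinity probability through a
    logistic with the given noise scale (larger = noisier labels;
    0 = deterministic threshold).  KD values are then drawn consistent
    with each label: -log10(KD) = 9 ± |N(0, 1.25)|, i.e. about five
    logs of spread around the 1 nM boundary.

    Returns (kd array in molar, label list 'high'/'low').
    """
    rng = np.random.default_rng(seed)
    eta = np.zeros(len(features))
    for name, coef in effect_spec:
        if name not in features.columns:
            raise KeyError(f"planted feature {name!r} not in table")
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        eta += float(coef) * z
    if noise_scale > 0:
        p_high = _sigmoid(eta / noise_scale)
        is_high = rng.random(len(features)) < p_high
    else:
        is_high = eta > 0
    spread = np.abs(rng.normal(0.0, 1.25, size=len(features)))
    nlkd = np.where(is_high, 9.0 + spread, 9.0 - spread)
    kd = 10.0 ** (-nlkd)
    labels = ["high" if h else "low" for h in is_high]
    return kd, labels


def synthetic_classification_table(
    n_complexes: int = 142,
    n_features: int = 16,
    n_informative: int = 2,
    coefficient: float = 2.0,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Feature-level synthetic benchmark: standard-normal features with
    a planted logistic effect on the first ``n_informative`` columns.

    Returns (table, labels, kd).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_complexes, n_features))
    names = [f"f{i:02d}" for i in range(n_features)]
    table = pd.DataFrame(X, columns=names,
                         index=[f"synth_{i:04d}" for i in range(n_complexes)])
    effect = [(names[i], coefficient) for i in range(n_informative)]
    kd, labels = plant_affinity(table, effect, noise_scale,
                                seed=int(rng.integers(2**31)))
    return table, labels, kd


# ---------------------------------------------------------------------------
# propensity-training reference sets

def generate_reference_set(
    n_maps: int = 84,
    contacts_per_map: int = 30,
    mode: str = "independent",
    enriched_pair: tuple[str, str] = ("Y", "Y"),
    enrichment: float = 0.5,
    seed: int = 0,
) -> list[ContactMap]:
    """Reference contact maps for propensity training.

    ``independent`` draws both sides i.i.d. uniform (trained matrix
    tends to 0); ``enriched`` replaces a fraction ``enrichment`` of the
    pairs with ``enriched_pair``.
    """
    if n_maps < 1:
        raise ValueError("need at least one reference map")
    if mode not in ("independent", "enriched"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    maps = []
    origin = np.zeros(3)
    for _ in range(n_maps):
        pairs = set()
        for j in range(contacts_per_map):
            if mode == "enriched" and rng.random() < enrichment:
                aa_ab, aa_ag = enriched_pair
            else:
                aa_ab = AA_ALPHABET[int(rng.integers(20))]
                aa_ag = AA_ALPHABET[int(rng.integers(20))]
            a = Residue("H", j + 1, aa_ab, origin)
            b = Residue("A", j + 1, aa_ag, origin)
            pairs.add((a, b))
        maps.append(ContactMap(pairs))
    return maps


# ---------------------------------------------------------------------------
# homolog families for curation tests

def generate_homolog_families(
    n_families: int = 5,
    family_size: int = 3,
    seq_len: int = 120,
    mutation_rate: float = 0.03,
    seed: int = 0,
) -> tuple[list[AbAgComplex], dict[str, int]]:
    """Minimal complexes in heavy-chain homology families.

    Members of a family differ by ~``mutation_rate`` substitutions
    (identity well above 0.95); unrelated families are random sequences
    (identity far below).  KD values are drawn log-uniform over
    1 pM - 100 µM.  Returns the complexes and a complex_id -> family
    index map.
    """
    rng = np.random.default_rng(seed)
    complexes = []
    family_of = {}
    for f in range(n_families):
        base = rng.integers(0, 20, size=seq_len)
        for m in range(family_size):
            seq = base.copy()
            if m > 0:
                k = max(1, int(round(mutation_rate * seq_len)))
                pos = rng.choice(seq_len, size=k, replace=False)
                seq[pos] = (seq[pos] + 1 + rng.integers(0, 19, size=k)) % 20
            heavy = "".join(AA_ALPHABET[i] for i in seq)
            cid = f"fam{f}_m{m}"
            residues = []
            for i, aa in enumerate(heavy):
                residues.append(Residue("H", i + 1, aa,
                                        np.array([i * 4.0, 0.0, 0.0])))
            for chain, y in (("L", 50.0), ("A", 100.0)):
                for i in range(5):
                    residues.append(Residue(chain, i + 1, "A",
                                            np.array([i * 4.0, y, 0.0])))
            kd = 10.0 ** rng.uniform(-12, -4)
            complexes.append(AbAgComplex(
                id=cid, residues=residues,
                chain_roles={"H": "heavy", "L": "light", "A": "antigen"},
                kd=kd))
            family_of[cid] = f
    return complexes, family_of


# ---------------------------------------------------------------------------
# PDB export

def complex_to_pdb(c: AbAgComplex) -> str:
    """Serialize a complex to PDB-format text (CA plus pseudo
    side-chain atoms) via biotite."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = sum(1 + len(r.sidechain_coords) for r in c.residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for r in sorted(c.residues, key=lambda x: (x.chain_id, x.number, x.icode)):
        for name, coord in [("CA", r.ca_coord)] + [
                (f"S{j+1}" if j else "CB", xyz)
                for j, xyz in enumerate(r.sidechain_coords)]:
            arr.coord[i] = coord
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.number
            arr.ins_code[i] = r.icode
            arr.res_name[i] = ONE_TO_THREE[r.aa]
            arr.atom_name[i] = name
            arr.element[i] = "C"
            arr.hetero[i] = False
            i += 1
    f = pdb.PDBFile()
    f.set_structure(arr)
    return "\n".join(f.lines) + "\n"
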