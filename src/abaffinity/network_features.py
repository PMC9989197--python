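"""Residue interaction network (SIN) scores and their 26-feature
aggregation.

Each amino acid of a complex is a node; edges join residue pairs for
which at least one of eight weighted interaction types is geometrically
detected.  A residue's networking score is the sum of the weights of its
edges that cross the epitope-paratope interface, i.e. edges joining an
antibody residue to an antigen residue.

The eight interaction categories, their geometric detection rules and
their weights are configurable; the defaults detect, from the CA and
side-chain heavy-atom coordinates available on the residue model:

========== ======================================================= ======
category   detection rule                                          cutoff
========== ======================================================= ======
hbond      side-chain heavy atoms of two polar-capable residues    3.5 Å
saltbridge acidic (D,E) vs basic (R,K,H) side-chain atoms          4.0 Å
disulfide  two cysteine side-chain atoms                           2.5 Å
pipi       aromatic (F,Y,W) side-chain centroids                   7.0 Å
cationpi   basic side-chain atom vs aromatic centroid              6.0 Å
hydrophob  hydrophobic-class (A,V,I,L,M) side-chain atoms          5.0 Å
vdw        any heavy atoms (CA included)                           4.5 Å
backbone   CA-CA                                                   6.0 Å
========== ======================================================= ======

All default weights are 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .aggregation import FeatureVector, aggregate_interface_scores
from .complex_model import AbAgComplex, CDRId, InterfaceDefinition, Residue

__all__ = [
    "SinConfig",
    "INTERACTION_TYPES",
    "build_sin_graph",
    "residue_networking",
    "sin_features",
    "write_sin_edgelist",
]

INTERACTION_TYPES = (
    "hbond", "saltbridge", "disulfide", "pipi",
    "cationpi", "hydrophob", "vdw", "backbone",
)

_POLAR_CAPABLE = frozenset("NQSTYHKRDEW")
_ACIDIC = frozenset("DE")
_BASIC = frozenset("RKH")
_AROMATIC = frozenset("FYW")
_HYDROPHOBIC = frozenset("AVILM")


@dataclass
class SinConfig:
    """Cutoffs (Å) and weights of the eight interaction types."""

    cutoffs: dict[str, float] = field(default_factory=lambda: {
        "hbond": 3.5, "saltbridge": 4.0, "disulfide": 2.5, "pipi": 7.0,
        "cationpi": 6.0, "hydrophob": 5.0, "vdw": 4.5, "backbone": 6.0,
    })
    weights: dict[str, float] = field(default_factory=lambda: {
        t: 1.0 for t in INTERACTION_TYPES
    })


def _min_dist(xs: np.ndarray, ys: np.ndarray) -> float:
    if xs.size == 0 or ys.size == 0:
        return np.inf
    d = xs[:, None, :] - ys[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).min())


def _detect(a: Residue, b: Residue, cfg: SinConfig) -> dict[str, float]:
    """Interaction categories detected between two residues."""
    sa = np.asarray(a.sidechain_coords).reshape(-1, 3)
    sb = np.asarray(b.sidechain_coords).reshape(-1, 3)
    heavy_a = np.vstack([a.ca_coord[None, :], sa]) if sa.size else a.ca_coord[None, :]
    heavy_b = np.vstack([b.ca_coord[None, :], sb]) if sb.size else b.ca_coord[None, :]
    found: dict[str, float] = {}

    def hit(kind: str, dist: float) -> None:
        if dist < cfg.cutoffs[kind]:
            found[kind] = cfg.weights[kind]

    sc_dist = _min_dist(sa, sb)
    if a.aa in _POLAR_CAPABLE and b.aa in _POLAR_CAPABLE:
        hit("hbond", sc_dist)
    if (a.aa in _ACIDIC and b.aa in _BASIC) or (a.aa in _BASIC and b.aa in _ACIDIC):
        hit("saltbridge", sc_dist)
    if a.aa == "C" and b.aa == "C":
        hit("disulfide", sc_dist)
    cen_a = sa.mean(axis=0) if sa.size else None
    cen_b = sb.mean(axis=0) if sb.size else None
    if a.aa in _AROMATIC and b.aa in _AROMATIC and cen_a is not None and cen_b is not None:
        hit("pipi", float(np.linalg.norm(cen_a - cen_b)))
    if a.aa in _BASIC and b.aa in _AROMATIC and cen_b is not None:
        hit("cationpi", _min_dist(sa, cen_b[None, :]))
    elif b.aa in _BASIC and a.aa in _AROMATIC and cen_a is not None:
        hit("cationpi", _min_dist(sb, cen_a[None, :]))
    if a.aa in _HYDROPHOBIC and b.aa in _HYDROPHOBIC:
        hit("hydrophob", sc_dist)
    hit("vdw", _min_dist(heavy_a, heavy_b))
    hit("backbone", float(np.linalg.norm(a.ca_coord - b.ca_coord)))
    return found


def build_sin_graph(c: AbAgComplex, config: SinConfig | None = None) -> nx.Graph:
    """Weighted residue-interaction graph of one complex.

    Edge weight is the sum of the configured weights of all detected
    categories; the per-category contribution is stored on the edge as
    ``breakdown``.
    """
    cfg = config or SinConfig()
    g = nx.Graph()
    g.add_nodes_from(c.residues)
    # candidate pruning: nothing can interact beyond the largest cutoff
    # plus both side-chain reaches
    from .complex_model import sidechain_length
    reach = {r: sidechain_length(r) for r in c.residues}
    max_cut = max(cfg.cutoffs.values())
    res = c.residues
    for i, a in enumerate(res):
        for b in res[i + 1:]:
            ca_d = float(np.linalg.norm(a.ca_coord - b.ca_coord))
            if ca_d > max_cut + reach[a] + reach[b]:
                continue
            breakdown = _detect(a, b, cfg)
            if breakdown:
                g.add_edge(a, b, weight=sum(breakdown.values()), breakdown=breakdown)
    return g


def residue_networking(
    g: nx.Graph,
    complex_: AbAgComplex,
    iface: InterfaceDefinition,
) -> dict[Residue, float]:
    """Cross-interface networking score per interface residue.

    For each epitope or paratope residue, the weights of its edges whose
    other endpoint lies on the opposite side of the interface are
    summed; interface residues with no cross edges score 0.
    """
    is_antigen = {r: complex_.role_of(r) == "antigen" for r in complex_.residues}
    scores: dict[Residue, float] = {
        r: 0.0 for r in iface.epitope | iface.paratope
    }
    for a, b, data in g.edges(data=True):
        if is_antigen[a] == is_antigen[b]:
            continue
        for r in (a, b):
            if r in scores:
                scores[r] += data["weight"]
    return scores


def sin_features(
    scores: Mapping[Residue, float],
    iface: InterfaceDefinition,
    cdr_map: Mapping[Residue, CDRId],
) -> FeatureVector:
    """26 network features: avg/total per CDR and per CDR-epitope, plus
    whole-epitope and whole-paratope averages."""
    fv = aggregate_interface_scores(scores, iface, cdr_map, prefix="SIN")
    fv.set_name = "SIN"
    return fv


def write_sin_edgelist(g: nx.Graph, path: str) -> None:
    """Export a SIN graph as a TSV edge list
    (node_a, node_b, weight, type breakdown)."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\ttype_breakdown\n")
        for a, b, data in g.edges(data=True):
            bd = ",".join(f"{k}:{v:g}" for k, v in sorted(data["breakdown"].items()))
            fh.write(
                f"{a.chain_id}{a.number}{a.icode}\t{b.chain_id}{b.number}{b.icode}"
                f"\t{data['weight']:g}\t{bd}\n"
            )
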