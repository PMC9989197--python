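"""Amino-acid interface-fitness (AIF) propensity scoring.

A 20×20 propensity matrix is trained from a reference set of contact
maps as a pseudocount-regularized log-odds of observing an ordered
(antibody amino acid, antigen amino acid) contact relative to
independence of the two sides:

    score(x, y) = log2( f(x, y) / (p(x) * p(y)) )

with f(x, y) = (n(x, y) + pc) / N', N' the pseudocount-adjusted total
contact count, and p(x), p(y) the corresponding marginals.  A uniform
reference yields an all-zero matrix, and any enrichment of a pairing
over the product of its marginals scores positive.

Interface residues are then scored as the mean matrix entry over their
cross-interface contact partners, and the per-residue scores aggregated
into the shared 26-feature schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .aggregation import FeatureVector, aggregate_interface_scores
from .complex_model import AA_ALPHABET, CDRId, ContactMap, InterfaceDefinition, Residue

__all__ = [
    "PropensityMatrix",
    "train_propensity",
    "aif_residue_scores",
    "aif_features",
]

_IDX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class PropensityMatrix:
    """20×20 log2 pairing propensities, rows antibody-side, columns
    antigen-side."""

    scores: np.ndarray
    pseudocount: float = 1.0
    training_size: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (20, 20):
            raise ValueError("propensity matrix must be 20x20")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("propensity matrix entries must be finite")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        ab, ag = pair
        return float(self.scores[_IDX[ab], _IDX[ag]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(AA_ALPHABET),
                            columns=list(AA_ALPHABET))

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ab_aa")

    @classmethod
    def read_tsv(cls, path: str) -> "PropensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(AA_ALPHABET), list(AA_ALPHABET)]
        return cls(scores=df.to_numpy())


def train_propensity(
    reference: Iterable[ContactMap],
    pseudocount: float = 1.0,
) -> PropensityMatrix:
    """Train a propensity matrix from reference contact maps.

    Ordered antibody/antigen contacts are pooled over the reference set;
    the result is deterministic and invariant to the order of the
    reference complexes.
    """
    counts = np.zeros((20, 20))
    n_maps = 0
    for m in reference:
        n_maps += 1
        for a, b in m.pairs:
            counts[_IDX[a.aa], _IDX[b.aa]] += 1
    if counts.sum() == 0:
        raise ValueError("no reference contacts")
    joint = counts + pseudocount
    joint /= joint.sum()
    p_ab = joint.sum(axis=1)
    p_ag = joint.sum(axis=0)
    scores = np.log2(joint / np.outer(p_ab, p_ag))
    return PropensityMatrix(scores=scores, pseudocount=pseudocount,
                            training_size=n_maps)


def aif_residue_scores(
    m: ContactMap,
    matrix: PropensityMatrix,
) -> dict[Residue, float]:
    """Mean pairing propensity per interface residue.

    Each residue with at least one cross-interface contact scores the
    mean of the matrix entries over its contact partners; residues with
    no contacts are excluded.
    """
    sums: dict[Residue, float] = {}
    counts: dict[Residue, int] = {}
    # sorted for reproducible float accumulation (pairs is a set of
    # identity-hashed residues)
    for a, b in sorted(m.pairs, key=lambda p: (p[0].key, p[1].key)):
        entry = matrix[a.aa, b.aa]
        for r in (a, b):
            sums[r] = sums.get(r, 0.0) + entry
            counts[r] = counts.get(r, 0) + 1
    return {r: sums[r] / counts[r] for r in sums}


def aif_features(
    scores: Mapping[Residue, float],
    iface: InterfaceDefinition,
    cdr_map: Mapping[Residue, CDRId],
) -> FeatureVector:
    """26 propensity features, same aggregation schema as the network
    feature set."""
    fv = aggregate_interface_scores(scores, iface, cdr_map, prefix="AIF")
    fv.set_name = "AIF"
    return fv
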