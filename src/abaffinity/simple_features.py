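"""Counting feature sets computed directly from the contact map.

Four sets:

``aa_counts`` (400)
    counts of every ordered amino-acid pairing across the interface
    (antibody residue type × antigen residue type).
``aa_counts_CDR`` (150)
    the same contacts abstracted to five chemical classes on each side
    and attributed to the contacting CDR (6 CDRs × 5 × 5).
``num_multivalent`` (7)
    per-CDR multivalency — the number of epitope residues a CDR engages
    that are each engaged by at least two additional CDRs — plus a
    whole-paratope summary.
``Ab_info`` (6 + one-hot block)
    CDR lengths and a one-hot encoding of CDR canonical classes, the
    vocabulary being determined from the dataset at table-build time.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .aggregation import FeatureVector
from .complex_model import (
    AA_ALPHABET,
    AbAgComplex,
    CDRId,
    ContactMap,
    InterfaceDefinition,
    Residue,
)

__all__ = [
    "CHEM_CLASSES",
    "CHEM_CLASS_OF",
    "aa_counts",
    "aa_counts_by_cdr",
    "multivalency_features",
    "cdr_multivalency",
    "AbInfoEncoder",
]

#: Chemical classes partitioning the 20 amino acids.  Histidine is
#: charged only.
CHEM_CLASSES: dict[str, frozenset[str]] = {
    "charged": frozenset("RHKDE"),
    "aromatic": frozenset("FYW"),
    "polar": frozenset("STNQ"),
    "hydrophobic": frozenset("AVILM"),
    "special": frozenset("CGP"),
}
CHEM_CLASS_OF: dict[str, str] = {
    aa: cls for cls, members in CHEM_CLASSES.items() for aa in members
}
_CLASS_ORDER = tuple(CHEM_CLASSES)


def aa_counts(m: ContactMap) -> FeatureVector:
    """400-feature ordered pair counts: (antibody aa, antigen aa).

    The sum over all 400 features equals the number of contact pairs.
    """
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    counts = np.zeros((20, 20))
    for a, b in m.pairs:
        counts[idx[a.aa], idx[b.aa]] += 1
    names = [f"{x}-{y}" for x in AA_ALPHABET for y in AA_ALPHABET]
    return FeatureVector("aa_counts", names, counts.ravel())


def aa_counts_by_cdr(
    m: ContactMap,
    iface: InterfaceDefinition,
    cdr_map: Mapping[Residue, CDRId],
) -> FeatureVector:
    """150-feature chemical-class contact counts per CDR.

    Each contact whose antibody residue belongs to a CDR increments the
    (CDR, antibody class, antigen class) cell; framework contacts are
    excluded.
    """
    names = [
        f"{cdr.value}_{ca}-epitope_{cg}"
        for cdr in CDRId for ca in _CLASS_ORDER for cg in _CLASS_ORDER
    ]
    pos = {n: i for i, n in enumerate(names)}
    values = np.zeros(150)
    for a, b in m.pairs:
        cdr = cdr_map.get(a)
        if cdr is None:
            continue
        key = f"{cdr.value}_{CHEM_CLASS_OF[a.aa]}-epitope_{CHEM_CLASS_OF[b.aa]}"
        values[pos[key]] += 1
    return FeatureVector("aa_counts_CDR", names, values)


def cdr_multivalency(
    m: ContactMap,
    cdr_map: Mapping[Residue, CDRId],
) -> tuple[dict[Residue, set[CDRId]], dict[CDRId, int]]:
    """Per-epitope-residue distinct-CDR incidence and per-CDR
    multivalency counts.

    An epitope residue is multivalent for CDR ``c`` when, besides ``c``,
    at least two additional CDRs contact it (distinct-CDR count >= 3).
    """
    touching: dict[Residue, set[CDRId]] = {}
    for a, b in m.pairs:
        cdr = cdr_map.get(a)
        if cdr is not None:
            touching.setdefault(b, set()).add(cdr)
    counts = {
        c: sum(1 for cdrs in touching.values() if c in cdrs and len(cdrs) >= 3)
        for c in CDRId
    }
    return touching, counts


def multivalency_features(
    m: ContactMap,
    iface: InterfaceDefinition,
    cdr_map: Mapping[Residue, CDRId],
    per_cdr_threshold: int = 5,
) -> FeatureVector:
    """Seven multivalency features.

    Six per-CDR multivalent-contact counts, then the number of CDRs with
    at least ``per_cdr_threshold`` multivalent interactions each.
    """
    _, counts = cdr_multivalency(m, cdr_map)
    names = [f"{c.value}_multivalent" for c in CDRId]
    values = [float(counts[c]) for c in CDRId]
    names.append("num_multivalent_CDRs")
    values.append(float(sum(1 for c in CDRId if counts[c] >= per_cdr_threshold)))
    return FeatureVector("num_multivalent", names, np.array(values))


class AbInfoEncoder:
    """Antibody-information features: six CDR lengths plus a one-hot
    encoding of per-CDR canonical classes.

    The one-hot vocabulary is learned from the dataset annotations at
    fit time (plus a ``None`` category per CDR for missing or failed
    assignments), following the scikit-learn fit/transform convention.
    """

    def __init__(self) -> None:
        self.vocabulary_: Optional[dict[CDRId, list[str]]] = None

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "AbInfoEncoder":
        return self

    def fit(
        self,
        annotations: Sequence[Optional[Mapping[CDRId, str]]],
    ) -> "AbInfoEncoder":
        """Learn the per-CDR class vocabulary from per-complex
        annotations (each a CDR -> class-label map, or None)."""
        vocab: dict[CDRId, set[str]] = {c: set() for c in CDRId}
        for ann in annotations:
            if not ann:
                continue
            for cdr, label in ann.items():
                vocab[CDRId(cdr)].add(str(label))
        self.vocabulary_ = {
            c: sorted(vocab[c]) + ["None"] for c in CDRId
        }
        return self

    @property
    def feature_names_(self) -> list[str]:
        if self.vocabulary_ is None:
            raise RuntimeError("AbInfoEncoder is not fitted")
        names = [f"{c.value}_length" for c in CDRId]
        for c in CDRId:
            names.extend(f"{c.value}_class_{lbl}" for lbl in self.vocabulary_[c])
        return names

    def transform_one(
        self,
        complex_: AbAgComplex,
        annotation: Optional[Mapping[CDRId, str]] = None,
    ) -> FeatureVector:
        if self.vocabulary_ is None:
            raise RuntimeError("AbInfoEncoder is not fitted")
        lengths = {c: 0 for c in CDRId}
        for _, cdr in complex_.cdr_map.items():
            lengths[cdr] += 1
        values = [float(lengths[c]) for c in CDRId]
        for c in CDRId:
            label = "None"
            if annotation:
                label = str(annotation.get(c, annotation.get(c.value, "None")))
            if label not in self.vocabulary_[c]:
                label = "None"
            values.extend(1.0 if lbl == label else 0.0 for lbl in self.vocabulary_[c])
        return FeatureVector("Ab_info", self.feature_names_, np.array(values))
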