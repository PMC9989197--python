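"""Adapters for externally computed scores.

Two kinds of upstream output are consumed rather than computed here:
per-residue surface-interface scores from a trained surface-fingerprint
model (dMaSIF-site style), aggregated into the shared 26-feature schema,
and per-complex interface-energetics records from a macromolecular
modelling suite, passed through as an 18-feature set with strict schema
validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregation import FeatureVector, aggregate_interface_scores
from .complex_model import AbAgComplex, CDRId, InterfaceDefinition, Residue

__all__ = [
    "ResidueScoreFile",
    "ENERGETICS_FIELDS",
    "EnergeticsRecord",
    "read_residue_scores",
    "dmasif_features",
    "energetics_features",
]


@dataclass
class ResidueScoreFile:
    """Per-residue scores keyed by (chain_id, residue number, icode)."""

    complex_id: str
    scores: dict[tuple[str, int, str], float]

    def resolve(self, complex_: AbAgComplex) -> dict[Residue, float]:
        """Map file rows onto the residues of a complex; rows that match
        no residue are reported with a warning and excluded."""
        by_key = {r.key: r for r in complex_.residues}
        out: dict[Residue, float] = {}
        missing = []
        for key, score in self.scores.items():
            r = by_key.get(key)
            if r is None:
                missing.append(key)
            else:
                out[r] = score
        if missing:
            warnings.warn(
                f"{self.complex_id}: {len(missing)} score row(s) match no residue"
            )
        return out


def read_residue_scores(path: str) -> ResidueScoreFile:
    """Read a residue-score TSV (complex_id, chain_id, resnum, score).

    Residue numbers may carry a trailing insertion code (e.g. ``100A``).
    A duplicated residue row is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "resnum": str})
    required = {"complex_id", "chain_id", "resnum", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"residue score file must have columns {sorted(required)}")
    cid = str(df["complex_id"].iloc[0]) if len(df) else ""
    scores: dict[tuple[str, int, str], float] = {}
    for _, row in df.iterrows():
        resnum = str(row["resnum"])
        icode = ""
        if resnum and resnum[-1].isalpha():
            resnum, icode = resnum[:-1], resnum[-1]
        key = (str(row["chain_id"]), int(resnum), icode)
        if key in scores:
            raise ValueError(f"duplicate residue row {key} in {path}")
        scores[key] = float(row["score"])
    return ResidueScoreFile(complex_id=cid, scores=scores)


def dmasif_features(
    scores: ResidueScoreFile | Mapping[Residue, float],
    iface: InterfaceDefinition,
    cdr_map: Mapping[Residue, CDRId],
    complex_: AbAgComplex | None = None,
) -> FeatureVector:
    """26 surface-interface-score features via the shared avg/total
    aggregation.  Accepts either a resolved residue->score mapping or a
    :class:`ResidueScoreFile` plus the complex to resolve against."""
    if isinstance(scores, ResidueScoreFile):
        if complex_ is None:
            raise ValueError("complex_ required to resolve a ResidueScoreFile")
        resolved = scores.resolve(complex_)
    else:
        resolved = dict(scores)
    interface = iface.epitope | iface.paratope
    if not any(r in resolved for r in interface):
        warnings.warn("score file covers no interface residues; features all zero")
    fv = aggregate_interface_scores(resolved, iface, cdr_map, prefix="dMaSIF")
    fv.set_name = "dMaSIF"
    return fv


#: The 18 interface-energetics fields, in feature order.
ENERGETICS_FIELDS = (
    "n_epitope_residues",
    "epitope_sasa",
    "epitope_total_energy",
    "interaction_energy",
    "crossterm_interface_energy",
    "interface_dG",
    "separated_interface_energy_ratio",
    "total_complex_energy",
    "antibody_normalized_score",
    "antigen_normalized_score",
    "sc_total",
    "dSASA",
    "H1_interaction_energy",
    "H2_interaction_energy",
    "H3_interaction_energy",
    "L1_interaction_energy",
    "L2_interaction_energy",
    "L3_interaction_energy",
)


@dataclass
class EnergeticsRecord:
    """One complex's 18 interface-energetics values."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [f for f in ENERGETICS_FIELDS if f not in self.values]
        if missing:
            raise ValueError(f"energetics record missing field(s): {missing}")
        extra = set(self.values) - set(ENERGETICS_FIELDS)
        if extra:
            raise ValueError(f"unknown energetics field(s): {sorted(extra)}")
        for f in ENERGETICS_FIELDS:
            v = float(self.values[f])
            if not np.isfinite(v):
                raise ValueError(f"energetics field {f} is not finite")
            self.values[f] = v

    @classmethod
    def from_json(cls, path: str) -> "EnergeticsRecord":
        with open(path) as fh:
            return cls(values=json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.values, fh, indent=1)


def energetics_features(rec: EnergeticsRecord) -> FeatureVector:
    """Pass an energetics record through as an 18-feature vector."""
    return FeatureVector(
        "Energetics",
        list(ENERGETICS_FIELDS),
        np.array([rec.values[f] for f in ENERGETICS_FIELDS]),
    )
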