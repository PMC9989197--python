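"""Shared 26-feature aggregation of per-residue interface scores.

Several feature sets (residue-network scores, pairing-propensity scores,
externally computed surface-interface scores) reduce to the same schema:
average and total score per CDR (12 features), per CDR-epitope
(12 features), and the average over the entire epitope and the entire
paratope (2 features).  Averages over empty sets are defined as 0 so the
feature vector is always total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .complex_model import CDRId, InterfaceDefinition, Residue

__all__ = ["FeatureVector", "aggregate_interface_scores"]


@dataclass
class FeatureVector:
    """Named, ordered feature values belonging to one feature set."""

    set_name: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate feature names in set {self.set_name!r}")

    def __len__(self) -> int:
        return len(self.names)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.set_name)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _avg_total(scores: Mapping[Residue, float], members) -> tuple[float, float]:
    # members may be identity-hashed sets: sort by positional key so the
    # float accumulation order (hence the last ulp) is reproducible
    vals = [scores[r] for r in sorted(members, key=lambda r: r.key)
            if r in scores]
    if not vals:
        return 0.0, 0.0
    return float(np.mean(vals)), float(np.sum(vals))


def aggregate_interface_scores(
    scores: Mapping[Residue, float],
    iface: InterfaceDefinition,
    cdr_map: Mapping[Residue, CDRId],
    prefix: str,
) -> FeatureVector:
    """Aggregate per-residue scores into the 26-feature schema.

    Per-CDR statistics run over the scored residues of that CDR;
    per-CDR-epitope statistics over the scored antigen residues the CDR
    contacts; the two closing features average over the scored epitope
    and paratope.  Residues absent from ``scores`` do not contribute.
    """
    names: list[str] = []
    values: list[float] = []
    cdr_members: dict[CDRId, list[Residue]] = {c: [] for c in CDRId}
    for r, cdr in cdr_map.items():
        cdr_members[cdr].append(r)

    for cdr in CDRId:
        avg, tot = _avg_total(scores, cdr_members[cdr])
        names += [f"{prefix}_{cdr.value}_avg", f"{prefix}_{cdr.value}_total"]
        values += [avg, tot]
    for cdr in CDRId:
        avg, tot = _avg_total(scores, iface.cdr_epitopes.get(cdr, ()))
        names += [f"{prefix}_{cdr.value}_epitope_avg", f"{prefix}_{cdr.value}_epitope_total"]
        values += [avg, tot]
    for label, members in (("epitope", iface.epitope), ("paratope", iface.paratope)):
        avg, _ = _avg_total(scores, members)
        names.append(f"{prefix}_{label}_avg")
        values.append(avg)
    return FeatureVector(set_name=prefix, names=names, values=np.array(values))
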