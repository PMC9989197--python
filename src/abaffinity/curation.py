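"""Leakage-aware dataset curation.

Reproduces the filtering sequence used before affinity classification:

1. nanobody removal — single-domain antibodies lack a light chain and
   have systematically different affinities, which a classifier would
   exploit;
2. heavy-chain homology filtering — of any group of antibodies sharing
   more than 95% heavy-chain sequence identity, only the member whose
   affinity lies furthest from the dataset median is retained, so
   near-duplicates cannot leak across cross-validation folds;
3. middle drop-out (MDO) — complexes with affinity within one order of
   magnitude of the median are removed, sharpening the high/low
   dichotomy;
4. binary labelling at a KD cutoff (default 1 nM, ``high`` iff
   KD < cutoff).

Affinity is analysed throughout as -log10(KD [M]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .complex_model import AbAgComplex

__all__ = [
    "CurationConfig",
    "CurationReport",
    "neglog10_kd",
    "binary_label",
    "filter_nanobodies",
    "heavy_chain_identity",
    "homology_filter",
    "mdo_filter",
    "curate",
]


@dataclass
class CurationConfig:
    """Thresholds and switches of the curation pipeline."""

    identity_threshold: float = 0.95   # heavy-chain identity fraction
    mdo_width: float = 1.0             # logs around the median
    affinity_cutoff: float = 1e-9      # molar; high iff KD < cutoff
    include_nanobodies: bool = False
    include_homologs: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if not self.affinity_cutoff > 0:
            raise ValueError("affinity_cutoff must be positive")


@dataclass
class CurationReport:
    """Every removal, with its reason."""

    removed: list[dict] = field(default_factory=list)

    def add(self, complex_id: str, stage: str, reason: str) -> None:
        self.removed.append({"complex_id": complex_id, "stage": stage,
                             "reason": reason})

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.removed, fh, indent=1)


def neglog10_kd(kd: float) -> float:
    """Affinity score -log10(KD [M]); higher = stronger binding."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    return -float(np.log10(kd))


def binary_label(complex_: AbAgComplex, cfg: CurationConfig | None = None) -> str:
    """``high`` iff KD is strictly below the affinity cutoff."""
    cfg = cfg or CurationConfig()
    if complex_.kd is None:
        raise ValueError(f"{complex_.id}: no affinity label")
    return "high" if complex_.kd < cfg.affinity_cutoff else "low"


def filter_nanobodies(
    dataset: Sequence[AbAgComplex],
    cfg: CurationConfig | None = None,
    report: Optional[CurationReport] = None,
) -> list[AbAgComplex]:
    """Drop complexes without a light chain, unless nanobodies are
    explicitly included."""
    cfg = cfg or CurationConfig()
    if cfg.include_nanobodies:
        return list(dataset)
    out = []
    for c in dataset:
        if c.has_light_chain:
            out.append(c)
        elif report is not None:
            report.add(c.id, "nanobody", "no light chain")
    return out


def heavy_chain_identity(a: AbAgComplex | str, b: AbAgComplex | str) -> float:
    """Fraction of identical positions under global alignment.

    Alignment uses match 1 / mismatch 0 / gap -1 (the gap penalty shapes
    the alignment only); identity is identical positions divided by the
    alignment length including gap columns.  Because co-optimal
    alignments can differ in match count (extra gap columns can buy
    extra matches at equal score), score ties are broken toward more
    matches with an epsilon on the match score, which makes the identity
    well-defined; the pair is canonically ordered before aligning, so
    the function is symmetric.
    """
    from Bio import Align

    sa = a if isinstance(a, str) else a.chain_sequence("heavy")
    sb = b if isinstance(b, str) else b.chain_sequence("heavy")
    if not sa or not sb:
        raise ValueError("empty heavy-chain sequence")
    sa, sb = sorted((sa, sb))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1 + 1e-6   # epsilon cannot flip unit score gaps
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(sa, sb)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def homology_filter(
    dataset: Sequence[AbAgComplex],
    cfg: CurationConfig | None = None,
    report: Optional[CurationReport] = None,
) -> list[AbAgComplex]:
    """Collapse groups of high-identity antibodies to one member each.

    Complexes are visited in id order and greedily clustered: a complex
    joins the first existing cluster whose representative (its first
    member) exceeds the identity threshold.  From each cluster the
    member whose affinity is furthest (on the -log10 KD scale) from the
    dataset median is retained, ties going to the lower id.
    """
    cfg = cfg or CurationConfig()
    if cfg.include_homologs or len(dataset) <= 1:
        return list(dataset)
    ordered = sorted(dataset, key=lambda c: c.id)
    median = float(np.median([neglog10_kd(c.kd) for c in ordered]))
    clusters: list[list[AbAgComplex]] = []
    for c in ordered:
        for cluster in clusters:
            if heavy_chain_identity(c, cluster[0]) > cfg.identity_threshold:
                cluster.append(c)
                break
        else:
            clusters.append([c])
    kept: list[AbAgComplex] = []
    for cluster in clusters:
        # furthest from median; lower id on ties
        best = sorted(cluster,
                      key=lambda c: (-abs(neglog10_kd(c.kd) - median), c.id))[0]
        kept.append(best)
        if report is not None:
            for c in cluster:
                if c is not best:
                    report.add(c.id, "homology",
                               f">{cfg.identity_threshold:.0%} heavy identity "
                               f"with {best.id}")
    return sorted(kept, key=lambda c: c.id)


def mdo_filter(
    dataset: Sequence[AbAgComplex],
    cfg: CurationConfig | None = None,
    report: Optional[CurationReport] = None,
) -> list[AbAgComplex]:
    """Middle drop-out: remove complexes within ``mdo_width`` logs of
    the dataset median affinity (median computed on the input set,
    before removal)."""
    cfg = cfg or CurationConfig()
    if not dataset:
        return []
    median = float(np.median([neglog10_kd(c.kd) for c in dataset]))
    out = []
    for c in dataset:
        dist = abs(neglog10_kd(c.kd) - median)
        if dist < cfg.mdo_width:
            if report is not None:
                report.add(c.id, "mdo",
                           f"{dist:.2f} logs from median {median:.2f}")
        else:
            out.append(c)
    return out


def curate(
    dataset: Sequence[AbAgComplex],
    cfg: CurationConfig | None = None,
) -> tuple[list[AbAgComplex], CurationReport]:
    """Full curation sequence: nanobody removal, homology filter, MDO."""
    cfg = cfg or CurationConfig()
    report = CurationReport()
    out = filter_nanobodies(dataset, cfg, report)
    out = homology_filter(out, cfg, report)
    out = mdo_filter(out, cfg, report)
    return out, report
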