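"""Orchestration: feature-table assembly and end-to-end runs.

The eight feature sets are

====================== ===== ==========================================
set                    width source
====================== ===== ==========================================
aa_counts              400   ordered amino-acid pair counts
aa_counts_CDR          150   chemical-class counts per CDR
num_multivalent        7     per-CDR multivalency
Ab_info                6+v   CDR lengths + canonical-class one-hot
SIN                    26    residue-network scores
AIF                    26    pairing-propensity scores
dMaSIF                 26    external surface-interface scores
Energetics             18    external interface energetics
====================== ===== ==========================================

External sets are consumed through adapter files; complexes without a
file get masked (not zero-filled) entries for that set only, so runs on
the six internally computed sets are first-class.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import classify, curation, network_features, simple_features, statistical_features
from .aggregation import FeatureVector
from .complex_model import (
    AbAgComplex,
    CDRId,
    compute_contact_map,
    define_interface,
    parse_complex,
)
from .external_adapters import (
    EnergeticsRecord,
    ResidueScoreFile,
    dmasif_features,
    energetics_features,
)
from .statistical_features import PropensityMatrix, train_propensity

logger = logging.getLogger("abaffinity")

__all__ = [
    "SIMPLE_SETS",
    "EXTERNAL_SETS",
    "ALL_SETS",
    "EXPECTED_WIDTHS",
    "FeatureTable",
    "InterfaceFeaturizer",
    "assemble_table",
    "read_manifest",
    "run_end_to_end",
]

SIMPLE_SETS = ("aa_counts", "aa_counts_CDR", "num_multivalent", "Ab_info")
INTERFACE_SETS = ("SIN", "AIF")
EXTERNAL_SETS = ("dMaSIF", "Energetics")
ALL_SETS = SIMPLE_SETS + INTERFACE_SETS + EXTERNAL_SETS

#: Fixed per-set widths (Ab_info is dataset-dependent).
EXPECTED_WIDTHS = {
    "aa_counts": 400,
    "aa_counts_CDR": 150,
    "num_multivalent": 7,
    "SIN": 26,
    "AIF": 26,
    "dMaSIF": 26,
    "Energetics": 18,
}


@dataclass
class FeatureTable:
    """Complexes × named features, partitioned into feature sets.

    ``mask`` is True where a value is missing (external adapter file
    absent for that complex).
    """

    data: pd.DataFrame
    set_map: dict[str, str]            # feature name -> set name
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("complex ids must be unique")
        for name in self.data.columns:
            if name not in self.set_map:
                raise ValueError(f"feature {name!r} has no parent set")
        self.validate_widths()

    def validate_widths(self) -> None:
        widths: dict[str, int] = {}
        for name, set_name in self.set_map.items():
            widths[set_name] = widths.get(set_name, 0) + 1
        for set_name, width in widths.items():
            expected = EXPECTED_WIDTHS.get(set_name)
            if expected is not None and width != expected:
                raise ValueError(
                    f"feature set {set_name!r} has width {width}, "
                    f"expected {expected}")

    @property
    def set_names(self) -> list[str]:
        seen: list[str] = []
        for name in self.data.columns:
            s = self.set_map[name]
            if s not in seen:
                seen.append(s)
        return seen

    def per_set(self, set_name: str, drop_masked: bool = True) -> pd.DataFrame:
        """The sub-table of one feature set; rows with masked entries
        are dropped by default."""
        cols = [n for n in self.data.columns if self.set_map[n] == set_name]
        if not cols:
            raise KeyError(f"no features in set {set_name!r}")
        sub = self.data[cols]
        if drop_masked:
            keep = ~self.mask[cols].any(axis=1)
            sub = sub.loc[keep]
        return sub

    def subset(self, ids: Sequence[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.data.loc[ids], dict(self.set_map),
                            self.mask.loc[ids])

    # -- CSV round trip ------------------------------------------------
    def to_csv(self, path: str) -> None:
        df = self.data.copy()
        df.columns = pd.MultiIndex.from_tuples(
            [(self.set_map[c], c) for c in df.columns],
            names=["set", "feature"])
        out = df.where(~self.mask.to_numpy())
        out.to_csv(path, index_label="complex_id")

    @classmethod
    def from_csv(cls, path: str) -> "FeatureTable":
        df = pd.read_csv(path, header=[0, 1], index_col=0)
        df.index.name = None
        set_map = {feat: s for s, feat in df.columns}
        df.columns = [feat for _, feat in df.columns]
        mask = df.isna()
        return cls(df.fillna(0.0), set_map, mask)


class InterfaceFeaturizer(TransformerMixin, BaseEstimator):
    """Structure-to-features transformer.

    ``fit`` learns the dataset-dependent pieces: the canonical-class
    one-hot vocabulary of the Ab_info set and — when no propensity
    matrix is supplied — a pairing-propensity matrix trained on the
    contact maps of the fit complexes.  ``transform`` emits a
    :class:`FeatureTable` over the enabled sets, resolving optional
    external adapter inputs per complex and masking absentees.

    Parameters
    ----------
    enabled_sets:
        subset of the eight set names; defaults to the six internally
        computed sets.
    interaction_distance:
        contact-criterion interaction distance in Å.
    sin_config:
        interaction-type cutoffs/weights for the network set.
    propensity:
        pre-trained :class:`PropensityMatrix`; trained on the fit data
        when omitted.
    """

    def __init__(
        self,
        enabled_sets: Sequence[str] = SIMPLE_SETS + INTERFACE_SETS,
        interaction_distance: float = 4.5,
        sin_config: Optional[network_features.SinConfig] = None,
        propensity: Optional[PropensityMatrix] = None,
        propensity_pseudocount: float = 1.0,
    ):
        self.enabled_sets = tuple(enabled_sets)
        self.interaction_distance = interaction_distance
        self.sin_config = sin_config
        self.propensity = propensity
        self.propensity_pseudocount = propensity_pseudocount

    def fit(self, complexes: Sequence[AbAgComplex], y=None,
            canonical_classes: Optional[Mapping[str, Mapping]] = None,
            ) -> "InterfaceFeaturizer":
        unknown = set(self.enabled_sets) - set(ALL_SETS)
        if unknown:
            raise ValueError(f"unknown feature set(s): {sorted(unknown)}")
        self.ab_info_encoder_ = simple_features.AbInfoEncoder().fit([
            (canonical_classes or {}).get(c.id) for c in complexes])
        if "AIF" in self.enabled_sets:
            if self.propensity is not None:
                self.propensity_ = self.propensity
            else:
                maps = [compute_contact_map(c, self.interaction_distance)
                        for c in complexes]
                self.propensity_ = train_propensity(
                    [m for m in maps if m.pairs],
                    pseudocount=self.propensity_pseudocount)
        return self

    def featurize_one(
        self,
        c: AbAgComplex,
        residue_scores: Optional[ResidueScoreFile] = None,
        energetics: Optional[EnergeticsRecord] = None,
        canonical: Optional[Mapping] = None,
    ) -> dict[str, Optional[FeatureVector]]:
        """All enabled feature vectors for one complex (None where an
        external adapter input is absent)."""
        m = compute_contact_map(c, self.interaction_distance)
        iface = define_interface(c, m)
        out: dict[str, Optional[FeatureVector]] = {}
        for set_name in self.enabled_sets:
            if set_name == "aa_counts":
                out[set_name] = simple_features.aa_counts(m)
            elif set_name == "aa_counts_CDR":
                out[set_name] = simple_features.aa_counts_by_cdr(m, iface, c.cdr_map)
            elif set_name == "num_multivalent":
                out[set_name] = simple_features.multivalency_features(
                    m, iface, c.cdr_map)
            elif set_name == "Ab_info":
                out[set_name] = self.ab_info_encoder_.transform_one(c, canonical)
            elif set_name == "SIN":
                g = network_features.build_sin_graph(c, self.sin_config)
                scores = network_features.residue_networking(g, c, iface)
                out[set_name] = network_features.sin_features(scores, iface, c.cdr_map)
            elif set_name == "AIF":
                scores = statistical_features.aif_residue_scores(m, self.propensity_)
                out[set_name] = statistical_features.aif_features(
                    scores, iface, c.cdr_map)
            elif set_name == "dMaSIF":
                out[set_name] = (
                    dmasif_features(residue_scores, iface, c.cdr_map, c)
                    if residue_scores is not None else None)
            elif set_name == "Energetics":
                out[set_name] = (energetics_features(energetics)
                                 if energetics is not None else None)
        return out

    def transform(
        self,
        complexes: Sequence[AbAgComplex],
        residue_scores: Optional[Mapping[str, ResidueScoreFile]] = None,
        energetics: Optional[Mapping[str, EnergeticsRecord]] = None,
        canonical_classes: Optional[Mapping[str, Mapping]] = None,
    ) -> FeatureTable:
        rows: list[dict[str, float]] = []
        masks: list[dict[str, bool]] = []
        set_map: dict[str, str] = {}
        for c in complexes:
            fvs = self.featurize_one(
                c,
                (residue_scores or {}).get(c.id),
                (energetics or {}).get(c.id),
                (canonical_classes or {}).get(c.id),
            )
            row: dict[str, float] = {}
            mask: dict[str, bool] = {}
            for set_name, fv in fvs.items():
                if fv is None:
                    continue
                for name, value in zip(fv.names, fv.values):
                    row[name] = float(value)
                    mask[name] = False
                    set_map.setdefault(name, set_name)
            rows.append(row)
            masks.append(mask)
        data = pd.DataFrame(rows, index=[c.id for c in complexes])
        maskf = pd.DataFrame(masks, index=data.index, dtype=object)
        maskf = maskf.reindex(columns=data.columns)
        maskf = maskf.where(maskf.notna(), True).astype(bool)
        data = data.fillna(0.0)
        return FeatureTable(data, set_map, maskf)


def assemble_table(
    complexes: Sequence[AbAgComplex],
    enabled_sets: Sequence[str] = SIMPLE_SETS + INTERFACE_SETS,
    residue_scores: Optional[Mapping[str, ResidueScoreFile]] = None,
    energetics: Optional[Mapping[str, EnergeticsRecord]] = None,
    canonical_classes: Optional[Mapping[str, Mapping]] = None,
    **featurizer_kwargs,
) -> FeatureTable:
    """One-call feature-table assembly (fit + transform on the same
    complexes)."""
    fz = InterfaceFeaturizer(enabled_sets=enabled_sets, **featurizer_kwargs)
    fz.fit(complexes, canonical_classes=canonical_classes)
    return fz.transform(complexes, residue_scores, energetics, canonical_classes)


# ---------------------------------------------------------------------------
# manifest I/O

def read_manifest(path: str) -> list[AbAgComplex]:
    """Load complexes from a dataset manifest TSV with columns
    complex_id, pdb_path, heavy_chain, light_chain, antigen_chains,
    kd_molar, resolution.  Relative PDB paths resolve against the
    manifest's directory; an empty light_chain marks a nanobody."""
    base = os.path.dirname(os.path.abspath(path))
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        roles = {row["heavy_chain"]: "heavy"}
        light = row.get("light_chain")
        if isinstance(light, str) and light.strip():
            roles[light] = "light"
        for ch in str(row["antigen_chains"]).split(","):
            roles[ch.strip()] = "antigen"
        pdb_path = row["pdb_path"]
        if not os.path.isabs(pdb_path):
            pdb_path = os.path.join(base, pdb_path)
        with open(pdb_path) as fh:
            text = fh.read()
        kd = row.get("kd_molar")
        res = row.get("resolution")
        out.append(parse_complex(
            text, roles, complex_id=row["complex_id"],
            kd=float(kd) if kd and not pd.isna(kd) else None,
            resolution=float(res) if res and not pd.isna(res) else None))
    return out


# ---------------------------------------------------------------------------
# end-to-end

@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs."""

    generator: Optional["object"] = None      # GeneratorConfig for synthetic runs
    curation: curation.CurationConfig = field(
        default_factory=curation.CurationConfig)
    cv: classify.CVConfig = field(default_factory=classify.CVConfig)
    enabled_sets: tuple = SIMPLE_SETS + INTERFACE_SETS
    run_randomization_control: bool = False
    seed: int = 0


def run_end_to_end(
    config: PipelineConfig,
    complexes: Optional[Sequence[AbAgComplex]] = None,
    out_dir: Optional[str] = None,
    **transform_inputs,
) -> dict:
    """curate → featurize → select → classify → report.

    With no ``complexes``, a synthetic dataset is generated from
    ``config.generator`` and affinities are planted per its effect
    spec.  Returns the report dict (also written as JSON to
    ``out_dir``); deterministic given the seeds in ``config``.
    """
    from .synthetic_data import GeneratorConfig, generate_dataset, plant_affinity

    if complexes is None:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        logger.info("generating %d synthetic complexes", gen.n_complexes)
        complexes, _ = generate_dataset(gen)
        fz = InterfaceFeaturizer(enabled_sets=config.enabled_sets)
        fz.fit(complexes)
        table0 = fz.transform(complexes, **transform_inputs)
        kd, _ = plant_affinity(table0.data, gen.effect_spec,
                               gen.noise_scale, seed=gen.seed)
        for c, k in zip(complexes, kd):
            c.kd = float(k)

    curated, report = curation.curate(list(complexes), config.curation)
    logger.info("curation kept %d of %d complexes",
                len(curated), len(complexes))
    table = assemble_table(curated, config.enabled_sets, **transform_inputs)
    labels = [curation.binary_label(c, config.curation) for c in curated]
    affinities = [curation.neglog10_kd(c.kd) for c in curated]

    results: dict = {
        "n_input": len(complexes),
        "n_curated": len(curated),
        "n_removed": len(report.removed),
        "seed": config.seed,
        "per_set": {},
    }
    label_of = {c.id: lab for c, lab in zip(curated, labels)}
    reports: dict[str, classify.CVReport] = {}
    per_set_tables: dict[str, pd.DataFrame] = {}
    for set_name in table.set_names:
        sub = table.per_set(set_name)
        per_set_tables[set_name] = sub
        cv = classify.run_cv(sub, [label_of[i] for i in sub.index], config.cv)
        reports[set_name] = cv
        results["per_set"][set_name] = {
            "median_auc": cv.median_auc,
            "median_f1": cv.median_f1,
            "n_features": sub.shape[1],
        }

    combined = classify.combined_select(per_set_tables, labels, k_per_set=2)
    cfg_comb = classify.CVConfig(
        n_repeats=config.cv.n_repeats, n_folds=config.cv.n_folds,
        selector_k=None, seed=config.cv.seed,
        classifier_kind=config.cv.classifier_kind)
    cv_comb = classify.run_cv(table.data[combined], labels, cfg_comb)
    reports["combined"] = cv_comb
    results["combined"] = {
        "median_auc": cv_comb.median_auc,
        "median_f1": cv_comb.median_f1,
        "features": combined,
    }
    results["recurrently_misclassified"] = classify.track_misclassified(reports)
    if config.run_randomization_control:
        results["randomization_control_auc"] = classify.randomization_control(
            table.data[combined], labels, cfg_comb)
    corr, constant = classify.feature_affinity_correlations(
        table.data[combined], affinities)
    results["affinity_correlations"] = {
        name: float(corr.loc[name, "neg_log10_kd"]) for name in combined}

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "features.csv"))
        report.to_json(os.path.join(out_dir, "curation_report.json"))
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(results, fh, indent=1)
    return results
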