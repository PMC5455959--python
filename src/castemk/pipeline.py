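"""Orchestration: expression filter, class labels, and the full analysis.

``run_pipeline`` ties the stages together the way the study does: gene
classes (reproductive / worker / NDE) -> per-class ML alpha with bootstrap
CIs and pairwise comparisons -> per-class age distributions with the
Poisson GLM -> class x condensed-category residual grid -> per-class GO
over-representation.  Inputs come either from files named in the config or
from the synthetic study generator; a provenance block (seeds, thresholds,
version) is embedded in every report, and a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .classstats import contingency_residuals, glm_mean_stratum, go_enrichment
from .mk import MKAlphaModel, compare_classes
from .simulate import StudyBundle, StudyConfig, simulate_study

__all__ = [
    "PipelineConfig",
    "filter_expressed",
    "ingest_de_labels",
    "run_pipeline",
]

CLASS_LABELS = ("reproductive", "worker", "NDE")


def filter_expressed(fpkm: pd.DataFrame, tissue_of_sample: Mapping[str, str],
                     min_fpkm: float = 1.0, rule: str = "per-tissue"):
    """Remove genes with FPKM below threshold in at least half of each tissue.

    Under the default ``per-tissue`` rule a gene is removed iff, in every
    one of the three tissues separately, at least half of that tissue's
    samples fall below ``min_fpkm`` ("at least half" is inclusive).  The
    alternative ``pooled`` rule applies the half-of-samples test to all
    samples at once.

    Returns ``(retained_gene_ids, n_removed)``.
    """
    unknown = [s for s in fpkm.columns if s not in tissue_of_sample]
    if unknown:
        raise ValueError(f"samples with unknown tissue: {unknown[:10]}")
    tissues = sorted(set(tissue_of_sample[s] for s in fpkm.columns))
    if rule == "per-tissue":
        if len(tissues) != 3:
            raise ValueError(f"expected samples from exactly 3 tissues, got {tissues}")
        low_in_tissue = []
        for t in tissues:
            cols = [s for s in fpkm.columns if tissue_of_sample[s] == t]
            frac_low = (fpkm[cols] < min_fpkm).sum(axis=1) / len(cols)
            low_in_tissue.append(frac_low >= 0.5)
        removed = np.logical_and.reduce(low_in_tissue)
    elif rule == "pooled":
        frac_low = (fpkm < min_fpkm).sum(axis=1) / fpkm.shape[1]
        removed = (frac_low >= 0.5).to_numpy()
    else:
        raise ValueError("rule must be 'per-tissue' or 'pooled'")
    retained = list(fpkm.index[~removed])
    return retained, int(removed.sum())


def ingest_de_labels(de_results: pd.DataFrame, fdr_cutoff: float = 0.05,
                     effect_col: str = "logFC", fdr_col: str = "FDR",
                     gene_col: str = "gene_id",
                     positive_label: str = "reproductive",
                     negative_label: str = "worker") -> pd.Series:
    """Caste class labels from a differential-expression results table.

    Genes with FDR below the cutoff are labelled by the sign of the effect
    (positive = upregulated toward ``positive_label``); everything else is
    NDE.  The labels are mutually exclusive by construction.
    """
    for c in (gene_col, effect_col, fdr_col):
        if c not in de_results.columns:
            raise ValueError(f"DE results table lacks required column {c!r}")
    sig = de_results[fdr_col] < fdr_cutoff
    labels = np.where(
        sig & (de_results[effect_col] > 0), positive_label,
        np.where(sig & (de_results[effect_col] < 0), negative_label, "NDE"),
    )
    return pd.Series(labels, index=de_results[gene_col].astype(str).values,
                     name="class_label")


@dataclass
class PipelineConfig:
    """Everything one run needs; file paths may be replaced by simulation.

    When ``synthetic`` is set, inputs are generated by
    :func:`castemk.simulate.simulate_study` under ``study`` (planted study
    conditions); otherwise ``counts_tsv``/``classes_tsv``/``ages_tsv``/
    ``go_tsv`` must point at existing files.
    """

    synthetic: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)
    counts_tsv: Optional[str] = None
    classes_tsv: Optional[str] = None
    ages_tsv: Optional[str] = None
    go_tsv: Optional[str] = None
    bootstrap_B: int = 1000
    seed: int = 7
    go_p_cutoff: float = 0.05
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("counts_tsv", "classes_tsv", "ages_tsv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config.{name}: missing input {p!r}")


def _load_inputs(config: PipelineConfig):
    if config.synthetic:
        bundle = simulate_study(config.study)
        return bundle.counts, bundle.classes, bundle.ages, bundle.go
    counts = pd.read_csv(config.counts_tsv, sep="\t")
    classes = pd.read_csv(config.classes_tsv, sep="\t").set_index("gene_id")[
        "class_label"
    ]
    ages = pd.read_csv(config.ages_tsv, sep="\t")
    go = pd.read_csv(config.go_tsv, sep="\t") if config.go_tsv else None
    return counts, classes, ages, go


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the complete class-level analysis; returns the report dict.

    Report sections: ``alpha`` (per-class estimates with CIs when
    ``bootstrap_B > 0``), ``comparisons`` (pairwise bootstrap tests,
    including each class against zero), ``glm`` (reproductive vs worker
    mean condensed category), ``contingency`` (chi-square + residual
    grid), ``go`` (enriched terms per class) and ``provenance``.
    Writes JSON + TSVs under ``config.out_dir`` when set.
    """
    config.validate()
    counts, classes, ages, go = _load_inputs(config)
    counts = counts.set_index("gene_id", drop=False)
    class_of = classes.reindex(counts.index)
    rng = np.random.default_rng(config.seed)
    report: dict = {"alpha": {}, "comparisons": {}, "glm": None,
                    "contingency": None, "go": {}}

    per_class_counts = {
        label: counts.loc[class_of == label] for label in CLASS_LABELS
    }
    class_seeds = {label: int(rng.integers(2**31)) for label in CLASS_LABELS}
    for label in CLASS_LABELS:
        model = MKAlphaModel(per_class_counts[label], label=label)
        if config.bootstrap_B > 0:
            res = model.bootstrap(B=config.bootstrap_B, seed=class_seeds[label])
        else:
            res = model.fit()
        report["alpha"][label] = res.to_dict()
    all_model = MKAlphaModel(counts, label="all")
    all_seed = int(rng.integers(2**31))
    res_all = (
        all_model.bootstrap(B=config.bootstrap_B, seed=all_seed)
        if config.bootstrap_B > 0 else all_model.fit()
    )
    report["alpha"]["all"] = res_all.to_dict()

    if config.bootstrap_B > 0:
        pairs = [("reproductive", "worker"), ("reproductive", "NDE"),
                 ("worker", "NDE")]
        for a, b in pairs:
            cmp_seed = int(rng.integers(2**31))
            cmp_res = compare_classes(
                per_class_counts[a], per_class_counts[b],
                B=config.bootstrap_B, seed=cmp_seed, label_a=a, label_b=b,
            )
            report["comparisons"][f"{a}_vs_{b}"] = {
                "delta_hat": cmp_res.delta_hat,
                "bootstrap_p": cmp_res.bootstrap_p,
                "seed": cmp_seed,
            }
        for a in CLASS_LABELS:
            cmp_seed = int(rng.integers(2**31))
            cmp_res = compare_classes(
                per_class_counts[a], None, B=config.bootstrap_B,
                seed=cmp_seed, label_a=a, label_b="zero",
            )
            report["comparisons"][f"{a}_vs_zero"] = {
                "delta_hat": cmp_res.delta_hat,
                "bootstrap_p": cmp_res.bootstrap_p,
                "seed": cmp_seed,
            }

    # gene ages: shared table across sections (no re-derivation)
    ages = ages.set_index("gene_id")
    from .phylostrat import CONDENSED_CATEGORIES

    cat_index = {c: i + 1 for i, c in enumerate(CONDENSED_CATEGORIES)}
    caste = class_of[class_of.isin(("reproductive", "worker"))]
    glm_table = pd.DataFrame(
        {
            "class_label": caste,
            "stratum": ages.loc[caste.index, "condensed_category"].map(cat_index),
        }
    ).dropna()
    glm_res = glm_mean_stratum(glm_table)
    report["glm"] = {
        "coefficient": glm_res.coefficient, "std_error": glm_res.std_error,
        "z": glm_res.z, "p_value": glm_res.p_value, "df": glm_res.df,
        "dispersion": glm_res.dispersion, "family_used": glm_res.family_used,
        "reference_class": glm_res.reference_class,
        "contrast_class": glm_res.contrast_class,
    }

    ctab = (
        pd.crosstab(caste, ages.loc[caste.index, "condensed_category"])
        .reindex(columns=[c for c in CONDENSED_CATEGORIES], fill_value=0)
    )
    ctab = ctab.loc[:, ctab.sum(axis=0) > 0]
    cont = contingency_residuals(ctab)
    report["contingency"] = {
        "chi_square": cont.chi_square, "df": cont.df, "p_value": cont.p_value,
        "cells": cont.cells.to_dict(orient="records"),
    }

    if go is not None and len(go):
        background = list(counts.index)
        for label in ("reproductive", "worker"):
            gene_set = list(class_of[class_of == label].index)
            enr = go_enrichment(gene_set, background, go,
                                p_cutoff=config.go_p_cutoff)
            report["go"][label] = enr[enr["enriched"]].to_dict(orient="records")

    report["class_counts"] = {
        label: int((class_of == label).sum()) for label in CLASS_LABELS
    }
    report["provenance"] = {
        "castemk_version": __version__,
        "seed": config.seed,
        "class_seeds": class_seeds,
        "bootstrap_B": config.bootstrap_B,
        "go_p_cutoff": config.go_p_cutoff,
        "synthetic": config.synthetic,
    }
    if config.out_dir:
        _write_report(report, counts, ages, config)
    return report


def _write_report(report, counts, ages, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    pd.DataFrame(report["contingency"]["cells"]).to_csv(
        out / "mosaic_cells.tsv", sep="\t", index=False
    )
    rows = []
    for label, d in report["alpha"].items():
        rows.append({"class_label": label, **{k: v for k, v in d.items()
                                              if k != "class_label"}})
    pd.DataFrame(rows).to_csv(out / "alpha_estimates.tsv", sep="\t", index=False)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
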