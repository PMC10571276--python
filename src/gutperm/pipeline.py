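"""End-to-end orchestration: curate -> describe -> ionize -> assemble ->
stats -> rules -> stacked model, with per-stage CSV outputs and a JSON
report.

All randomness flows from one master seed, split into per-stage seeds, so a
rerun with the same config is numerically identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import descriptors as desc
from . import rules as rules_mod
from . import set_assembly as sa
from . import stats as st
from . import superlearner as sl
from .ionization import DEFAULT_PH, assign_ionization_class
from .records import (
    CompoundRecord,
    ReadReport,
    deduplicate_across_sets,
    read_compound_table,
    write_compound_table,
    write_skip_log,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    inputs: list  # list of {"path": ..., "source": ...}
    out_dir: str
    ph: float = DEFAULT_PH
    outer_folds: int = sl.DEFAULT_OUTER_FOLDS
    cv_folds: int = sl.DEFAULT_CV_FOLDS
    seed: int = 0
    split: str = "random"  # or "butina"
    butina_threshold: float = sl.BUTINA_THRESHOLD
    alpha: float = st.DEFAULT_ALPHA
    correction: str = "bonferroni"
    strip_stereo: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for item in self.inputs:
            p = Path(item["path"])
            if not p.exists():
                raise FileNotFoundError(f"input table not found: {p}")
        if self.split not in ("random", "butina"):
            raise ValueError(f"unknown split mode {self.split!r}")


def _descriptor_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = desc.compute_descriptors(r.smiles)
        rows.append([r.id, *d.as_array()])
    return pd.DataFrame(rows, columns=["id", *desc.DescriptorVector.NAMES])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as report.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {k: int(s) for k, s in zip(("folds", "model"), rng.integers(0, 2**31 - 1, 2))}
    report: dict = {"config": {**vars(config)}, "stages": {}}
    t0 = time.time()

    def _stage(name: str, **info) -> None:
        info["elapsed_s"] = round(time.time() - t0, 2)
        report["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    # -- curate --------------------------------------------------------------
    read_report = ReadReport()
    records: list[CompoundRecord] = []
    for item in config.inputs:
        records.extend(
            read_compound_table(item["path"], item["source"], report=read_report)
        )
    records = deduplicate_across_sets(records, strip_stereo=config.strip_stereo)
    write_skip_log(read_report, out / "skip_log.txt")
    _stage("curate", n_rows=read_report.n_rows, n_curated=len(records),
           n_skipped_structure=read_report.n_skipped_structure)

    # -- assemble ------------------------------------------------------------
    records, assembly = sa.assemble(records)
    write_compound_table(records, out / "master.csv")
    with open(out / "set_sizes.json", "w", encoding="utf-8") as fh:
        json.dump({"sizes": assembly.sizes, "moved_fl": assembly.moved_fl}, fh, indent=2)
    _stage("assemble", sizes=assembly.sizes, moved_fl=assembly.moved_fl)

    # -- descriptors & scaffolds --------------------------------------------
    desc_df = _descriptor_frame(records)
    desc_df.to_csv(out / "descriptors.csv", index=False)
    scaff_rows = []
    for set_name in (sa.DRUGBANK, sa.GUT_SERUM, sa.GUT):
        smiles = [r.smiles for r in records if r.compartment_set == set_name]
        if smiles:
            s = desc.scaffold_set_stats(smiles)
            scaff_rows.append({"set": set_name, **vars(s)})
    pd.DataFrame(scaff_rows).to_csv(out / "scaffolds.csv", index=False)
    _stage("describe", n_descriptor_rows=len(desc_df), n_scaffold_sets=len(scaff_rows))

    # -- ionization ----------------------------------------------------------
    ion_rows = []
    for r in records:
        call = assign_ionization_class(r.pka_strongest_acidic, r.pka_strongest_basic, config.ph)
        ion_rows.append((r.id, call.ion_class.value))
    ion_df = pd.DataFrame(ion_rows, columns=["id", "ion_class"])
    ion_df.to_csv(out / "ionization.csv", index=False)
    _stage("ionize", ph=config.ph, classes=ion_df["ion_class"].value_counts().to_dict())

    # -- stats ---------------------------------------------------------------
    labeled = [r for r in records if r.permanence_label is not None]
    sets_present = sorted({r.compartment_set for r in records})
    classes_present = sorted({r.chem_class for r in records})
    table = np.zeros((len(sets_present), len(classes_present)), dtype=int)
    for r in records:
        table[sets_present.index(r.compartment_set), classes_present.index(r.chem_class)] += 1
    enrich = st.contingency_posthoc(table, alpha=config.alpha, correction=config.correction)
    enrich.to_frame(sets_present, classes_present).to_csv(out / "enrichment.csv", index=False)

    ion_by_id = dict(ion_rows)
    desc_by_id = {row.id: row for row in desc_df.itertuples(index=False)}
    cells = {}
    for prop in desc.DescriptorVector.NAMES:
        for cls in classes_present:
            ling = [getattr(desc_by_id[r.id], prop) for r in labeled
                    if r.chem_class == cls and r.permanence_label == sa.LINGERER and not r.fl_flag]
            trav = [getattr(desc_by_id[r.id], prop) for r in labeled
                    if r.chem_class == cls and r.permanence_label == sa.TRAVERSER]
            if ling and trav:
                cells[(cls, prop)] = (ling, trav)
    prop_df = st.mannwhitney_bh(cells, alpha=config.alpha) if cells else pd.DataFrame()
    prop_df.to_csv(out / "property_tests.csv", index=False)
    _stage("stats", n_enrichment_cells=int(table.size), n_property_cells=len(cells))

    # -- rules baseline ------------------------------------------------------
    rule_rows = []
    for r in labeled:
        d = desc.compute_descriptors(r.smiles)
        lip = rules_mod.reversed_lipinski(d)
        veb = rules_mod.reversed_veber(d)
        rule_rows.append((r.id, r.permanence_label, lip.label, lip.violations, veb.label))
    rule_df = pd.DataFrame(
        rule_rows, columns=["id", "permanence_label", "lipinski", "lipinski_violations", "veber"]
    )
    rule_df.to_csv(out / "rules.csv", index=False)
    y_all = np.array([int(lbl == sa.LINGERER) for lbl in rule_df["permanence_label"]])
    fl_all = np.array([bool(r.fl_flag) for r in labeled])
    rule_reports = {}
    for col in ("lipinski", "veber"):
        pred = np.array([int(v == sa.LINGERER) for v in rule_df[col]], dtype=float)
        rep = sl.evaluate(y_all, pred, fl_all, scores_are_probabilities=False)
        rule_reports[col] = rep.scopes
    _stage("rules", n_labeled=len(labeled))

    # -- stacked model -------------------------------------------------------
    model_report = {}
    if len(labeled) >= config.outer_folds and len({r.permanence_label for r in labeled}) == 2:
        if config.split == "random":
            folds = sl.stratified_folds(labeled, config.outer_folds, stage_seeds["folds"])
            test_mask = folds == 0
        else:
            fps = [desc.path_fingerprint(r.smiles) for r in labeled]
            train_idx, test_idx = sl.butina_split(
                fps, config.butina_threshold, 1.0 / config.outer_folds, stage_seeds["folds"]
            )
            test_mask = np.zeros(len(labeled), dtype=bool)
            test_mask[test_idx] = True
        train = [r for r, m in zip(labeled, test_mask) if not m]
        test = [r for r, m in zip(labeled, test_mask) if m]
        x_train, standardizer = sl.build_feature_matrix(train, ph=config.ph)
        x_test, _ = sl.build_feature_matrix(test, standardizer, ph=config.ph)
        y_train = sl.permanence_targets(train)
        y_test = sl.permanence_targets(test)
        model = sl.fit_superlearner(
            x_train, y_train, config.cv_folds, stage_seeds["model"], standardizer
        )
        proba = sl.predict_proba(model, x_test)
        fl_mask = np.array([bool(r.fl_flag) for r in test])
        ext = sl.evaluate(y_test, proba, fl_mask)
        model_report = {
            "n_train": len(train),
            "n_test": len(test),
            "base_auroc_oof": model.base_auroc,
            "external": ext.scopes,
        }
        pd.DataFrame(
            {"id": [r.id for r in test], "y_true": y_test, "proba": proba}
        ).to_csv(out / "predictions.csv", index=False)
    _stage("train", **({"n_train": model_report.get("n_train")} if model_report else {}))

    report["rules"] = rule_reports
    report["superlearner"] = model_report
    report["seed"] = config.seed
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
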