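"""End-to-end panel-discovery pipeline and report writing.

Stages (in analysis order): generate or load the intensity matrix and
annotations -> readout-drift correction -> plate normalization ->
comparison-cohort selection -> stability LASSO + random-forest importance
ensemble -> consensus panel -> model evaluation (test-set ROC/Youden
confusion, forest OOB) -> univariate/unsupervised panel characterization.
The run is a pure function of (config, base_seed): rerunning with the
same configuration reproduces every number and file bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ComparisonConfig, select_comparison_cohort, stratified_split
from .consensus import ConsensusThresholds, PanelSelection, consensus_panel
from .describe import (cluster_composition, group_balance_tests, hcluster_pc,
                       pca_log, spearman_matrix, wilcoxon_rank_sum)
from .forest import ForestConfig, forest_ensemble, single_forest, tune_forest
from .lasso import LassoConfig, cv_lasso_fit, stability_lasso
from .metrics import confusion_at_cutoff, roc_auc, youden_cutoff
from .normalize import DriftNormalizer, PlateNormalizer
from .simulate import (AssaySpec, CohortSpec, EffectSpec, generate_assay,
                       generate_cohort, read_matrix, read_samples,
                       write_matrix, write_samples)

log = logging.getLogger("csfpanel")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    # inputs: either file paths or the synthetic generator
    matrix_path: Optional[str] = None
    samples_path: Optional[str] = None
    simulate: bool = True
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    assay_spec: AssaySpec = field(default_factory=AssaySpec)
    # analysis
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    drift_correction: bool = True
    plate_correction: bool = True
    lasso: LassoConfig = field(default_factory=LassoConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    tune_ntree_grid: Optional[Tuple[int, ...]] = None  # tune when given
    thresholds: ConsensusThresholds = field(default_factory=ConsensusThresholds)
    repeats: int = 1000
    train_fraction: float = 2 / 3
    base_seed: int = 0
    n_clusters: int = 3

    def validate(self) -> None:
        if not self.simulate and (self.matrix_path is None
                                  or self.samples_path is None):
            raise ValueError("matrix_path and samples_path required unless "
                             "simulate=True")
        if self.simulate is False:
            for p in (self.matrix_path, self.samples_path):
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        self.thresholds.validate()
        self.lasso.validate()
        self.forest.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    evidence: pd.DataFrame
    metrics: Dict
    panel: PanelSelection
    provenance: Dict
    intermediates: Dict


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()
    timings = {}

    t0 = _stage("data")
    if config.simulate:
        cohort = generate_cohort(config.cohort_spec)
        matrix, samples, truth = generate_assay(
            cohort, config.effect_spec, config.assay_spec,
            seed=config.base_seed)
    else:
        matrix = read_matrix(config.matrix_path)
        samples = read_samples(config.samples_path)
        truth = None
    timings["data"] = time.time() - t0

    t0 = _stage("normalize")
    norm_log = {}
    if config.drift_correction and "readout_order" in samples:
        dn = DriftNormalizer()
        matrix = dn.fit_transform(matrix, readout_order=samples["readout_order"])
        norm_log["drift"] = dn.log_dict()
    if config.plate_correction and "plate" in samples:
        pn = PlateNormalizer()
        matrix = pn.fit_transform(matrix, plate=samples["plate"])
        norm_log["plate"] = pn.log_dict()
    timings["normalize"] = time.time() - t0

    t0 = _stage("cohort")
    selected = select_comparison_cohort(samples, config.comparison)
    X = matrix.loc[selected["sample_id"]]
    y = selected["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise RuntimeError(
            f"stage cohort: comparison '{config.comparison.name}' produced a "
            "single class")
    split = stratified_split(y, config.train_fraction, seed=config.base_seed)
    timings["cohort"] = time.time() - t0

    t0 = _stage("stability_lasso")
    Xa = X.to_numpy(float)
    stab = stability_lasso(
        Xa[split.train_idx], y[split.train_idx],
        Xa[split.test_idx], y[split.test_idx],
        R=config.repeats, config=config.lasso, base_seed=config.base_seed,
        feature_names=list(X.columns))
    timings["stability_lasso"] = time.time() - t0

    t0 = _stage("forest_ensemble")
    if config.tune_ntree_grid:
        fcfg, tune_trace = tune_forest(Xa, y, config.tune_ntree_grid,
                                       seed=config.base_seed)
    else:
        fcfg, tune_trace = config.forest, []
    ens = forest_ensemble(Xa, y, fcfg, R=config.repeats,
                          base_seed=config.base_seed,
                          feature_names=list(X.columns))
    timings["forest_ensemble"] = time.time() - t0

    t0 = _stage("consensus")
    panel = consensus_panel(stab, ens, config.thresholds)
    timings["consensus"] = time.time() - t0

    t0 = _stage("evaluation")
    model = cv_lasso_fit(Xa[split.train_idx], y[split.train_idx],
                         config=config.lasso, cv_seed=config.base_seed)
    test_scores = model.decision_function(Xa[split.test_idx])
    roc = roc_auc(test_scores, y[split.test_idx])
    cut = youden_cutoff(roc)
    conf = confusion_at_cutoff(test_scores, y[split.test_idx], cut)
    fres = single_forest(Xa, y, fcfg, seed=config.base_seed,
                         warn_degenerate=False)
    oob_votes = fres.oob_votes
    valid = np.isfinite(oob_votes)
    oob_conf = confusion_at_cutoff(oob_votes[valid], y[valid], 0.5)
    timings["evaluation"] = time.time() - t0

    t0 = _stage("downstream")
    downstream = {}
    if panel.union:
        downstream["wilcoxon_p"] = {
            pr: wilcoxon_rank_sum(X.loc[y == 1, pr], X.loc[y == 0, pr])[1]
            for pr in panel.union}
        downstream["spearman"] = spearman_matrix(X, panel.union)
    cluster_summary = None
    pca = None
    if len(panel.core) >= 2:
        pca = pca_log(X, panel.core)
        clus = hcluster_pc(pca, n_pcs=2, k=config.n_clusters)
        cluster_summary = cluster_composition(
            clus, np.where(y == 1, "positive", "negative"))
        downstream["pca_explained_pct"] = pca.explained_pct[:2].tolist()
        downstream["cluster_composition"] = cluster_summary.to_dict("records")
    downstream["demographics"] = group_balance_tests(samples)
    timings["downstream"] = time.time() - t0

    evidence = panel.evidence.copy()
    evidence.insert(1, "description_id", evidence["protein"])
    evidence = evidence[["protein", "description_id", "lasso_pct_selected",
                         "mean_mda", "in_union", "in_core"]]

    metrics = {
        "comparison": config.comparison.name,
        "n_samples": int(len(y)),
        "n_positive": int(y.sum()),
        "train_counts": {str(k): v for k, v in split.train_counts.items()},
        "test_counts": {str(k): v for k, v in split.test_counts.items()},
        "lasso": {**stab.summary(),
                  "single_model_test_auc": roc.auc,
                  "youden_cutoff": cut,
                  "test_confusion": dataclasses.asdict(conf),
                  "test_correct": conf.n_correct,
                  "test_n": conf.n},
        "forest": {**ens.summary(),
                   "config": dataclasses.asdict(fcfg),
                   "tune_trace": tune_trace,
                   "oob_auc_single": fres.oob_auc,
                   "oob_confusion": dataclasses.asdict(oob_conf),
                   "oob_correct": oob_conf.n_correct,
                   "oob_n": oob_conf.n},
        "panel": {"union": panel.union, "core": panel.core},
        "downstream": {k: v for k, v in downstream.items()
                       if k not in ("spearman",)},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    provenance = {
        "config_hash": config.hash(),
        "base_seed": config.base_seed,
        "repeats": config.repeats,
        "version": __version__,
    }
    intermediates = {
        "matrix": matrix, "samples": samples, "truth": truth,
        "selected_cohort": selected, "split": split, "stability": stab,
        "ensemble": ens, "normalization_log": norm_log,
        "spearman": downstream.get("spearman"), "pca": pca,
        "cluster_summary": cluster_summary,
    }
    return ReportBundle(evidence=evidence, metrics=metrics, panel=panel,
                        provenance=provenance, intermediates=intermediates)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(bundle: ReportBundle, outdir) -> Dict[str, str]:
    """Persist the results bundle; returns {filename: sha256} manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    ev_path = out / "evidence.tsv"
    bundle.evidence.to_csv(ev_path, sep="\t", index=False,
                           float_format="%.6g")
    files.append(ev_path)

    metrics_path = out / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump({"metrics": bundle.metrics,
                   "provenance": bundle.provenance}, fh, indent=1,
                  default=str)
    files.append(metrics_path)

    summary_path = out / "summary.md"
    m = bundle.metrics
    lines = [
        "# Panel selection summary",
        "",
        f"Comparison: {m['comparison']} "
        f"({m['n_positive']}/{m['n_samples']} positive)",
        f"Core panel (both methods): "
        f"{', '.join(bundle.panel.core) if bundle.panel.core else '(empty)'}",
        f"Union panel: "
        f"{', '.join(bundle.panel.union) if bundle.panel.union else '(empty)'}",
        f"LASSO test AUC range over {m['lasso']['R']} models: "
        f"{m['lasso']['auc_min']:.3f}-{m['lasso']['auc_max']:.3f}",
        f"Forest OOB AUC range over {m['forest']['R']} forests: "
        f"{m['forest']['oob_auc_min']:.3f}-{m['forest']['oob_auc_max']:.3f}",
        f"Single-model test set: {m['lasso']['test_correct']}/"
        f"{m['lasso']['test_n']} correct at the Youden cut-off",
        "",
        f"config {bundle.provenance['config_hash']}, seed "
        f"{bundle.provenance['base_seed']}, csfpanel "
        f"{bundle.provenance['version']}",
    ]
    summary_path.write_text("\n".join(lines) + "\n")
    files.append(summary_path)

    sp = bundle.intermediates.get("spearman")
    if sp is not None:
        sp_path = out / "spearman.tsv"
        sp.to_csv(sp_path, sep="\t", float_format="%.6g")
        files.append(sp_path)
    cs = bundle.intermediates.get("cluster_summary")
    if cs is not None:
        cs_path = out / "clusters.tsv"
        cs.to_csv(cs_path, sep="\t", index=False)
        files.append(cs_path)

    manifest = {f.name: _sha256(f) for f in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
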