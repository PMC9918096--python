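"""End-to-end pipeline orchestration.

Runs the stages in dependency order on a simulated (or loaded) cohort:
QC and normalization -> differential expression -> candidate selection ->
ddPCR quantification -> ROC/group statistics -> elastic-net panel ->
lesion volumetry and biomarker/lesion correlation. Emits a manifest
recording every output file, the configuration hash and the seed, and a
JSON-lines log of each filter's in/out counts; reruns with the same config
and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (SimConfig, simulate_cohort, DDPCR_REFERENCE_ASSAY,
                        T2_TIMEPOINTS)
from .qc import cpm_normalize, hemolysis_qc, detection_sets, prevalence_filter, \
    pca_summary
from .de import nb_wald_test
from .candidates import select_upregulated, select_downregulated
from .pcr import ddpcr_expression
from .stats import roc_curve, kruskal_wallis
from .panels import PanelConfig, elastic_net_panel
from .lesions import normal_t2_band, lesion_volume, correlate_biomarker_lesion

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_THRESHOLDS"]

log = logging.getLogger("mirseed")

#: paper-default analysis thresholds, auditable as a flat block
DEFAULT_THRESHOLDS = {
    "a414": 0.25,          # hemolysis absorbance cut (>= is hemolyzed)
    "log2fc": 1.0,         # up-candidate |log2FC| cut
    "cpm_up": 30.0,        # mean CPM in the TBI group, upregulated list
    "cpm_down": 100.0,     # mean CPM in both groups, downregulated list
    "fdr": 0.05,           # BH-adjusted significance level
    "prevalence": 0.8,     # read-prevalence fraction for discovery features
    "alpha": 0.5,          # elastic-net mixing (equal LASSO/Ridge)
    "n_boot": 10_000,      # BCa bootstrap resamples
}

_STAGES = ("qc", "de", "select", "pcr", "stats", "panel", "lesion")


@dataclass
class RunConfig:
    """Pipeline run configuration; round-trips losslessly through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    outdir: str = "mirseed_run"
    seed: int = 0
    log_level: str = "INFO"
    panel_outcome: str = "epilepsy"    # epilepsy | seizures_ge3 | clusters

    def to_yaml(self, path: str | Path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        for k, v in list(d["sim"].items()):
            if isinstance(v, tuple):
                d["sim"][k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_raw = dict(raw.get("sim", {}))
        for k in ("t2_grid", "injury_log2fc", "sham_log2fc"):
            if k in sim_raw and isinstance(sim_raw[k], list):
                sim_raw[k] = tuple(sim_raw[k])
        cfg = cls(sim=SimConfig(**sim_raw))
        cfg.thresholds.update(raw.get("thresholds", {}))
        cfg.stages.update(raw.get("stages", {}))
        for k in ("outdir", "seed", "log_level", "panel_outcome"):
            if k in raw:
                setattr(cfg, k, raw[k])
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log_counts(stage: str, **counts):
    log.info(json.dumps({"stage": stage, **counts}, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = {**DEFAULT_THRESHOLDS, **config.thresholds}
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "version": __version__, "outputs": {}}

    sim = dataclasses.replace(config.sim, seed=config.seed)
    cohort = simulate_cohort(sim)
    manifest["outputs"].update(cohort.write(outdir / "cohort"))
    groups = cohort.meta["group"]

    de = None
    cpm = None
    if config.stages.get("qc", True):
        qc_res = hemolysis_qc(cohort.meta, threshold=thr["a414"])
        _log_counts("qc", n_in=qc_res.n_total, n_out=qc_res.n_qualified,
                    pct=qc_res.pct_qualified)
        path = outdir / "qc_summary.json"
        with open(path, "w") as fh:
            json.dump(qc_res.summary(), fh, indent=1)
        manifest["outputs"]["qc_summary"] = str(path)

        cpm = cpm_normalize(cohort.counts)
        path = outdir / "cpm.tsv"
        cpm.round(4).to_csv(path, sep="\t")
        manifest["outputs"]["cpm"] = str(path)

        sets = detection_sets(cohort.counts, groups)
        path = outdir / "detection_sets.json"
        with open(path, "w") as fh:
            json.dump(sets.sizes(), fh, indent=1)
        manifest["outputs"]["detection_sets"] = str(path)

        pca = pca_summary(cpm, n_components=5)
        path = outdir / "pca_scores.tsv"
        pca.scores.round(5).to_csv(path, sep="\t")
        manifest["outputs"]["pca_scores"] = str(path)

    if config.stages.get("de", True):
        de = nb_wald_test(cohort.counts, groups, ("TBI", "sham"))
        _log_counts("de", n_in=len(cohort.counts),
                    n_tested=int(de["tested"].sum()),
                    n_sig=int((de["padj"] < thr["fdr"]).sum()))
        path = outdir / "de_tbi_vs_sham.tsv"
        de.to_csv(path, sep="\t")
        manifest["outputs"]["de"] = str(path)

    if config.stages.get("select", True):
        if de is None or cpm is None:
            raise RuntimeError("stage 'select' requires stages 'qc' and 'de'")
        ann = pd.DataFrame(
            {"brain_enriched": True},
            index=pd.Index(cohort.truth["injury_responsive"], name="mirna_id"))
        up = select_upregulated(de, cpm, groups, "TBI", annotation=ann,
                                log2fc_min=thr["log2fc"], cpm_min=thr["cpm_up"],
                                padj_max=thr["fdr"])
        down = select_downregulated(de, cpm, groups, ("TBI", "sham"),
                                    log2fc_max=-thr["log2fc"],
                                    cpm_min=thr["cpm_down"],
                                    padj_max=thr["fdr"])
        _log_counts("select", n_in=int(de["tested"].sum()),
                    n_up=len(up.entries), n_down=len(down.entries))
        for name, lst in (("up", up), ("down", down)):
            path = outdir / f"candidates_{name}.tsv"
            lst.entries.round(5).to_csv(path, sep="\t")
            manifest["outputs"][f"candidates_{name}"] = str(path)

    expr = None
    if config.stages.get("pcr", True):
        expr = ddpcr_expression(cohort.ddpcr, DDPCR_REFERENCE_ASSAY)
        _log_counts("pcr", n_in=cohort.ddpcr["sample_id"].nunique(),
                    n_out=len(expr))
        path = outdir / "ddpcr_expression.tsv"
        expr.round(5).to_csv(path, sep="\t")
        manifest["outputs"]["ddpcr_expression"] = str(path)

    if config.stages.get("stats", True) and expr is not None:
        rows = []
        grp = groups.loc[expr.index]
        for assay in expr.columns:
            vals = expr[assay].to_numpy(dtype=float)
            kw = kruskal_wallis(vals, grp.to_numpy())
            labels = (grp == "TBI").astype(int).to_numpy()
            roc = roc_curve(vals, labels)
            rows.append((assay, kw.statistic, kw.p_value, roc.auc, roc.p_value,
                         roc.cutoff, roc.sensitivity, roc.specificity))
        stats_tab = pd.DataFrame(rows, columns=[
            "assay_id", "kw_stat", "kw_p", "auc_tbi_vs_rest", "auc_p",
            "cutoff", "sensitivity", "specificity"])
        path = outdir / "biomarker_stats.tsv"
        stats_tab.round(5).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["biomarker_stats"] = str(path)

    if config.stages.get("panel", True) and expr is not None:
        meta_tbi = cohort.meta[cohort.meta["group"] == "TBI"]
        tbi_expr = expr.loc[expr.index.intersection(meta_tbi.index)]
        outcome_col = {
            "epilepsy": meta_tbi["epilepsy"],
            "seizures_ge3": meta_tbi["n_seizures"] >= 3,
            "clusters": meta_tbi["has_clusters"],
        }[config.panel_outcome]
        y = outcome_col.loc[tbi_expr.index].astype(bool).astype(int)
        pcfg = PanelConfig(alpha=thr["alpha"], n_boot=int(thr["n_boot"]),
                           seed=config.seed)
        if y.nunique() < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
            log.warning("panel stage skipped: outcome class too small")
        else:
            panel = elastic_net_panel(tbi_expr, y, pcfg)
            summary = {
                "outcome": config.panel_outcome,
                "kept_features": panel.kept_features,
                "empty_panel": panel.empty_panel,
                "cv_auc": None if np.isnan(panel.cv_auc) else panel.cv_auc,
                "ci_low": None if np.isnan(panel.ci_low) else panel.ci_low,
                "ci_high": None if np.isnan(panel.ci_high) else panel.ci_high,
                "p_value": None if np.isnan(panel.p_value) else panel.p_value,
            }
            _log_counts("panel", n_features_in=tbi_expr.shape[1],
                        n_kept=len(panel.kept_features))
            path = outdir / "panel_summary.json"
            with open(path, "w") as fh:
                json.dump(summary, fh, indent=1)
            manifest["outputs"]["panel_summary"] = str(path)
            path = outdir / "panel_fold_coefs.tsv"
            panel.fold_coefs.round(6).to_csv(path, sep="\t")
            manifest["outputs"]["panel_fold_coefs"] = str(path)

    if config.stages.get("lesion", True) and expr is not None:
        shams = [v for (sid, tp), v in cohort.t2.items()
                 if groups.get(sid) == "sham"]
        band = normal_t2_band(shams)
        vols = {}
        for (sid, tp), vol in cohort.t2.items():
            if groups.get(sid) == "TBI":
                vols.setdefault(sid, {})[f"t2_volume_{tp}"] = \
                    lesion_volume(vol, band).volume_mm3
        lesion_tab = pd.DataFrame.from_dict(vols, orient="index")
        lesion_tab = lesion_tab.reindex(
            columns=[f"t2_volume_{tp}" for tp in T2_TIMEPOINTS])
        lesion_tab["lesion_area_d182"] = cohort.lesion_area_d182_mm2
        corr = correlate_biomarker_lesion(expr, lesion_tab)
        _log_counts("lesion", n_volumes=len(vols),
                    band_lower=band.lower_ms, band_upper=band.upper_ms)
        path = outdir / "lesion_band.json"
        with open(path, "w") as fh:
            json.dump({"lower_ms": band.lower_ms, "upper_ms": band.upper_ms},
                      fh, indent=1)
        manifest["outputs"]["lesion_band"] = str(path)
        path = outdir / "lesion_correlations.tsv"
        corr.round(5).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["lesion_correlations"] = str(path)

    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
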