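"""End-to-end orchestration: simulate -> normalize -> ANOVA -> conservation
-> marker screen -> panel discovery -> descriptive reports.

Every stage writes plain-text artifacts (TSV/JSON/FASTA) into the output
directory and the run ends with a manifest of per-file SHA-256 checksums;
identical configuration and seed reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova, conservation, markers, normalize, panels, reporting
from .design import default_design
from .io import (
    read_counts_tsv,
    read_metadata_tsv,
    write_counts_tsv,
    write_json,
    write_matrix_tsv,
    write_metadata_tsv,
)
from .synthetic import HomologyMap, SimulationConfig, simulate_cohort, simulate_mirna_fasta

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "mirdose-out"
    seed: int = 0
    # input paths; when counts is None a synthetic cohort is simulated
    counts: str | None = None
    metadata: str | None = None
    fasta_a: str | None = None
    fasta_b: str | None = None
    # simulation
    n_features: int = 150
    # thresholds
    alpha: float = 0.05
    min_nonzero_frac: float = 0.40
    min_identity: float = 90.0
    auc_min: float = 0.80
    panel_min_size: int = 2
    panel_max_size: int = 10
    kfold_k: int = 10
    rsbmr_split: float = 0.70
    rsbmr_repeats: int = 10
    n_forest_reps: int = 50
    top_panels: int = 10
    rf_panel_size: int = 4
    n_trees: int = 50

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (0 < self.min_nonzero_frac <= 1, "min_nonzero_frac must lie in (0, 1]"),
            (0 <= self.min_identity <= 101, "min_identity must lie in [0, 101]"),
            (0 <= self.auc_min <= 1, "auc_min must lie in [0, 1]"),
            (2 <= self.panel_min_size <= self.panel_max_size <= 10,
             "panel sizes must satisfy 2 <= min <= max <= 10"),
            (2 <= self.kfold_k, "kfold_k must be >= 2"),
            (0 < self.rsbmr_split < 1, "rsbmr_split must lie in (0, 1)"),
            (self.rsbmr_repeats >= 1, "rsbmr_repeats must be >= 1"),
            (self.n_forest_reps >= 1, "n_forest_reps must be >= 1"),
            (self.n_features >= 50, "n_features must be >= 50"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        if (self.counts is None) != (self.metadata is None):
            raise ValueError("counts and metadata must be given together")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = SimulationConfig(n_features=cfg.n_features, seed=cfg.seed)
    counts, meta, truth = simulate_cohort(sim, default_design())
    rng = np.random.default_rng(cfg.seed + 1)
    planted = truth.features()
    pairs = []
    for feat in counts.index:
        if feat in planted or rng.uniform() < 0.5:
            pct = float(rng.uniform(92.0, 100.0))  # conserved homologue
        else:
            pct = float(rng.uniform(40.0, 70.0))  # diverged
        pairs.append((feat, f"hsa-{feat}", pct))
    fasta_a = outdir / "species_a.fasta"
    fasta_b = outdir / "species_b.fasta"
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rounding of unreachable identities
        simulate_mirna_fasta(HomologyMap(tuple(pairs)), fasta_a, fasta_b,
                             seed=cfg.seed + 2)
    write_counts_tsv(counts, outdir / "counts.tsv")
    write_metadata_tsv(meta, outdir / "metadata.tsv")
    write_json(
        {
            "dose_markers": [list(m) for m in truth.dose_markers],
            "time_markers": [list(m) for m in truth.time_markers],
            "sex_markers": [list(m) for m in truth.sex_markers],
            "survival_panel": [list(m) for m in truth.survival_panel],
        },
        outdir / "planted_truth.json",
    )
    return {"counts": counts, "meta": meta,
            "fasta_a": fasta_a, "fasta_b": fasta_b}


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute every stage; returns the artifact manifest (stage, file, sha256)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[tuple[str, Path]] = []

    def record(stage: str, *paths: Path):
        artifacts.extend((stage, p) for p in paths)

    # --- inputs ---------------------------------------------------------
    if config.counts is None:
        log.info("stage simulate: generating synthetic cohort")
        data = _simulate_stage(config, outdir)
        record("simulate", outdir / "counts.tsv", outdir / "metadata.tsv",
               outdir / "planted_truth.json", data["fasta_a"], data["fasta_b"])
        counts, meta = data["counts"], data["meta"]
        fasta_a_path, fasta_b_path = data["fasta_a"], data["fasta_b"]
    else:
        counts = read_counts_tsv(config.counts)
        meta = read_metadata_tsv(config.metadata)
        fasta_a_path, fasta_b_path = config.fasta_a, config.fasta_b
    log.info("inputs: %d features x %d samples", *counts.shape)

    # --- normalize ------------------------------------------------------
    filtered = normalize.prefilter_features(counts, config.min_nonzero_frac)
    factors = normalize.tmm_factors(filtered)
    cpm_values = normalize.cpm(filtered, factors)
    expr = normalize.normalized_log2_cpm(cpm_values)
    fc = normalize.log2fc_baseline(cpm_values, meta)
    factors.to_frame().to_csv(outdir / "tmm_factors.tsv", sep="\t", index=False)
    write_matrix_tsv(cpm_values, outdir / "cpm.tsv")
    write_matrix_tsv(fc, outdir / "log2fc.tsv")
    record("normalize", outdir / "tmm_factors.tsv", outdir / "cpm.tsv",
           outdir / "log2fc.tsv")
    log.info("normalize: kept %d features", filtered.shape[0])

    # --- differential ---------------------------------------------------
    results = anova.fit_four_way_anova(expr, meta, alpha=config.alpha)
    de = results.de_union()
    results.table.to_csv(outdir / "anova_results.tsv", sep="\t", index=False)
    (outdir / "de_union.txt").write_text("\n".join(de.union) + "\n")
    record("differential", outdir / "anova_results.tsv", outdir / "de_union.txt")
    log.info("differential: %d DE features", len(de.union))

    # --- conservation ---------------------------------------------------
    if fasta_a_path and fasta_b_path:
        fa = conservation.read_fasta(fasta_a_path)
        fb = conservation.read_fasta(fasta_b_path)
        sc, homologues = conservation.curate_sc(
            de.union, fa, fb, min_identity=config.min_identity
        )
        fs, _ = conservation.curate_fs(
            filtered, meta, fb, fa, alpha=config.alpha,
            min_nonzero_frac=config.min_nonzero_frac,
        )
        sets = conservation.intersect_sets(sc, fs, homologues)
        rows = [
            (r.query, r.target, r.score, r.pct_identity)
            for matches in homologues.values()
            for r in matches
        ]
        pd.DataFrame(
            rows, columns=["query", "target", "score", "pct_identity"]
        ).to_csv(outdir / "homologue_map.tsv", sep="\t", index=False)
        for name, values in (("sc", sets.sc), ("fs", sets.fs), ("cnvd", sets.cnvd)):
            (outdir / f"{name}_mirna.txt").write_text("\n".join(sorted(values)) + "\n")
        write_json(sets.venn_counts(), outdir / "venn_counts.json")
        record("conservation", outdir / "homologue_map.tsv",
               outdir / "sc_mirna.txt", outdir / "fs_mirna.txt",
               outdir / "cnvd_mirna.txt", outdir / "venn_counts.json")
        log.info("conservation: %s", sets.venn_counts())
        analysis_features = sorted(sets.cnvd) or sorted(de.union)
    else:
        analysis_features = sorted(de.union)

    analysis_features = [f for f in analysis_features if f in fc.index]
    if not analysis_features:
        analysis_features = list(fc.index)

    # --- marker screen --------------------------------------------------
    fc_sub = fc.loc[analysis_features]
    dose_table = markers.screen_markers(fc_sub, meta, axis="dose", alpha=config.alpha)
    time_table = markers.screen_markers(fc_sub, meta, axis="time", alpha=config.alpha)
    dose_table.to_csv(outdir / "dose_markers.tsv", sep="\t", index=False)
    time_table.to_csv(outdir / "time_markers.tsv", sep="\t", index=False)
    roc_out = {}
    if not dose_table.empty:
        top = dose_table.loc[dose_table["p"].idxmin(), "feature"]
        meta_ix = meta.set_index("sample_id")
        pre_samples = meta_ix[meta_ix["timepoint"] == "pre"].index
        pre_cols = [s for s in pre_samples if s in cpm_values.columns]
        post_cols = list(fc.columns)
        expr_all = normalize.normalized_log2_cpm(cpm_values)
        roc = markers.single_marker_auc(
            expr_all.loc[top, post_cols].to_numpy(),
            expr_all.loc[top, pre_cols].to_numpy(),
            seed=config.seed,
        )
        roc_out = {"feature": top, "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                   "n_pos": roc.n_pos, "n_neg": roc.n_neg}
    write_json(roc_out, outdir / "top_marker_roc.json")
    record("marker_screen", outdir / "dose_markers.tsv",
           outdir / "time_markers.tsv", outdir / "top_marker_roc.json")
    log.info("marker_screen: %d dose rows, %d time rows",
             len(dose_table), len(time_table))

    # --- panel discovery ------------------------------------------------
    per_animal = fc_sub.T.groupby(
        meta.set_index("sample_id").loc[fc_sub.columns, "animal_id"]
    ).mean()
    outcome = meta.drop_duplicates("animal_id").set_index("animal_id")["survived"]
    y = outcome.loc[per_animal.index].astype(float).to_numpy()
    disc_cfg = panels.DiscoveryConfig(
        n_forest_reps=config.n_forest_reps,
        top_panels=config.top_panels,
        panel_size=config.rf_panel_size,
        n_trees=config.n_trees,
        min_size=config.panel_min_size,
        max_size=config.panel_max_size,
        rsbmr_split=config.rsbmr_split,
        rsbmr_repeats=config.rsbmr_repeats,
        kfold_k=config.kfold_k,
        auc_min=config.auc_min,
        p_max=config.alpha,
    )
    discovery = panels.discover_panels(per_animal, y, disc_cfg, seed=config.seed)
    panel_report = {}
    flat_rows = []
    for method in ("RSBMR", "kfold"):
        panel_report[method] = [
            {
                "features": list(e.features),
                "intercept": e.model.intercept,
                "coefficients": list(e.model.coefficients),
                "mean_auc": e.mean_auc,
                "auc_ci": list(e.auc_ci),
                "sensitivity": e.sensitivity,
                "specificity": e.specificity,
                "mcfadden_r2": e.mcfadden_r2,
                "fit_p": e.fit_p,
                "separated": e.separated,
            }
            for e in discovery[method]
        ]
        flat_rows += [
            {"method": method, "features": ";".join(e.features),
             "mean_auc": e.mean_auc, "mcfadden_r2": e.mcfadden_r2,
             "fit_p": e.fit_p}
            for e in discovery[method]
        ]
    write_json(panel_report, outdir / "panels.json")
    pd.DataFrame(
        flat_rows, columns=["method", "features", "mean_auc", "mcfadden_r2", "fit_p"]
    ).to_csv(outdir / "panels.tsv", sep="\t", index=False)
    record("panel_discovery", outdir / "panels.json", outdir / "panels.tsv")
    log.info("panel_discovery: %d RSBMR / %d k-fold panels pass screening",
             len(discovery["RSBMR"]), len(discovery["kfold"]))

    # --- reports --------------------------------------------------------
    pca = reporting.pca_report(fc, n_components=5)
    pca["scores"].to_csv(outdir / "pca_scores.tsv", sep="\t")
    write_json(
        {"explained_fraction": [float(v) for v in pca["explained_fraction"]]},
        outdir / "pca_explained.json",
    )
    hc = reporting.hclust_report(fc, subset=analysis_features[: min(50, len(analysis_features))])
    write_json({"leaf_order": list(hc["leaf_order"])}, outdir / "hclust_leaves.json")
    record("report", outdir / "pca_scores.tsv", outdir / "pca_explained.json",
           outdir / "hclust_leaves.json")

    manifest = pd.DataFrame(
        [(stage, p.name, _sha256(p)) for stage, p in artifacts],
        columns=["stage", "file", "sha256"],
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
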