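"""End-to-end orchestration: simulate/read -> filter -> test -> call ->
select -> score -> clock comparisons -> report.

A run is driven by a single :class:`RunConfig` (parseable from TOML).  Every
source of randomness derives from one base seed through stage-name hashed
substreams, so inserting a stage never reshuffles the randomness of the
stages after it, and identical configs give byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import simdata, methio, dmr as dmrcalling, clocks

log = logging.getLogger("eaclock")

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "config_from_toml"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stage-name CRC mixed in)."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``coverage_paths`` (with ``sample_table_path``) or the
    simulation block (``simulate=True``) must be active.
    """

    out_dir: str = "eaclock_run"
    seed: int = 1

    # input mode A: files on disk
    coverage_paths: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()
    sample_table_path: str | None = None

    # input mode B: simulation
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    design: str = "two_group"  # two_group | ladder | crossed | rest

    # stage parameters
    min_coverage: int = 5
    group_a: str | None = None
    group_b: str | None = None
    p_thresh: float = 0.01
    max_gap_bp: int = 300
    min_cpg: int = 3
    merge_dist_bp: int = 100
    top_k: int = 150
    direction: str = "gain"
    pca_n_top: int = 3000
    age_column: str = "divisions"

    def validate(self) -> None:
        if self.simulate and self.coverage_paths:
            raise ValueError("choose either simulation or input files, not both")
        if not self.simulate and not self.coverage_paths:
            raise ValueError("no input: set simulate=true or provide coverage_paths")
        if not self.simulate and len(self.coverage_paths) != len(self.sample_ids):
            raise ValueError("one sample id per coverage path required")


_DESIGNS = {
    "two_group": simdata.two_group_design,
    "ladder": simdata.ladder_design,
    "crossed": simdata.crossed_design,
    "rest": simdata.rest_design,
}


def config_from_toml(path) -> RunConfig:
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("coverage_paths", "sample_ids"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        sim_kwargs = dict(cfg.sim)
        design = _DESIGNS[cfg.design]
        design_kwargs = sim_kwargs.pop("design_kwargs", {})
        samples = design(**design_kwargs)
        sim_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        sc = simdata.SimConfig(samples=samples, **sim_kwargs)
        cm, table, truth = simdata.simulate_cohort(sc)
        return cm, table, truth, sc
    cm = methio.read_coverage(cfg.coverage_paths, cfg.sample_ids)
    table = pd.read_csv(cfg.sample_table_path, sep="\t")
    missing = set(cm.samples) - set(table["sample_id"])
    if missing:
        raise ValueError(f"samples absent from sample table: {sorted(missing)}")
    return cm, table, None, None


def _default_groups(cfg: RunConfig, table: pd.DataFrame) -> tuple[list[str], list[str]]:
    groups = table.groupby("group")["divisions"].mean().sort_values()
    ga = cfg.group_a or groups.index[0]
    gb = cfg.group_b or groups.index[-1]
    a = table.loc[table["group"] == ga, "sample_id"].tolist()
    b = table.loc[table["group"] == gb, "sample_id"].tolist()
    return a, b


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to
    ``out_dir/report.json`` along with all intermediate artifacts)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "stages": {}}

    def stage(name, **info):
        log.info("stage %-12s %s", name, info)
        report["stages"][name] = info

    # --- input ------------------------------------------------------------
    cm, table, truth, sc = _load_inputs(cfg)
    table.to_csv(out / "samples.tsv", sep="\t", index=False)
    methio.write_coverage(cm, out / "counts")
    if truth is not None:
        simdata.write_truth(truth, cm.sites, out / "truth")
    stage("input", n_sites=cm.n_sites, n_samples=cm.n_samples, simulated=cfg.simulate)

    # --- coverage filter --------------------------------------------------
    cmf = methio.filter_coverage(cm, cfg.min_coverage)
    stage("filter", min_coverage=cfg.min_coverage, n_sites=cmf.n_sites)

    # --- betas, global methylation, PCA -----------------------------------
    bm = methio.compute_beta(cmf)
    gm = methio.global_methylation(bm)
    gm.to_csv(out / "global_methylation.tsv", sep="\t")
    stage("global_methylation", mean_of_means=float(gm["mean_beta"].mean()))
    if cmf.n_samples >= 2 and cmf.n_sites >= 2:
        scores_pca, varexp, _ = methio.variable_site_pca(bm, n_top=cfg.pca_n_top)
        scores_pca.to_csv(out / "pca_scores.tsv", sep="\t")
        stage("pca", n_top=min(cfg.pca_n_top, cmf.n_sites),
              varexp=[float(v) for v in varexp])
    else:
        stage("pca", skipped=True)

    # --- differential methylation ------------------------------------------
    group_a, group_b = _default_groups(cfg, table)
    stats_df = dmrcalling.test_sites(cmf, group_a, group_b)
    stats_df.to_csv(out / "site_stats.tsv", sep="\t", index=False)
    dmrs = dmrcalling.call_dmrs(
        stats_df, p_thresh=cfg.p_thresh, max_gap_bp=cfg.max_gap_bp,
        min_cpg=cfg.min_cpg, merge_dist_bp=cfg.merge_dist_bp,
    )
    dmrcalling.dmrs_to_bed(dmrs, out / "dmrs.bed")
    stage("test_and_call", group_a=group_a, group_b=group_b,
          n_candidates=int((stats_df["p"] < cfg.p_thresh).sum()), n_dmrs=len(dmrs))

    program = dmrcalling.select_top(
        dmrs, k=cfg.top_k, direction=cfg.direction,
        p_thresh=cfg.p_thresh, max_gap_bp=cfg.max_gap_bp,
        min_cpg=cfg.min_cpg, merge_dist_bp=cfg.merge_dist_bp,
    )
    dmrcalling.dmrs_to_bed(program.dmrs, out / "signature.bed", program=program)
    stage("select_top", k=cfg.top_k, direction=cfg.direction, n_selected=len(program))

    # --- signature scoring and clock comparisons ---------------------------
    report["recovery"] = None
    if truth is not None and len(truth.gain_regions) and len(program):
        from .enrichment import overlap_regions

        ov = overlap_regions(program.regions(), truth.gain_regions)
        report["recovery"] = {
            "n_selected": len(program),
            "n_overlapping_planted": ov.n_overlap,
            "fraction": ov.n_overlap / len(program),
        }

    if len(program):
        level, score = dmrcalling.score_regions(cm, program)
        level.to_csv(out / "region_methylation.tsv", sep="\t")
        score.to_frame().to_csv(out / "signature_scores.tsv", sep="\t")
        ages = table.set_index("sample_id")[cfg.age_column]
        fit = None
        if ages.nunique() >= 3:
            fit = clocks.fit_age_regression(score, ages)
            report["regression"] = {
                "slope": fit.slope, "intercept": fit.intercept,
                "pearson_r": fit.r, "p": fit.p, "n": fit.n,
            }
        groups = table.set_index("sample_id")["group"]
        if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
            comp = clocks.compare_groups(score, groups)
            comp.to_csv(out / "group_tests.tsv", sep="\t", index=False)
            report["group_tests"] = comp.to_dict(orient="records")
        if ages.nunique() >= 5:
            pf = clocks.fit_plateau(score, ages)
            report["plateau"] = {
                "c": pf.c, "delta_aic": pf.delta_aic,
                "saturation_age": pf.saturation_age, "converged": pf.converged,
            }
        stage("score", n_regions=len(program),
              score_mean=float(score.mean()))
    else:
        stage("score", skipped=True)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
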