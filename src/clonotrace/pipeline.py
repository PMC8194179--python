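"""Simulate-then-analyze orchestration with a consolidated report.

``run_pipeline`` executes the four analysis stages on synthetic inputs in
dependency order, writes every stage's TSV, and emits a Markdown report
plus a machine-readable JSON summary. All randomness derives from the
config seed, and numeric output is formatted to fixed precision, so a
repeated run is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, integration, invasion, junction, simulate
from .config import PipelineConfig

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("invasion", "association", "integration", "junction")
_FLOAT = "%.10g"

log = logging.getLogger("clonotrace")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def _stage_invasion(cfg: PipelineConfig, outdir: Path) -> dict:
    cohort, truth = simulate.simulate_invasion_cohort(n_clones=20, seed=cfg.seed)
    rel_area = invasion.relative_invasion_area(cohort, t_eval=48.0)
    entries = []
    for tc in cohort:
        t0 = invasion.detect_invasion_start(
            tc, rel_threshold=cfg.onset_rel_threshold,
            consecutive=cfg.onset_consecutive)
        if t0 is None:
            warnings.warn(f"{tc.clone_id}: no invasion onset detected; skipped")
            continue
        entries.append((tc.clone_id, rel_area[tc.clone_id], t0))
    scores = invasion.rank_clones(entries)
    frame = invasion.scores_to_frame(scores).sort_values("rank")
    _write(frame, outdir / "invasion_scores.tsv")
    ranking = frame[["clone_id", "rank", "relative_invasiveness", "class"]]
    return {"scores": scores,
            "summary": {"n_clones": len(scores),
                        "most_invasive": ranking.iloc[0]["clone_id"],
                        "least_invasive": ranking.iloc[-1]["clone_id"]}}


def _stage_association(cfg: PipelineConfig, outdir: Path, scores) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10,)))
    clones = [s.clone_id for s in scores]
    half = len(clones) // 2
    # two planted mesenchymal states; LCK tracks invasiveness in high_high
    vim = {c: (3.0 if i < half else 1.0) + rng.normal(0, 0.1)
           for i, c in enumerate(clones)}
    ncad = {c: (3.0 if i < half else 1.0) + rng.normal(0, 0.1)
            for i, c in enumerate(clones)}
    subgroups = expression.split_subgroups(vim, ncad)
    label = {s.clone_id: s.label for s in subgroups}
    folds = {}
    for s in scores:
        lck = (2.0 * s.relative_invasiveness
               if label[s.clone_id] == "high_high" else 1.0)
        folds[s.clone_id] = {"LCK": max(lck, 0.05),
                             "CDH2": max(vim[s.clone_id], 0.05)}
    ct, _ = simulate.simulate_qpcr(folds, noise_sd=0.05, seed=cfg.seed)
    expr = expression.normalize_qpcr(ct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small subgroups are expected here
        fits = expression.correlate_with_invasion(expr, scores, subgroups)
    _write(fits, outdir / "expression_association.tsv")
    return {"summary": {"n_fits": int(len(fits)),
                        "subgroup_sizes": {k: sum(1 for s in subgroups
                                                  if s.label == k)
                                           for k in sorted({s.label
                                                            for s in subgroups})}}}


def _stage_integration(cfg: PipelineConfig, outdir: Path) -> dict:
    matrices, truth = simulate.simulate_counts(seed=cfg.seed)
    tables = [simulate.simple_de(matrices[d], dataset_id=d)
              for d in integration.DATASETS]
    for t in tables:
        integration.write_de_table(t, outdir / f"de_{t.dataset_id}.tsv")
    matrix = integration.build_integration_matrix(tables, fdr_max=cfg.fdr_max)
    recurrent = integration.sort_by_lcs(
        integration.filter_recurrent(matrix, min_datasets=cfg.min_datasets))
    _write(recurrent.reset_index(names="gene"), outdir / "integration.tsv")
    cands = integration.candidate_venn(matrix, fdr_max=cfg.fdr_max)
    cand_frame = pd.DataFrame(
        [{"gene": g, "pattern": "up_in_invasion_down_on_inhibition"}
         for g in cands.up_in_invasion_down_on_inhibition]
        + [{"gene": g, "pattern": "down_in_invasion_up_on_inhibition"}
           for g in cands.down_in_invasion_up_on_inhibition])
    _write(cand_frame, outdir / "candidates.tsv")
    top = recurrent[recurrent["lcs"].abs() >= 4]
    planted = set(truth.planted_genes)
    return {"summary": {
        "n_genes": int(matrix.shape[0]),
        "n_recurrent": int(recurrent.shape[0]),
        "n_high_lcs": int(top.shape[0]),
        "planted_recovered": int(sum(g in planted for g in top.index)),
        "candidates_up": cands.up_in_invasion_down_on_inhibition[:10],
        "candidates_down": cands.down_in_invasion_up_on_inhibition[:10]}}


def _stage_junction(cfg: PipelineConfig, outdir: Path) -> dict:
    frames = []
    for i, (cond, ef_true) in enumerate([("control", 1.2), ("treated", 2.0)]):
        images, segments, _ = simulate.simulate_contact_batch(
            n_contacts=100, true_ef=ef_true, noise_sd=5.0,
            condition=cond, seed=cfg.seed + i)
        frames.append(junction.batch_enrichment(images, segments,
                                                align=cfg.junction_align))
    efs = pd.concat(frames, ignore_index=True)
    _write(efs, outdir / "enrichment_factors.tsv")
    summary = junction.summarize_enrichment(efs)
    _write(summary, outdir / "enrichment_summary.tsv")
    anova = junction.compare_conditions(efs, control="control", seed=cfg.seed)
    return {"summary": {
        "means": {r["condition"]: round(float(r["mean"]), 6)
                  for _, r in summary.iterrows()},
        "anova_p": float(anova.p_value)}}


def run_pipeline(config: PipelineConfig, outdir,
                 stages=STAGES) -> dict:
    """Run the requested stages; returns the JSON-serializable report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    report: dict = {"config": {k: getattr(config, k)
                               for k in ("fdr_max", "min_log2cpm",
                                         "min_datasets", "seed")},
                    "stages": {}}
    caught: list[str] = []
    scores = None
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for stage in STAGES:
            if stage not in stages:
                continue
            if stage == "association" and scores is None:
                raise RuntimeError(
                    "stage 'association' requires stage 'invasion'")
            t0 = time.perf_counter()
            if stage == "invasion":
                res = _stage_invasion(config, outdir)
                scores = res.pop("scores")
            elif stage == "association":
                res = _stage_association(config, outdir, scores)
            elif stage == "integration":
                res = _stage_integration(config, outdir)
            else:
                res = _stage_junction(config, outdir)
            elapsed = time.perf_counter() - t0
            log.info("stage %s finished in %.2f s", stage, elapsed)
            report["stages"][stage] = res["summary"]
        caught = sorted({str(w.message) for w in wlist})
    report["warnings"] = caught

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_markdown(report, outdir / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    for stage, summary in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in sorted(summary.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    if report["warnings"]:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in report["warnings"])
        lines.append("")
    path.write_text("\n".join(lines))
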