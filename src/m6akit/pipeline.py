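"""End-to-end pipeline orchestration.

Runs the stages simulate -> callpeaks -> diffpeaks -> quadrants -> screen
-> gsea -> decay -> msquant from a single configuration, writing
format-stable outputs and a JSON run manifest.  A single global seed is
expanded into per-stage seeds by a fixed counter scheme
(``stage_seed = (seed + 1000 * stage_index) % 2**31``) so any stage rerun
in isolation reproduces its outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import gsea, integrate, io, kinetics, peaks as pk, simulate, workflow
from .simulate import SimulationConfig

log = logging.getLogger(__name__)

STAGES = ("simulate", "callpeaks", "diffpeaks", "quadrants",
          "screen", "gsea", "decay", "msquant")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},  # SimulationConfig field overrides
    "callpeaks": {"alpha": 0.05, "min_run": 2, "max_gap": 1},
    "diffpeaks": {"alpha": 0.05, "fdr": 0.05},
    "quadrants": {"min_abs_log2fc": 0.0, "min_share": 3},
    "screen": {"fc_threshold": 2.0},
    "gsea": {"n_permutations": 1000},
    "decay": {
        "timepoints": [0.0, 1.0, 2.0, 4.0, 8.0],
        "cv": 0.05,
        "n_series": 3,
        "rates": {"control": 0.35, "treated": 0.18},
    },
    "msquant": {
        "standards": [0.5, 1.0, 2.0, 5.0, 10.0],
        "noise": 0.002,
        "true_ratios": {"paratumor": 0.010, "tumor": 0.015},
    },
}

_STAGE_REQUIRES = {
    "callpeaks": ["windows.tsv"],
    "diffpeaks": ["windows.tsv", "peaks.bed"],
    "quadrants": ["windows.tsv", "transcripts.tsv", "expression.tsv", "peaks.bed"],
    "screen": ["windows.tsv", "transcripts.tsv", "expression.tsv",
               "expression_kd.tsv", "peaks.bed"],
    "gsea": ["expression.tsv"],
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + 1000 * STAGES.index(stage)) % (2**31)


@dataclass
class RunManifest:
    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, params: dict, inputs: list, outputs: list,
               status: str, elapsed_s: float) -> None:
        self.stages[stage] = {
            "params_hash": hashlib.sha256(
                json.dumps(params, sort_keys=True).encode()).hexdigest()[:12],
            "inputs": sorted(str(p) for p in inputs),
            "outputs": sorted(str(p) for p in outputs),
            "status": status,
            "elapsed_s": round(elapsed_s, 3),
        }

    def to_dict(self) -> dict:
        return {"seed": self.seed, "version": self.version, "stages": self.stages}


def _validate(config: dict, outdir: Path) -> None:
    enabled = config["stages"]
    for st in enabled:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
    for st in enabled:
        for req in _STAGE_REQUIRES.get(st, []):
            if "simulate" in enabled:
                continue  # produced upstream in this run
            if not (outdir / req).exists():
                raise FileNotFoundError(
                    f"stage {st!r} needs {req} in {outdir} (enable 'simulate' "
                    "or provide the file)")


def run_pipeline(config: dict, outdir, seed: int | None = None) -> RunManifest:
    """Execute the configured stages in dependency order.

    Inputs are validated before anything runs; a stage failure is recorded
    in the manifest and skips the downstream stages.  The manifest is
    written to ``<outdir>/manifest.json``.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = {**config, "seed": int(seed)}
    _validate(config, outdir)
    manifest = RunManifest(seed=int(config["seed"]), version=__version__)
    failed = False
    for st in STAGES:
        if st not in config["stages"]:
            continue
        if failed:
            manifest.record(st, {}, [], [], "skipped", 0.0)
            continue
        t0 = time.perf_counter()
        try:
            inputs, outputs = _run_stage(st, config, outdir)
            manifest.record(st, config.get(st, {}), inputs, outputs,
                            "ok", time.perf_counter() - t0)
            log.info("stage %s ok (%.2fs): %s", st, time.perf_counter() - t0,
                     [Path(o).name for o in outputs])
        except Exception as exc:  # record and halt downstream
            manifest.record(st, config.get(st, {}), [], [],
                            f"failed: {exc}", time.perf_counter() - t0)
            log.error("stage %s failed: %s", st, exc)
            failed = True
    io.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest


def _run_stage(stage: str, config: dict, outdir: Path):
    seed = stage_seed(config["seed"], stage)
    params = config.get(stage, {})
    fn = {
        "simulate": _stage_simulate, "callpeaks": _stage_callpeaks,
        "diffpeaks": _stage_diffpeaks, "quadrants": _stage_quadrants,
        "screen": _stage_screen, "gsea": _stage_gsea,
        "decay": _stage_decay, "msquant": _stage_msquant,
    }[stage]
    return fn(params, config, outdir, seed)


def _stage_simulate(params, config, outdir, seed):
    cfg = SimulationConfig(**{**params, "seed": seed})
    transcripts, truth = simulate.generate_truth(cfg)
    windows = simulate.simulate_merip_windows(truth, transcripts, cfg)
    expression = simulate.simulate_expression(truth, cfg)
    kd = simulate.simulate_knockdown_expression(truth, cfg)
    io.write_transcripts(transcripts, outdir / "transcripts.tsv")
    io.write_truth(truth, outdir / "truth.tsv")
    io.write_windows(windows, outdir / "windows.tsv")
    io.write_expression(expression, outdir / "expression.tsv")
    io.write_expression(kd, outdir / "expression_kd.tsv")
    return [], [outdir / f for f in ("transcripts.tsv", "truth.tsv", "windows.tsv",
                                     "expression.tsv", "expression_kd.tsv")]


def _stage_callpeaks(params, config, outdir, seed):
    windows = io.read_windows(outdir / "windows.tsv")
    peak_list = pk.call_peaks(windows, **params)
    io.write_peaks_bed(peak_list, outdir / "peaks.bed")
    transcripts = io.read_transcripts(outdir / "transcripts.tsv")
    frac = pk.segment_fractions(peak_list, transcripts)
    io.write_json({"frac_utr5": frac.frac_utr5, "frac_cds": frac.frac_cds,
                   "frac_utr3": frac.frac_utr3, "n_peaks": frac.n_peaks},
                  outdir / "segment_fractions.json")
    return ([outdir / "windows.tsv"],
            [outdir / "peaks.bed", outdir / "segment_fractions.json"])


def _stage_diffpeaks(params, config, outdir, seed):
    windows = io.read_windows(outdir / "windows.tsv")
    peak_list = io.read_peaks_bed(outdir / "peaks.bed")
    wa, wb = workflow.split_conditions(windows)
    dps = pk.differential_methylation(peak_list, wa, wb, **params)
    io.write_differential_peaks(dps, outdir / "differential_peaks.tsv")
    return ([outdir / "windows.tsv", outdir / "peaks.bed"],
            [outdir / "differential_peaks.tsv"])


def _stage_quadrants(params, config, outdir, seed):
    windows = io.read_windows(outdir / "windows.tsv")
    expression = io.read_expression(outdir / "expression.tsv")
    transcripts = io.read_transcripts(outdir / "transcripts.tsv")
    dp_cfg = config.get("diffpeaks", {})
    _, calls = workflow.per_patient_quadrants(
        windows, expression, transcripts,
        alpha=dp_cfg.get("alpha", 0.05), fdr=dp_cfg.get("fdr", 0.05),
        min_abs_log2fc=params.get("min_abs_log2fc", 0.0),
    )
    rows = [{"gene_id": c.gene_id, "patient": patient, "quadrant": c.quadrant}
            for patient, cs in calls.items() for c in cs]
    pd.DataFrame(rows, columns=["gene_id", "patient", "quadrant"]).to_csv(
        outdir / "quadrants.tsv", sep="\t", index=False)
    summary = integrate.quadrant_percentages(calls)
    hyperup_sets = {p: {c.gene_id for c in cs if c.quadrant == "hyper-up"}
                    for p, cs in calls.items()}
    min_share = min(params.get("min_share", 3), len(hyperup_sets))
    io.write_json({
        "per_patient_counts": summary.per_patient.to_dict(orient="index"),
        "per_patient_pct": summary.per_patient_pct.to_dict(orient="index"),
        "cohort_mean_pct": summary.cohort_mean_pct,
        "pooled_pct": summary.pooled_pct,
        "n_calls": summary.n_calls,
        "high_frequency_hyperup": integrate.high_frequency_hyperup(
            hyperup_sets, min_share=min_share),
    }, outdir / "quadrant_summary.json")
    return ([outdir / f for f in ("windows.tsv", "expression.tsv", "transcripts.tsv")],
            [outdir / "quadrants.tsv", outdir / "quadrant_summary.json"])


def _stage_screen(params, config, outdir, seed):
    windows = io.read_windows(outdir / "windows.tsv")
    transcripts = io.read_transcripts(outdir / "transcripts.tsv")
    expression = io.read_expression(outdir / "expression.tsv")
    kd = io.read_expression(outdir / "expression_kd.tsv")
    peak_list = io.read_peaks_bed(outdir / "peaks.bed")
    wa, wb = workflow.split_conditions(windows)
    dp_cfg = config.get("diffpeaks", {})
    dps = pk.differential_methylation(peak_list, wa, wb,
                                      fdr=dp_cfg.get("fdr", 0.05),
                                      alpha=dp_cfg.get("alpha", 0.05))
    hyper = workflow.hyper_gene_set(dps, transcripts)
    fc_a = workflow.fold_change_table(kd, workflow.expression_conditions(kd.columns))
    fc_b = workflow.fold_change_table(
        expression, workflow.expression_conditions(expression.columns))
    fc_b["hyper"] = fc_b["gene_id"].isin(hyper)
    result = integrate.screen_candidates(fc_a, fc_b,
                                         fc_threshold=params.get("fc_threshold", 2.0))
    io.write_json({
        "n_list_a": result.n_list_a, "n_list_b": result.n_list_b,
        "n_candidates": result.n_candidates,
        "candidates": list(result.candidates),
        "list_a": sorted(result.list_a), "list_b": sorted(result.list_b),
    }, outdir / "screen.json")
    return ([outdir / f for f in ("windows.tsv", "transcripts.tsv",
                                  "expression.tsv", "expression_kd.tsv", "peaks.bed")],
            [outdir / "screen.json"])


def _stage_gsea(params, config, outdir, seed):
    expression = io.read_expression(outdir / "expression.tsv")
    ranked = gsea.rank_from_expression(
        expression, workflow.expression_conditions(expression.columns))
    signature = gsea.load_hypoxia_signature()
    result = gsea.nes_and_pvalue(ranked, signature,
                                 n_permutations=params.get("n_permutations", 1000),
                                 seed=seed)
    io.write_json({
        "gene_set": signature.name, "es": result.es, "nes": result.nes,
        "p_value": result.p_value, "n_permutations": result.n_permutations,
        "n_hits": result.n_hits, "seed": result.seed,
    }, outdir / "enrichment.json")
    return [outdir / "expression.tsv"], [outdir / "enrichment.json"]


def _stage_decay(params, config, outdir, seed):
    rows, fits = [], []
    i = 0
    for label, k in params["rates"].items():
        for r in range(params["n_series"]):
            series = simulate.simulate_decay_series(
                k, params["timepoints"], cv=params["cv"], seed=seed + i)
            i += 1
            sid = f"{label}_r{r + 1}"
            for t, a in zip(series.timepoints, series.abundances):
                rows.append({"series_id": sid, "time_h": t, "rel_abundance": a})
            fit = kinetics.fit_decay(series)
            fits.append({"series_id": sid, "condition": label, "true_k": k,
                         "k": fit.k, "t_half": fit.t_half,
                         "r_squared": fit.r_squared, "n_points": fit.n_points})
    io.write_decay(pd.DataFrame(rows), outdir / "decay.tsv")
    pd.DataFrame(fits).to_csv(outdir / "decay_fits.tsv", sep="\t", index=False)
    return [], [outdir / "decay.tsv", outdir / "decay_fits.tsv"]


def _stage_msquant(params, config, outdir, seed):
    all_standards, results = [], {}
    for i, (label, ratio) in enumerate(params["true_ratios"].items()):
        standards, responses = simulate.simulate_calibration_run(
            ratio, params["standards"], noise=params["noise"], seed=seed + i)
        standards = standards.assign(sample=label)
        all_standards.append(standards)
        curves = {
            ch: kinetics.fit_calibration(
                standards.loc[standards["channel"] == ch,
                              ["concentration", "response"]].to_numpy(), ch)
            for ch in (kinetics.CHANNEL_M6A, kinetics.CHANNEL_A)
        }
        results[label] = {
            "true_ratio": ratio,
            "estimated_ratio": kinetics.quantify_m6a_to_a_ratio(responses, curves),
            "curves": {ch: {"slope": c.slope, "intercept": c.intercept,
                            "r_squared": c.r_squared} for ch, c in curves.items()},
        }
    cal = pd.concat(all_standards, ignore_index=True)
    cal.to_csv(outdir / "calibration.tsv", sep="\t", index=False,
               columns=["sample", "channel", "concentration", "response"])
    io.write_json(results, outdir / "ms_quant.json")
    return [], [outdir / "calibration.tsv", outdir / "ms_quant.json"]
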