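"""Quadrant classification per patient, high-frequency genes, candidate screen.

Classifies each gene with both a differential peak and an expression
change into hyper-up/hyper-down/hypo-up/hypo-down per patient pair,
averages the percentages over the cohort (the analysis behind the
"hyper-up ~70% of altered m6A-mRNAs" observation), lists genes hyper-up
in at least 3 patients, and intersects the two >2-fold lists (knockdown-up
x hypermethylated-and-up) into candidate targets.
"""

import argparse
from pathlib import Path

from m6akit import io
from m6akit.integrate import high_frequency_hyperup, quadrant_percentages, screen_candidates
from m6akit.peaks import differential_methylation
from m6akit.workflow import (
    expression_conditions,
    fold_change_table,
    hyper_gene_set,
    per_patient_quadrants,
    split_conditions,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results/integration"))
    ap.add_argument("--fc-threshold", type=float, default=2.0)
    ap.add_argument("--min-share", type=int, default=3)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    windows = io.read_windows(args.cohort / "windows.tsv")
    transcripts = io.read_transcripts(args.cohort / "transcripts.tsv")
    expression = io.read_expression(args.cohort / "expression.tsv")
    kd = io.read_expression(args.cohort / "expression_kd.tsv")

    peaks, calls = per_patient_quadrants(windows, expression, transcripts)
    summary = quadrant_percentages(calls)
    print("cohort-mean quadrant percentages:",
          {k: round(v, 2) for k, v in summary.cohort_mean_pct.items()})
    hyperup_sets = {p: {c.gene_id for c in cs if c.quadrant == "hyper-up"}
                    for p, cs in calls.items()}
    hf = high_frequency_hyperup(hyperup_sets, min_share=args.min_share)
    print(f"high-frequency hyper-up genes (>= {args.min_share} patients): "
          f"{len(hf)}; top: {hf[:8]}")

    wa, wb = split_conditions(windows)
    dps = differential_methylation(peaks, wa, wb)
    hyper = hyper_gene_set(dps, transcripts)
    fc_a = fold_change_table(kd, expression_conditions(kd.columns))
    fc_b = fold_change_table(expression, expression_conditions(expression.columns))
    fc_b["hyper"] = fc_b["gene_id"].isin(hyper)
    screen = screen_candidates(fc_a, fc_b, fc_threshold=args.fc_threshold)
    print(f"screen: {screen.n_list_a} knockdown-up genes x {screen.n_list_b} "
          f"hyper-and-up genes -> {screen.n_candidates} candidates")

    io.write_json({
        "cohort_mean_pct": summary.cohort_mean_pct,
        "pooled_pct": summary.pooled_pct,
        "n_calls": summary.n_calls,
        "high_frequency_hyperup": hf,
        "screen": {"n_list_a": screen.n_list_a, "n_list_b": screen.n_list_b,
                   "n_candidates": screen.n_candidates,
                   "candidates": list(screen.candidates)},
    }, args.outdir / "integration_summary.json")


if __name__ == "__main__":
    main()
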