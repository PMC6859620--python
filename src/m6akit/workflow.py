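"""Study-level workflows composed from the module primitives.

These are the routines the analysis drivers and the validation benchmarks
share: the per-patient quadrant workflow (peaks pooled across the cohort,
differential methylation and expression per patient pair), the screen
construction from two contrasts, and the simulation benchmarks that check
error-rate control (type-I error of the window test, false-discovery
proportion of the differential calls) and quadrant recovery.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import integrate, peaks as pk, simulate
from .integrate import QuadrantCall
from .peaks import DifferentialPeak, Peak
from .simulate import SimulationConfig

log = logging.getLogger(__name__)


def patient_of_sample(sample: str) -> str:
    return sample.split("_")[0]


def split_conditions(windows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    return (windows[windows["condition"] == "A"],
            windows[windows["condition"] == "B"])


def expression_conditions(columns: Sequence[str]) -> dict[str, str]:
    """Condition labels for the simulator's sample naming (…_N = A, …_T = B)."""
    cond = {}
    for c in columns:
        if c.endswith("_N") or c.startswith("CTRL"):
            cond[c] = "A"
        elif c.endswith("_T") or c.startswith("KD"):
            cond[c] = "B"
        else:
            raise ValueError(f"cannot infer condition for sample {c!r}")
    return cond


def per_patient_quadrants(
    windows: pd.DataFrame,
    expression: pd.DataFrame,
    transcripts: pd.DataFrame,
    alpha: float = pk.DEFAULT_ALPHA,
    fdr: float = pk.DEFAULT_FDR,
    min_run: int = pk.DEFAULT_MIN_RUN,
    max_gap: int = pk.DEFAULT_MAX_GAP,
    min_abs_log2fc: float = 0.0,
) -> tuple[list[Peak], dict[str, list[QuadrantCall]]]:
    """Cohort-pooled peak calling, then per-patient quadrant classification.

    Peaks are called once on counts pooled over every sample (both
    conditions); each patient's tumor/paratumor pair is then tested for
    differential methylation over those peaks and for expression change,
    and genes directional on both axes get a quadrant call.
    """
    peak_list = pk.call_peaks(windows, alpha=alpha, min_run=min_run, max_gap=max_gap)
    calls_by_patient: dict[str, list[QuadrantCall]] = {}
    patients = sorted({patient_of_sample(s) for s in windows["sample"].unique()})
    for patient in patients:
        w = windows[windows["sample"].map(patient_of_sample) == patient]
        wa, wb = split_conditions(w)
        dps = pk.differential_methylation(peak_list, wa, wb, fdr=fdr, alpha=alpha)
        cols = [c for c in expression.columns if patient_of_sample(c) == patient]
        cond = expression_conditions(cols)
        changes = integrate.expression_changes(expression[cols], cond,
                                              min_abs_log2fc=min_abs_log2fc)
        calls_by_patient[patient] = integrate.classify_quadrants(dps, changes, transcripts)
    return peak_list, calls_by_patient


def fold_change_table(expression: pd.DataFrame, conditions: Mapping[str, str]) -> pd.DataFrame:
    """Linear fold changes (B over A) per gene, for the screen lists."""
    changes = integrate.expression_changes(expression, conditions, min_abs_log2fc=0.0)
    return pd.DataFrame({
        "gene_id": [c.gene_id for c in changes],
        "fold_change": [2.0 ** c.log2_fc for c in changes],
    })


def hyper_gene_set(diff_peaks: Sequence[DifferentialPeak], transcripts: pd.DataFrame) -> set[str]:
    gene_of = dict(zip(transcripts["transcript_id"], transcripts["gene_id"]))
    return {gene_of[dp.peak.transcript_id] for dp in diff_peaks if dp.direction == "hyper"}


# ---------------------------------------------------------------------------
# simulation benchmarks
# ---------------------------------------------------------------------------

def type1_error_benchmark(
    n_windows: int = 10_000,
    seed: int = 0,
    alpha: float = pk.DEFAULT_ALPHA,
    dispersion: float = 0.05,
) -> float:
    """Empirical type-I error of the one-sided window enrichment test.

    Simulates a methylation-free cohort (IP and input rates identical for
    every window), pools samples, tests each window against its transcript
    totals, and returns the fraction of the first ``n_windows`` windows
    with p below ``alpha``.  The exact test is conservative, so this
    fraction should sit below the nominal level.
    """
    approx_len = 2200  # expected transcript length under default segment means
    cfg = SimulationConfig(
        n_transcripts=int(np.ceil(n_windows / (approx_len / 50))) + 20,
        n_patients=2, frac_methylated=0.0, dispersion=dispersion, seed=seed,
    )
    transcripts, truth = simulate.generate_truth(cfg)
    windows = simulate.simulate_merip_windows(truth, transcripts, cfg)
    pooled = windows.groupby(
        ["transcript_id", "window_start", "window_end"], sort=True
    )[["ip_count", "input_count"]].sum().reset_index()

    pvals = []
    for _, grp in pooled.groupby("transcript_id", sort=True):
        tot_ip = int(grp["ip_count"].sum())
        tot_in = int(grp["input_count"].sum())
        if tot_ip == 0 or tot_in == 0:
            continue
        p, _ = pk.window_enrichment_tests(
            grp["ip_count"].to_numpy(), grp["input_count"].to_numpy(), tot_ip, tot_in
        )
        pvals.append(p)
    allp = np.concatenate(pvals)
    if allp.size < n_windows:
        raise RuntimeError("simulated fewer windows than requested")
    return float(np.mean(allp[:n_windows] < alpha))


def fdr_benchmark(
    n_replicates: int = 20,
    seed: int = 0,
    n_transcripts: int = 2000,
    frac_gain: float = 0.10,
    diff_shift: float = 2.5,
    n_patients: int = 4,
    fdr: float = pk.DEFAULT_FDR,
    alpha: float = pk.DEFAULT_ALPHA,
) -> float:
    """Mean false-discovery proportion of the differential peak calls.

    Each replicate plants a true methylation gain (IP-rate shift
    ``diff_shift`` in condition B) on ``frac_gain`` of transcripts; an
    equal fraction carries a stable peak and the rest are unmethylated,
    so the nulls include both noise windows and non-differential peaks.
    A called peak is a false discovery when its transcript carries no
    true gain or its direction contradicts the planted one.
    """
    mix = (0.5, 0.5, 0.0, 0.0)  # all differential transcripts are "gain"
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    fdps = []
    for rs in rep_seeds:
        cfg = SimulationConfig(
            n_transcripts=n_transcripts, n_patients=n_patients,
            frac_methylated=2 * frac_gain, frac_diff_methylated=0.5,
            quadrant_mix=mix, diff_shift=diff_shift, seed=rs,
        )
        transcripts, truth = simulate.generate_truth(cfg)
        windows = simulate.simulate_merip_windows(truth, transcripts, cfg)
        peak_list = pk.call_peaks(windows, alpha=alpha)
        wa, wb = split_conditions(windows)
        dps = pk.differential_methylation(peak_list, wa, wb, fdr=fdr, alpha=alpha)
        truth_dir = dict(zip(truth["transcript_id"], truth["meth_direction"]))
        called = [dp for dp in dps if dp.direction != "none"]
        if not called:
            fdps.append(0.0)
            continue
        false = sum(
            1 for dp in called
            if not (dp.direction == "hyper"
                    and truth_dir.get(dp.peak.transcript_id) == "gain")
        )
        fdps.append(false / len(called))
    return float(np.mean(fdps))


def quadrant_recovery_benchmark(
    n_seeds: int = 10,
    seed: int = 0,
    n_transcripts: int = 1000,
    config: SimulationConfig | None = None,
) -> list[float]:
    """Cohort-mean hyper-up percentage recovered across seeded cohorts.

    Runs the full per-patient quadrant workflow on simulated cohorts with
    the default quadrant mixture (0.7 hyper-up) and strong planted effects
    and returns one cohort-mean hyper-up percentage per seed.
    """
    base = config or SimulationConfig(n_transcripts=n_transcripts)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_seeds)]
    shares = []
    for rs in rep_seeds:
        cfg = base.replace(seed=rs, n_transcripts=n_transcripts)
        transcripts, truth = simulate.generate_truth(cfg)
        windows = simulate.simulate_merip_windows(truth, transcripts, cfg)
        expression = simulate.simulate_expression(truth, cfg)
        _, calls = per_patient_quadrants(windows, expression, transcripts)
        summary = integrate.quadrant_percentages(calls)
        shares.append(float(summary.cohort_mean_pct["hyper-up"]))
    return shares
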