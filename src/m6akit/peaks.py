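"""m6A peak detection and differential methylation from IP/input counts.

Each window of each transcript carries an IP count and an input count.
Enrichment is assessed with a one-sided exact (hypergeometric-tail) test
of whether the window's share of the transcript's IP reads exceeds its
share of the input reads; significant windows are merged into peaks, and
peaks are tested for differential methylation between conditions with a
two-sided exact test and Benjamini-Hochberg FDR control — the "P < 0.05
and 5% FDR" convention of MeRIP-seq differential analyses.

All coordinates are transcript-space, 0-based and half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FDR = 0.05
DEFAULT_MIN_RUN = 2
DEFAULT_MAX_GAP = 1
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class Peak:
    transcript_id: str
    start: int
    end: int
    enrichment: float      # pseudocounted IP/input odds ratio over the run
    p_value: float         # minimum window p inside the run

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("peak needs start < end")


@dataclass(frozen=True)
class DifferentialPeak:
    peak: Peak
    log2_meth_fc: float    # log2 of (IP/input)_B over (IP/input)_A, pseudocounted
    p_value: float
    q_value: float
    direction: str         # hyper | hypo | none
    ip_a: int = 0
    input_a: int = 0
    ip_b: int = 0
    input_b: int = 0


@dataclass(frozen=True)
class SegmentFractionSummary:
    frac_utr5: float
    frac_cds: float
    frac_utr3: float
    n_peaks: int


def window_enrichment_test(
    ip_count: int,
    input_count: int,
    total_ip: int,
    total_input: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float]:
    """One-sided exact enrichment test for a single window.

    Tests whether the window's share of IP reads exceeds its share of
    input reads, via the upper hypergeometric tail of the 2x2 table
    ``[ip, total_ip - ip; input, total_input - input]``.  Returns
    ``(p_value, odds_ratio)`` with the odds ratio pseudocounted on all
    four cells.
    """
    if total_ip <= 0 or total_input <= 0:
        raise ValueError("enrichment test undefined with zero library totals")
    if ip_count < 0 or input_count < 0 or ip_count > total_ip or input_count > total_input:
        raise ValueError("counts must be nonnegative and bounded by the totals")
    m = total_ip + total_input
    drawn = ip_count + input_count
    p = float(stats.hypergeom.sf(ip_count - 1, m, total_ip, drawn))
    a = pseudocount
    odds = ((ip_count + a) * (total_input - input_count + a)) / (
        (input_count + a) * (total_ip - ip_count + a)
    )
    return min(p, 1.0), odds


def window_enrichment_tests(
    ip_counts: np.ndarray,
    input_counts: np.ndarray,
    total_ip: int,
    total_input: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised form of :func:`window_enrichment_test` over many windows."""
    if total_ip <= 0 or total_input <= 0:
        raise ValueError("enrichment test undefined with zero library totals")
    ip = np.asarray(ip_counts, dtype=np.int64)
    inp = np.asarray(input_counts, dtype=np.int64)
    m = total_ip + total_input
    p = stats.hypergeom.sf(ip - 1, m, total_ip, ip + inp)
    a = pseudocount
    odds = ((ip + a) * (total_input - inp + a)) / ((inp + a) * (total_ip - ip + a))
    return np.minimum(p, 1.0), odds


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exact_two_sided_p(ip_b: int, input_b: int, ip_a: int, input_a: int) -> float:
    """Two-sided exact (Fisher) p for the 2x2 table [ip_b, input_b; ip_a, input_a].

    Sums the conditional hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    one (with a 1e-7 relative tie guard against floating-point noise).
    """
    for v in (ip_b, input_b, ip_a, input_a):
        if v < 0:
            raise ValueError("cell counts must be nonnegative")
    n = ip_b + input_b + ip_a + input_a
    if n == 0:
        return 1.0
    row_b = ip_b + input_b
    col_ip = ip_b + ip_a
    lo = max(0, row_b + col_ip - n)
    hi = min(row_b, col_ip)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col_ip, row_b)
    p_obs = pmf[ip_b - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def _pooled_window_table(windows: pd.DataFrame) -> pd.DataFrame:
    """Sum IP and input counts over samples per (transcript, window)."""
    return (
        windows.groupby(["transcript_id", "window_start", "window_end"], sort=True)[
            ["ip_count", "input_count"]
        ]
        .sum()
        .reset_index()
    )


def call_peaks(
    windows: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_run: int = DEFAULT_MIN_RUN,
    max_gap: int = DEFAULT_MAX_GAP,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[Peak]:
    """Merge significantly enriched windows into peaks.

    Counts are pooled over every sample present in ``windows`` (replicates
    within — or across — conditions are summed before testing).  Per
    transcript, windows with one-sided p < ``alpha`` are merged into
    maximal runs allowing up to ``max_gap`` intervening non-significant
    windows; runs with fewer than ``min_run`` significant windows are
    dropped.  The peak p-value is the minimum window p, the enrichment the
    pooled odds ratio over the merged span.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if windows.empty:
        return []
    pooled = _pooled_window_table(windows)  # sorted by transcript, window_start
    ip = pooled["ip_count"].to_numpy(dtype=np.int64)
    inp = pooled["input_count"].to_numpy(dtype=np.int64)
    w_start = pooled["window_start"].to_numpy(dtype=np.int64)
    w_end = pooled["window_end"].to_numpy(dtype=np.int64)
    codes, tids = pd.factorize(pooled["transcript_id"], sort=False)

    tot_ip = np.bincount(codes, weights=ip).astype(np.int64)
    tot_in = np.bincount(codes, weights=inp).astype(np.int64)
    t_ip, t_in = tot_ip[codes], tot_in[codes]
    valid = (t_ip > 0) & (t_in > 0)
    p = np.ones(len(pooled))
    p[valid] = stats.hypergeom.sf(
        ip[valid] - 1, t_ip[valid] + t_in[valid], t_ip[valid],
        ip[valid] + inp[valid],
    )
    p = np.minimum(p, 1.0)

    bounds = np.concatenate(([0], np.flatnonzero(np.diff(codes)) + 1, [codes.size]))
    a = pseudocount
    peaks: list[Peak] = []
    cum_ip = np.concatenate(([0], np.cumsum(ip)))
    cum_in = np.concatenate(([0], np.cumsum(inp)))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        sig = b0 + np.flatnonzero(p[b0:b1] < alpha)
        if sig.size == 0:
            continue
        runs: list[list[int]] = [[sig[0]]]
        for i in sig[1:]:
            if i - runs[-1][-1] - 1 <= max_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        total_ip, total_input = int(tot_ip[codes[b0]]), int(tot_in[codes[b0]])
        for run in runs:
            if len(run) < min_run:
                continue
            lo, hi = run[0], run[-1]
            ip_run = int(cum_ip[hi + 1] - cum_ip[lo])
            in_run = int(cum_in[hi + 1] - cum_in[lo])
            odds = ((ip_run + a) * (total_input - in_run + a)) / (
                (in_run + a) * (total_ip - ip_run + a)
            )
            peaks.append(Peak(
                transcript_id=str(tids[codes[b0]]),
                start=int(w_start[lo]),
                end=int(w_end[hi]),
                enrichment=float(odds),
                p_value=float(p[run].min()),
            ))
    return peaks


def _group_by_transcript(pooled: pd.DataFrame) -> dict:
    """Per-transcript window arrays (start, end, ip, input) for fast lookup."""
    out = {}
    for tid, grp in pooled.groupby("transcript_id", sort=False):
        out[str(tid)] = (
            grp["window_start"].to_numpy(dtype=np.int64),
            grp["window_end"].to_numpy(dtype=np.int64),
            grp["ip_count"].to_numpy(dtype=np.int64),
            grp["input_count"].to_numpy(dtype=np.int64),
        )
    return out


def _sum_over_interval(grouped: dict, tid: str, start: int, end: int) -> tuple[int, int]:
    if tid not in grouped:
        return 0, 0
    ws, we, ip, inp = grouped[tid]
    mask = (ws < end) & (we > start)
    return int(ip[mask].sum()), int(inp[mask].sum())


def differential_methylation(
    peaks: list[Peak],
    windows_condition_a: pd.DataFrame,
    windows_condition_b: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DifferentialPeak]:
    """Test each peak for a methylation change between conditions.

    Per peak, IP and input counts are summed over the peak interval and
    over samples within each condition; the p-value is the two-sided exact
    (Fisher) test of the table [IP_B, input_B; IP_A, input_A], the effect
    size log2 of the pseudocounted (IP/input) ratio of B over A.  q-values
    are Benjamini-Hochberg across all peaks; a direction (hyper/hypo) is
    assigned where p < ``alpha`` and q < ``fdr``.
    """
    if not peaks:
        return []
    grouped_a = _group_by_transcript(_pooled_window_table(windows_condition_a))
    grouped_b = _group_by_transcript(_pooled_window_table(windows_condition_b))
    a = pseudocount

    records = []
    for pk in peaks:
        ip_a, in_a = _sum_over_interval(grouped_a, pk.transcript_id, pk.start, pk.end)
        ip_b, in_b = _sum_over_interval(grouped_b, pk.transcript_id, pk.start, pk.end)
        if ip_a + in_a + ip_b + in_b == 0:
            p = 1.0
        else:
            p = exact_two_sided_p(ip_b, in_b, ip_a, in_a)
        lfc = math.log2(((ip_b + a) / (in_b + a)) / ((ip_a + a) / (in_a + a)))
        records.append((pk, lfc, p, ip_a, in_a, ip_b, in_b))

    q = bh_adjust([r[2] for r in records])
    out = []
    for (pk, lfc, p, ip_a, in_a, ip_b, in_b), qv in zip(records, q):
        if p < alpha and qv < fdr and lfc > 0:
            direction = "hyper"
        elif p < alpha and qv < fdr and lfc < 0:
            direction = "hypo"
        else:
            direction = "none"
        out.append(DifferentialPeak(
            peak=pk, log2_meth_fc=float(lfc), p_value=p, q_value=float(qv),
            direction=direction, ip_a=ip_a, input_a=in_a, ip_b=ip_b, input_b=in_b,
        ))
    return out


def segment_fractions(peaks: list[Peak], transcripts: pd.DataFrame) -> SegmentFractionSummary:
    """Fraction of peaks whose midpoint falls in the 5'UTR, CDS and 3'UTR.

    The midpoint is floor((start+end)/2); segments are half-open intervals
    [0, utr5), [utr5, utr5+cds), [utr5+cds, total), so a midpoint exactly
    on the CDS/3'UTR boundary belongs to the 3'UTR.
    """
    if not peaks:
        return SegmentFractionSummary(0.0, 0.0, 0.0, 0)
    tx = transcripts.set_index("transcript_id")
    counts = [0, 0, 0]
    for pk in peaks:
        if pk.transcript_id not in tx.index:
            raise KeyError(f"peak references unknown transcript {pk.transcript_id!r}")
        row = tx.loc[pk.transcript_id]
        mid = (pk.start + pk.end) // 2
        b1, b2 = int(row["utr5_len"]), int(row["utr5_len"]) + int(row["cds_len"])
        if mid < b1:
            counts[0] += 1
        elif mid < b2:
            counts[1] += 1
        else:
            counts[2] += 1
    n = len(peaks)
    return SegmentFractionSummary(counts[0] / n, counts[1] / n, counts[2] / n, n)
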