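"""Ground-truthed synthetic data for the MeRIP-seq analysis pipeline.

The generator emulates a paired tumor/paratumor (or hypoxia/normoxia)
MeRIP-seq cohort: transcripts with 5'UTR/CDS/3'UTR structure, one planted
m6A peak per methylated transcript with a 3'UTR/CDS placement bias,
negative-binomial IP and input window counts, gene-level expression counts
with planted shifts biased toward the "hyper-up" quadrant, exponential
decay time courses, and linear nucleoside calibration standards.

Every draw goes through a single :class:`numpy.random.Generator`, so a
fixed seed gives bit-identical outputs.  Counts are negative binomial with
mean ``mu`` and overdispersion ``d`` (variance ``mu + d*mu**2``); the
Poisson limit is approached as ``d -> 0`` but ``d`` must stay positive.
For window counts the NB arises hierarchically: a gamma abundance factor
(mean 1, variance ``d``) per transcript x sample — shared by the paired
IP and input fractions of that sample — multiplies the window rates, and
reads are then Poisson-sampled.  Marginally every window count is
NB(mean, d); conditionally on the shared abundance factors, read sampling
is Poisson, which is the sampling model the downstream exact tests assume.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import CHANNEL_A, CHANNEL_M6A, DecaySeries

QUADRANTS = ("hyper-up", "hyper-down", "hypo-up", "hypo-down")

#: symbols of the 14-gene hypoxia metagene signature embedded in the
#: simulated gene universe when ``embed_hypoxia_signature`` is on
_SIGNATURE_SYMBOLS = (
    "ALDOA", "MIF", "TUBB6", "P4HA1", "SLC2A1", "PGAM1", "ENO1",
    "LDHA", "CDKN3", "TPI1", "NDRG1", "VEGFA", "ACOT7", "ADM",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the emulated study: 8 paired samples, ~30% of
    transcripts methylated, half of those with a differential peak, a
    quadrant mixture dominated by hyper-up (0.7), 4x IP enrichment inside
    peaks, a 2.5x methylation shift and 2x expression shift for planted
    differential transcripts, and a 3'UTR/CDS-biased peak placement.
    """

    n_transcripts: int = 1000
    n_patients: int = 8
    window_size: int = 50
    segment_length_means: tuple[int, int, int] = (200, 1200, 800)
    frac_methylated: float = 0.3
    frac_diff_methylated: float = 0.5
    quadrant_mix: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    peak_enrichment: float = 4.0
    diff_shift: float = 2.5
    expr_fc: float = 2.0
    seq_depth: float = 300.0
    dispersion: float = 0.05
    peak_segment_bias: tuple[float, float, float] = (0.1, 0.35, 0.55)
    peak_width_windows: int = 2
    embed_hypoxia_signature: bool = True
    kd_fc: float = 4.0            # planted fold change in the knockdown contrast
    kd_hit_rate: float = 0.9      # P(hyper-up gene responds to knockdown)
    kd_background_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        for name in ("frac_methylated", "frac_diff_methylated",
                     "kd_hit_rate", "kd_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (Poisson limit excluded)")
        if any(w < 0 for w in self.quadrant_mix) or sum(self.quadrant_mix) <= 0:
            raise ValueError("quadrant_mix needs nonnegative weights, sum > 0")
        if any(w < 0 for w in self.peak_segment_bias) or sum(self.peak_segment_bias) <= 0:
            raise ValueError("peak_segment_bias needs nonnegative weights, sum > 0")
        if self.peak_enrichment < 1:
            raise ValueError("peak_enrichment must be >= 1")
        if self.diff_shift < 1:
            raise ValueError("diff_shift must be >= 1")
        if self.expr_fc < 1 or self.kd_fc < 1:
            raise ValueError("fold changes must be >= 1; direction is encoded in the truth")
        if self.seq_depth <= 0:
            raise ValueError("seq_depth must be > 0")
        if any(m <= 0 for m in self.segment_length_means):
            raise ValueError("segment_length_means must be positive")

    @property
    def normalized_quadrant_mix(self) -> np.ndarray:
        w = np.asarray(self.quadrant_mix, dtype=float)
        return w / w.sum()

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mu`` and overdispersion ``dispersion``."""
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mu, dtype=float))
    return rng.negative_binomial(size, p)


def _sample_names(n_patients: int) -> tuple[list[str], list[str], np.ndarray]:
    """Sample ids, condition labels (A=normal-like, B=tumor-like), patient index."""
    samples, conditions, patients = [], [], []
    for p in range(n_patients):
        for cond, tag in (("A", "N"), ("B", "T")):
            samples.append(f"P{p + 1:02d}_{tag}")
            conditions.append(cond)
            patients.append(p)
    return samples, conditions, np.asarray(patients)


def generate_truth(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the transcript models and the planted ground truth.

    Returns ``(transcripts, truth)``.  ``transcripts`` has columns
    ``transcript_id, gene_id, utr5_len, cds_len, utr3_len, total_len``;
    ``truth`` has per-transcript flags: ``is_methylated``, a planted
    ``peak_start/peak_end`` interval (nullable), ``meth_direction`` in
    {gain, loss, none}, ``expr_direction`` in {up, down, none},
    ``true_quadrant`` (nullable) and the knockdown-response flag ``kd_up``.
    """
    config.validate()
    n = config.n_transcripts
    rng = np.random.default_rng(config.seed)

    m5, mcds, m3 = config.segment_length_means
    utr5 = rng.poisson(m5, n).astype(np.int64)
    cds = np.maximum(3, rng.poisson(mcds, n)).astype(np.int64)
    utr3 = rng.poisson(m3, n).astype(np.int64)
    total = utr5 + cds + utr3

    tids = np.array([f"T{i:05d}" for i in range(n)])
    gids = np.array([f"G{i:05d}" for i in range(n)], dtype=object)

    is_meth = rng.random(n) < config.frac_methylated
    is_diff = is_meth & (rng.random(n) < config.frac_diff_methylated)

    quad = np.full(n, "none", dtype=object)
    idx_diff = np.flatnonzero(is_diff)
    if idx_diff.size:
        quad[idx_diff] = rng.choice(QUADRANTS, size=idx_diff.size,
                                    p=config.normalized_quadrant_mix)
    meth_dir = np.where(np.isin(quad, ("hyper-up", "hyper-down")), "gain",
                        np.where(np.isin(quad, ("hypo-up", "hypo-down")), "loss", "none"))
    expr_dir = np.where(np.isin(quad, ("hyper-up", "hypo-up")), "up",
                        np.where(np.isin(quad, ("hyper-down", "hypo-down")), "down", "none"))

    # peak placement: segment by weight, midpoint uniform within the segment
    peak_start = np.full(n, -1, dtype=np.int64)
    peak_end = np.full(n, -1, dtype=np.int64)
    width = config.peak_width_windows * config.window_size
    seg_bias = np.asarray(config.peak_segment_bias, dtype=float)
    for i in np.flatnonzero(is_meth):
        seg_len = np.array([utr5[i], cds[i], utr3[i]], dtype=float)
        w = seg_bias * (seg_len > 0)
        w = w / w.sum() if w.sum() > 0 else (seg_len > 0) / (seg_len > 0).sum()
        seg = rng.choice(3, p=w)
        seg_off = (0, utr5[i], utr5[i] + cds[i])[seg]
        mid = seg_off + rng.integers(0, max(1, (utr5[i], cds[i], utr3[i])[seg]))
        s = int(np.clip(mid - width // 2, 0, max(0, total[i] - width)))
        peak_start[i] = s
        peak_end[i] = min(s + width, total[i])

    if config.embed_hypoxia_signature and n >= len(_SIGNATURE_SYMBOLS):
        # give the signature symbols to planted "up" genes first so the
        # simulated cohort carries a positive hypoxia enrichment signal
        up_idx = list(np.flatnonzero(expr_dir == "up"))
        other_idx = [i for i in range(n) if expr_dir[i] != "up"]
        chosen = (up_idx + other_idx)[: len(_SIGNATURE_SYMBOLS)]
        for sym, i in zip(_SIGNATURE_SYMBOLS, chosen):
            gids[i] = sym

    hyper_up = (quad == "hyper-up")
    kd_up = np.where(hyper_up,
                     rng.random(n) < config.kd_hit_rate,
                     rng.random(n) < config.kd_background_rate)

    transcripts = pd.DataFrame({
        "transcript_id": tids, "gene_id": gids,
        "utr5_len": utr5, "cds_len": cds, "utr3_len": utr3, "total_len": total,
    })
    truth = pd.DataFrame({
        "transcript_id": tids, "gene_id": gids,
        "is_methylated": is_meth,
        "peak_start": pd.array(np.where(is_meth, peak_start, pd.NA), dtype="Int64"),
        "peak_end": pd.array(np.where(is_meth, peak_end, pd.NA), dtype="Int64"),
        "meth_direction": meth_dir,
        "expr_direction": expr_dir,
        "true_quadrant": np.where(quad == "none", "none", quad),
        "kd_up": kd_up,
    })
    return transcripts, truth


def _tile_all_windows(total_len: np.ndarray, window_size: int):
    """Vectorized half-open tiling of every transcript.

    Returns ``(t_idx, starts, ends)`` where the union of ``[start, end)``
    windows for each transcript covers exactly ``[0, total_len)``.
    """
    n_win = np.maximum(1, np.ceil(total_len / window_size)).astype(np.int64)
    t_idx = np.repeat(np.arange(total_len.size), n_win)
    offsets = np.concatenate(([0], np.cumsum(n_win)))[:-1]
    within = np.arange(t_idx.size) - np.repeat(offsets, n_win)
    starts = within * window_size
    ends = np.minimum(starts + window_size, total_len[t_idx])
    return t_idx, starts, ends


def simulate_merip_windows(
    truth: pd.DataFrame,
    transcripts: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate IP/input window counts for every sample of the paired cohort.

    Windows tile each transcript end-to-end (0-based half-open).  Input
    rates track expression only (transcript abundance, patient size factor,
    planted expression shift); IP rates are the input rates multiplied by
    ``peak_enrichment`` inside the planted peak, and additionally by
    ``diff_shift`` in the condition where the transcript gains methylation
    (condition B for "gain", condition A for "loss").

    Overdispersion enters through a gamma abundance factor per
    transcript x sample, shared by that sample's paired IP and input
    libraries; window counts are Poisson given the factor and marginally
    negative binomial with the configured dispersion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(transcripts)
    total = transcripts["total_len"].to_numpy()
    t_idx, w_start, w_end = _tile_all_windows(total, config.window_size)

    rel = rng.lognormal(0.0, 0.5, n)                       # transcript abundance
    sf = rng.lognormal(0.0, 0.15, config.n_patients)       # paired size factor
    samples, conditions, patients = _sample_names(config.n_patients)

    expr_mult_b = np.ones(n)
    expr_mult_b[truth["expr_direction"].to_numpy() == "up"] = config.expr_fc
    expr_mult_b[truth["expr_direction"].to_numpy() == "down"] = 1.0 / config.expr_fc

    ps = truth["peak_start"].fillna(-1).to_numpy(dtype=np.int64)
    pe = truth["peak_end"].fillna(-1).to_numpy(dtype=np.int64)
    in_peak = (w_start < pe[t_idx]) & (w_end > ps[t_idx]) & (ps[t_idx] >= 0)

    meth_dir = truth["meth_direction"].to_numpy()
    gain = meth_dir[t_idx] == "gain"
    loss = meth_dir[t_idx] == "loss"

    w_weight = (w_end - w_start) / total[t_idx]
    base = config.seq_depth * rel[t_idx] * w_weight

    # gamma abundance factor (mean 1, variance = dispersion) per
    # transcript x sample, shared by the paired IP and input fractions
    shape = 1.0 / config.dispersion
    frames = []
    for j, (sample, cond, pat) in enumerate(zip(samples, conditions, patients)):
        g = rng.gamma(shape, config.dispersion, n)[t_idx]
        expr_mult = expr_mult_b[t_idx] if cond == "B" else 1.0
        input_mu = base * sf[pat] * expr_mult * g
        peak_mult = np.where(in_peak, config.peak_enrichment, 1.0)
        shift_here = in_peak & (gain if cond == "B" else loss)
        peak_mult = peak_mult * np.where(shift_here, config.diff_shift, 1.0)
        ip_mu = input_mu * peak_mult
        frames.append(pd.DataFrame({
            "transcript_id": transcripts["transcript_id"].to_numpy()[t_idx],
            "window_start": w_start,
            "window_end": w_end,
            "sample": sample,
            "condition": cond,
            "ip_count": rng.poisson(ip_mu),
            "input_count": rng.poisson(input_mu),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["transcript_id", "window_start", "sample"], kind="stable"
    ).reset_index(drop=True)


def simulate_expression(
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene x sample negative-binomial count matrix for the paired cohort.

    Genes with a planted "up"/"down" direction have their mean multiplied /
    divided by ``expr_fc`` in the tumor-like condition (B).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = len(truth)
    rel = rng.lognormal(0.0, 0.5, n)
    sf = rng.lognormal(0.0, 0.15, config.n_patients)
    samples, conditions, patients = _sample_names(config.n_patients)

    mult_b = np.ones(n)
    mult_b[truth["expr_direction"].to_numpy() == "up"] = config.expr_fc
    mult_b[truth["expr_direction"].to_numpy() == "down"] = 1.0 / config.expr_fc

    data = {}
    for sample, cond, pat in zip(samples, conditions, patients):
        mu = config.seq_depth * rel * sf[pat] * (mult_b if cond == "B" else 1.0)
        data[sample] = _nb_counts(rng, mu, config.dispersion)
    return pd.DataFrame(data, index=pd.Index(truth["gene_id"], name="gene_id"))


def simulate_knockdown_expression(
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Second expression contrast emulating a reader-knockdown experiment.

    Genes flagged ``kd_up`` in the truth (mostly the planted hyper-up
    genes, whose transcripts the knocked-down reader would stabilise) gain
    a ``kd_fc``-fold mean increase in the knockdown samples.  Columns are
    ``KD_r*`` (condition B) and ``CTRL_r*`` (condition A).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    n = len(truth)
    rel = rng.lognormal(0.0, 0.5, n)
    kd_mult = np.where(truth["kd_up"].to_numpy(), config.kd_fc, 1.0)
    data = {}
    for r in range(n_replicates):
        data[f"CTRL_r{r + 1}"] = _nb_counts(rng, config.seq_depth * rel, config.dispersion)
    for r in range(n_replicates):
        data[f"KD_r{r + 1}"] = _nb_counts(rng, config.seq_depth * rel * kd_mult, config.dispersion)
    return pd.DataFrame(data, index=pd.Index(truth["gene_id"], name="gene_id"))


def simulate_decay_series(
    k: float,
    timepoints: Sequence[float],
    cv: float = 0.0,
    seed: int = 0,
) -> DecaySeries:
    """One transcription-shutoff time course: N_t = e^(-k t) with CV noise.

    The abundance at t = 0 is the normalisation reference and is exactly 1;
    later points get multiplicative mean-zero noise of coefficient of
    variation ``cv`` (clipped away from zero so abundances stay positive).
    """
    if k <= 0:
        raise ValueError("decay rate k must be > 0")
    t = np.asarray(list(timepoints), dtype=float)
    if t.size == 0:
        raise ValueError("timepoints must be non-empty")
    if not np.any(t == 0):
        raise ValueError("timepoints must include 0 (the normalisation reference)")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    clean = np.exp(-k * t)
    noise = np.clip(1.0 + rng.normal(0.0, cv, t.size), 1e-6, None) if cv > 0 else np.ones(t.size)
    noise[t == 0] = 1.0
    return DecaySeries(timepoints=t, abundances=clean * noise)


def simulate_calibration_run(
    true_ratio: float,
    standards: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
    slopes: tuple[float, float] = (2.0, 1.0),
    intercepts: tuple[float, float] = (0.05, 0.02),
    total_adenosine: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Synthetic LC-MS/MS run: standard curves plus one unknown sample.

    Per nucleoside channel (m6A, transition 282->150; A, transition
    268->136) instrument responses are linear in concentration with
    additive Gaussian noise of SD ``noise``.  The unknown sample is built
    from concentrations consistent with ``true_ratio`` = [m6A]/[A].

    Returns ``(standard_table, sample_responses)`` with the standard table
    in long format (``channel, concentration, response``).
    """
    std = np.asarray(list(standards), dtype=float)
    if std.size < 2:
        raise ValueError("need at least 2 calibration standards")
    if np.any(std <= 0) or np.unique(std).size != std.size:
        raise ValueError("standards must be strictly positive and distinct")
    if not 0.0 < true_ratio < 1.0:
        raise ValueError("true_ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    conc_a = float(np.median(std)) if total_adenosine is None else float(total_adenosine)
    conc = {CHANNEL_M6A: true_ratio * conc_a, CHANNEL_A: conc_a}

    rows = []
    responses: dict[str, float] = {}
    for channel, slope, icpt in zip((CHANNEL_M6A, CHANNEL_A), slopes, intercepts):
        resp = slope * std + icpt
        if noise > 0:
            resp = resp + rng.normal(0.0, noise, std.size)
        for c, r in zip(std, resp):
            rows.append({"channel": channel, "concentration": c, "response": r})
        r_sample = slope * conc[channel] + icpt
        if noise > 0:
            r_sample += rng.normal(0.0, noise)
        responses[channel] = float(r_sample)
    return pd.DataFrame(rows), responses
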