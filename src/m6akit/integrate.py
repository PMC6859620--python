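"""Joint methylation x expression integration.

Combines differential m6A peaks with expression fold changes into
per-gene quadrant calls (hyper-up, hyper-down, hypo-up, hypo-down),
summarises quadrant percentages per patient and cohort-wide, applies the
high-frequency rule (genes hyper-up in at least ``min_share`` patients),
and performs the two-list fold-change intersection screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import DifferentialPeak

log = logging.getLogger(__name__)

QUADRANTS = ("hyper-up", "hyper-down", "hypo-up", "hypo-down")
CPM_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ExpressionChange:
    gene_id: str
    log2_fc: float
    direction: str  # up | down | none


@dataclass(frozen=True)
class QuadrantCall:
    gene_id: str
    meth_direction: str  # hyper | hypo
    expr_direction: str  # up | down

    @property
    def quadrant(self) -> str:
        return f"{self.meth_direction}-{self.expr_direction}"


@dataclass(frozen=True)
class QuadrantSummary:
    """Per-patient counts/percentages and cohort-level averages.

    ``cohort_mean_pct`` is the unweighted mean of per-patient percentages
    (patients with zero calls excluded); ``pooled_pct`` pools all calls.
    """

    per_patient: pd.DataFrame           # index patient, columns quadrant counts
    per_patient_pct: pd.DataFrame
    cohort_mean_pct: dict[str, float]
    pooled_pct: dict[str, float]
    n_calls: int


@dataclass(frozen=True)
class ScreenResult:
    list_a: frozenset
    list_b: frozenset
    candidates: tuple
    n_list_a: int = field(init=False)
    n_list_b: int = field(init=False)
    n_candidates: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_list_a", len(self.list_a))
        object.__setattr__(self, "n_list_b", len(self.list_b))
        object.__setattr__(self, "n_candidates", len(self.candidates))


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation of a gene x sample count matrix."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0 for CPM normalisation")
    return counts / lib * 1e6


def expression_changes(
    expression: pd.DataFrame,
    conditions: Mapping[str, str],
    min_abs_log2fc: float = 0.0,
) -> list[ExpressionChange]:
    """Per-gene log2 fold change of condition B over A on the CPM scale.

    Counts are CPM-normalised per sample; the fold change is taken on the
    per-condition mean CPM with a pseudocount of 0.5 CPM.  A direction is
    assigned when |log2FC| exceeds ``min_abs_log2fc``.
    """
    cols_a = [s for s in expression.columns if conditions.get(s) == "A"]
    cols_b = [s for s in expression.columns if conditions.get(s) == "B"]
    if not cols_a or not cols_b:
        raise ValueError("need at least one sample per condition")
    norm = cpm(expression)
    mean_a = norm[cols_a].mean(axis=1) + CPM_PSEUDOCOUNT
    mean_b = norm[cols_b].mean(axis=1) + CPM_PSEUDOCOUNT
    lfc = np.log2(mean_b / mean_a)
    out = []
    for gene, v in lfc.items():
        if abs(v) > min_abs_log2fc:
            direction = "up" if v > 0 else "down"
        else:
            direction = "none"
        out.append(ExpressionChange(gene_id=str(gene), log2_fc=float(v), direction=direction))
    return out


def _best_peak_per_gene(
    diff_peaks: Sequence[DifferentialPeak],
    transcripts: pd.DataFrame,
) -> dict[str, DifferentialPeak]:
    """Directional peak with the strongest evidence per gene.

    Ties: smallest q, then largest |log2 fold change|, then leftmost start.
    """
    gene_of = dict(zip(transcripts["transcript_id"], transcripts["gene_id"]))
    best: dict[str, DifferentialPeak] = {}
    for dp in diff_peaks:
        if dp.direction == "none":
            continue
        gene = gene_of.get(dp.peak.transcript_id)
        if gene is None:
            raise KeyError(f"no gene mapping for transcript {dp.peak.transcript_id!r}")
        cur = best.get(gene)
        key = (dp.q_value, -abs(dp.log2_meth_fc), dp.peak.start)
        if cur is None or key < (cur.q_value, -abs(cur.log2_meth_fc), cur.peak.start):
            best[gene] = dp
    return best


def classify_quadrants(
    diff_peaks: Sequence[DifferentialPeak],
    expr_changes: Sequence[ExpressionChange],
    transcripts: pd.DataFrame,
) -> list[QuadrantCall]:
    """One quadrant call per gene with both a directional peak and change.

    Genes lacking a direction on either axis are excluded.  A gene with
    several directional peaks takes the one with the smallest q-value
    (ties: largest |log2 methylation fold change|, then leftmost start).
    """
    best = _best_peak_per_gene(diff_peaks, transcripts)
    expr_dir = {c.gene_id: c.direction for c in expr_changes}
    calls = []
    for gene in sorted(best):
        edir = expr_dir.get(gene, "none")
        if edir == "none":
            continue
        mdir = "hyper" if best[gene].direction == "hyper" else "hypo"
        calls.append(QuadrantCall(gene_id=gene, meth_direction=mdir, expr_direction=edir))
    return calls


def quadrant_percentages(
    calls_by_patient: Mapping[str, Sequence[QuadrantCall]],
) -> QuadrantSummary:
    """Quadrant counts and percentages per patient plus cohort averages.

    The cohort mean is the unweighted mean of per-patient percentages;
    patients with zero calls are excluded from it (and logged).  A pooled
    percentage over all calls is reported alongside.
    """
    counts = {}
    for patient, calls in calls_by_patient.items():
        row = dict.fromkeys(QUADRANTS, 0)
        for c in calls:
            row[c.quadrant] += 1
        counts[patient] = row
    per_patient = pd.DataFrame.from_dict(counts, orient="index")[list(QUADRANTS)]
    per_patient.index.name = "patient"
    totals = per_patient.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("no quadrant calls in any patient")
    empty = totals[totals == 0].index.tolist()
    if empty:
        log.warning("patients with zero quadrant calls excluded from cohort mean: %s", empty)
    nonzero = per_patient.loc[totals > 0]
    pct = nonzero.div(nonzero.sum(axis=1), axis=0) * 100.0
    pooled = per_patient.sum(axis=0)
    pooled_pct = (pooled / pooled.sum() * 100.0).to_dict()
    return QuadrantSummary(
        per_patient=per_patient,
        per_patient_pct=pct,
        cohort_mean_pct=pct.mean(axis=0).to_dict(),
        pooled_pct={k: float(v) for k, v in pooled_pct.items()},
        n_calls=int(per_patient.to_numpy().sum()),
    )


def high_frequency_hyperup(
    hyperup_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    min_share: int = 3,
) -> list[str]:
    """Genes hyper-up in at least ``min_share`` patients.

    Sorted by descending number of supporting patients, then gene id.
    """
    if min_share < 1:
        raise ValueError("min_share must be >= 1")
    sets = (list(hyperup_sets.values())
            if isinstance(hyperup_sets, Mapping) else list(hyperup_sets))
    if len(sets) < min_share:
        raise ValueError(
            f"need at least min_share={min_share} patients, got {len(sets)}"
        )
    share: dict[str, int] = {}
    for s in sets:
        for g in set(s):
            share[g] = share.get(g, 0) + 1
    hits = [g for g, n in share.items() if n >= min_share]
    return sorted(hits, key=lambda g: (-share[g], g))


def screen_candidates(
    list_a_changes: pd.DataFrame,
    list_b_changes: pd.DataFrame,
    fc_threshold: float = 2.0,
) -> ScreenResult:
    """Two-list fold-change intersection screen.

    ``list_a_changes`` needs columns ``gene_id, fold_change`` (e.g. the
    knockdown contrast); ``list_b_changes`` additionally needs a boolean
    ``hyper`` column (e.g. hypermethylated genes under hypoxia).  List A
    keeps genes with fold change > ``fc_threshold``; list B keeps
    hyper-flagged genes with fold change > ``fc_threshold``; candidates
    are the sorted intersection.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    a = frozenset(
        list_a_changes.loc[list_a_changes["fold_change"] > fc_threshold, "gene_id"]
    )
    mask = list_b_changes["hyper"].astype(bool) & (
        list_b_changes["fold_change"] > fc_threshold
    )
    b = frozenset(list_b_changes.loc[mask, "gene_id"])
    return ScreenResult(list_a=a, list_b=b, candidates=tuple(sorted(a & b)))
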