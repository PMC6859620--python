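"""Readers and writers for the pipeline's plain-text formats.

TSV tables with fixed column orders, BED6 for peaks (transcript-space,
0-based half-open, score = -10*log10(p) capped at 1000), GMT for gene
sets, and JSON with sorted keys and floats at 6 significant digits so
reruns are byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gsea import GeneSet
from .peaks import DifferentialPeak, Peak

TRANSCRIPT_COLUMNS = ["transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len", "total_len"]
WINDOW_COLUMNS = ["transcript_id", "window_start", "window_end", "sample",
                  "condition", "ip_count", "input_count"]
TRUTH_COLUMNS = ["transcript_id", "gene_id", "is_methylated", "peak_start", "peak_end",
                 "meth_direction", "expr_direction", "true_quadrant", "kd_up"]
DIFFPEAK_COLUMNS = ["transcript_id", "start", "end", "enrichment", "peak_p",
                    "log2_meth_fc", "p_value", "q_value", "direction",
                    "ip_a", "input_a", "ip_b", "input_b"]


def _write_tsv(df: pd.DataFrame, path, columns: Sequence[str]) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(columns))


def write_transcripts(transcripts: pd.DataFrame, path) -> None:
    _write_tsv(transcripts, path, TRANSCRIPT_COLUMNS)


def read_transcripts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})


def write_windows(windows: pd.DataFrame, path) -> None:
    _write_tsv(windows, path, WINDOW_COLUMNS)


def read_windows(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "sample": str,
                                              "condition": str})


def write_truth(truth: pd.DataFrame, path) -> None:
    _write_tsv(truth, path, TRUTH_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    for col in ("peak_start", "peak_end"):
        df[col] = df[col].astype("Int64")
    return df


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_decay(series_table: pd.DataFrame, path) -> None:
    _write_tsv(series_table, path, ["series_id", "time_h", "rel_abundance"])


def read_decay(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"series_id": str})


def write_calibration(standards: pd.DataFrame, path) -> None:
    _write_tsv(standards, path, ["channel", "concentration", "response"])


def read_calibration(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"channel": str})


def _bed_score(p: float) -> int:
    if p <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(p))))


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    """BED6 peaks: chrom = transcript id, score = -10*log10(p) capped at 1000."""
    with open(path, "w") as fh:
        for pk in peaks:
            fh.write(f"{pk.transcript_id}\t{pk.start}\t{pk.end}\t"
                     f"peak\t{_bed_score(pk.p_value)}\t+\n")


def read_peaks_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score, _strand = line.rstrip("\n").split("\t")
            p = 10.0 ** (-float(score) / 10.0)
            peaks.append(Peak(transcript_id=chrom, start=int(start), end=int(end),
                              enrichment=1.0, p_value=p))
    return peaks


def write_differential_peaks(diff_peaks: Iterable[DifferentialPeak], path) -> None:
    rows = [{
        "transcript_id": dp.peak.transcript_id,
        "start": dp.peak.start, "end": dp.peak.end,
        "enrichment": dp.peak.enrichment, "peak_p": dp.peak.p_value,
        "log2_meth_fc": dp.log2_meth_fc, "p_value": dp.p_value,
        "q_value": dp.q_value, "direction": dp.direction,
        "ip_a": dp.ip_a, "input_a": dp.input_a, "ip_b": dp.ip_b, "input_b": dp.input_b,
    } for dp in diff_peaks]
    pd.DataFrame(rows, columns=DIFFPEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_differential_peaks(path) -> list[DifferentialPeak]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "direction": str})
    out = []
    for row in df.itertuples(index=False):
        pk = Peak(transcript_id=row.transcript_id, start=int(row.start),
                  end=int(row.end), enrichment=float(row.enrichment),
                  p_value=float(row.peak_p))
        out.append(DifferentialPeak(
            peak=pk, log2_meth_fc=float(row.log2_meth_fc),
            p_value=float(row.p_value), q_value=float(row.q_value),
            direction=row.direction, ip_a=int(row.ip_a), input_a=int(row.input_a),
            ip_b=int(row.ip_b), input_b=int(row.input_b),
        ))
    return out


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets.append(GeneSet(name=name, members=frozenset(g for g in genes if g)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}") if math.isfinite(obj) else repr(obj)
    if isinstance(obj, Mapping):
        return {str(k): _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_round_floats(v, sig) for v in seq]
    return obj


def write_json(obj, path) -> None:
    """JSON with sorted keys and floats at 6 significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
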