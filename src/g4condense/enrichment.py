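"""Promoter-level ChIP signal enrichment by tangent-slope-1 thresholding.

The procedure mirrors the geometric cutoff used for super-enhancer-style
calling: promoter signals are ranked in ascending order, both axes are
min-max scaled to [0, 1], and the threshold is placed where a tangent line
of slope 1 touches the convex scaled curve.  Promoters beyond that point
carry disproportionate signal.  A second pass converts retained promoter
counts into binding densities (each promoter's share of all above-threshold
signal) and applies the same geometric rule to the density curve to call
the enriched set.

Coordinates are 0-based half-open (BED convention) throughout.  Promoter
windows span -1000 to +500 bp around the TSS, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    EmptyResultError,
    InvalidInputError,
    NoTangentError,
)

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500


@dataclass
class PromoterWindow:
    """A promoter interval around a TSS (half-open, 0-based)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    clipped: bool = False


@dataclass
class ReadCountTable:
    """Per-promoter aggregated signal with optional ground-truth labels."""

    promoter_ids: list
    counts: np.ndarray
    truth_labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.promoter_ids) != self.counts.size:
            raise InvalidInputError("ids and counts differ in length")
        if len(set(self.promoter_ids)) != len(self.promoter_ids):
            raise InvalidInputError("promoter ids must be unique")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise InvalidInputError("counts must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"promoter_id": self.promoter_ids,
                           "count": self.counts})
        if self.truth_labels is not None:
            df["truth_label"] = self.truth_labels
        return df


@dataclass
class ScaledRankCurve:
    """Ascending rank curve with both axes min-max scaled to [0, 1]."""

    x: np.ndarray              # scaled rank
    y: np.ndarray              # scaled signal, non-decreasing
    order: list                # curve position -> promoter_id
    raw: np.ndarray            # unscaled signal in curve order


@dataclass
class EnrichmentResult:
    """Output of the two-pass enrichment call."""

    raw_threshold: float            # unscaled read-count cutoff (first pass)
    scaled_threshold: float         # the same cutoff on the scaled y axis
    cutoff_index: int               # tangent position on the density curve
    densities: dict                 # promoter_id -> binding density fraction
    enriched: set
    n_retained: int
    mean_density_enriched: float = np.nan
    mean_density_other: float = np.nan
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def make_promoter_windows(tss_records) -> list[PromoterWindow]:
    """Build -1000/+500 promoter windows from (chrom, tss, strand, gene_id).

    Plus-strand windows are [tss-1000, tss+500); minus-strand windows mirror
    to [tss-500, tss+1000). Windows truncated at coordinate 0 are flagged.
    """
    windows = []
    for chrom, tss, strand, gene_id in tss_records:
        if tss < 0:
            raise InvalidInputError(f"negative TSS for {gene_id}")
        if strand == "+":
            start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
        elif strand == "-":
            start, end = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
        else:
            raise InvalidInputError(f"unknown strand {strand!r} for {gene_id}")
        clipped = start < 0
        windows.append(PromoterWindow(chrom=chrom, start=max(start, 0),
                                      end=end, strand=strand,
                                      gene_id=gene_id, clipped=clipped))
    return windows


def count_signal_in_windows(windows, features) -> ReadCountTable:
    """Sum feature values over each promoter window (>= 1 bp overlap).

    ``features`` are (chrom, start, end, value) half-open intervals. A
    feature overlapping two windows contributes its full value to both.
    """
    feats = {}
    for chrom, start, end, value in features:
        if end <= start:
            raise InvalidInputError(f"malformed interval {chrom}:{start}-{end}")
        feats.setdefault(chrom, []).append((start, end, float(value)))
    for rows in feats.values():
        rows.sort()
    ids, counts = [], []
    for w in windows:
        total = 0.0
        for fs, fe, v in feats.get(w.chrom, ()):
            if fs >= w.end:
                break
            if fe > w.start:
                total += v
        ids.append(w.gene_id)
        counts.append(total)
    return ReadCountTable(promoter_ids=ids, counts=np.array(counts))


def scaled_rank_curve(table: ReadCountTable) -> ScaledRankCurve:
    """Sort ascending and min-max scale both axes to [0, 1].

    Ties in counts are broken by promoter id so the curve is reproducible.
    """
    n = len(table.promoter_ids)
    if n < 3:
        raise InvalidInputError("need >= 3 records for a rank curve")
    order = sorted(range(n), key=lambda i: (table.counts[i],
                                            str(table.promoter_ids[i])))
    raw = table.counts[order]
    lo, hi = raw[0], raw[-1]
    if hi == lo:
        raise DegenerateCurveError("all counts identical; curve is flat")
    x = np.arange(n, dtype=float) / (n - 1)
    y = (raw - lo) / (hi - lo)
    return ScaledRankCurve(x=x, y=y,
                           order=[table.promoter_ids[i] for i in order],
                           raw=raw)


def tangent_threshold(curve: ScaledRankCurve) -> tuple[int, float]:
    """Locate the slope-1 tangent point of the scaled rank curve.

    For a convex non-decreasing curve the tangent point is the sample
    minimising ``y_i - x_i`` (the discrete slope crosses 1 there); ties go
    to the larger index. Returns ``(cutoff_index, raw_threshold)`` where
    ``raw_threshold`` is the unscaled signal at the cutoff.

    Raises :class:`NoTangentError` when no interior slope-1 crossing exists
    (linear or concave curves).
    """
    d = curve.y - curve.x
    if np.any(np.diff(curve.y) < -1e-12):
        raise InvalidInputError("curve y must be non-decreasing")
    # argmin with ties broken toward the larger index
    dmin = d.min()
    idx = int(np.flatnonzero(d <= dmin + 1e-15)[-1])
    if np.allclose(d, d[0], atol=1e-12):
        raise NoTangentError("curve is linear: tangent point is not unique")
    if idx in (0, d.size - 1):
        raise NoTangentError(
            "minimum of y - x sits on the curve boundary (index "
            f"{idx}); no interior slope-1 tangent exists — the curve is "
            "likely concave")
    return idx, float(curve.raw[idx])


def binding_density(table: ReadCountTable, raw_threshold: float) -> dict:
    """Each retained promoter's share of all above-threshold signal.

    A promoter is retained when its count exceeds ``raw_threshold``;
    densities are ``count_i / sum(retained counts)`` and sum to 1.
    """
    if not np.isfinite(raw_threshold):
        raise InvalidInputError("threshold must be finite")
    mask = table.counts > raw_threshold
    if not mask.any():
        raise EmptyResultError("no promoter above threshold")
    total = table.counts[mask].sum()
    return {pid: float(c) / total
            for pid, c, m in zip(table.promoter_ids, table.counts, mask) if m}


def classify_enriched(densities: dict, raw_threshold: float = np.nan,
                      scaled_threshold: float = np.nan,
                      n_retained: int | None = None) -> EnrichmentResult:
    """Call enriched promoters from the density rank curve.

    The density values are ranked and scaled exactly like the read counts,
    the slope-1 tangent is located, and promoters beyond the tangent point
    are designated enriched. The enriched set is an upper set of the density
    ordering by construction.
    """
    if len(densities) < 3:
        raise InvalidInputError("need >= 3 retained promoters")
    ids = list(densities)
    table = ReadCountTable(promoter_ids=ids,
                           counts=np.array([densities[i] for i in ids]))
    curve = scaled_rank_curve(table)
    cutoff_index, _ = tangent_threshold(curve)
    enriched = set(curve.order[cutoff_index + 1:])
    dens = np.array([densities[i] for i in ids])
    emask = np.array([i in enriched for i in ids])
    return EnrichmentResult(
        raw_threshold=raw_threshold,
        scaled_threshold=scaled_threshold,
        cutoff_index=cutoff_index,
        densities=dict(densities),
        enriched=enriched,
        n_retained=n_retained if n_retained is not None else len(densities),
        mean_density_enriched=float(dens[emask].mean()) if emask.any() else np.nan,
        mean_density_other=float(dens[~emask].mean()) if (~emask).any() else np.nan,
    )


def call_enriched_promoters(table: ReadCountTable) -> EnrichmentResult:
    """Full two-pass pipeline: rank counts, place the slope-1 tangent
    threshold, compute binding densities over retained promoters, then call
    the enriched set from the density rank curve."""
    curve = scaled_rank_curve(table)
    idx, raw_threshold = tangent_threshold(curve)
    densities = binding_density(table, raw_threshold)
    return classify_enriched(densities, raw_threshold=raw_threshold,
                             scaled_threshold=float(curve.y[idx]),
                             n_retained=len(densities))


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_tss_bed(path) -> list[tuple]:
    """Read TSS records from BED6 (start is the TSS for +, end-1 for -)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    records = []
    for row in df.itertuples(index=False):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), str(row[3])
        strand = row[5] if len(row) > 5 else "+"
        tss = start if strand == "+" else end - 1
        records.append((chrom, tss, strand, name))
    return records


def read_signal_tsv(path) -> list[tuple]:
    """Read (chrom, start, end, value) features from a bedGraph-like TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(r[0], int(r[1]), int(r[2]), float(r[3]))
            for r in df.itertuples(index=False)]


def write_enrichment(result: EnrichmentResult, table: ReadCountTable,
                     tsv_path, json_path=None):
    """Write per-promoter TSV and an optional JSON summary."""
    import json

    rows = []
    for pid, c in zip(table.promoter_ids, table.counts):
        rows.append({"promoter_id": pid, "count": c,
                     "density": result.densities.get(pid, np.nan),
                     "enriched": pid in result.enriched})
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({
                "raw_threshold": result.raw_threshold,
                "scaled_threshold": result.scaled_threshold,
                "cutoff_index": result.cutoff_index,
                "n_retained": result.n_retained,
                "n_enriched": len(result.enriched),
                "mean_density_enriched": result.mean_density_enriched,
                "mean_density_other": result.mean_density_other,
            }, fh, indent=2)
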