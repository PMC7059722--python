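"""Promoter-centric interaction dynamics over a differentiation time course.

Enhancers are annotated as regions supported by both ATAC-seq and
H3K27ac ChIP-seq peaks; a promoter bait's intra-chromosomal calls within
200 kb that land on an annotated enhancer are enhancer-promoter (E-P)
interactions and every remaining intra-chromosomal call is "other"
(inter-chromosomal calls belong to neither class).  Interaction PPKM and
signal FPKM trajectories over the five timepoints (0, 2, 6, 12, 24 h)
are mean-normalized per region, and cohort-mean trajectories are
correlated with expression via Pearson r and its t-statistic p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval, overlaps
from .quant import normalize_timecourse

__all__ = [
    "AnnotatedEnhancer",
    "annotate_enhancers",
    "classify_interactions",
    "timecourse_table",
    "correlate_expression",
    "TIMEPOINTS_H",
]

TIMEPOINTS_H = (0, 2, 6, 12, 24)


@dataclass
class AnnotatedEnhancer:
    """A putative enhancer: an ATAC footprint overlapped by H3K27ac."""

    interval: GenomicInterval
    atac_id: str
    k27ac_ids: list[str] = field(default_factory=list)


def annotate_enhancers(
    atac_peaks: list[GenomicInterval], k27ac_peaks: list[GenomicInterval]
) -> list[AnnotatedEnhancer]:
    """Emit every ATAC peak that overlaps >= 1 H3K27ac peak.

    The ATAC peak is taken as the enhancer footprint; overlap of the same
    region with both marks is required (nearby-but-disjoint peaks do not
    qualify).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for k in k27ac_peaks:
        by_chrom.setdefault(k.chrom, []).append(k)
    out = []
    for i, a in enumerate(atac_peaks):
        hits = [k for k in by_chrom.get(a.chrom, ()) if overlaps(a, k)]
        if hits:
            out.append(
                AnnotatedEnhancer(
                    interval=a,
                    atac_id=a.name or f"atac{i}",
                    k27ac_ids=[k.name or "" for k in hits],
                )
            )
    return out


def classify_interactions(
    calls: pd.DataFrame,
    bait_midpoints: dict[str, int],
    enhancers: list[AnnotatedEnhancer],
    max_dist: int = 200_000,
) -> pd.DataFrame:
    """Split a promoter bait's calls into E-P and other interactions.

    E-P: intra-chromosomal, bait-to-partner midpoint distance <=
    *max_dist*, and the partner region overlaps an annotated enhancer.
    Other: every remaining intra-chromosomal call.  Inter-chromosomal
    calls are dropped from both classes.
    """
    intra = calls[~calls["is_trans"]].copy()
    enh_by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in enhancers:
        enh_by_chrom.setdefault(e.interval.chrom, []).append(e.interval)

    cats = []
    for _, row in intra.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        dist = abs(mid - bait_midpoints[row["bait_id"]])
        partner = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        on_enh = any(overlaps(partner, e) for e in enh_by_chrom.get(partner.chrom, ()))
        cats.append("E-P" if (dist <= max_dist and on_enh) else "other")
    intra["category"] = cats
    return intra


def timecourse_table(
    values: pd.DataFrame,
    timepoints: tuple = TIMEPOINTS_H,
) -> dict[str, pd.DataFrame]:
    """Normalize per-region trajectories and aggregate cohort statistics.

    *values* has a (region, signal) MultiIndex or ``region``/``signal``
    columns plus one column per timepoint.  Returns ``raw``,
    ``normalized`` (each row divided by its own mean), and per-signal
    cohort ``mean`` and ``sem`` tables over timepoints.
    """
    df = values.copy()
    if not isinstance(df.index, pd.MultiIndex):
        df = df.set_index(["region", "signal"])
    missing = [t for t in timepoints if t not in df.columns]
    if missing:
        raise ValueError(f"missing timepoints: {missing}")
    df = df[list(timepoints)]

    norm = df.apply(lambda row: pd.Series(normalize_timecourse(row.to_numpy()),
                                          index=df.columns), axis=1)
    grouped = norm.groupby(level="signal")
    mean = grouped.mean()
    sem = grouped.sem(ddof=1).fillna(0.0)
    return {"raw": df, "normalized": norm, "mean": mean, "sem": sem}


def correlate_expression(
    interaction: np.ndarray | list,
    expression: np.ndarray | list,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Pearson r between two trajectories and its Student-t p-value.

    p is computed from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df;
    *alternative* is 'two-sided' or 'greater' (upper tail).
    """
    a = np.asarray(interaction, dtype=float)
    b = np.asarray(expression, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("trajectories must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 timepoints")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance trajectory")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        if alternative == "two-sided":
            p = 2 * float(stats.t.sf(abs(t), n - 2))
        elif alternative == "greater":
            p = float(stats.t.sf(t, n - 2))
        else:
            raise ValueError("alternative must be 'two-sided' or 'greater'")
    return r, p
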