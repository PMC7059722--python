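"""Depth- and length-normalized signal metrics.

PPKM (PETs per kilobase of bait region per million mapped read pairs) and
FPKM share one formula, implemented with the single 10^9 factor exactly as
defined (not via separate /1000 and /10^6 roundings):

    value = count * 1e9 / (region_size_bp * library_total)

Cross-timepoint comparison divides each region's trajectory by its own
mean over all timepoints (NPPKM / NFPKM), so every normalized trajectory
has mean 1.
"""

from __future__ import annotations

import numpy as np

from .genome import warn

__all__ = ["ppkm", "fpkm", "normalize_timecourse"]


def ppkm(pets: int, size_bp: int, total_pairs: int) -> float:
    """PETs per kilobase of bait region per million mapped read pairs.

    ``total_pairs`` is the deduplicated pair count after MAPQ filtering,
    so cross-sample comparisons use a consistent denominator.
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be > 0")
    if total_pairs <= 0:
        raise ValueError("total_pairs must be > 0")
    if pets < 0:
        raise ValueError("pets must be >= 0")
    return pets * 1e9 / (size_bp * total_pairs)


def fpkm(fragments: int, size_bp: int, total_mapped: int) -> float:
    """Fragments per kilobase per million mapped reads (same formula)."""
    return ppkm(fragments, size_bp, total_mapped)


def normalize_timecourse(values) -> np.ndarray:
    """Divide a trajectory by its own mean; the result has mean 1.

    All-zero input returns all zeros with a warning rather than NaN.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.any(arr < 0):
        raise ValueError("values must be non-negative")
    m = arr.mean()
    if m == 0.0:
        warn("normalize_timecourse: all-zero trajectory left as zeros")
        return arr.copy()
    return arr / m
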