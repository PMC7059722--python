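"""Read-pair preprocessing and pair-end-tag (PET) extraction.

A PET is one proximity-ligation contact with exactly one end inside a
captured bait region.  Read pairs arrive as a table with one row per pair
(columns ``read_id, chrom1, pos1, mapq1, chrom2, pos2, mapq2``); replicate
experiments are concatenated before processing.  The pipeline is:
junction trimming (pre-alignment) -> MAPQ filter -> PCR de-duplication ->
bait assignment, with self-ligations (both ends in the same bait) and
off-target pairs (no end in any bait) counted and set aside.  Off-target
pairs are not discarded outright: they are the raw material for the
random-background sampling in :mod:`capture3c.calling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomicInterval, Genome, merge_intervals

__all__ = [
    "PAIR_COLUMNS",
    "ReadPairRecord",
    "BaitRegion",
    "SummaryCounts",
    "trim_at_junction",
    "filter_mapq",
    "dedup",
    "extract_pets",
    "baits_from_bed",
    "read_pairs_tsv",
    "write_pairs_tsv",
]

PAIR_COLUMNS = ["read_id", "chrom1", "pos1", "mapq1", "chrom2", "pos2", "mapq2"]

_DNA = set("ACGTN")


@dataclass(frozen=True)
class ReadPairRecord:
    """One aligned read pair (both ends mapped)."""

    read_id: str
    chrom1: str
    pos1: int
    mapq1: int
    chrom2: str
    pos2: int
    mapq2: int

    def as_row(self) -> tuple:
        return (self.read_id, self.chrom1, self.pos1, self.mapq1,
                self.chrom2, self.pos2, self.mapq2)


def pairs_frame(records) -> pd.DataFrame:
    """Build the canonical pair table from ReadPairRecord objects."""
    return pd.DataFrame([r.as_row() for r in records], columns=PAIR_COLUMNS)


@dataclass
class BaitRegion:
    """A merged sgRNA-peak interval used as an interaction anchor.

    ``L`` is the peak size in bp; all sgRNA peaks targeting one CRE are
    merged into a single interval before PET extraction.
    """

    bait_id: str
    interval: GenomicInterval
    sgrna_ids: list[str] = field(default_factory=list)
    bait_class: str = "enhancer"  # enhancer | promoter | LCR-HS
    se_id: str | None = None

    @property
    def L(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class SummaryCounts:
    """Per-category pair counts from PET extraction.

    ``n_input = n_pet + n_bait_bait + n_self_ligation + n_off_target``:
    a pair whose two ends fall in two different baits emits two PETs but
    is counted once under ``n_bait_bait``.
    """

    n_input: int = 0
    n_pet: int = 0
    n_bait_bait: int = 0
    n_self_ligation: int = 0
    n_off_target: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input_pairs": self.n_input,
            "pet_pairs": self.n_pet,
            "bait_bait_pairs": self.n_bait_bait,
            "self_ligation_pairs": self.n_self_ligation,
            "off_target_pairs": self.n_off_target,
        }


def trim_at_junction(seq: str, site: str = "GATC", min_len: int = 20) -> str | None:
    """Trim a raw read at the first ligation-junction occurrence of *site*.

    DpnII sticky-end ligation reconstitutes GATC at the junction, so the
    5' fragment up to (and excluding) the first site is the part that maps
    to the anchoring fragment.  Returns the input unchanged when the site
    is absent, and ``None`` when the trimmed fragment is shorter than
    *min_len*.
    """
    if not site:
        raise ValueError("site must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in read: {sorted(bad)}")
    idx = seq.find(site)
    trimmed = seq if idx < 0 else seq[:idx]
    return trimmed if len(trimmed) >= min_len else None


def filter_mapq(pairs: pd.DataFrame, min_mapq: int = 30) -> pd.DataFrame:
    """Keep pairs with both ends at MAPQ >= *min_mapq*."""
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    keep = (pairs["mapq1"] >= min_mapq) & (pairs["mapq2"] >= min_mapq)
    return pairs.loc[keep].reset_index(drop=True)


def dedup(pairs: pd.DataFrame) -> pd.DataFrame:
    """Remove PCR duplicates.

    The duplicate key is the unordered coordinate tuple
    ``{(chrom1, pos1), (chrom2, pos2)}``; the first occurrence wins.
    """
    c1 = pairs["chrom1"].to_numpy(dtype=object)
    p1 = pairs["pos1"].to_numpy()
    c2 = pairs["chrom2"].to_numpy(dtype=object)
    p2 = pairs["pos2"].to_numpy()
    # canonical orientation: lexicographically smaller (chrom, pos) first
    swap = (c2 < c1) | ((c1 == c2) & (p2 < p1))
    lo_c = np.where(swap, c2, c1)
    lo_p = np.where(swap, p2, p1)
    hi_c = np.where(swap, c1, c2)
    hi_p = np.where(swap, p1, p2)
    key = pd.DataFrame({"lc": lo_c, "lp": lo_p, "hc": hi_c, "hp": hi_p})
    keep = ~key.duplicated(keep="first")
    return pairs.loc[keep.to_numpy()].reset_index(drop=True)


class _BaitIndex:
    """Point-in-bait lookup over non-overlapping bait intervals."""

    def __init__(self, baits: list[BaitRegion]):
        self.baits = baits
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in {b.chrom for b in baits}:
            sub = sorted(
                (i for i, b in enumerate(baits) if b.chrom == chrom),
                key=lambda i: baits[i].interval.start,
            )
            starts = np.array([baits[i].interval.start for i in sub])
            ends = np.array([baits[i].interval.end for i in sub])
            if np.any(starts[1:] < ends[:-1]):
                k = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    "overlapping bait peaks with distinct ids on "
                    f"{chrom} ({baits[sub[k]].bait_id} vs {baits[sub[k + 1]].bait_id}); "
                    "merge sgRNA peaks per bait first"
                )
            self._by_chrom[chrom] = (starts, ends, np.array(sub))

    def assign(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Return the bait index containing each point, or -1."""
        out = np.full(len(pos), -1, dtype=np.int64)
        for chrom, (starts, ends, idx) in self._by_chrom.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            p = pos[mask]
            slot = np.searchsorted(starts, p, side="right") - 1
            inside = (slot >= 0) & (p < ends[np.clip(slot, 0, len(ends) - 1)])
            res = np.where(inside, idx[np.clip(slot, 0, len(idx) - 1)], -1)
            out[mask] = res
        return out


def extract_pets(
    pairs: pd.DataFrame,
    baits: list[BaitRegion],
    genome: Genome | None = None,
) -> tuple[pd.DataFrame, SummaryCounts]:
    """Assign deduplicated read pairs to baits and emit PETs.

    Per pair: both ends in the same bait peak -> self-ligation (discarded,
    counted); exactly one end in a bait -> one PET for that bait; ends in
    two different baits -> one PET per bait, flagged ``bait_bait`` so global
    totals are not double-counted; no end in any bait -> off-target.

    Returns the PET table (columns ``bait_id, bait_chrom, bait_pos, chrom,
    pos, distance, is_trans, bait_bait, pair_index``) and category counts.
    """
    index = _BaitIndex(baits)
    c1 = pairs["chrom1"].to_numpy(dtype=object)
    p1 = pairs["pos1"].to_numpy()
    c2 = pairs["chrom2"].to_numpy(dtype=object)
    p2 = pairs["pos2"].to_numpy()
    if genome is not None:
        for c, p in ((c1, p1), (c2, p2)):
            for chrom in np.unique(c.astype(str)):
                if chrom not in genome:
                    raise ValueError(f"chromosome {chrom!r} not in genome")
                pc = p[c == chrom]
                if pc.size and (pc.min() < 0 or pc.max() >= genome[chrom]):
                    raise ValueError(f"position outside {chrom} bounds")

    b1 = index.assign(c1, p1)
    b2 = index.assign(c2, p2)

    counts = SummaryCounts(n_input=len(pairs))
    self_mask = (b1 >= 0) & (b1 == b2)
    both_mask = (b1 >= 0) & (b2 >= 0) & (b1 != b2)
    one_mask = (b1 >= 0) ^ (b2 >= 0)
    off_mask = (b1 < 0) & (b2 < 0)
    counts.n_self_ligation = int(self_mask.sum())
    counts.n_bait_bait = int(both_mask.sum())
    counts.n_pet = int(one_mask.sum())
    counts.n_off_target = int(off_mask.sum())

    rows: list[tuple] = []

    def emit(pair_idx: np.ndarray, bait_idx: np.ndarray, end_is_1: np.ndarray, flag: bool):
        for k in range(len(pair_idx)):
            i = pair_idx[k]
            b = baits[bait_idx[k]]
            if end_is_1[k]:
                bc, bp, oc, op = c1[i], p1[i], c2[i], p2[i]
            else:
                bc, bp, oc, op = c2[i], p2[i], c1[i], p1[i]
            trans = oc != bc
            dist = np.nan if trans else abs(int(op) - b.midpoint)
            rows.append((b.bait_id, bc, int(bp), oc, int(op), dist, trans, flag, int(i)))

    idx_one = np.nonzero(one_mask)[0]
    emit(idx_one, np.where(b1[idx_one] >= 0, b1[idx_one], b2[idx_one]), b1[idx_one] >= 0, False)
    idx_both = np.nonzero(both_mask)[0]
    emit(idx_both, b1[idx_both], np.ones(len(idx_both), bool), True)
    emit(idx_both, b2[idx_both], np.zeros(len(idx_both), bool), True)

    pets = pd.DataFrame(
        rows,
        columns=[
            "bait_id", "bait_chrom", "bait_pos", "chrom", "pos",
            "distance", "is_trans", "bait_bait", "pair_index",
        ],
    )
    if len(pets):
        pets = pets.sort_values(["bait_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return pets, counts


def baits_from_bed(
    peaks: list[GenomicInterval],
    bait_class: str = "enhancer",
    se_of: dict[str, str] | None = None,
) -> list[BaitRegion]:
    """Group sgRNA peaks by their name column and merge each group.

    Peaks sharing a name are sgRNAs targeting the same CRE; their merged
    span becomes the bait peak with size ``L``.
    """
    groups: dict[str, list[GenomicInterval]] = {}
    for i, p in enumerate(peaks):
        groups.setdefault(p.name or f"bait{i}", []).append(p)
    baits = []
    for bait_id in sorted(groups):
        merged = merge_intervals(groups[bait_id], name=bait_id)
        if len(merged) > 1:
            # disjoint sgRNA peaks for one bait: span them (single-peak invariant)
            merged = [
                GenomicInterval(
                    merged[0].chrom, merged[0].start, merged[-1].end, name=bait_id
                )
            ]
        baits.append(
            BaitRegion(
                bait_id=bait_id,
                interval=merged[0],
                sgrna_ids=[p.name or "" for p in groups[bait_id]],
                bait_class=bait_class,
                se_id=(se_of or {}).get(bait_id),
            )
        )
    return baits


def read_pairs_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pair columns {missing}")
    return df[PAIR_COLUMNS]


def write_pairs_tsv(pairs: pd.DataFrame, path: str) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)
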