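"""Significant long-range interaction calling per bait.

For a bait of peak size L, every chromosome is tiled into bins of size L
and the bait's PET partner ends are counted per bin.  Each tested pair
(bait, partner bin) — and each pair of distinct baits — gets its own
random background: 10,000 placements of two intervals with the same sizes
and the same intra-chromosomal midpoint distance, drawn uniformly over
the genome while avoiding every bait region, counting global contacts
(the full deduplicated, self-ligation-free read-pair set, off-target
pairs included) with one end in each placed interval.  The sampled counts
are fitted as a negative binomial and an FDR-prior-scaled Bayes factor is
computed for the observed count; BF >= 20 marks a significant call.

Placement counting is vectorized: for a placement start s the two
intervals are A = [s, s+L1) and B = [s+off, s+off+L2), so each contact
contributes a contiguous range of s values for which it is counted; the
per-placement count is then two searchsorted calls over the sorted range
endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .background import (
    DEFAULT_BF_THRESHOLD,
    DEFAULT_PRIOR_RATIO,
    InteractionCall,
    NegBinBackground,
    bayes_factor,
    fit_negbin,
)
from .genome import Genome, GenomicInterval
from .pets import BaitRegion

__all__ = [
    "BinGrid",
    "CallConfig",
    "ContactIndex",
    "InteractionModel",
    "InteractionResults",
    "bin_genome",
    "count_pets",
    "sample_background",
    "call_interactions",
    "capture_rate",
    "merge_se_baits",
]


@dataclass
class BinGrid:
    """Per-chromosome tiling of the genome at one bait's peak size."""

    bin_size: int
    genome: Genome
    bait_id: str | None = None

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome[chrom] // self.bin_size)

    def bin_interval(self, chrom: str, k: int) -> GenomicInterval:
        start = k * self.bin_size
        end = min(start + self.bin_size, self.genome[chrom])
        return GenomicInterval(chrom, start, end)

    def bin_of(self, chrom: str, pos: int) -> int:
        if chrom not in self.genome:
            raise ValueError(f"chromosome {chrom!r} not in genome")
        if not (0 <= pos < self.genome[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.genome)


def bin_genome(genome: Genome, bin_size: int, bait_id: str | None = None) -> BinGrid:
    """Tile every chromosome into ceil(M / bin_size) half-open bins."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    return BinGrid(bin_size=int(bin_size), genome=genome, bait_id=bait_id)


def count_pets(pets: pd.DataFrame, grid: BinGrid) -> dict[tuple[str, int], int]:
    """Tally each PET's partner end into exactly one bin."""
    out: dict[tuple[str, int], int] = {}
    if len(pets) == 0:
        return out
    for chrom, sub in pets.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if chrom not in grid.genome:
            raise ValueError(f"partner chromosome {chrom!r} not in genome")
        if pos.min() < 0 or pos.max() >= grid.genome[chrom]:
            raise ValueError(f"partner position outside {chrom}")
        bins, counts = np.unique(pos // grid.bin_size, return_counts=True)
        for b, c in zip(bins, counts):
            out[(chrom, int(b))] = int(c)
    return out


class ContactIndex:
    """Genome-wide contact set indexed for fast background counting.

    Built from the full deduplicated, MAPQ-filtered read-pair table with
    self-ligations removed (off-target pairs included: with placements
    avoiding every bait region, only contacts with both ends outside
    baits can ever be counted, so bait-anchored PETs alone would give an
    identically zero background).
    """

    def __init__(self, pairs: pd.DataFrame, genome: Genome):
        self.genome = genome
        self.n_contacts = len(pairs)
        self._intra: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._trans: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

        c1 = pairs["chrom1"].to_numpy(dtype=object)
        c2 = pairs["chrom2"].to_numpy(dtype=object)
        p1 = pairs["pos1"].to_numpy(dtype=np.int64)
        p2 = pairs["pos2"].to_numpy(dtype=np.int64)

        cis = c1 == c2
        for chrom in np.unique(c1[cis].astype(str)):
            m = cis & (c1 == chrom)
            lo = np.minimum(p1[m], p2[m])
            hi = np.maximum(p1[m], p2[m])
            gap = hi - lo
            order = np.argsort(gap, kind="stable")
            self._intra[chrom] = (gap[order], lo[order], hi[order])

        tr = ~cis
        if tr.any():
            a_first = c1[tr] < c2[tr]
            cmin = np.where(a_first, c1[tr], c2[tr])
            cmax = np.where(a_first, c2[tr], c1[tr])
            pmin = np.where(a_first, p1[tr], p2[tr])
            pmax = np.where(a_first, p2[tr], p1[tr])
            df = pd.DataFrame({"cmin": cmin, "cmax": cmax, "pmin": pmin, "pmax": pmax})
            for (ca, cb), sub in df.groupby(["cmin", "cmax"], sort=False):
                u = sub["pmin"].to_numpy()
                v = sub["pmax"].to_numpy()
                order = np.argsort(u, kind="stable")
                self._trans[(ca, cb)] = (u[order], v[order])

    # -- intra-chromosomal -------------------------------------------------
    def count_pair_runs(self, chrom: str, off: int, L1: int, L2: int,
                        starts: np.ndarray) -> np.ndarray:
        """Counts of contacts with one end in [s, s+L1) and the other in
        [s+off, s+off+L2), for each placement start s in *starts*."""
        if chrom not in self._intra:
            return np.zeros(len(starts), dtype=np.int64)
        gap, lo, hi = self._intra[chrom]
        a_parts, b_parts = [], []
        # contact (lo, hi): lo in A, hi in B  => s in [max(lo-L1+1, hi-off-L2+1), min(lo, hi-off)]
        i0, i1 = np.searchsorted(gap, [off - L1 + 1, off + L2 - 1 + 1])
        if i1 > i0:
            a = np.maximum(lo[i0:i1] - L1 + 1, hi[i0:i1] - off - L2 + 1)
            b = np.minimum(lo[i0:i1], hi[i0:i1] - off)
            ok = a <= b
            a_parts.append(a[ok]); b_parts.append(b[ok])
        # contact (lo, hi): hi in A, lo in B  => s in [max(hi-L1+1, lo-off-L2+1), min(hi, lo-off)]
        j0, j1 = np.searchsorted(gap, [max(0, -off - L2 + 1), max(-1, -off + L1 - 1) + 1])
        if j1 > j0:
            a = np.maximum(hi[j0:j1] - L1 + 1, lo[j0:j1] - off - L2 + 1)
            b = np.minimum(hi[j0:j1], lo[j0:j1] - off)
            ok = a <= b
            a_parts.append(a[ok]); b_parts.append(b[ok])
        if not a_parts:
            return np.zeros(len(starts), dtype=np.int64)
        a_all = np.concatenate(a_parts)
        b_all = np.concatenate(b_parts)
        # sweep over the (few) sorted placement starts rather than sorting
        # the (many) candidate ranges: each contact covers a contiguous run
        # of placements, accumulated with bincount + cumsum
        order = np.argsort(starts, kind="stable")
        s_sorted = starts[order]
        n = len(s_sorted)
        first = np.searchsorted(s_sorted, a_all, side="left")
        last = np.searchsorted(s_sorted, b_all, side="right")
        keep = first < last
        delta = np.bincount(first[keep], minlength=n + 1) - np.bincount(
            last[keep], minlength=n + 1
        )
        counts_sorted = np.cumsum(delta[:n])
        out = np.empty(n, dtype=np.int64)
        out[order] = counts_sorted
        return out

    # -- inter-chromosomal -------------------------------------------------
    def count_trans(self, chrom_a: str, sa: int, La: int,
                    chrom_b: str, sb: int, Lb: int) -> int:
        """Contacts with one end in [sa, sa+La) on chrom_a and the other in
        [sb, sb+Lb) on chrom_b."""
        if chrom_a == chrom_b:
            raise ValueError("count_trans requires distinct chromosomes")
        if chrom_a > chrom_b:
            chrom_a, sa, La, chrom_b, sb, Lb = chrom_b, sb, Lb, chrom_a, sa, La
        key = (chrom_a, chrom_b)
        if key not in self._trans:
            return 0
        u, v = self._trans[key]
        i0, i1 = np.searchsorted(u, [sa, sa + La])
        if i1 <= i0:
            return 0
        w = v[i0:i1]
        return int(np.count_nonzero((w >= sb) & (w < sb + Lb)))


class _BaitMask:
    """Merged bait intervals per chromosome, for placement rejection."""

    def __init__(self, baits: list[BaitRegion]):
        from .genome import merge_intervals

        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        ivs = [b.interval for b in baits]
        if ivs:
            for iv in merge_intervals(ivs):
                s, e = self.by_chrom.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
        self.by_chrom = {
            c: (np.array(s), np.array(e)) for c, (s, e) in self.by_chrom.items()
        }

    def overlaps_any(self, chrom: str, start: np.ndarray, length: int) -> np.ndarray:
        if chrom not in self.by_chrom:
            return np.zeros(len(start), dtype=bool)
        s, e = self.by_chrom[chrom]
        # [start, start+length) overlaps some [s_i, e_i)
        return np.searchsorted(s, start + length, side="left") > np.searchsorted(
            e, start, side="right"
        )


@dataclass
class CallConfig:
    """Tunables for interaction calling (defaults follow the method)."""

    n_samples: int = 10_000
    prior_ratio: float = DEFAULT_PRIOR_RATIO
    bf_threshold: float = DEFAULT_BF_THRESHOLD
    min_count: int = 2
    seed: int = 1234
    n_min_accepted: int = 1_000
    max_attempt_factor: int = 50
    store_counts: bool = False
    use_empirical: bool = False  # use the sampled counts' CDF instead of the fit

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_min_accepted <= 0:
            raise ValueError("n_samples and n_min_accepted must be positive")
        if self.prior_ratio <= 0:
            raise ValueError("prior_ratio must be > 0")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def _sample_intra_counts(
    contacts: ContactIndex,
    mask: _BaitMask,
    L1: int,
    L2: int,
    d: int,
    n: int,
    rng: np.random.Generator,
    n_min: int,
    max_attempt_factor: int,
) -> np.ndarray:
    """Sampled null counts for an intra-chromosomal pair at midpoint distance d."""
    genome = contacts.genome
    off = d + (L1 - L2) // 2  # B start relative to A start, midpoint distance d
    chroms, smin, widths = [], [], []
    for chrom, M in genome.items():
        lo = max(0, -off)
        hi = M - max(L1, off + L2)
        w = hi - lo + 1
        if w > 0:
            chroms.append(chrom)
            smin.append(lo)
            widths.append(w)
    if not chroms:
        raise ValueError(
            f"no chromosome can host a region pair of sizes {L1},{L2} at distance {d}"
        )
    weights = np.array(widths, dtype=float)
    probs = weights / weights.sum()
    smin = np.array(smin)
    widths_arr = np.array(widths)

    acc_chrom: list[np.ndarray] = []
    acc_start: list[np.ndarray] = []
    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n
    while accepted < n and attempts < max_attempts:
        batch = min(max(2 * (n - accepted), 1024), max_attempts - attempts)
        ci = rng.choice(len(chroms), size=batch, p=probs)
        s = smin[ci] + (rng.random(batch) * widths_arr[ci]).astype(np.int64)
        bad = np.zeros(batch, dtype=bool)
        for k, chrom in enumerate(chroms):
            m = ci == k
            if not m.any():
                continue
            sa = s[m]
            bad_k = mask.overlaps_any(chrom, sa, L1) | mask.overlaps_any(
                chrom, sa + off, L2
            )
            bad[m] = bad_k
        ok = ~bad
        acc_chrom.append(ci[ok])
        acc_start.append(s[ok])
        accepted += int(ok.sum())
        attempts += batch
    if accepted < n_min:
        raise ValueError(
            f"only {accepted} background placements accepted after {attempts} "
            "attempts; use a larger genome or fewer/smaller bait regions"
        )
    ci = np.concatenate(acc_chrom)[:n] if accepted >= n else np.concatenate(acc_chrom)
    s = np.concatenate(acc_start)[:n] if accepted >= n else np.concatenate(acc_start)

    counts = np.zeros(len(s), dtype=np.int64)
    for k, chrom in enumerate(chroms):
        m = ci == k
        if m.any():
            counts[m] = contacts.count_pair_runs(chrom, off, L1, L2, s[m])
    return counts


def _sample_trans_counts(
    contacts: ContactIndex,
    mask: _BaitMask,
    L1: int,
    L2: int,
    n: int,
    rng: np.random.Generator,
    n_min: int,
    max_attempt_factor: int,
) -> np.ndarray:
    """Sampled null counts for an inter-chromosomal pair: two independent
    intervals on two distinct random chromosomes."""
    genome = contacts.genome
    names = list(genome)
    if len(names) < 2:
        raise ValueError("inter-chromosomal background needs >= 2 chromosomes")

    def placements(L: int) -> tuple[list[str], np.ndarray, np.ndarray]:
        ch, w = [], []
        for chrom, M in genome.items():
            if M - L + 1 > 0:
                ch.append(chrom)
                w.append(M - L + 1)
        return ch, np.array(w, dtype=float), np.array(w)

    ch1, w1, width1 = placements(L1)
    ch2, w2, width2 = placements(L2)
    if not ch1 or not ch2:
        raise ValueError("no chromosome long enough for the region sizes")
    p1 = np.cumsum(w1 / w1.sum())
    p2 = np.cumsum(w2 / w2.sum())

    acc_i: list[np.ndarray] = []
    acc_j: list[np.ndarray] = []
    acc_sa: list[np.ndarray] = []
    acc_sb: list[np.ndarray] = []
    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n
    while accepted < n and attempts < max_attempts:
        batch = min(max(2 * (n - accepted), 1024), max_attempts - attempts)
        i = np.searchsorted(p1, rng.random(batch))
        j = np.searchsorted(p2, rng.random(batch))
        sa = (rng.random(batch) * width1[i]).astype(np.int64)
        sb = (rng.random(batch) * width2[j]).astype(np.int64)
        bad = np.asarray(ch1, dtype=object)[i] == np.asarray(ch2, dtype=object)[j]
        for k, chrom in enumerate(ch1):
            m = i == k
            if m.any():
                bad[m] |= mask.overlaps_any(chrom, sa[m], L1)
        for k, chrom in enumerate(ch2):
            m = j == k
            if m.any():
                bad[m] |= mask.overlaps_any(chrom, sb[m], L2)
        ok = ~bad
        acc_i.append(i[ok]); acc_j.append(j[ok])
        acc_sa.append(sa[ok]); acc_sb.append(sb[ok])
        accepted += int(ok.sum())
        attempts += batch
    if accepted < n_min:
        raise ValueError(
            f"only {accepted} inter-chromosomal placements accepted; "
            "use a larger genome or fewer baits"
        )
    i = np.concatenate(acc_i)[:n]
    j = np.concatenate(acc_j)[:n]
    sa = np.concatenate(acc_sa)[:n]
    sb = np.concatenate(acc_sb)[:n]
    out = np.fromiter(
        (contacts.count_trans(ch1[a], int(x), L1, ch2[b], int(y), L2)
         for a, b, x, y in zip(i, j, sa, sb)),
        dtype=np.int64, count=len(i),
    )
    return out


def sample_background(
    region_i: GenomicInterval,
    region_j: GenomicInterval,
    contacts: ContactIndex,
    baits: list[BaitRegion],
    genome: Genome,
    n: int = 10_000,
    seed: int | np.random.Generator = 1234,
    n_min: int = 1_000,
    max_attempt_factor: int = 50,
    store_counts: bool = False,
) -> NegBinBackground:
    """Random paired-sampling background for one region pair.

    Places two intervals with sizes L(i) and L(j) — at the same
    intra-chromosomal midpoint distance when the pair is cis, as two
    independent intervals on distinct chromosomes when trans — *n* times,
    avoiding every bait region, and fits the per-placement contact counts
    as a negative binomial.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _BaitMask(baits)
    L1, L2 = region_i.length, region_j.length
    if region_i.chrom == region_j.chrom:
        d = abs(region_j.midpoint - region_i.midpoint)
        counts = _sample_intra_counts(
            contacts, mask, L1, L2, d, n, rng, n_min, max_attempt_factor
        )
        prov = {"distance": d, "trans": False}
    else:
        counts = _sample_trans_counts(
            contacts, mask, L1, L2, n, rng, n_min, max_attempt_factor
        )
        prov = {"trans": True}
    return fit_negbin(counts, store_counts=store_counts, **prov)


def _call_one(
    x: int,
    bg: NegBinBackground,
    config: CallConfig,
) -> tuple[float, float, float, bool]:
    if config.use_empirical and bg.counts is not None:
        bg = replace(bg, kind="empirical")
    return bayes_factor(x, bg, config.prior_ratio, config.bf_threshold)


def call_interactions(
    bait: BaitRegion,
    pets: pd.DataFrame,
    contacts: ContactIndex,
    baits: list[BaitRegion],
    genome: Genome,
    config: CallConfig | None = None,
    bait_index: int = 0,
) -> list[InteractionCall]:
    """Test every partner bin (and every other bait) with enough PETs.

    Bin-level tests treat the bin as a pseudo-bait of size = bin size;
    bins overlapping the bait peak itself are skipped (a PET partner can
    never fall there).  Bait-bait pairs are tested with the two peak
    sizes.  Each tested pair draws its own seeded background so results
    do not depend on iteration order.
    """
    config = config or CallConfig()
    config.validate()
    grid = bin_genome(genome, bait.L, bait_id=bait.bait_id)
    own = pets[pets["bait_id"] == bait.bait_id]
    bin_counts = count_pets(own[~own["bait_bait"]], grid)

    calls: list[InteractionCall] = []
    chrom_order = {c: k for k, c in enumerate(genome)}

    for (chrom, k), x in sorted(bin_counts.items(), key=lambda t: (chrom_order[t[0][0]], t[0][1])):
        if x < config.min_count:
            continue
        bin_iv = grid.bin_interval(chrom, k)
        if chrom == bait.chrom and bin_iv.start < bait.interval.end and bait.interval.start < bin_iv.end:
            continue  # overlaps the bait peak itself
        # disjointness of the sampled pair requires |off| outside (-L2, L1)
        if chrom == bait.chrom:
            d = abs(bin_iv.midpoint - bait.midpoint)
            off = d + (bait.L - bin_iv.length) // 2
            if -bin_iv.length < off < bait.L:
                continue
        rng = np.random.default_rng([config.seed, bait_index, chrom_order[chrom], k])
        bg = sample_background(
            bait.interval, bin_iv, contacts, baits, genome,
            n=config.n_samples, seed=rng, n_min=config.n_min_accepted,
            max_attempt_factor=config.max_attempt_factor,
            store_counts=config.store_counts or config.use_empirical,
        )
        p_lt, p_ge, bf, sig = _call_one(x, bg, config)
        calls.append(
            InteractionCall(
                bait_id=bait.bait_id, chrom=chrom, start=bin_iv.start, end=bin_iv.end,
                x=int(x), p_lt=p_lt, p_ge=p_ge, bf=bf, significant=sig,
                high_confidence=bf >= DEFAULT_BF_THRESHOLD,
                is_trans=chrom != bait.chrom, partner_kind="bin",
                partner_id=f"{chrom}:{k}",
                degenerate_background=bg.degenerate,
                distance=(abs(bin_iv.midpoint - bait.midpoint)
                          if chrom == bait.chrom else math.nan),
                bg_mean=bg.mean,
            )
        )

    # bait-bait pairs
    other_ids = {b.bait_id: (j, b) for j, b in enumerate(baits) if b.bait_id != bait.bait_id}
    bb = own[own["bait_bait"]]
    if len(bb):
        partner = _partner_bait_ids(bb, baits)
        for pid, x in partner.value_counts().items():
            if pid not in other_ids or x < config.min_count:
                continue
            j, b2 = other_ids[pid]
            rng = np.random.default_rng([config.seed, bait_index, 10_000_019, j])
            bg = sample_background(
                bait.interval, b2.interval, contacts, baits, genome,
                n=config.n_samples, seed=rng, n_min=config.n_min_accepted,
                max_attempt_factor=config.max_attempt_factor,
                store_counts=config.store_counts or config.use_empirical,
            )
            p_lt, p_ge, bf, sig = _call_one(int(x), bg, config)
            trans = b2.chrom != bait.chrom
            calls.append(
                InteractionCall(
                    bait_id=bait.bait_id, chrom=b2.chrom,
                    start=b2.interval.start, end=b2.interval.end,
                    x=int(x), p_lt=p_lt, p_ge=p_ge, bf=bf, significant=sig,
                    high_confidence=bf >= DEFAULT_BF_THRESHOLD,
                    is_trans=trans, partner_kind="bait", partner_id=pid,
                    degenerate_background=bg.degenerate,
                    distance=(abs(b2.midpoint - bait.midpoint) if not trans else math.nan),
                    bg_mean=bg.mean,
                )
            )
    return calls


def _partner_bait_ids(bb_pets: pd.DataFrame, baits: list[BaitRegion]) -> pd.Series:
    """Map each bait-bait PET's partner end to the bait containing it."""
    from .pets import _BaitIndex

    idx = _BaitIndex(baits)
    assign = idx.assign(
        bb_pets["chrom"].to_numpy(dtype=object), bb_pets["pos"].to_numpy()
    )
    ids = np.array([b.bait_id for b in baits] + ["?"], dtype=object)
    return pd.Series(ids[assign], index=bb_pets.index)


def capture_rate(n_with_significant: int, n_targeted: int) -> float:
    """Percentage of targeted regions with >= 1 significant interaction,
    rounded to one decimal."""
    if n_targeted <= 0:
        raise ValueError("n_targeted must be > 0")
    if not (0 <= n_with_significant <= n_targeted):
        raise ValueError("need 0 <= n_with_significant <= n_targeted")
    return round(100.0 * n_with_significant / n_targeted, 1)


def merge_se_baits(
    baits: list[BaitRegion], pets: pd.DataFrame
) -> tuple[list[BaitRegion], pd.DataFrame]:
    """Merge constituent-enhancer baits of each SE into one SE-level bait.

    All tested PETs of an SE's member enhancers become the PETs of the SE,
    union-deduplicated by source pair; the SE interval spans its members.
    Baits without an SE id pass through unchanged.
    """
    out_baits: list[BaitRegion] = []
    pet_parts: list[pd.DataFrame] = []
    by_se: dict[str, list[BaitRegion]] = {}
    for b in baits:
        if b.se_id is None:
            out_baits.append(b)
            pet_parts.append(pets[pets["bait_id"] == b.bait_id])
        else:
            by_se.setdefault(b.se_id, []).append(b)
    for se_id in sorted(by_se):
        members = by_se[se_id]
        chroms = {b.chrom for b in members}
        if len(chroms) > 1:
            raise ValueError(f"SE {se_id} spans multiple chromosomes")
        start = min(b.interval.start for b in members)
        end = max(b.interval.end for b in members)
        iv = GenomicInterval(chroms.pop(), start, end, name=se_id)
        out_baits.append(BaitRegion(bait_id=se_id, interval=iv, bait_class="SE"))
        sub = pets[pets["bait_id"].isin([b.bait_id for b in members])]
        sub = sub.drop_duplicates(subset="pair_index", keep="first").copy()
        sub["bait_id"] = se_id
        pet_parts.append(sub)
    merged = pd.concat(pet_parts, ignore_index=True) if pet_parts else pets.iloc[0:0]
    return out_baits, merged


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class InteractionModel:
    """Bayes-factor interaction model for bait-anchored contact data.

    Parameters
    ----------
    pets : DataFrame
        PET table from :func:`capture3c.pets.extract_pets`.
    baits : list of BaitRegion
        The captured bait regions (merged sgRNA peaks).
    genome : Genome
    contacts : DataFrame or ContactIndex
        Full deduplicated, self-ligation-free read-pair set used for
        background sampling (off-target pairs included).
    config : CallConfig, optional
    """

    def __init__(self, pets, baits, genome, contacts, config: CallConfig | None = None):
        self.pets = pets
        self.baits = list(baits)
        self.genome = genome
        self.contacts = (
            contacts if isinstance(contacts, ContactIndex)
            else ContactIndex(contacts, genome)
        )
        self.config = config or CallConfig()
        self.config.validate()

    @classmethod
    def from_tables(cls, pets, baits, genome, contacts, **kwargs) -> "InteractionModel":
        return cls(pets, baits, genome, contacts, **kwargs)

    def fit(self, baits: list[BaitRegion] | None = None) -> "InteractionResults":
        """Call interactions for every bait; returns an InteractionResults."""
        targets = baits if baits is not None else self.baits
        all_calls: list[InteractionCall] = []
        for b in targets:
            i = next(k for k, bb in enumerate(self.baits) if bb.bait_id == b.bait_id)
            all_calls.extend(
                call_interactions(
                    b, self.pets, self.contacts, self.baits, self.genome,
                    self.config, bait_index=i,
                )
            )
        return InteractionResults(self, targets, all_calls)


class InteractionResults:
    """Fitted interaction calls with significance flags and summaries."""

    def __init__(self, model: InteractionModel, baits: list[BaitRegion],
                 calls: list[InteractionCall]):
        self.model = model
        self.baits = baits
        self.calls = pd.DataFrame([asdict(c) for c in calls]) if calls else pd.DataFrame(
            columns=[f.name for f in InteractionCall.__dataclass_fields__.values()]
        )

    @property
    def significant(self) -> pd.DataFrame:
        return self.calls[self.calls["significant"]]

    def capture_rate(self, bait_class: str | None = None) -> float:
        """Percent of (optionally class-filtered) baits with >= 1
        significant interaction."""
        baits = [
            b for b in self.baits if bait_class is None or b.bait_class == bait_class
        ]
        if not baits:
            raise ValueError(f"no baits of class {bait_class!r}")
        with_sig = set(self.significant["bait_id"])
        n_hit = sum(1 for b in baits if b.bait_id in with_sig)
        return capture_rate(n_hit, len(baits))

    def summary(self) -> str:
        n_tested = len(self.calls)
        n_sig = int(self.calls["significant"].sum()) if n_tested else 0
        lines = [
            "Interaction calling summary",
            "===========================",
            f"baits fitted:            {len(self.baits)}",
            f"pairs tested:            {n_tested}",
            f"significant (BF >= {self.model.config.bf_threshold:g}): {n_sig}",
            f"prior odds Pr(H1)/Pr(H0): {self.model.config.prior_ratio}",
            f"background samplings:    {self.model.config.n_samples} per pair",
            f"capture rate (all):      {self.capture_rate():.1f}%",
        ]
        per_bait = (
            self.significant.groupby("bait_id").size() if n_tested else pd.Series(dtype=int)
        )
        lines.append("")
        lines.append("significant calls per bait (top 10):")
        for bait_id, n in per_bait.sort_values(ascending=False).head(10).items():
            lines.append(f"  {bait_id:<20s} {n}")
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        cols = [
            "bait_id", "chrom", "start", "end", "x", "p_lt", "p_ge", "bf",
            "significant", "high_confidence", "is_trans", "partner_kind",
            "partner_id", "distance", "degenerate_background", "bg_mean",
        ]
        return self.calls[cols].copy()

    def to_tsv(self, path: str) -> None:
        df = self.to_table()
        df = df.replace([np.inf], "inf")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
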