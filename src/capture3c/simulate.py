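"""Seeded synthetic-data generators for every pipeline input.

The null model is a homogeneous proximity-ligation contact field: anchor
ends are placed uniformly over the genome (optionally modulated by a
block-wise gamma intensity field, giving negative-binomial bin counts),
and partner ends follow a shifted power-law distance decay

    P(d) proportional to (1 + d/d0)^(-gamma)

with a configurable trans-contact fraction.  Baits simply capture the
contacts that happen to anchor inside them, so observed bait-bin counts
and the randomly placed background pairs are draws from the same field —
the condition under which the Bayes-factor caller is calibrated.
Planted loops multiply the local contact intensity for chosen bait-bin
pairs by an enrichment fold and are recorded in a truth table.

Raw read pairs wrap the contact field with configurable artifact rates
(PCR duplicates, self-ligations, low-MAPQ ends, GATC ligation-junction
reads); the time-course generator couples E-P interaction strength to
monotone expression trajectories for activated and repressed promoters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, GenomicInterval, GeneModel
from .pets import PAIR_COLUMNS, BaitRegion

__all__ = [
    "SimConfig",
    "simulate_pets",
    "simulate_read_pairs",
    "simulate_timecourse",
    "simulate_genes",
    "simulate_peaks",
    "assign_ses",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic CAPTURE-3C experiment.

    Defaults reproduce the benchmark conditions used throughout the test
    suite: 50 baits of ~5 kb on a 3 x 4 Mb genome, with the contact-field
    size chosen so the baits capture on the order of 1e5 PETs in total.
    """

    seed: int = 1234
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000, "chr3": 4_000_000}
    )
    n_baits: int = 50
    bait_size_range: tuple[int, int] = (4_000, 6_000)
    bait_margin: int = 1_100_000  # keep baits away from chromosome ends
    min_bait_gap: int = 30_000
    decay_exponent: float = 1.2  # gamma of the shifted power law
    decay_scale: float = 5_000.0  # d0 in bp
    n_contacts: int = 2_400_000  # total field contacts (~1e5 bait PETs)
    f_trans: float = 0.05
    dispersion: float = 0.2  # block gamma variance; 0 = Poisson field
    block_size: int = 50_000
    # planted loops
    n_loops: int = 0
    loop_enrichment: float = 25.0  # fold over the local decay background
    loop_dist_range: tuple[int, int] = (50_000, 800_000)
    # read-pair artifacts
    duplicate_rate: float = 0.05
    self_ligation_rate: float = 0.05
    low_mapq_rate: float = 0.05
    junction_fraction: float = 0.2
    read_length: int = 75
    # time course
    timepoints: tuple = (0, 2, 6, 12, 24)
    coupling_slope: float = 1.0
    other_coupling: float = 0.3
    noise_sd: float = 0.1

    def validate(self) -> None:
        for name in ("f_trans", "duplicate_rate", "self_ligation_rate",
                     "low_mapq_rate", "junction_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.loop_enrichment < 1:
            raise ValueError("loop_enrichment must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def genome(self) -> Genome:
        return Genome(self.chrom_lengths)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _decay_inverse_cdf(u: np.ndarray, d0: float, g: float, dmax: float) -> np.ndarray:
    """Sample distances from the truncated shifted power law via inversion."""
    if abs(g - 1.0) < 1e-9:
        top = math.log1p(dmax / d0)
        return d0 * (np.exp(u * top) - 1.0)
    a = 1.0 - g
    top = (1.0 + dmax / d0) ** a - 1.0
    return d0 * ((1.0 + u * top) ** (1.0 / a) - 1.0)


def _decay_mass(d_lo: float, d_hi: float, d0: float, g: float, dmax: float) -> float:
    """Probability that a sampled distance falls in [d_lo, d_hi]."""
    def cdf_unnorm(x: float) -> float:
        if abs(g - 1.0) < 1e-9:
            return math.log1p(x / d0)
        a = 1.0 - g
        return ((1.0 + x / d0) ** a - 1.0) / a
    z = cdf_unnorm(dmax)
    return max(0.0, (cdf_unnorm(min(d_hi, dmax)) - cdf_unnorm(max(0.0, d_lo))) / z)


def place_baits(cfg: SimConfig, rng: np.random.Generator) -> list[BaitRegion]:
    """Non-overlapping bait peaks, margin away from chromosome ends."""
    genome = cfg.genome
    chroms = list(genome)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    baits: list[BaitRegion] = []
    tries = 0
    while len(baits) < cfg.n_baits:
        tries += 1
        if tries > 200 * cfg.n_baits:
            raise ValueError("could not place baits; genome too small")
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = int(rng.integers(cfg.bait_size_range[0], cfg.bait_size_range[1] + 1))
        lo, hi = cfg.bait_margin, genome[chrom] - cfg.bait_margin - L
        if hi <= lo:
            continue
        s = int(rng.integers(lo, hi))
        if any(s < e + cfg.min_bait_gap and x - cfg.min_bait_gap < s + L
               for x, e in placed[chrom]):
            continue
        placed[chrom].append((s, s + L))
        baits.append((chrom, s, s + L))
    baits.sort()
    return [
        BaitRegion(bait_id=f"bait{i:03d}",
                   interval=GenomicInterval(c, s, e, name=f"bait{i:03d}"))
        for i, (c, s, e) in enumerate(baits)
    ]


def _block_weights(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-chromosome block intensity multipliers (gamma mixing)."""
    out = {}
    for chrom, M in cfg.genome.items():
        n_blocks = -(-M // cfg.block_size)
        if cfg.dispersion > 0:
            shape = 1.0 / cfg.dispersion
            g = rng.gamma(shape, cfg.dispersion, size=n_blocks)
        else:
            g = np.ones(n_blocks)
        out[chrom] = g
    return out


def simulate_pets(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[BaitRegion]]:
    """Generate the contact field, plant loops, and return the truth table.

    Returns ``(pairs, truth, baits)``: *pairs* is a read-pair table in the
    canonical format (all MAPQ 60, no artifacts — see
    :func:`simulate_read_pairs` for those), *truth* lists every planted
    loop with its bait, target bin, distance and enrichment fold.
    Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    baits = place_baits(cfg, rng)

    blocks = _block_weights(cfg, rng)

    # anchor ends: chromosome by length, block by intensity, uniform inside
    n = cfg.n_contacts
    ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    a_pos = np.empty(n, dtype=np.int64)
    for k, chrom in enumerate(chroms):
        m = ci == k
        nk = int(m.sum())
        if nk == 0:
            continue
        g = blocks[chrom]
        bi = rng.choice(len(g), size=nk, p=g / g.sum())
        lo = bi * cfg.block_size
        width = np.minimum(cfg.block_size, genome[chrom] - lo)
        a_pos[m] = lo + (rng.random(nk) * width).astype(np.int64)

    # partner ends
    trans = rng.random(n) < cfg.f_trans
    b_ci = ci.copy()
    b_pos = np.empty(n, dtype=np.int64)

    nt = int(trans.sum())
    if nt:
        for k in range(len(chroms)):
            m = trans & (ci == k)
            nk = int(m.sum())
            if nk == 0:
                continue
            others = [j for j in range(len(chroms)) if j != k]
            w = lengths[others] / lengths[others].sum()
            pick = rng.choice(others, size=nk, p=w)
            b_ci[m] = pick
            b_pos[m] = (rng.random(nk) * lengths[pick]).astype(np.int64)

    cis = ~trans
    idx = np.nonzero(cis)[0]
    pending = idx
    for _ in range(200):
        if pending.size == 0:
            break
        M = lengths[ci[pending]]
        d = _decay_inverse_cdf(rng.random(pending.size), cfg.decay_scale,
                               cfg.decay_exponent, float(M.max()))
        sign = np.where(rng.random(pending.size) < 0.5, -1.0, 1.0)
        cand = a_pos[pending] + (sign * (d + 1.0)).astype(np.int64)
        ok = (cand >= 0) & (cand < M.astype(np.int64))
        b_pos[pending[ok]] = cand[ok]
        pending = pending[~ok]
    if pending.size:
        # pathological anchors: mirror into range
        b_pos[pending] = np.clip(a_pos[pending], 0, None)

    # planted loops
    truth_rows = []
    extra_parts = []
    if cfg.n_loops > 0:
        g = cfg.decay_exponent
        order = rng.permutation(len(baits))
        chrom_index = {c: i for i, c in enumerate(chroms)}
        for li in range(cfg.n_loops):
            b = baits[order[li % len(baits)]]
            L = b.L
            M = genome[b.chrom]
            grid_lo = (b.midpoint - cfg.loop_dist_range[1]) // L
            grid_hi = (b.midpoint + cfg.loop_dist_range[1]) // L
            for _try in range(200):
                k = int(rng.integers(max(0, grid_lo), min(M // L, grid_hi + 1)))
                t_start, t_end = k * L, min((k + 1) * L, M)
                d = abs((t_start + t_end) // 2 - b.midpoint)
                if not (cfg.loop_dist_range[0] <= d <= cfg.loop_dist_range[1]):
                    continue
                if any(bb.chrom == b.chrom and t_start < bb.interval.end
                       and bb.interval.start < t_end for bb in baits):
                    continue
                if any(r[0] == b.bait_id and r[1] == b.chrom and r[2] == t_start
                       for r in truth_rows):
                    continue
                break
            else:
                continue
            # local decay background intensity for this bait-bin pair
            lam = (
                cfg.n_contacts * (1 - cfg.f_trans) * L
                * _decay_mass(d - L / 2, d + L / 2, cfg.decay_scale, g, M) / 2.0
                * 2.0 / genome.total_bp
            )
            n_extra = int(rng.poisson(max(0.0, (cfg.loop_enrichment - 1.0) * lam)))
            if n_extra > 0:
                ea = rng.integers(b.interval.start, b.interval.end, size=n_extra)
                ep = rng.integers(t_start, t_end, size=n_extra)
                extra_parts.append(
                    (np.full(n_extra, chrom_index[b.chrom]), ea,
                     np.full(n_extra, chrom_index[b.chrom]), ep)
                )
            truth_rows.append(
                (b.bait_id, b.chrom, t_start, t_end, d, cfg.loop_enrichment, lam, n_extra)
            )

    if extra_parts:
        ci = np.concatenate([ci] + [p[0] for p in extra_parts])
        a_pos = np.concatenate([a_pos] + [p[1] for p in extra_parts])
        b_ci = np.concatenate([b_ci] + [p[2] for p in extra_parts])
        b_pos = np.concatenate([b_pos] + [p[3] for p in extra_parts])

    # randomize end order so unordered-pair handling is exercised
    total = len(ci)
    swap = rng.random(total) < 0.5
    c1 = np.where(swap, b_ci, ci)
    p1 = np.where(swap, b_pos, a_pos)
    c2 = np.where(swap, ci, b_ci)
    p2 = np.where(swap, a_pos, b_pos)

    chrom_arr = np.array(chroms, dtype=object)
    pairs = pd.DataFrame(
        {
            "read_id": [f"r{i:08d}" for i in range(total)],
            "chrom1": chrom_arr[c1],
            "pos1": p1,
            "mapq1": np.full(total, 60),
            "chrom2": chrom_arr[c2],
            "pos2": p2,
            "mapq2": np.full(total, 60),
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["bait_id", "chrom", "start", "end", "distance",
                 "enrichment", "bg_lambda", "n_extra"],
    )
    return pairs, truth, baits


@dataclass
class ArtifactTruth:
    """Ground-truth counts of injected read-pair artifacts."""

    n_clean: int
    n_duplicates: int
    n_self_ligations: int
    n_low_mapq: int
    n_junction_reads: int


def simulate_read_pairs(
    cfg: SimConfig,
    pairs: pd.DataFrame,
    baits: list[BaitRegion],
) -> tuple[pd.DataFrame, dict[str, str], ArtifactTruth]:
    """Inject PCR duplicates, self-ligations, low-MAPQ ends and raw reads
    with GATC ligation junctions into a clean pair table.

    Returns the augmented pair table (shuffled), a read_id -> raw
    sequence map for the junction-trimming stage, and truth counts.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 7])
    n = len(pairs)
    out = [pairs]

    n_dup = int(round(cfg.duplicate_rate * n))
    if n_dup:
        take = rng.choice(n, size=n_dup, replace=True)
        dup = pairs.iloc[take].copy().reset_index(drop=True)
        dup["read_id"] = [f"dup{i:07d}" for i in range(n_dup)]
        out.append(dup)

    n_self = int(round(cfg.self_ligation_rate * n))
    if n_self and baits:
        bi = rng.integers(0, len(baits), size=n_self)
        rows = []
        for i, k in enumerate(bi):
            b = baits[k]
            p1, p2 = rng.integers(b.interval.start, b.interval.end, size=2)
            rows.append((f"self{i:07d}", b.chrom, int(p1), 60, b.chrom, int(p2), 60))
        out.append(pd.DataFrame(rows, columns=PAIR_COLUMNS))

    full = pd.concat(out, ignore_index=True)
    n_low = int(round(cfg.low_mapq_rate * len(full)))
    if n_low:
        take = rng.choice(len(full), size=n_low, replace=False)
        side = rng.random(n_low) < 0.5
        mq = rng.integers(0, 30, size=n_low)
        col = full.columns.get_indexer(["mapq1", "mapq2"])
        for t, s, q in zip(take, side, mq):
            full.iat[t, col[0] if s else col[1]] = int(q)

    # raw sequences; a configured fraction carries a GATC junction
    seqs: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    is_junction = rng.random(len(full)) < cfg.junction_fraction
    n_junction = 0
    for i, rid in enumerate(full["read_id"]):
        raw = bases[rng.integers(0, 4, size=cfg.read_length)]
        seq = "".join(raw)
        while "GATC" in seq:  # keep non-junction reads site-free
            seq = seq.replace("GATC", "GATG")
        if is_junction[i]:
            cut = int(rng.integers(25, cfg.read_length - 10))
            seq = seq[:cut] + "GATC" + seq[cut + 4:]
            n_junction += 1
        seqs[rid] = seq

    full = full.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    truth = ArtifactTruth(
        n_clean=n, n_duplicates=n_dup, n_self_ligations=n_self,
        n_low_mapq=n_low, n_junction_reads=n_junction,
    )
    return full, seqs, truth


def simulate_timecourse(
    cfg: SimConfig,
    promoters: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coupled expression / interaction trajectories over five timepoints.

    *promoters* is a list of (promoter_id, class) with class 'activated'
    or 'repressed'.  Activated promoters get monotone-increasing
    expression; repressed, monotone-decreasing; E-P interaction PPKM is
    linearly coupled to expression (slope ``coupling_slope`` plus
    Gaussian noise ``noise_sd``), "other" interactions with the weaker
    ``other_coupling``.  Returns the (region, signal) x timepoint value
    table and the ground-truth coupling table.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    tps = np.array(cfg.timepoints, dtype=float)
    u = tps / tps.max()  # 0..1 monotone ramp

    rows = []
    truth_rows = []
    for pid, cls in promoters:
        if cls not in ("activated", "repressed"):
            raise ValueError(f"unknown promoter class {cls!r}")
        base = float(rng.uniform(5, 20))
        amp = float(rng.uniform(1.0, 3.0))
        ramp = u if cls == "activated" else 1.0 - u
        expr = base * (1.0 + amp * ramp)
        ep = cfg.coupling_slope * expr + rng.normal(0, cfg.noise_sd * base, len(tps))
        other = (
            cfg.other_coupling * expr
            + (1 - cfg.other_coupling) * base
            + rng.normal(0, cfg.noise_sd * base, len(tps))
        )
        ep = np.maximum(ep, 0.0)
        other = np.maximum(other, 0.0)
        allsig = ep + other
        for signal, vals in (
            ("RNA", expr), ("3C-EP", ep), ("3C-other", other), ("3C-all", allsig)
        ):
            rows.append((pid, signal, *vals))
        truth_rows.append((pid, cls, cfg.coupling_slope, cfg.other_coupling))

    values = pd.DataFrame(
        rows, columns=["region", "signal", *cfg.timepoints]
    ).set_index(["region", "signal"])
    truth = pd.DataFrame(
        truth_rows, columns=["promoter", "class", "ep_slope", "other_slope"]
    )
    return values, truth


# ---------------------------------------------------------------------------
# auxiliary annotation generators
# ---------------------------------------------------------------------------

def simulate_genes(cfg: SimConfig, n_genes: int = 60) -> list[GeneModel]:
    """Random gene models (20-50 kb bodies, random strand)."""
    rng = np.random.default_rng([cfg.seed, 13])
    genome = cfg.genome
    chroms = list(genome)
    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.integers(20_000, 50_000))
        start = int(rng.integers(0, genome[chrom] - size))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i:03d}"
        genes.append(
            GeneModel(
                gene_id=gid, name=gid.upper(),
                body=GenomicInterval(chrom, start, start + size, name=gid, strand=strand),
            )
        )
    return genes


def simulate_peaks(
    cfg: SimConfig,
    truth: pd.DataFrame,
    n_random: int = 100,
    at_loop_fraction: float = 0.7,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """ATAC and H3K27ac peak sets: random peaks plus peaks at planted
    loop targets (so E-P classification has enhancers to find)."""
    rng = np.random.default_rng([cfg.seed, 17])
    genome = cfg.genome
    chroms = list(genome)
    atac, k27 = [], []

    def rand_peak(tag: str, i: int) -> GenomicInterval:
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.integers(300, 1500))
        start = int(rng.integers(0, genome[chrom] - size))
        return GenomicInterval(chrom, start, start + size, name=f"{tag}{i:04d}")

    for i in range(n_random):
        atac.append(rand_peak("atac", i))
        k27.append(rand_peak("k27", i))
    for j, row in truth.iterrows():
        if rng.random() < at_loop_fraction:
            mid = (int(row["start"]) + int(row["end"])) // 2
            atac.append(GenomicInterval(row["chrom"], mid - 400, mid + 400,
                                        name=f"atac_loop{j:03d}"))
            k27.append(GenomicInterval(row["chrom"], mid - 700, mid + 700,
                                       name=f"k27_loop{j:03d}"))
    return atac, k27


def assign_ses(baits: list[BaitRegion], members_per_se: tuple[int, int] = (2, 5),
               seed: int = 1234) -> list[BaitRegion]:
    """Group position-consecutive baits per chromosome into SEs in place."""
    rng = np.random.default_rng([seed, 19])
    by_chrom: dict[str, list[BaitRegion]] = {}
    for b in baits:
        by_chrom.setdefault(b.chrom, []).append(b)
    se_n = 0
    for chrom in sorted(by_chrom):
        run = sorted(by_chrom[chrom], key=lambda b: b.interval.start)
        i = 0
        while i < len(run):
            k = int(rng.integers(members_per_se[0], members_per_se[1] + 1))
            group = run[i:i + k]
            if len(group) >= 2:
                se_id = f"SE{se_n:03d}"
                se_n += 1
                for b in group:
                    b.se_id = se_id
            i += k
    return baits
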