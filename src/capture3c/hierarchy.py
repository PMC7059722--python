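"""Super-enhancer hierarchy: H-scores, hub enhancers, and SE taxonomy.

For each constituent enhancer i of a super-enhancer j with s members,
the hierarchical score is

    H_j(i) = EN_j(i) / (L(i) * mean of EN over the SE's members)

where EN_j(i) is the enhancer's PET count and L(i) its peak size (used
in kb here so scores are O(1); hub calls are invariant to that unit
choice).  H-scores pooled over all enhancers are fitted as a gamma
distribution; enhancers in the upper tail (P < alpha, default 0.05) are
hub enhancers, and an SE with at least one hub is a hierarchical SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomicInterval, warn

__all__ = [
    "EnhancerRecord",
    "SuperEnhancer",
    "GammaNull",
    "h_score",
    "call_hubs",
    "classify_hierarchical",
    "categorize_se_interactions",
    "classify_se_gene_patterns",
    "se_gene_distance",
    "compare_distance_sets",
    "SEHierarchyModel",
    "SEHierarchyResults",
    "PATTERN_LABELS",
]


@dataclass
class EnhancerRecord:
    """One constituent enhancer with its PET count and H-score."""

    enhancer_id: str
    se_id: str
    interval: GenomicInterval
    EN: int
    H: float = np.nan
    p_value: float = np.nan
    hub: bool = False

    @property
    def L(self) -> int:
        return self.interval.length


@dataclass
class SuperEnhancer:
    se_id: str
    member_ids: list[str] = field(default_factory=list)
    hierarchical: bool = False
    genes: set[str] = field(default_factory=set)
    pattern: str = ""

    @property
    def s(self) -> int:
        return len(self.member_ids)


@dataclass
class GammaNull:
    """Gamma fit over pooled positive H-scores (location fixed at 0)."""

    shape: float
    scale: float
    alpha: float = 0.05
    n_fitted: int = 0

    def p_upper(self, h: float) -> float:
        return float(stats.gamma.sf(h, self.shape, scale=self.scale))

    def quantile(self, q: float) -> float:
        return float(stats.gamma.ppf(q, self.shape, scale=self.scale))


def h_score(EN, L) -> np.ndarray:
    """H-scores for one SE's members: EN_i / (L_i * mean(EN)).

    *L* is the peak size per enhancer in kb.  A zero mean PET count gives
    all-zero scores with a warning.
    """
    EN = np.asarray(EN, dtype=float)
    L = np.asarray(L, dtype=float)
    if EN.shape != L.shape:
        raise ValueError("EN and L must have the same length")
    if EN.size == 0:
        raise ValueError("need at least one enhancer")
    if np.any(L <= 0):
        raise ValueError("all peak sizes must be > 0")
    m = EN.mean()
    if m == 0.0:
        warn("h_score: SE has zero total PETs; all H-scores set to 0")
        return np.zeros_like(EN)
    return EN / (L * m)


def call_hubs(
    enhancers: list[EnhancerRecord],
    alpha: float = 0.05,
    min_positive: int = 20,
    method: str = "mle",
) -> tuple[list[EnhancerRecord], GammaNull]:
    """Fit a gamma null to pooled H-scores and flag upper-tail hubs.

    Zero H-scores are excluded from the fit and can never be hubs.  The
    fit is maximum likelihood by default (``method='moments'`` switches
    to a moment match).  All-equal H-scores yield zero hubs.
    """
    h = np.array([e.H for e in enhancers], dtype=float)
    if np.any(np.isnan(h)):
        raise ValueError("H-scores must be computed before hub calling")
    pos = h[h > 0]
    if pos.size < min_positive:
        raise ValueError(
            f"only {pos.size} positive H-scores; need >= {min_positive} for a stable fit"
        )
    if np.allclose(pos, pos[0]) and np.all(h[h > 0] == pos[0]):
        warn("call_hubs: all positive H-scores identical; no hubs called")
        null = GammaNull(shape=np.inf, scale=0.0, alpha=alpha, n_fitted=pos.size)
        for e in enhancers:
            e.p_value = 1.0
            e.hub = False
        return enhancers, null

    if method == "mle":
        shape, _, scale = stats.gamma.fit(pos, floc=0)
    elif method == "moments":
        m, v = pos.mean(), pos.var(ddof=1)
        shape, scale = m * m / v, v / m
    else:
        raise ValueError(f"unknown gamma fit method {method!r}")
    null = GammaNull(shape=shape, scale=scale, alpha=alpha, n_fitted=pos.size)

    for e in enhancers:
        if e.H <= 0:
            e.p_value = 1.0
            e.hub = False
        else:
            e.p_value = null.p_upper(e.H)
            e.hub = e.p_value < alpha
    return enhancers, null


def classify_hierarchical(
    ses: list[SuperEnhancer], enhancers: list[EnhancerRecord]
) -> list[SuperEnhancer]:
    """Mark an SE hierarchical iff it contains >= 1 hub enhancer."""
    hubs_by_se: dict[str, bool] = {}
    for e in enhancers:
        hubs_by_se[e.se_id] = hubs_by_se.get(e.se_id, False) or e.hub
    for se in ses:
        se.hierarchical = hubs_by_se.get(se.se_id, False)
    return ses


def categorize_se_interactions(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    promoter_window: int = 2000,
) -> pd.Series:
    """Label each call SE-P, SE-G or SE-O by its partner region.

    Precedence: partner overlapping any promoter window (TSS +/- window)
    -> SE-P; else overlapping a gene body -> SE-G; else SE-O.
    """
    promoters = [(g.body.chrom, max(0, g.tss - promoter_window), g.tss + promoter_window + 1)
                 for g in genes]
    bodies = [(g.body.chrom, g.body.start, g.body.end) for g in genes]

    def hits(regions, chrom, start, end) -> bool:
        return any(c == chrom and start < e and s < end for c, s, e in regions)

    labels = []
    for _, row in calls.iterrows():
        chrom, start, end = row["chrom"], row["start"], row["end"]
        if hits(promoters, chrom, start, end):
            labels.append("SE-P")
        elif hits(bodies, chrom, start, end):
            labels.append("SE-G")
        else:
            labels.append("SE-O")
    return pd.Series(labels, index=calls.index, name="category")


PATTERN_LABELS = {
    (1, 1): "single SE to single gene",
    (1, "n"): "single SE to multiple genes",
    ("n", 1): "multiple SEs to single gene",
    ("n", "n"): "multiple SEs to multiple genes",
    (0, 0): "no significant interacting gene",
}


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def classify_se_gene_patterns(
    links: list[tuple[str, str]], all_se_ids: list[str]
) -> dict[str, str]:
    """Label every SE by the shape of its connected SE-gene component.

    *links* are significant (SE id, gene id) edges; SEs absent from the
    graph get "no significant interacting gene".  The five labels
    partition the SE set.
    """
    uf = _UnionFind()
    linked_ses: set[str] = set()
    for se, gene in links:
        uf.union(("se", se), ("gene", gene))
        linked_ses.add(se)

    comp_members: dict = {}
    for se, gene in links:
        root = uf.find(("se", se))
        comp_members.setdefault(root, (set(), set()))
        comp_members[root][0].add(se)
        comp_members[root][1].add(gene)

    out: dict[str, str] = {}
    for se_id in all_se_ids:
        if se_id not in linked_ses:
            out[se_id] = PATTERN_LABELS[(0, 0)]
            continue
        ses, genes = comp_members[uf.find(("se", se_id))]
        key = (1 if len(ses) == 1 else "n", 1 if len(genes) == 1 else "n")
        out[se_id] = PATTERN_LABELS[key]
    return out


def se_gene_distance(links: pd.DataFrame) -> pd.DataFrame:
    """Per interacting gene, the distance from its TSS to the strongest
    interacting enhancer.

    *links* has one row per significant enhancer-gene link with columns
    ``gene_id, tss, enhancer_id, enh_mid, strength, bf``.  Strength is
    the PET count; ties break by higher BF, then leftmost enhancer.
    """
    rows = []
    for gene_id, sub in links.groupby("gene_id", sort=True):
        sub = sub.sort_values(
            ["strength", "bf", "enh_mid"], ascending=[False, False, True],
            kind="mergesort",
        )
        best = sub.iloc[0]
        rows.append(
            (gene_id, best["enhancer_id"], int(abs(best["tss"] - best["enh_mid"])))
        )
    return pd.DataFrame(rows, columns=["gene_id", "enhancer_id", "distance"])


def compare_distance_sets(dist_a, dist_b) -> tuple[float, float]:
    """Two-sample t test between two SE-gene distance sets -> (t, p)."""
    t, p = stats.ttest_ind(np.asarray(dist_a, float), np.asarray(dist_b, float))
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SEHierarchyModel:
    """Gamma-null hub-enhancer model over a cohort of super-enhancers.

    Parameters
    ----------
    enhancers : DataFrame
        One row per constituent enhancer with columns ``enhancer_id,
        se_id, chrom, start, end, EN`` (EN = PET count at the enhancer).
    alpha : float
        Upper-tail significance level for hub calls.
    pool : str
        'all' fits one gamma null over every enhancer's H-score (the
        default); 'per_se' fits within each SE.
    """

    def __init__(self, enhancers: pd.DataFrame, alpha: float = 0.05,
                 pool: str = "all", min_positive: int = 20, method: str = "mle"):
        required = {"enhancer_id", "se_id", "chrom", "start", "end", "EN"}
        missing = required - set(enhancers.columns)
        if missing:
            raise ValueError(f"enhancer table missing columns {sorted(missing)}")
        if pool not in ("all", "per_se"):
            raise ValueError("pool must be 'all' or 'per_se'")
        self.data = enhancers.reset_index(drop=True)
        self.alpha = alpha
        self.pool = pool
        self.min_positive = min_positive
        self.method = method

    def fit(self) -> "SEHierarchyResults":
        records: list[EnhancerRecord] = []
        for _, row in self.data.iterrows():
            records.append(
                EnhancerRecord(
                    enhancer_id=row["enhancer_id"],
                    se_id=row["se_id"],
                    interval=GenomicInterval(
                        row["chrom"], int(row["start"]), int(row["end"]),
                        name=row["enhancer_id"],
                    ),
                    EN=int(row["EN"]),
                )
            )
        for se_id in sorted({r.se_id for r in records}):
            members = [r for r in records if r.se_id == se_id]
            hs = h_score([r.EN for r in members], [r.L / 1000.0 for r in members])
            for r, h in zip(members, hs):
                r.H = float(h)

        nulls: dict[str, GammaNull] = {}
        if self.pool == "all":
            records, null = call_hubs(records, self.alpha, self.min_positive, self.method)
            nulls["all"] = null
        else:
            for se_id in sorted({r.se_id for r in records}):
                members = [r for r in records if r.se_id == se_id]
                _, nulls[se_id] = call_hubs(
                    members, self.alpha, self.min_positive, self.method
                )

        ses = [
            SuperEnhancer(se_id=se_id,
                          member_ids=[r.enhancer_id for r in records if r.se_id == se_id])
            for se_id in sorted({r.se_id for r in records})
        ]
        classify_hierarchical(ses, records)
        return SEHierarchyResults(self, records, ses, nulls)


class SEHierarchyResults:
    """Hub/hierarchical classification with the fitted gamma null."""

    def __init__(self, model: SEHierarchyModel, records: list[EnhancerRecord],
                 ses: list[SuperEnhancer], nulls: dict[str, GammaNull]):
        self.model = model
        self.records = records
        self.ses = ses
        self.nulls = nulls

    @property
    def gamma_null(self) -> GammaNull:
        return self.nulls["all" if self.model.pool == "all" else next(iter(self.nulls))]

    @property
    def enhancer_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enhancer_id": [r.enhancer_id for r in self.records],
                "se_id": [r.se_id for r in self.records],
                "L": [r.L for r in self.records],
                "EN": [r.EN for r in self.records],
                "H": [r.H for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "hub": [r.hub for r in self.records],
            }
        )

    @property
    def se_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "se_id": [s.se_id for s in self.ses],
                "s": [s.s for s in self.ses],
                "hierarchical": [s.hierarchical for s in self.ses],
                "pattern": [s.pattern for s in self.ses],
            }
        )

    @property
    def hierarchical_fraction_pct(self) -> float:
        n = sum(s.hierarchical for s in self.ses)
        return round(100.0 * n / len(self.ses), 1)

    def summary(self) -> str:
        n_hub = sum(r.hub for r in self.records)
        n_hier = sum(s.hierarchical for s in self.ses)
        g = self.gamma_null
        return "\n".join(
            [
                "SE hierarchy summary",
                "====================",
                f"enhancers scored:      {len(self.records)}",
                f"super-enhancers:       {len(self.ses)}",
                f"hub enhancers (P < {self.model.alpha:g}): {n_hub}",
                f"hierarchical SEs:      {n_hier} of {len(self.ses)} "
                f"({self.hierarchical_fraction_pct:.1f}%)",
                f"gamma null: shape={g.shape:.4g} scale={g.scale:.4g} "
                f"(n={g.n_fitted})",
            ]
        )
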