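"""Null count distributions and the Bayes factor for interaction calling.

The null for a region pair is built from 10,000 random paired placements
(see :mod:`capture3c.calling`); the sampled counts are fitted as a
negative binomial by the method of moments, falling back to Poisson when
the sample is underdispersed and to a point mass at zero when every
sampled count is zero.  The Bayes factor compares H1 (the observed count
x exceeds random contact counts) against H0 (it does not):

    BF = [Pr(X < x) / Pr(X >= x)] * [Pr(H1)/Pr(H0)]

with the prior odds Pr(H1)/Pr(H0) fixed at 0.001 to control the false
discovery rate; BF >= 20 defines a high-confidence interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NegBinBackground",
    "InteractionCall",
    "fit_negbin",
    "bayes_factor",
    "DEFAULT_PRIOR_RATIO",
    "DEFAULT_BF_THRESHOLD",
]

DEFAULT_PRIOR_RATIO = 0.001
DEFAULT_BF_THRESHOLD = 20.0


@dataclass
class NegBinBackground:
    """A fitted null distribution for random contact counts.

    ``kind`` is one of ``negbin`` (size ``r`` > 0 and success probability
    ``p`` in (0,1), scipy parameterization with mean r(1-p)/p),
    ``poisson`` (rate ``lam``), ``point_mass`` (all mass at zero) or
    ``empirical`` (the raw sampled counts themselves).
    """

    kind: str
    r: float | None = None
    p: float | None = None
    lam: float | None = None
    n_samples: int = 0
    counts: np.ndarray | None = field(default=None, repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        if self.kind == "negbin":
            return self.r * (1 - self.p) / self.p
        if self.kind == "poisson":
            return self.lam
        if self.kind == "empirical":
            return float(np.mean(self.counts))
        return 0.0

    @property
    def var(self) -> float:
        if self.kind == "negbin":
            return self.r * (1 - self.p) / self.p**2
        if self.kind == "poisson":
            return self.lam
        if self.kind == "empirical":
            return float(np.var(self.counts))
        return 0.0

    def p_less(self, x: int) -> float:
        """Pr(X < x) under the fitted null."""
        if x <= 0:
            return 0.0
        if self.kind == "negbin":
            return float(stats.nbinom.cdf(x - 1, self.r, self.p))
        if self.kind == "poisson":
            return float(stats.poisson.cdf(x - 1, self.lam))
        if self.kind == "empirical":
            return float(np.mean(self.counts < x))
        return 1.0  # point mass at 0: any x >= 1 exceeds all mass

    def p_geq(self, x: int) -> float:
        """Pr(X >= x) under the fitted null."""
        if x <= 0:
            return 1.0
        if self.kind == "negbin":
            return float(stats.nbinom.sf(x - 1, self.r, self.p))
        if self.kind == "poisson":
            return float(stats.poisson.sf(x - 1, self.lam))
        if self.kind == "empirical":
            return float(np.mean(self.counts >= x))
        return 0.0

    @property
    def degenerate(self) -> bool:
        return self.kind == "point_mass"


def fit_negbin(counts, store_counts: bool = False, **provenance) -> NegBinBackground:
    """Method-of-moments negative-binomial fit to sampled null counts.

    With sample mean m and (unbiased) variance v: r = m^2/(v-m) and
    p = m/v when v > m; Poisson(lam=m) when v <= m; a point mass at zero
    when every count is zero.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    kept = counts.astype(float)
    m = float(kept.mean())
    stored = counts.astype(np.int64) if store_counts else None
    if m == 0.0:
        return NegBinBackground(
            kind="point_mass", n_samples=counts.size, counts=stored, provenance=provenance
        )
    v = float(kept.var(ddof=1)) if counts.size > 1 else 0.0
    if v > m:
        r = m * m / (v - m)
        p = m / v
        return NegBinBackground(
            kind="negbin", r=r, p=p, n_samples=counts.size, counts=stored,
            provenance=provenance,
        )
    return NegBinBackground(
        kind="poisson", lam=m, n_samples=counts.size, counts=stored, provenance=provenance
    )


@dataclass
class InteractionCall:
    """One tested bait-partner pair with its Bayes factor."""

    bait_id: str
    chrom: str
    start: int
    end: int
    x: int
    p_lt: float
    p_ge: float
    bf: float
    significant: bool
    high_confidence: bool
    is_trans: bool
    partner_kind: str = "bin"  # bin | bait
    partner_id: str = ""
    degenerate_background: bool = False
    distance: float = math.nan
    bg_mean: float = math.nan


def bayes_factor(
    x: int,
    bg: NegBinBackground,
    prior_ratio: float = DEFAULT_PRIOR_RATIO,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
) -> tuple[float, float, float, bool]:
    """Return (p_lt, p_ge, BF, significant) for observed count *x*.

    A degenerate (all-zero) background gives BF = +inf for any x >= 1,
    reported rather than suppressed.
    """
    if prior_ratio <= 0:
        raise ValueError("prior_ratio must be > 0")
    if x < 0:
        raise ValueError("x must be >= 0")
    p_lt = bg.p_less(x)
    p_ge = bg.p_geq(x)
    if p_ge == 0.0:
        bf = math.inf
    else:
        bf = (p_lt / p_ge) * prior_ratio
    return p_lt, p_ge, bf, bf >= bf_threshold
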