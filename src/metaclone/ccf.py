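"""Cancer cell fraction (CCF) estimation and clonal/subclonal classification.

A somatic mutation's CCF is the fraction of tumor cells that carry it. It is
inferred from the variant allele fraction (VAF) given the sample purity, the
local tumor copy number and the mutation multiplicity (number of mutated
copies per tumor cell). The posterior over CCF is computed on a fixed grid
with a binomial read-count likelihood and a uniform prior; the mutation is
called *clonal* when the upper bound of the central 95% credible interval
reaches 0.95 (on the capped [0, 1] scale) and the posterior mass near CCF = 1
exceeds the mass below it, otherwise *subclonal*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: CCF grid: 101 points from 0.00 to 1.00 in steps of 0.01.
CCF_GRID: np.ndarray = np.round(np.linspace(0.0, 1.0, 101), 2)

#: Boundary for the clonal-vs-subclonal posterior odds: pr_clonal is the
#: posterior mass at or above this CCF. At the 0.5 midpoint the second
#: conjunct of the clonal rule compares P(nearer clonal) vs P(nearer absent)
#: and the CI-95 conjunct carries the discrimination.
CLONAL_MASS_CUT: float = 0.50

#: Upper credible bound required for a clonal call (CCF capped at 1).
CI_HIGH_CUT: float = 0.95

#: Autosomal copy number of the normal (non-tumor) cell compartment.
CN_NORMAL: int = 2

#: Samples with tumor purity below this fraction are excluded.
MIN_PURITY: float = 0.20


@dataclass
class MutationCall:
    """One somatic SNV/indel in one sample, with read counts and local CN."""

    patient: str
    sample: str
    lesion: str  # normal | primary | metastasis
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    t_alt: int
    t_depth: int
    n_alt: int
    n_depth: int
    cn_major: int
    cn_minor: int
    purity: float

    def __post_init__(self) -> None:
        if not 0 <= self.t_alt <= self.t_depth:
            raise ValueError(f"t_alt={self.t_alt} outside [0, t_depth={self.t_depth}]")
        if not self.cn_major >= self.cn_minor >= 0:
            raise ValueError("require cn_major >= cn_minor >= 0")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity {self.purity} outside (0, 1]")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def cn_tumor(self) -> int:
        return self.cn_major + self.cn_minor


@dataclass
class CCFEstimate:
    """Point estimate, 95% credible interval and clonality call for one mutation."""

    ccf_hat: float
    ccf_ci95_low: float
    ccf_ci95_high: float
    pr_clonal: float
    pr_subclonal: float
    multiplicity: int
    clonality: str = field(default="subclonal")
    posterior: np.ndarray | None = field(default=None, repr=False, compare=False)


def expected_vaf(
    ccf: float,
    purity: float,
    cn_tumor: float,
    cn_normal: float = CN_NORMAL,
    multiplicity: int = 1,
) -> float:
    """Expected variant allele fraction for a mutation at cancer cell fraction ``ccf``.

    vaf = ccf * purity * multiplicity / (purity * cn_tumor + (1 - purity) * cn_normal)

    The denominator is the average number of locus copies per sequenced cell;
    the numerator is the average number of mutated copies. Monotone in ``ccf``.
    """
    denom = purity * cn_tumor + (1.0 - purity) * cn_normal
    if denom <= 0:
        raise ValueError("zero or negative locus copy denominator")
    return ccf * purity * multiplicity / denom


def estimate_multiplicity(t_alt: int, t_depth: int, purity: float, cn_tumor: int) -> int:
    """Nearest-integer multiplicity implied by the observed VAF, clamped to [1, cn_tumor].

    Inverts the VAF relation at CCF = 1 with half-up rounding.
    """
    if t_depth <= 0:
        raise ValueError("t_depth must be positive")
    if cn_tumor < 1:
        raise ValueError("cn_tumor must be >= 1")
    vaf = t_alt / t_depth
    m = np.floor(vaf * (purity * cn_tumor + (1.0 - purity) * CN_NORMAL) / purity + 0.5)
    return int(min(max(m, 1), cn_tumor))


def estimate_ccf(
    call: MutationCall,
    clonal_mass_cut: float = CLONAL_MASS_CUT,
    ci_high_cut: float = CI_HIGH_CUT,
    keep_posterior: bool = False,
) -> CCFEstimate:
    """Grid posterior over CCF for one mutation.

    Likelihood: Binomial(t_alt | t_depth, expected_vaf(ccf)); prior uniform on
    the grid. ``ccf_hat`` is the posterior mode, the interval is the 95%
    highest-posterior-density interval (HPD rather than equal-tailed, so that
    a truly clonal mutation's interval reaches the CCF = 1 boundary) and
    ``pr_clonal`` is the mass at CCF >= ``clonal_mass_cut``.
    """
    if call.t_depth <= 0:
        raise ValueError("t_depth must be positive")
    m = estimate_multiplicity(call.t_alt, call.t_depth, call.purity, max(call.cn_tumor, 1))
    vafs = np.clip(
        expected_vaf(CCF_GRID, call.purity, max(call.cn_tumor, 1), CN_NORMAL, m), 0.0, 1.0
    )
    loglik = stats.binom.logpmf(call.t_alt, call.t_depth, vafs)
    loglik[np.isneginf(loglik) & (vafs == 0) & (call.t_alt == 0)] = 0.0
    post = np.exp(loglik - loglik.max())
    post /= post.sum()

    ccf_hat = float(CCF_GRID[int(np.argmax(post))])
    lo, hi = _hpd_interval(post)
    lo, hi = min(lo, ccf_hat), max(hi, ccf_hat)
    pr_clonal = float(post[CCF_GRID >= clonal_mass_cut].sum())

    est = CCFEstimate(
        ccf_hat=ccf_hat,
        ccf_ci95_low=lo,
        ccf_ci95_high=hi,
        pr_clonal=pr_clonal,
        pr_subclonal=1.0 - pr_clonal,
        multiplicity=m,
        posterior=post if keep_posterior else None,
    )
    est.clonality = classify_clonality(est, ci_high_cut=ci_high_cut)
    return est


def _hpd_interval(post: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Smallest set of grid points holding >= ``mass`` posterior, as [min, max]."""
    order = np.argsort(post)[::-1]
    take = np.cumsum(post[order]) < mass
    take[np.argmin(take)] = True  # include the point that crosses the mass target
    chosen = order[take]
    return float(CCF_GRID[chosen.min()]), float(CCF_GRID[chosen.max()])


def classify_clonality(est: CCFEstimate, ci_high_cut: float = CI_HIGH_CUT) -> str:
    """Clonal iff the CI-95 upper bound reaches ``ci_high_cut`` AND Pr(clonal) > Pr(subclonal)."""
    if est.ccf_ci95_high >= ci_high_cut and est.pr_clonal > est.pr_subclonal:
        return "clonal"
    return "subclonal"


def add_ccf_columns(
    muts: pd.DataFrame,
    clonal_mass_cut: float = CLONAL_MASS_CUT,
    ci_high_cut: float = CI_HIGH_CUT,
) -> pd.DataFrame:
    """Append CCF estimate columns to a mutation table.

    Adds ``multiplicity, ccf_hat, ccf_ci95_low, ccf_ci95_high, pr_clonal, clonality``.
    Vectorised over rows: one (rows x grid) binomial log-pmf evaluation.
    """
    out = muts.copy()
    if out.empty:
        for col in ("multiplicity", "ccf_hat", "ccf_ci95_low", "ccf_ci95_high", "pr_clonal"):
            out[col] = pd.Series(dtype=float)
        out["clonality"] = pd.Series(dtype=object)
        return out
    t_alt = out["t_alt"].to_numpy(float)
    t_depth = out["t_depth"].to_numpy(float)
    if (t_depth <= 0).any():
        raise ValueError("t_depth must be positive for all rows")
    purity = out["purity"].to_numpy(float)
    cn_tumor = np.maximum(out["cn_major"].to_numpy(float) + out["cn_minor"].to_numpy(float), 1.0)

    vaf = t_alt / t_depth
    mult = np.floor(vaf * (purity * cn_tumor + (1 - purity) * CN_NORMAL) / purity + 0.5)
    mult = np.clip(mult, 1, cn_tumor)

    denom = purity * cn_tumor + (1 - purity) * CN_NORMAL
    vafs = np.clip(CCF_GRID[None, :] * (purity * mult / denom)[:, None], 0.0, 1.0)
    loglik = stats.binom.logpmf(t_alt[:, None], t_depth[:, None], vafs)
    loglik[np.isneginf(loglik) & (vafs == 0) & (t_alt[:, None] == 0)] = 0.0
    post = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)

    idx_mode = post.argmax(axis=1)
    ccf_hat = CCF_GRID[idx_mode]
    # 95% HPD per row: rank grid points by posterior, keep the smallest set
    # reaching 0.95 mass, report its span
    order = np.argsort(post, axis=1)[:, ::-1]
    sorted_post = np.take_along_axis(post, order, axis=1)
    csum = np.cumsum(sorted_post, axis=1)
    n_keep = (csum < 0.95).sum(axis=1) + 1
    lo = np.empty(len(post))
    hi = np.empty(len(post))
    for i in range(len(post)):
        chosen = order[i, : n_keep[i]]
        lo[i], hi[i] = CCF_GRID[chosen.min()], CCF_GRID[chosen.max()]
    lo = np.minimum(lo, ccf_hat)
    hi = np.maximum(hi, ccf_hat)
    pr_clonal = post[:, CCF_GRID >= clonal_mass_cut].sum(axis=1)

    out["multiplicity"] = mult.astype(int)
    out["ccf_hat"] = ccf_hat
    out["ccf_ci95_low"] = lo
    out["ccf_ci95_high"] = hi
    out["pr_clonal"] = pr_clonal
    out["clonality"] = np.where(
        (hi >= ci_high_cut) & (pr_clonal > 1 - pr_clonal), "clonal", "subclonal"
    )
    return out


def filter_low_purity(samples: pd.DataFrame, min_purity: float = MIN_PURITY) -> pd.DataFrame:
    """Drop samples whose tumor purity is strictly below ``min_purity``.

    ``samples`` needs columns ``sample`` and ``purity``. Exclusions are logged.
    """
    if "purity" not in samples.columns or samples["purity"].isna().any():
        raise ValueError("every sample needs a purity value")
    keep = samples["purity"] >= min_purity
    for _, row in samples[~keep].iterrows():
        logger.info(
            "excluding sample %s: purity %.2f below %.2f", row["sample"], row["purity"], min_purity
        )
    return samples[keep].reset_index(drop=True)
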