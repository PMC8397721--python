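"""Cohort-level summary statistics and two-group tests.

Percentages are reported with their numerator and denominator so printed
values can be audited; integer display uses half-up rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class Frequency:
    """A cohort percentage with its audit counts."""

    percent: float
    numerator: int
    denominator: int

    @property
    def display(self) -> int:
        """Half-up integer percent (e.g. 11/30 -> 37)."""
        return int(math.floor(self.percent + 0.5))


def mutational_frequency(muts: pd.DataFrame, gene: str, unit: str = "sample") -> Frequency:
    """Percent of units (samples or patients) with >= 1 call in ``gene``."""
    if unit not in ("sample", "patient"):
        raise ValueError("unit must be 'sample' or 'patient'")
    total = muts[unit].nunique()
    if total == 0:
        raise ValueError("empty cohort")
    hit = muts.loc[muts["gene"] == gene, unit].nunique()
    if hit == 0:
        logger.warning("gene %s not mutated anywhere in the cohort", gene)
    return Frequency(100.0 * hit / total, hit, total)


def pathway_patient_frequency(muts: pd.DataFrame, gene_set: list[str]) -> Frequency:
    """Percent of patients with >= 1 mutated gene from ``gene_set`` (counted once)."""
    if not gene_set:
        raise ValueError("empty gene set")
    total = muts["patient"].nunique()
    if total == 0:
        raise ValueError("empty cohort")
    hit = muts.loc[muts["gene"].isin(set(gene_set)), "patient"].nunique()
    return Frequency(100.0 * hit / total, hit, total)


def group_compare(groups: dict[str, list], test: str = "wilcoxon") -> tuple[float, float]:
    """Two-sided comparison of two groups; returns (statistic, p value).

    ``wilcoxon`` (Mann-Whitney U) for continuous values; ``fisher`` and
    ``chisq`` for a 2x2 table given as two rows of counts.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name_a, a), (name_b, b) = groups.items()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("degenerate group with n=0")
    logger.info("group_compare %s vs %s using %s", name_a, name_b, test)
    if test == "wilcoxon":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "fisher":
        odds, p = sps.fisher_exact([a, b], alternative="two-sided")
        return float(odds), float(p)
    if test == "chisq":
        res = sps.chi2_contingency([a, b], correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
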