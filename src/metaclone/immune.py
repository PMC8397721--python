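"""Immune-escape analysis: HLA loss of heterozygosity, neoantigen filtering,
expression calls, and HLA-corrected tumor mutational burden.

An HLA class-I gene loses an allele (HLA-LOH) when the allele-specific copy
number of one allele drops below 0.5 and the per-bin log copy-ratios of the
two alleles differ significantly (paired t test, p < 0.01). Neoantigens pass
DNA depth/VAF filters, inherit clonality from their source mutation, and are
"expressed" when the mutation site has >= 5 RNA-seq reads of which >= 3 carry
the mutant base. HLA-corrected TMB discounts mutations whose only predicted
presenting alleles were lost, since their neoantigens can no longer be shown
to T cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Allele-specific CN below which an allele counts as lost.
LOH_CN_CUT = 0.5
#: Paired-t p-value below which the two alleles' log ratios differ.
LOH_P_CUT = 0.01
#: netMHC percentile rank at or below which a peptide binds an allele.
BINDER_RANK_CUT = 2.0
#: Capture size in megabases for optional per-Mb TMB normalisation.
CAPTURE_MB = 53.0

MIN_HLA_BINS = 5


@dataclass
class HLAAllelePair:
    """Binned log copy-ratios for the two alleles of one HLA gene in one sample."""

    sample: str
    hla_gene: str
    logr_allele1: np.ndarray
    logr_allele2: np.ndarray
    purity: float
    allele1: str = "allele1"
    allele2: str = "allele2"

    def __post_init__(self) -> None:
        self.logr_allele1 = np.asarray(self.logr_allele1, dtype=float)
        self.logr_allele2 = np.asarray(self.logr_allele2, dtype=float)
        if self.logr_allele1.shape != self.logr_allele2.shape:
            raise ValueError("allele bins must be paired: unequal bin counts")

    def estimated_cn(self) -> tuple[float, float]:
        """Allele-specific copy number from mean log ratio and purity.

        Inverts ratio = purity * cn + (1 - purity) (one normal copy per
        allele), floored at 0.
        """
        cns = []
        for logr in (self.logr_allele1, self.logr_allele2):
            ratio = 2.0 ** float(np.mean(logr))
            cns.append(max((ratio - (1.0 - self.purity)) / self.purity, 0.0))
        return cns[0], cns[1]


@dataclass
class LOHCall:
    sample: str
    hla_gene: str
    cn_allele1: float
    cn_allele2: float
    minor_cn: float
    p_value: float
    is_loh: bool
    lost_allele: str | None


@dataclass
class TMBReport:
    """Mutation-count burden for one sample, split by clonality and HLA-corrected."""

    sample: str
    tmb_total: int
    tmb_clonal: int
    tmb_subclonal: int
    tmb_hla_corrected: int

    def per_megabase(self, capture_mb: float = CAPTURE_MB) -> float:
        return self.tmb_total / capture_mb


def call_hla_loh(
    pair: HLAAllelePair, cn_cut: float = LOH_CN_CUT, p_cut: float = LOH_P_CUT
) -> LOHCall:
    """LOH call for one HLA gene: minor allele CN < ``cn_cut`` AND paired-t p < ``p_cut``."""
    if pair.logr_allele1.size < MIN_HLA_BINS:
        raise ValueError(f"need >= {MIN_HLA_BINS} paired bins")
    cn1, cn2 = pair.estimated_cn()
    minor = min(cn1, cn2)
    tstat = stats.ttest_rel(pair.logr_allele1, pair.logr_allele2)
    p = float(tstat.pvalue)
    if np.isnan(p):  # identical bins, zero variance of differences
        p = 1.0
    is_loh = bool(minor < cn_cut and p < p_cut)
    lost = None
    if is_loh:
        lost = pair.allele1 if cn1 <= cn2 else pair.allele2
    return LOHCall(
        sample=pair.sample,
        hla_gene=pair.hla_gene,
        cn_allele1=cn1,
        cn_allele2=cn2,
        minor_cn=minor,
        p_value=p,
        is_loh=is_loh,
        lost_allele=lost,
    )


def loh_incidence(calls: pd.DataFrame, by: str = "patient") -> tuple[float, int, int]:
    """Percentage of units (patients or samples) with >= 1 positive LOH call.

    Returns (percentage, positive units, total units).
    """
    if calls.empty:
        raise ValueError("no LOH calls")
    per_unit = calls.groupby(by)["is_loh"].any()
    k, n = int(per_unit.sum()), int(per_unit.size)
    return 100.0 * k / n, k, n


def depth_filter_variants(
    records: pd.DataFrame,
    normal_cov_cutoff: int = 5,
    normal_vaf_cutoff: float = 0.02,
    tumor_cov_cutoff: int = 10,
    tumor_vaf_cutoff: float = 0.40,
    strict: bool = False,
    strict_normal_cov: int = 20,
) -> pd.DataFrame:
    """Depth-based neoantigen variant filters.

    Removes likely-germline records (normal depth <= ``normal_cov_cutoff`` with
    normal VAF >= ``normal_vaf_cutoff``) and keeps only records with tumor
    depth >= ``tumor_cov_cutoff`` and tumor VAF >= ``tumor_vaf_cutoff``.
    ``strict=True`` raises the normal-coverage cutoff to ``strict_normal_cov``
    to further suppress germline misclassification. Idempotent.
    """
    cut = strict_normal_cov if strict else normal_cov_cutoff
    germline_like = (records["dna_normal_depth"] <= cut) & (
        records["dna_normal_vaf"] >= normal_vaf_cutoff
    )
    tumor_ok = (records["dna_tumor_depth"] >= tumor_cov_cutoff) & (
        records["dna_tumor_vaf"] >= tumor_vaf_cutoff
    )
    return records[~germline_like & tumor_ok].reset_index(drop=True)


def call_expressed(
    rna_site_depth: float, rna_alt_reads: float, min_depth: int = 5, min_alt: int = 3
) -> bool | None:
    """Expressed iff >= ``min_depth`` RNA reads cover the site and >= ``min_alt`` carry the
    mutant base; None (unknown) when RNA data are missing."""
    if rna_site_depth is None or (isinstance(rna_site_depth, float) and np.isnan(rna_site_depth)):
        return None
    return bool(rna_site_depth >= min_depth and rna_alt_reads >= min_alt)


def add_expression_calls(records: pd.DataFrame) -> pd.DataFrame:
    """Append an ``expressed`` column (True/False/NA) to a neoantigen table."""
    out = records.copy()
    out["expressed"] = [
        call_expressed(d, a) for d, a in zip(out["rna_site_depth"], out["rna_alt_reads"])
    ]
    return out


def neoantigen_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Per-sample neoantigen counts by clonality x expression, plus the cohort
    Pearson correlation between total and non-expressed neoantigen counts.

    Records with unknown expression (no RNA) are excluded from the expression
    split. Correlation is None with < 3 samples or zero variance.
    """
    rows = []
    for sample, grp in records.groupby("sample"):
        known = grp[grp["expressed"].notna()]
        rows.append(
            {
                "sample": sample,
                "n_total": len(grp),
                "n_clonal": int((grp["clonality"] == "clonal").sum()),
                "n_subclonal": int((grp["clonality"] == "subclonal").sum()),
                "n_expressed": int((known["expressed"] == True).sum()),  # noqa: E712
                "n_non_expressed": int((known["expressed"] == False).sum()),  # noqa: E712
                "n_clonal_expressed": int(
                    ((known["clonality"] == "clonal") & (known["expressed"] == True)).sum()  # noqa: E712
                ),
                "n_subclonal_expressed": int(
                    ((known["clonality"] == "subclonal") & (known["expressed"] == True)).sum()  # noqa: E712
                ),
            }
        )
    table = pd.DataFrame(rows)
    r: float | None = None
    if len(table) >= 3:
        x = table["n_total"].to_numpy(float)
        y = table["n_non_expressed"].to_numpy(float)
        if np.std(x) > 0 and np.std(y) > 0:
            r = float(stats.pearsonr(x, y).statistic)
    return table, r


def hla_corrected_tmb(
    mutations: pd.DataFrame,
    neoantigens: pd.DataFrame,
    loh_calls: list[LOHCall] | pd.DataFrame,
    binder_rank_cut: float = BINDER_RANK_CUT,
) -> TMBReport:
    """TMB report for one sample with the HLA-LOH correction.

    tmb_total counts the sample's nonsynonymous mutations; the corrected
    burden removes mutations all of whose binding HLA alleles (netMHC rank <=
    ``binder_rank_cut``) were lost per the LOH calls. Mutations without any
    binder are kept (nothing presentable was lost).
    """
    if isinstance(loh_calls, pd.DataFrame):
        lost_alleles = set(loh_calls.loc[loh_calls["is_loh"], "lost_allele"].dropna())
    else:
        lost_alleles = {c.lost_allele for c in loh_calls if c.is_loh and c.lost_allele}
    sample = mutations["sample"].iloc[0] if len(mutations) else ""

    if "variant_key" in mutations.columns:
        mut_keys = set(mutations["variant_key"])
    elif len(mutations):
        mut_keys = set(
            mutations["chrom"].astype(str)
            + ":"
            + mutations["pos"].astype(str)
            + ":"
            + mutations["ref"].astype(str)
            + ":"
            + mutations["alt"].astype(str)
        )
    else:
        mut_keys = set()

    removed = 0
    if len(neoantigens):
        binders = neoantigens[neoantigens["binding_rank"] <= binder_rank_cut]
        for key, grp in binders.groupby("variant_key"):
            if key not in mut_keys:
                continue
            alleles = set(grp["allele"])
            if alleles and alleles <= lost_alleles:
                removed += 1

    total = len(mutations)
    clonal = int((mutations.get("clonality", pd.Series(dtype=object)) == "clonal").sum())
    return TMBReport(
        sample=sample,
        tmb_total=total,
        tmb_clonal=clonal,
        tmb_subclonal=total - clonal,
        tmb_hla_corrected=total - removed,
    )
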