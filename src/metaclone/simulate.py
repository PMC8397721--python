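"""Synthetic paired primary/metastasis cohorts with known clonal ground truth.

Each patient is generated from a small set of clones, each with a cancer
cell fraction (CCF) in the primary lesion and in the liver metastasis. Read
counts at every mutation follow the same generative model the CCF estimator
inverts: sequencing depth is Poisson around the mean exome depth (150x by
default), and alt reads are Binomial with

    vaf = ccf * purity * multiplicity / (purity * cn_tumor + (1 - purity) * cn_normal).

The generator also emits allele-specific copy-number segments with embedded
arm-level events, binned HLA allele coverage (with optional true LOH), RNA
read counts at mutation sites, and neoantigen candidate records — together
with ground-truth tables for every label a downstream stage infers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from .patterns import classify_pattern, load_arm_definitions

#: True clonality threshold: a clone at CCF >= this is clonal in that lesion.
TRUE_CLONAL_CCF = 0.95

GENE_POOL = [
    "APC", "TP53", "KRAS", "SYNE1", "CACNA1H", "PCLO", "FBXL2", "DNAH11",
    "SMAD2", "SMAD4", "PIK3CA", "FAT4", "RYR1", "PCDHA2", "PCDHB15",
    "TCF7L2", "KMT2D", "AXIN1", "AMER1", "COL5A1", "HGF", "MYC", "BRAF",
    "NRAS", "CTNNB1", "TTN", "MUC16", "OBSCN", "LRP1B", "FLG", "CSMD3",
    "ZFHX4", "USH2A", "DNAH5", "RYR2", "PCDH15", "XIRP2", "SPTA1", "NEB",
    "CSMD1", "FAT3", "HMCN1", "ADGRV1", "DST", "PKHD1", "ABCA13", "COL11A1",
]

BASES = ("A", "C", "G", "T")


@dataclass
class CloneSpec:
    """One clone: its CCF in each lesion and how many mutations it carries."""

    clone_id: str
    ccf_primary: float
    ccf_metastasis: float
    n_mutations: int

    def __post_init__(self) -> None:
        for v in (self.ccf_primary, self.ccf_metastasis):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"clone CCF {v} outside [0, 1]")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")

    def true_status(self, lesion: str) -> str:
        c = self.ccf_primary if lesion == "primary" else self.ccf_metastasis
        if c == 0.0:
            return "absent"
        return "clonal" if c >= TRUE_CLONAL_CCF else "subclonal"


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings; a fixed seed gives identical tables."""

    n_patients: int = 15
    mean_depth: float = 150.0
    purity_primary: float = 0.6
    purity_metastasis: float = 0.6
    seed: int = 0
    hla_bins: int = 20
    rna_mean_depth: float = 50.0
    min_alt_reads: int = 3  # detection threshold for a call to appear in a table
    p_expressed: float = 0.6
    neoantigen_fraction: float = 0.4
    p_loh_truncal: float = 0.13  # true HLA-LOH present in both lesions
    p_loh_met_only: float = 0.13  # additional metastasis-private HLA-LOH
    error_rate: float = 0.0  # background alt-read rate in the matched normal
    cn_alt_fraction: float = 0.15  # fraction of mutations on a (2,1) segment

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for p in (self.purity_primary, self.purity_metastasis):
            if not 0.0 < p <= 1.0:
                raise ValueError("purities must be in (0, 1]")
        if self.hla_bins < 5:
            raise ValueError("hla_bins must be >= 5")


def default_clone_template() -> list[CloneSpec]:
    """One truncal clone plus lesion-variable clones spanning all eight patterns."""
    return [
        CloneSpec("truncal", 1.0, 1.0, 40),
        CloneSpec("cs", 1.0, 0.35, 12),
        CloneSpec("sc", 0.35, 1.0, 12),
        CloneSpec("ss", 0.40, 0.45, 10),
        CloneSpec("zc", 0.0, 1.0, 12),
        CloneSpec("cz", 1.0, 0.0, 10),
        CloneSpec("zs", 0.0, 0.45, 8),
        CloneSpec("sz", 0.40, 0.0, 8),
    ]


#: Per-patient arm-level copy-number truth: (arm, direction, f_primary, f_metastasis).
DEFAULT_ARM_EVENTS = [
    ("20q", "amp", 1.0, 1.0),   # C-C
    ("17p", "del", 1.0, 1.0),   # C-C
    ("13q", "amp", 0.6, 1.0),   # S-C (0.6 keeps the arm above the +/-0.2 log2 call threshold)
    ("8q", "amp", 0.0, 1.0),    # 0-C
]


def simulate_reads(
    ccf: float,
    purity: float,
    cn_tumor: int,
    cn_normal: int,
    multiplicity: int,
    depth: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """(alt_count, total_count) at one site: Poisson depth, Binomial alt reads."""
    if not 0.0 <= ccf <= 1.0:
        raise ValueError("ccf outside [0, 1]")
    if not 1 <= multiplicity <= cn_tumor:
        raise ValueError("require 1 <= multiplicity <= cn_tumor")
    total = int(rng.poisson(depth))
    if total == 0:
        return 0, 0
    vaf = ccf_mod.expected_vaf(ccf, purity, cn_tumor, cn_normal, multiplicity)
    return int(rng.binomial(total, min(vaf, 1.0))), total


def simulate_hla_coverage(
    true_cn_allele_a: float,
    true_cn_allele_b: float,
    purity: float,
    n_bins: int,
    depth: float,
    rng: np.random.Generator,
    sample: str = "S",
    hla_gene: str = "A",
):
    """Binned per-allele log copy-ratios for one HLA gene vs the matched normal.

    Per bin and allele, tumor coverage is Poisson with mean
    depth/2 * (purity * cn + (1 - purity)) and normal coverage Poisson(depth/2);
    the log2 ratio uses a 0.5 pseudocount. As purity -> 0 both alleles' ratios
    collapse to 0 (estimated CN -> 1) regardless of the tumor CN.
    """
    from .immune import HLAAllelePair

    if n_bins < 5:
        raise ValueError("need >= 5 bins")
    logrs = []
    for cn in (true_cn_allele_a, true_cn_allele_b):
        mean_t = depth / 2.0 * (purity * cn + (1.0 - purity))
        t = rng.poisson(mean_t, size=n_bins).astype(float)
        n = rng.poisson(depth / 2.0, size=n_bins).astype(float)
        logrs.append(np.log2((t + 0.5) / (n + 0.5)))
    return HLAAllelePair(
        sample=sample,
        hla_gene=hla_gene,
        logr_allele1=logrs[0],
        logr_allele2=logrs[1],
        purity=purity,
        allele1=f"HLA-{hla_gene}*01",
        allele2=f"HLA-{hla_gene}*02",
    )


def _random_variant(rng: np.random.Generator, used: set) -> tuple[str, int, str, str]:
    while True:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1, 100_000_000))
        ref, alt = rng.choice(BASES, size=2, replace=False)
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos, str(ref), str(alt)


def _arm_segments(
    arms: pd.DataFrame,
    events: list[tuple[str, str, float]],
    purity: float,
    rng: np.random.Generator,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """SEG rows for every arm; non-neutral arms carry log2 = log2((2 + purity*f*delta)/2)."""
    by_arm = {row["arm"]: row for _, row in arms.iterrows()}
    event_map = {arm: (direction, f) for arm, direction, f in events}
    rows = []
    for arm, row in by_arm.items():
        direction, f = event_map.get(arm, ("neutral", 0.0))
        delta = {"amp": 1.0, "del": -1.0, "neutral": 0.0}[direction]
        base_log2 = np.log2((2.0 + purity * f * delta) / 2.0)
        mid = (row["start"] + row["end"]) // 2
        for lo, hi in ((row["start"], mid), (mid + 1, row["end"])):
            rows.append(
                {
                    "chrom": str(row["chrom"]),
                    "start": int(lo),
                    "end": int(hi),
                    "log2_ratio": float(base_log2 + rng.normal(0.0, noise_sd)),
                    "cn_major": 1 + (1 if delta > 0 and f >= TRUE_CLONAL_CCF else 0),
                    "cn_minor": 1 - (1 if delta < 0 and f >= TRUE_CLONAL_CCF else 0),
                }
            )
    return pd.DataFrame(rows)


def simulate_patient(
    config: SimulationConfig,
    clones: list[CloneSpec],
    rng: np.random.Generator,
    patient_id: str = "P1",
    arm_events: list[tuple[str, str, float, float]] | None = None,
    arms: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """All tables for one patient (both lesions) plus ground truth.

    Returns a dict with keys mutations, segments, hla, rna, neoantigens,
    samples, truth_mutations, truth_arms, truth_hla.
    """
    if not clones:
        raise ValueError("empty clone list")
    if not any(c.ccf_primary == 1.0 and c.ccf_metastasis == 1.0 for c in clones):
        raise ValueError("need at least one truncal clone (CCF 1.0 in both lesions)")
    if arms is None:
        arms = load_arm_definitions()
    if arm_events is None:
        arm_events = DEFAULT_ARM_EVENTS

    purities = {"primary": config.purity_primary, "metastasis": config.purity_metastasis}
    samples = {
        lesion: f"{patient_id}_{lesion[0].upper()}" for lesion in ("primary", "metastasis")
    }

    # deterministic recurrent-gene seeding for selected clones
    seeded_genes = {"truncal": ["APC", "TP53"], "sc": ["KRAS", "SYNE1"]}

    used_sites: set = set()
    mut_rows, truth_rows, rna_rows, neo_rows = [], [], [], []
    for clone in clones:
        for i in range(clone.n_mutations):
            chrom, pos, ref, alt = _random_variant(rng, used_sites)
            seeds = seeded_genes.get(clone.clone_id, [])
            gene = seeds[i] if i < len(seeds) else str(rng.choice(GENE_POOL))
            if rng.random() < config.cn_alt_fraction:
                cn_major, cn_minor = 2, 1
            else:
                cn_major, cn_minor = 1, 1
            cn_tumor = cn_major + cn_minor
            multiplicity = 1
            key = f"{chrom}:{pos}:{ref}:{alt}"
            expressed_true = bool(rng.random() < config.p_expressed)

            present_in = {}
            for lesion in ("primary", "metastasis"):
                ccf = clone.ccf_primary if lesion == "primary" else clone.ccf_metastasis
                purity = purities[lesion]
                if ccf == 0.0:
                    continue
                alt_count, total = simulate_reads(
                    ccf, purity, cn_tumor, 2, multiplicity, config.mean_depth, rng
                )
                n_depth = int(rng.poisson(config.mean_depth))
                n_alt = int(rng.binomial(n_depth, config.error_rate)) if n_depth else 0
                if alt_count < config.min_alt_reads:
                    continue
                present_in[lesion] = (alt_count, total)
                mut_rows.append(
                    {
                        "patient": patient_id,
                        "sample": samples[lesion],
                        "lesion": lesion,
                        "gene": gene,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "t_alt": alt_count,
                        "t_depth": total,
                        "n_alt": n_alt,
                        "n_depth": n_depth,
                        "cn_major": cn_major,
                        "cn_minor": cn_minor,
                        "purity": purity,
                    }
                )
                # RNA coverage at the site: transcribed mutations get full
                # RNA depth and mutant reads at the DNA VAF; silent ones get
                # sparse background coverage with no mutant reads.
                vaf = ccf_mod.expected_vaf(ccf, purity, cn_tumor, 2, multiplicity)
                if expressed_true:
                    rna_depth = int(rng.poisson(config.rna_mean_depth))
                    rna_alt = int(rng.binomial(rna_depth, min(vaf, 1.0))) if rna_depth else 0
                else:
                    rna_depth = int(rng.poisson(1.5))
                    rna_alt = 0
                rna_rows.append(
                    {
                        "sample": samples[lesion],
                        "variant_key": key,
                        "rna_site_depth": rna_depth,
                        "rna_alt_reads": rna_alt,
                    }
                )
                if rng.random() < config.neoantigen_fraction:
                    hla_gene = str(rng.choice(["A", "B", "C"]))
                    n_alleles = int(rng.integers(1, 3))
                    chosen = rng.choice(["01", "02"], size=n_alleles, replace=False)
                    peptide = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9))
                    for allele_suffix in chosen:
                        neo_rows.append(
                            {
                                "sample": samples[lesion],
                                "variant_key": key,
                                "peptide": peptide,
                                "allele": f"HLA-{hla_gene}*{allele_suffix}",
                                "binding_rank": float(
                                    np.exp(rng.uniform(np.log(0.05), np.log(50.0)))
                                ),
                                "dna_normal_depth": n_depth,
                                "dna_normal_vaf": (n_alt / n_depth) if n_depth else 0.0,
                                "dna_tumor_depth": total,
                                "dna_tumor_vaf": alt_count / total if total else 0.0,
                                "rna_site_depth": rna_depth,
                                "rna_alt_reads": rna_alt,
                            }
                        )

            status_p = clone.true_status("primary")
            status_m = clone.true_status("metastasis")
            truth_rows.append(
                {
                    "patient": patient_id,
                    "variant_key": key,
                    "gene": gene,
                    "clone_id": clone.clone_id,
                    "ccf_primary": clone.ccf_primary,
                    "ccf_metastasis": clone.ccf_metastasis,
                    "status_primary": status_p,
                    "status_metastasis": status_m,
                    "pattern": classify_pattern(status_p, status_m),
                    "detected_primary": "primary" in present_in,
                    "detected_metastasis": "metastasis" in present_in,
                    "expressed": expressed_true,
                }
            )

    # arm-level copy-number segments per lesion
    seg_rows, truth_arm_rows = [], []
    for lesion in ("primary", "metastasis"):
        f_idx = 2 if lesion == "primary" else 3
        events = [(ev[0], ev[1], ev[f_idx]) for ev in arm_events if ev[f_idx] > 0]
        seg = _arm_segments(arms, events, purities[lesion], rng)
        seg.insert(0, "sample", samples[lesion])
        seg_rows.append(seg)
    for ev in arm_events:
        arm, direction, f_p, f_m = ev

        def status(f):
            if f == 0.0:
                return "absent"
            return "clonal" if f >= TRUE_CLONAL_CCF else "subclonal"

        truth_arm_rows.append(
            {
                "patient": patient_id,
                "arm": arm,
                "direction": direction,
                "f_primary": f_p,
                "f_metastasis": f_m,
                "status_primary": status(f_p),
                "status_metastasis": status(f_m),
                "pattern": classify_pattern(status(f_p), status(f_m)),
            }
        )

    # HLA allele coverage per lesion, with optional true LOH
    u = rng.random()
    loh_lesions: set = set()
    if u < config.p_loh_truncal:
        loh_lesions = {"primary", "metastasis"}
    elif u < config.p_loh_truncal + config.p_loh_met_only:
        loh_lesions = {"metastasis"}
    loh_gene = str(rng.choice(["A", "B", "C"]))
    hla_rows, truth_hla_rows = [], []
    for lesion in ("primary", "metastasis"):
        for gene in ("A", "B", "C"):
            has_loh = lesion in loh_lesions and gene == loh_gene
            cn_a, cn_b = (1.0, 0.0) if has_loh else (1.0, 1.0)
            pair = simulate_hla_coverage(
                cn_a, cn_b, purities[lesion], config.hla_bins, config.mean_depth, rng,
                sample=samples[lesion], hla_gene=gene,
            )
            for b in range(config.hla_bins):
                hla_rows.append(
                    {
                        "patient": patient_id,
                        "sample": samples[lesion],
                        "lesion": lesion,
                        "hla_gene": gene,
                        "bin": b,
                        "logr_allele1": pair.logr_allele1[b],
                        "logr_allele2": pair.logr_allele2[b],
                        "allele1": pair.allele1,
                        "allele2": pair.allele2,
                        "purity": purities[lesion],
                    }
                )
            truth_hla_rows.append(
                {
                    "patient": patient_id,
                    "sample": samples[lesion],
                    "lesion": lesion,
                    "hla_gene": gene,
                    "is_loh": has_loh,
                    "lost_allele": pair.allele2 if has_loh else None,
                }
            )

    sample_rows = [
        {
            "patient": patient_id,
            "sample": samples[lesion],
            "lesion": lesion,
            "purity": purities[lesion],
            "ploidy": 2.0,
        }
        for lesion in ("primary", "metastasis")
    ]

    mut_cols = [
        "patient", "sample", "lesion", "gene", "chrom", "pos", "ref", "alt",
        "t_alt", "t_depth", "n_alt", "n_depth", "cn_major", "cn_minor", "purity",
    ]
    return {
        "mutations": pd.DataFrame(mut_rows, columns=mut_cols),
        "segments": pd.concat(seg_rows, ignore_index=True),
        "hla": pd.DataFrame(hla_rows),
        "rna": pd.DataFrame(rna_rows, columns=["sample", "variant_key", "rna_site_depth", "rna_alt_reads"]),
        "neoantigens": pd.DataFrame(
            neo_rows,
            columns=[
                "sample", "variant_key", "peptide", "allele", "binding_rank",
                "dna_normal_depth", "dna_normal_vaf", "dna_tumor_depth",
                "dna_tumor_vaf", "rna_site_depth", "rna_alt_reads",
            ],
        ),
        "samples": pd.DataFrame(sample_rows),
        "truth_mutations": pd.DataFrame(truth_rows),
        "truth_arms": pd.DataFrame(truth_arm_rows),
        "truth_hla": pd.DataFrame(truth_hla_rows),
    }


def simulate_cohort(
    config: SimulationConfig, clones: list[CloneSpec] | None = None
) -> dict[str, pd.DataFrame]:
    """Full cohort: ``config.n_patients`` patients concatenated per table."""
    rng = np.random.default_rng(config.seed)
    if clones is None:
        clones = default_clone_template()
    arms = load_arm_definitions()
    parts: dict[str, list[pd.DataFrame]] = {}
    for i in range(config.n_patients):
        pt = simulate_patient(config, clones, rng, patient_id=f"P{i + 1}", arms=arms)
        for key, df in pt.items():
            parts.setdefault(key, []).append(df)
    return {key: pd.concat(dfs, ignore_index=True) for key, dfs in parts.items()}


def write_cohort(tables: dict[str, pd.DataFrame], outdir) -> None:
    """Write every cohort table as a headered TSV under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
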