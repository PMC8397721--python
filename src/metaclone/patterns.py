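"""Clonal-evolution pattern analysis across paired primary/metastasis lesions.

Each somatic event (SNV/indel or arm-level copy-number aberration) gets a
status in each lesion — absent (0), subclonal (S) or clonal (C) — and the
pair of statuses defines its evolutionary pattern, written
``<primary>-<metastasis>``: C-C events are truncal/early, S-C events rose to
clonality in the metastasis (mid-stage), 0-C events are metastasis-private
late events, and so on over the eight combinations.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PATTERN_CODES = {"absent": "0", "subclonal": "S", "clonal": "C"}
ALL_PATTERNS = ("C-C", "C-S", "S-C", "S-S", "0-C", "0-S", "C-0", "S-0")

#: Arm mean log2 ratio at or above which an arm is amplified / at or below
#: which it is deleted (common WES convention; exposed for configuration).
ARM_AMP_LOG2 = 0.2
ARM_DEL_LOG2 = -0.2

#: An arm event with copy-number CCF at or above this is clonal.
SCNA_CLONAL_CUT = 0.9


def load_arm_definitions() -> pd.DataFrame:
    """Packaged hg19 chromosome-arm boundaries (columns chrom, arm, start, end)."""
    ref = importlib.resources.files("metaclone") / "data" / "arms_hg19.tsv"
    with importlib.resources.as_file(ref) as path:
        arms = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return arms


def _variant_keyed(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    t["variant_key"] = (
        t["chrom"].astype(str)
        + ":"
        + t["pos"].astype(str)
        + ":"
        + t["ref"].astype(str)
        + ":"
        + t["alt"].astype(str)
    )
    dup = t["variant_key"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate variant keys within one sample: {t.loc[dup, 'variant_key'].tolist()}")
    return t


def match_mutations(primary: pd.DataFrame, metastasis: pd.DataFrame) -> pd.DataFrame:
    """Pair the mutation tables of both lesions of one patient on chrom:pos:ref:alt.

    Returns one row per distinct variant with per-lesion status
    (absent/subclonal/clonal, from the ``clonality`` column when present) and
    per-lesion CCF (NaN where absent).
    """
    cols = ["variant_key", "gene", "clonality", "ccf_hat"]
    frames = []
    for lesion, table in (("primary", primary), ("metastasis", metastasis)):
        if table.empty:
            t = pd.DataFrame(columns=cols)
        else:
            t = _variant_keyed(table)
            if "clonality" not in t.columns:
                t["clonality"] = "clonal"
            if "ccf_hat" not in t.columns:
                t["ccf_hat"] = np.nan
            t = t[cols]
        frames.append(
            t.rename(
                columns={"clonality": f"status_{lesion}", "ccf_hat": f"ccf_{lesion}"}
            )
        )
    paired = frames[0].merge(frames[1], on="variant_key", how="outer", suffixes=("", "_m"))
    if "gene_m" in paired.columns:
        paired["gene"] = paired["gene"].fillna(paired.pop("gene_m"))
    for lesion in ("primary", "metastasis"):
        paired[f"status_{lesion}"] = paired[f"status_{lesion}"].fillna("absent")
    paired["shared"] = (paired["status_primary"] != "absent") & (
        paired["status_metastasis"] != "absent"
    )
    return paired.sort_values("variant_key").reset_index(drop=True)


def classify_pattern(status_primary: str, status_metastasis: str) -> str:
    """Pattern label from the two lesion statuses, e.g. (subclonal, clonal) -> 'S-C'."""
    if status_primary == "absent" and status_metastasis == "absent":
        raise ValueError("event absent from both lesions has no pattern")
    try:
        return f"{PATTERN_CODES[status_primary]}-{PATTERN_CODES[status_metastasis]}"
    except KeyError as exc:
        raise ValueError(f"unknown status {exc}") from exc


def add_pattern_labels(paired: pd.DataFrame) -> pd.DataFrame:
    """Append a ``pattern`` column to a matched-mutation table."""
    out = paired.copy()
    out["pattern"] = [
        classify_pattern(p, m)
        for p, m in zip(out["status_primary"], out["status_metastasis"])
    ]
    return out


def proportions(paired: pd.DataFrame) -> tuple[float, float, float]:
    """(shared, primary-private, metastasis-private) fractions of distinct variants."""
    n = len(paired)
    if n == 0:
        raise ValueError("no paired mutations")
    shared = int(paired["shared"].sum())
    p_priv = int(((paired["status_primary"] != "absent") & ~paired["shared"]).sum())
    m_priv = int(((paired["status_metastasis"] != "absent") & ~paired["shared"]).sum())
    return shared / n, p_priv / n, m_priv / n


def median_ccf_ranking(muts: pd.DataFrame, lesion: str) -> pd.DataFrame:
    """Genes ranked by descending median CCF within one lesion (high = early event).

    Ties broken lexicographically by gene symbol; stable.
    """
    sub = muts[muts["lesion"] == lesion] if "lesion" in muts.columns else muts
    ranked = (
        sub.groupby("gene", as_index=False)["ccf_hat"]
        .median()
        .rename(columns={"ccf_hat": "median_ccf"})
        .sort_values(["median_ccf", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def recurrent_pattern_genes(
    cohort_patterns: pd.DataFrame, pattern: str, min_samples: int = 2
) -> list[str]:
    """Genes showing the requested pattern in at least ``min_samples`` patients.

    ``cohort_patterns`` holds per-patient labelled events (columns patient,
    gene, pattern).
    """
    hits = cohort_patterns[cohort_patterns["pattern"] == pattern]
    counts = hits.groupby("gene")["patient"].nunique()
    return sorted(counts[counts >= min_samples].index)


def arm_level_call(
    segments: pd.DataFrame,
    arms: pd.DataFrame | None = None,
    amp_log2: float = ARM_AMP_LOG2,
    del_log2: float = ARM_DEL_LOG2,
) -> pd.DataFrame:
    """Length-weighted mean log2 ratio per chromosome arm, with amp/del/neutral call.

    ``segments`` is a SEG-like table (chrom, start, end, log2_ratio); intervals
    are 1-based inclusive. Arms with zero covered bases are omitted.
    """
    if arms is None:
        arms = load_arm_definitions()
    seg = segments.copy()
    seg["chrom"] = seg["chrom"].astype(str)
    rows = []
    for _, arm in arms.iterrows():
        on_chrom = seg[seg["chrom"] == str(arm["chrom"])]
        if on_chrom.empty:
            continue
        ov_start = np.maximum(on_chrom["start"].to_numpy(), arm["start"])
        ov_end = np.minimum(on_chrom["end"].to_numpy(), arm["end"])
        lengths = np.maximum(ov_end - ov_start + 1, 0)
        covered = lengths.sum()
        if covered == 0:
            continue
        mean_log2 = float(np.average(on_chrom["log2_ratio"].to_numpy(), weights=lengths))
        if mean_log2 >= amp_log2:
            direction = "amp"
        elif mean_log2 <= del_log2:
            direction = "del"
        else:
            direction = "neutral"
        rows.append(
            {
                "arm": arm["arm"],
                "mean_log2": mean_log2,
                "direction": direction,
                "covered_bases": int(covered),
            }
        )
    return pd.DataFrame(rows, columns=["arm", "mean_log2", "direction", "covered_bases"])


def scna_ccf(mean_log2_ratio: float, purity: float, delta_cn: float) -> float:
    """Fraction of tumor cells carrying an arm event with total-CN change ``delta_cn``.

    Inverts the total copy-ratio model ratio = (2 + purity * f * delta_cn) / 2,
    assuming a single event per arm on a diploid background:
    f = (2^(log2_ratio + 1) - 2) / (purity * delta_cn), clamped to [0, 1].
    """
    if delta_cn == 0:
        raise ValueError("delta_cn must be nonzero")
    if purity <= 0:
        raise ValueError("purity must be positive")
    f = (2.0 ** (mean_log2_ratio + 1.0) - 2.0) / (purity * delta_cn)
    return float(np.clip(f, 0.0, 1.0))


def arm_event_status(
    mean_log2: float,
    direction: str,
    purity: float,
    clonal_cut: float = SCNA_CLONAL_CUT,
) -> str:
    """Lesion status of an arm event: absent if neutral, else clonal/subclonal by SCNA CCF.

    delta_cn is +1 for a single-copy gain, -1 for a single-copy loss.
    """
    if direction == "neutral":
        return "absent"
    delta = 1.0 if direction == "amp" else -1.0
    f = scna_ccf(mean_log2, purity, delta)
    return "clonal" if f >= clonal_cut else "subclonal"


def arm_evolution_patterns(
    segments_primary: pd.DataFrame,
    segments_metastasis: pd.DataFrame,
    purity_primary: float,
    purity_metastasis: float,
    arms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pattern labels for arm-level copy-number events across the lesion pair.

    An arm contributes a row when it is non-neutral in at least one lesion and
    the non-neutral directions agree (an arm gained in one lesion and lost in
    the other is flagged 'discordant' instead of labelled).
    """
    calls_p = arm_level_call(segments_primary, arms).set_index("arm")
    calls_m = arm_level_call(segments_metastasis, arms).set_index("arm")
    rows = []
    for arm in sorted(set(calls_p.index) | set(calls_m.index)):
        dir_p = calls_p["direction"].get(arm, "neutral")
        dir_m = calls_m["direction"].get(arm, "neutral")
        if dir_p == dir_m == "neutral":
            continue
        directions = {d for d in (dir_p, dir_m) if d != "neutral"}
        if len(directions) > 1:
            rows.append({"arm": arm, "direction": "discordant", "pattern": None,
                         "status_primary": None, "status_metastasis": None})
            continue
        direction = directions.pop()
        status_p = (
            "absent"
            if dir_p == "neutral"
            else arm_event_status(calls_p.loc[arm, "mean_log2"], dir_p, purity_primary)
        )
        status_m = (
            "absent"
            if dir_m == "neutral"
            else arm_event_status(calls_m.loc[arm, "mean_log2"], dir_m, purity_metastasis)
        )
        rows.append(
            {
                "arm": arm,
                "direction": direction,
                "pattern": classify_pattern(status_p, status_m),
                "status_primary": status_p,
                "status_metastasis": status_m,
            }
        )
    return pd.DataFrame(
        rows, columns=["arm", "direction", "pattern", "status_primary", "status_metastasis"]
    )


def cohort_snv_patterns(
    muts: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pattern labels and shared/private proportions for every lesion-paired patient.

    ``muts`` is a CCF-annotated mutation table (with ``clonality``), ``samples``
    the metadata (patient, sample, lesion). Patients lacking either lesion are
    skipped. Returns (per-variant pattern table, per-patient proportion table).
    """
    pattern_frames, proportion_rows = [], []
    for patient in sorted(samples["patient"].unique()):
        p_samples = samples[samples["patient"] == patient]
        prim = p_samples.loc[p_samples["lesion"] == "primary", "sample"]
        met = p_samples.loc[p_samples["lesion"] == "metastasis", "sample"]
        if prim.empty or met.empty:
            logger.info("patient %s lacks a lesion pair; skipping patterns", patient)
            continue
        t_p = muts[muts["sample"] == prim.iloc[0]]
        t_m = muts[muts["sample"] == met.iloc[0]]
        if t_p.empty and t_m.empty:
            continue
        paired = add_pattern_labels(match_mutations(t_p, t_m))
        paired.insert(0, "patient", patient)
        pattern_frames.append(paired)
        shared, p_priv, m_priv = proportions(paired)
        proportion_rows.append(
            {
                "patient": patient,
                "n_variants": len(paired),
                "shared": shared,
                "primary_private": p_priv,
                "metastasis_private": m_priv,
            }
        )
    patterns_table = (
        pd.concat(pattern_frames, ignore_index=True) if pattern_frames else pd.DataFrame()
    )
    return patterns_table, pd.DataFrame(proportion_rows)


def gene_set_enrichment(
    genes: list[str], gene_sets: dict[str, list[str]], universe: list[str]
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``genes`` in each gene set.

    P = Pr(overlap >= observed) drawing len(genes) genes from the universe.
    Gene-set members outside the universe are dropped with a warning.
    """
    uni = set(universe)
    query = set(genes) & uni
    if len(query) < len(set(genes)):
        logger.warning("query genes outside the universe were dropped")
    rows = []
    for name, members in gene_sets.items():
        members_set = set(members)
        if not members_set <= uni:
            logger.warning("gene set %s not a subset of the universe; intersecting", name)
            members_set &= uni
        k = len(query & members_set)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members_set), len(query)))
        rows.append({"gene_set": name, "overlap": k, "set_size": len(members_set), "p_value": p})
    return pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p_value"])
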