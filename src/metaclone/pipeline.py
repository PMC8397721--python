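"""End-to-end analysis pipeline over a paired-lesion cohort.

Stages: purity filter -> CCF/clonality -> evolution patterns (SNV + arm) ->
per-patient parsimony trees -> immune escape (HLA-LOH, neoantigens, TMB) ->
cohort summaries. Every stage writes headered TSVs under the output
directory; a JSON manifest records the configuration and seed so a run can
be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import ccf as ccf_mod
from . import immune as immune_mod
from . import patterns as patterns_mod
from . import phylogeny as phylo_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with the stage name and offending sample/patient."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every stage, serialised into the run manifest."""

    min_purity: float = ccf_mod.MIN_PURITY
    clonal_ci_cut: float = ccf_mod.CI_HIGH_CUT
    clonal_mass_cut: float = ccf_mod.CLONAL_MASS_CUT
    arm_amp_log2: float = patterns_mod.ARM_AMP_LOG2
    arm_del_log2: float = patterns_mod.ARM_DEL_LOG2
    scna_clonal_cut: float = patterns_mod.SCNA_CLONAL_CUT
    loh_cn_cut: float = immune_mod.LOH_CN_CUT
    loh_p_cut: float = immune_mod.LOH_P_CUT
    binder_rank_cut: float = immune_mod.BINDER_RANK_CUT
    expr_min_depth: int = 5
    expr_min_alt: int = 3
    recurrent_min_samples: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _variant_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def run_pipeline(
    tables: dict[str, pd.DataFrame], config: PipelineConfig, outdir
) -> Path:
    """Run every stage on an in-memory cohort; returns the report directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: purity filter -------------------------------------------
    samples = tables.get("samples")
    muts_in = tables.get("mutations")
    if samples is None or muts_in is None or samples.empty or muts_in.empty:
        raise PipelineError("purity_filter", "empty cohort: need samples and mutations")
    tumor_meta = samples[samples["lesion"].isin(["primary", "metastasis"])]
    try:
        kept = ccf_mod.filter_low_purity(tumor_meta, config.min_purity)
    except ValueError as exc:
        raise PipelineError("purity_filter", str(exc)) from exc
    excluded = sorted(set(tumor_meta["sample"]) - set(kept["sample"]))
    if excluded:
        logger.info("excluded low-purity samples: %s", excluded)

    # --- stage 2: CCF / clonality -----------------------------------------
    muts = muts_in[muts_in["sample"].isin(set(kept["sample"]))].reset_index(drop=True)
    if muts.empty:
        raise PipelineError("ccf", "no mutations left after the purity filter")
    try:
        muts = ccf_mod.add_ccf_columns(
            muts, clonal_mass_cut=config.clonal_mass_cut, ci_high_cut=config.clonal_ci_cut
        )
    except ValueError as exc:
        raise PipelineError("ccf", str(exc)) from exc
    muts["variant_key"] = _variant_key(muts)
    muts.to_csv(out / "mutations_ccf.tsv", sep="\t", index=False)

    lesion_of = dict(zip(kept["sample"], kept["lesion"]))
    patient_of = dict(zip(kept["sample"], kept["patient"]))

    # --- stage 3: SNV evolution patterns ----------------------------------
    patients = sorted(kept["patient"].unique())
    try:
        patterns_table, proportions_table = patterns_mod.cohort_snv_patterns(muts, kept)
    except ValueError as exc:
        raise PipelineError("patterns", str(exc)) from exc
    patterns_table.to_csv(out / "snv_patterns.tsv", sep="\t", index=False)
    proportions_table.to_csv(out / "shared_private.tsv", sep="\t", index=False)

    recurrent = {
        pat: patterns_mod.recurrent_pattern_genes(
            patterns_table, pat, config.recurrent_min_samples
        )
        for pat in patterns_mod.ALL_PATTERNS
    } if len(patterns_table) else {}
    pd.DataFrame(
        [{"pattern": k, "genes": ",".join(v)} for k, v in recurrent.items()]
    ).to_csv(out / "recurrent_pattern_genes.tsv", sep="\t", index=False)

    # --- stage 4: arm-level SCNA patterns ---------------------------------
    arm_frames = []
    segments = tables.get("segments")
    if segments is not None and not segments.empty:
        for patient in patients:
            p_samples = kept[kept["patient"] == patient]
            prim = p_samples.loc[p_samples["lesion"] == "primary", "sample"]
            met = p_samples.loc[p_samples["lesion"] == "metastasis", "sample"]
            if prim.empty or met.empty:
                continue
            seg_p = segments[segments["sample"] == prim.iloc[0]]
            seg_m = segments[segments["sample"] == met.iloc[0]]
            if seg_p.empty or seg_m.empty:
                continue
            purity_p = float(p_samples.loc[p_samples["lesion"] == "primary", "purity"].iloc[0])
            purity_m = float(
                p_samples.loc[p_samples["lesion"] == "metastasis", "purity"].iloc[0]
            )
            try:
                arm_pat = patterns_mod.arm_evolution_patterns(
                    seg_p, seg_m, purity_p, purity_m
                )
            except ValueError as exc:
                raise PipelineError("arm_patterns", f"patient {patient}: {exc}") from exc
            arm_pat.insert(0, "patient", patient)
            arm_frames.append(arm_pat)
    arm_table = pd.concat(arm_frames, ignore_index=True) if arm_frames else pd.DataFrame()
    arm_table.to_csv(out / "arm_patterns.tsv", sep="\t", index=False)

    # --- stage 5: per-patient parsimony trees -----------------------------
    tree_rows = []
    for patient in patients:
        p_samples = kept[kept["patient"] == patient]["sample"].tolist()
        sample_tables = {
            s: muts[muts["sample"] == s] for s in p_samples if not muts[muts["sample"] == s].empty
        }
        if len(sample_tables) < 2:
            continue
        try:
            tree, matrix = phylo_mod.patient_tree(sample_tables)
        except ValueError as exc:
            raise PipelineError("phylogeny", f"patient {patient}: {exc}") from exc
        newick = phylo_mod.write_newick(tree)
        (out / f"tree_{patient}.nwk").write_text(newick + "\n")
        tree_rows.append(
            {
                "patient": patient,
                "n_variants": len(matrix),
                "parsimony_score": tree.score,
                "n_homoplastic": len(tree.homoplastic_variants),
                "newick": newick,
            }
        )
    pd.DataFrame(tree_rows).to_csv(out / "trees.tsv", sep="\t", index=False)

    # --- stage 6: immune escape -------------------------------------------
    loh_df = pd.DataFrame()
    hla = tables.get("hla")
    if hla is not None and not hla.empty:
        loh_rows = []
        for (sample, gene), grp in hla.groupby(["sample", "hla_gene"]):
            if sample not in lesion_of:
                continue
            grp = grp.sort_values("bin")
            pair = immune_mod.HLAAllelePair(
                sample=sample,
                hla_gene=str(gene),
                logr_allele1=grp["logr_allele1"].to_numpy(),
                logr_allele2=grp["logr_allele2"].to_numpy(),
                purity=float(grp["purity"].iloc[0]),
                allele1=str(grp["allele1"].iloc[0]),
                allele2=str(grp["allele2"].iloc[0]),
            )
            try:
                call = immune_mod.call_hla_loh(pair, config.loh_cn_cut, config.loh_p_cut)
            except ValueError as exc:
                raise PipelineError("hla_loh", f"sample {sample}: {exc}") from exc
            row = asdict(call)
            row["patient"] = patient_of[sample]
            row["lesion"] = lesion_of[sample]
            loh_rows.append(row)
        loh_df = pd.DataFrame(loh_rows)
    loh_df.to_csv(out / "hla_loh.tsv", sep="\t", index=False)

    neo = tables.get("neoantigens")
    neo_summary = pd.DataFrame()
    neo_corr = None
    tmb_rows = []
    if neo is not None and not neo.empty:
        neo = immune_mod.depth_filter_variants(neo)
        neo = immune_mod.add_expression_calls(neo)
        clonality = muts[["sample", "variant_key", "clonality"]]
        neo = neo.merge(clonality, on=["sample", "variant_key"], how="left")
        neo.to_csv(out / "neoantigens_filtered.tsv", sep="\t", index=False)
        if len(neo):
            neo_summary, neo_corr = immune_mod.neoantigen_summary(neo)
            neo_summary.to_csv(out / "neoantigen_summary.tsv", sep="\t", index=False)
    for sample in sorted(kept["sample"]):
        m_s = muts[muts["sample"] == sample]
        if m_s.empty:
            continue
        n_s = neo[neo["sample"] == sample] if neo is not None and len(neo) else pd.DataFrame()
        l_s = loh_df[loh_df["sample"] == sample] if len(loh_df) else pd.DataFrame(
            columns=["is_loh", "lost_allele"]
        )
        report = immune_mod.hla_corrected_tmb(m_s, n_s, l_s, config.binder_rank_cut)
        tmb_rows.append(asdict(report))
    pd.DataFrame(tmb_rows).to_csv(out / "tmb.tsv", sep="\t", index=False)

    # --- manifest ----------------------------------------------------------
    cfg = asdict(config)
    manifest = {
        "package": "metaclone",
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "n_patients": len(patients),
        "n_samples_retained": int(len(kept)),
        "excluded_samples": excluded,
        "neoantigen_nonexpressed_correlation": neo_corr,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
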