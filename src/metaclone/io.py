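"""Readers and writers for the pipeline's headered TSV table formats.

All positions are 1-based inclusive (MAF/SEG convention). Readers validate
required columns and report malformed rows with their line numbers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MUTATION_COLUMNS = [
    "patient", "sample", "lesion", "gene", "chrom", "pos", "ref", "alt",
    "t_alt", "t_depth", "n_alt", "n_depth", "cn_major", "cn_minor", "purity",
]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio", "cn_major", "cn_minor"]
HLA_COLUMNS = [
    "patient", "sample", "lesion", "hla_gene", "bin",
    "logr_allele1", "logr_allele2", "allele1", "allele2", "purity",
]
RNA_COLUMNS = ["sample", "variant_key", "rna_site_depth", "rna_alt_reads"]
NEOANTIGEN_COLUMNS = [
    "sample", "variant_key", "peptide", "allele", "binding_rank",
    "dna_normal_depth", "dna_normal_vaf", "dna_tumor_depth", "dna_tumor_vaf",
    "rna_site_depth", "rna_alt_reads",
]
SAMPLE_COLUMNS = ["patient", "sample", "lesion", "purity"]


def _read(path, required: list[str], dtype: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=dtype)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _check_positions(df: pd.DataFrame, cols: list[str], path) -> None:
    for col in cols:
        bad = df.index[df[col] < 1]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based line numbers
            raise ValueError(
                f"{path}: column '{col}' has values < 1 (positions are 1-based), "
                f"e.g. at line(s) {lines}"
            )


def read_mutation_table(path) -> pd.DataFrame:
    df = _read(path, MUTATION_COLUMNS, dtype={"chrom": str, "ref": str, "alt": str})
    _check_positions(df, ["pos"], path)
    bad = df.index[df["t_alt"] > df["t_depth"]]
    if len(bad):
        raise ValueError(f"{path}: t_alt > t_depth at line(s) {[int(i) + 2 for i in bad[:5]]}")
    return df


def read_segment_table(path) -> pd.DataFrame:
    df = _read(path, SEGMENT_COLUMNS, dtype={"chrom": str})
    _check_positions(df, ["start", "end"], path)
    return df


def read_hla_table(path) -> pd.DataFrame:
    return _read(path, HLA_COLUMNS, dtype={"hla_gene": str})


def read_rna_table(path) -> pd.DataFrame:
    return _read(path, RNA_COLUMNS)


def read_neoantigen_table(path) -> pd.DataFrame:
    return _read(path, NEOANTIGEN_COLUMNS)


def read_sample_table(path) -> pd.DataFrame:
    return _read(path, SAMPLE_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_cohort(indir) -> dict[str, pd.DataFrame]:
    """Read a cohort directory written by ``simulate.write_cohort`` or the pipeline."""
    indir = Path(indir)
    readers = {
        "mutations": read_mutation_table,
        "segments": read_segment_table,
        "hla": read_hla_table,
        "rna": read_rna_table,
        "neoantigens": read_neoantigen_table,
        "samples": read_sample_table,
    }
    tables = {}
    for name, reader in readers.items():
        path = indir / f"{name}.tsv"
        if path.exists():
            tables[name] = reader(path)
    if "mutations" not in tables or "samples" not in tables:
        raise ValueError(f"{indir}: cohort needs at least mutations.tsv and samples.tsv")
    extra = set(tables["mutations"]["sample"]) - set(tables["samples"]["sample"])
    if extra:
        raise ValueError(f"samples {sorted(extra)} missing from samples.tsv metadata")
    return tables
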