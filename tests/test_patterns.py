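"""Pattern taxonomy, lesion matching, arm-level SCNA calls and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import metaclone as mc
from metaclone.patterns import (
    add_pattern_labels,
    arm_event_status,
    arm_level_call,
    load_arm_definitions,
)


def _table(rows):
    cols = ["chrom", "pos", "ref", "alt", "gene", "clonality", "ccf_hat"]
    return pd.DataFrame(rows, columns=cols)


A = ("1", 100, "A", "T", "APC", "clonal", 1.0)
B = ("2", 200, "C", "G", "KRAS", "subclonal", 0.4)
C = ("3", 300, "G", "A", "TP53", "clonal", 0.95)


# ---------------------------------------------------------------- matching


def test_identical_tables_all_shared():
    paired = mc.match_mutations(_table([A, B]), _table([A, B]))
    assert paired["shared"].all()
    assert mc.proportions(paired) == (1.0, 0.0, 0.0)


def test_disjoint_tables_no_shared():
    paired = mc.match_mutations(_table([A]), _table([B, C]))
    assert not paired["shared"].any()
    assert len(paired) == 3


def test_empty_primary_all_metastasis_private():
    paired = mc.match_mutations(_table([]), _table([A, B]))
    assert mc.proportions(paired) == (0.0, 0.0, 1.0)


def test_duplicate_variant_keys_rejected():
    with pytest.raises(ValueError):
        mc.match_mutations(_table([A, A]), _table([B]))


def test_proportions_mixed_counts():
    paired = mc.match_mutations(_table([A, B]), _table([A, C]))
    shared, p_priv, m_priv = mc.proportions(paired)
    assert (shared, p_priv, m_priv) == (pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3))
    assert shared + p_priv + m_priv == pytest.approx(1.0)


def test_proportions_empty_rejected():
    with pytest.raises(ValueError):
        mc.proportions(pd.DataFrame(columns=["shared", "status_primary", "status_metastasis"]))


# ---------------------------------------------------------------- pattern labels


@pytest.mark.parametrize(
    "sp, sm, label",
    [
        ("subclonal", "clonal", "S-C"),
        ("absent", "clonal", "0-C"),
        ("clonal", "clonal", "C-C"),
        ("clonal", "subclonal", "C-S"),
        ("subclonal", "absent", "S-0"),
        ("absent", "subclonal", "0-S"),
    ],
)
def test_classify_pattern(sp, sm, label):
    assert mc.classify_pattern(sp, sm) == label


def test_classify_pattern_double_absent_rejected():
    with pytest.raises(ValueError):
        mc.classify_pattern("absent", "absent")


def test_pattern_recovery_on_synthetic_truth(small_cohort):
    """Inferred labels match generator truth for >= 90% of detected mutations."""
    _, tables = small_cohort
    muts = mc.add_ccf_columns(tables["mutations"])
    muts["variant_key"] = (
        muts.chrom.astype(str) + ":" + muts.pos.astype(str) + ":" + muts.ref + ":" + muts.alt
    )
    frames = []
    for patient, grp in muts.groupby("patient"):
        paired = add_pattern_labels(
            mc.match_mutations(grp[grp.lesion == "primary"], grp[grp.lesion == "metastasis"])
        )
        paired["patient"] = patient
        frames.append(paired)
    inferred = pd.concat(frames)
    merged = inferred.merge(
        tables["truth_mutations"], on=["patient", "variant_key"], suffixes=("", "_true")
    )
    assert (merged["pattern"] == merged["pattern_true"]).mean() >= 0.90


# ---------------------------------------------------------------- timing & recurrence


def test_median_ccf_ranking_orders_early_events_first():
    muts = pd.DataFrame(
        {
            "gene": ["A", "A", "B", "C"],
            "ccf_hat": [1.0, 1.0, 0.4, 0.4],
            "lesion": ["primary"] * 4,
        }
    )
    ranked = mc.median_ccf_ranking(muts, "primary")
    assert list(ranked["gene"]) == ["A", "B", "C"]  # ties broken lexicographically
    assert ranked.loc[0, "median_ccf"] == 1.0


def test_recurrent_pattern_genes_thresholds():
    cohort = pd.DataFrame(
        {
            "patient": ["P1", "P2", "P3", "P1"],
            "gene": ["KRAS", "KRAS", "SYNE1", "APC"],
            "pattern": ["S-C", "S-C", "S-C", "C-C"],
        }
    )
    assert mc.recurrent_pattern_genes(cohort, "S-C", min_samples=2) == ["KRAS"]
    assert mc.recurrent_pattern_genes(cohort, "S-C", min_samples=1) == ["KRAS", "SYNE1"]
    assert mc.recurrent_pattern_genes(cohort, "C-C", min_samples=2) == []


# ---------------------------------------------------------------- arm-level calls


def _seg(chrom, start, end, log2):
    return {"chrom": chrom, "start": start, "end": end, "log2_ratio": log2}


def test_arm_call_neutral_amp_del():
    arms = load_arm_definitions()
    arm8q = arms[arms["arm"] == "8q"].iloc[0]
    lo, hi = int(arm8q["start"]), int(arm8q["end"])
    neutral = pd.DataFrame([_seg("8", lo, hi, 0.0)])
    assert arm_level_call(neutral).set_index("arm").loc["8q", "direction"] == "neutral"
    amp = pd.DataFrame([_seg("8", lo, hi, math.log2(3 / 2))])
    assert arm_level_call(amp).set_index("arm").loc["8q", "direction"] == "amp"
    cancel = pd.DataFrame([_seg("8", lo, (lo + hi) // 2, 0.6), _seg("8", (lo + hi) // 2 + 1, hi, -0.6)])
    assert arm_level_call(cancel).set_index("arm").loc["8q", "direction"] == "neutral"


def test_arm_call_invariant_to_segment_splitting():
    arms = load_arm_definitions()
    arm = arms[arms["arm"] == "13q"].iloc[0]
    lo, hi = int(arm["start"]), int(arm["end"])
    whole = pd.DataFrame([_seg("13", lo, hi, 0.31)])
    mid = (lo + hi) // 2
    split = pd.DataFrame([_seg("13", lo, mid, 0.31), _seg("13", mid + 1, hi, 0.31)])
    a = arm_level_call(whole).set_index("arm").loc["13q"]
    b = arm_level_call(split).set_index("arm").loc["13q"]
    assert a["mean_log2"] == pytest.approx(b["mean_log2"])
    assert a["direction"] == b["direction"]


def test_uncovered_arm_missing_from_calls():
    calls = arm_level_call(pd.DataFrame([_seg("8", 1, 1000, 0.5)]))
    assert "8p" in set(calls["arm"]) and "17p" not in set(calls["arm"])


# ---------------------------------------------------------------- SCNA CCF


@pytest.mark.parametrize(
    "log2, purity, delta, expected",
    [
        (math.log2(3 / 2), 1.0, 1, 1.0),  # fully clonal single-copy gain
        (0.0, 1.0, 1, 0.0),
        (math.log2(2.5 / 2), 1.0, 1, 0.5),
        (math.log2(1.5 / 2), 1.0, -1, 0.5),  # half-clonal single-copy loss
    ],
)
def test_scna_ccf_inverts_ratio_model(log2, purity, delta, expected):
    assert mc.scna_ccf(log2, purity, delta) == pytest.approx(expected)


def test_scna_ccf_roundtrip_generative_model():
    """Zero-noise inversion: ratio built from (purity, f, delta) returns f."""
    for purity in (0.4, 0.6, 1.0):
        for f in (0.2, 0.6, 1.0):
            for delta in (1, -1):
                log2 = math.log2((2 + purity * f * delta) / 2)
                assert mc.scna_ccf(log2, purity, delta) == pytest.approx(f, abs=1e-12)


def test_scna_ccf_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        mc.scna_ccf(0.3, 0.5, 0)
    with pytest.raises(ValueError):
        mc.scna_ccf(0.3, 0.0, 1)


def test_arm_event_status_thresholds():
    assert arm_event_status(0.0, "neutral", 0.6) == "absent"
    assert arm_event_status(math.log2(3 / 2), "amp", 1.0) == "clonal"
    assert arm_event_status(math.log2(2.3 / 2), "amp", 1.0) == "subclonal"


# ---------------------------------------------------------------- enrichment


def hypergeom_tail_oracle(k, n_universe, n_set, n_query):
    """Brute-force P(overlap >= k) by summing hypergeometric terms."""
    total = 0.0
    for i in range(k, min(n_set, n_query) + 1):
        total += (
            math.comb(n_set, i)
            * math.comb(n_universe - n_set, n_query - i)
            / math.comb(n_universe, n_query)
        )
    return total


def test_enrichment_degenerate_full_overlap():
    genes = [f"g{i}" for i in range(5)]
    res = mc.gene_set_enrichment(genes, {"s": genes}, genes)
    assert res.loc[0, "p_value"] == pytest.approx(1.0)


def test_enrichment_nested_in_large_universe():
    universe = [f"g{i}" for i in range(100)]
    genes = universe[:5]
    res = mc.gene_set_enrichment(genes, {"s": universe[:5]}, universe)
    assert res.loc[0, "p_value"] == pytest.approx(1 / math.comb(100, 5))


def test_enrichment_matches_bruteforce_oracle(rng):
    universe = [f"g{i}" for i in range(60)]
    for _ in range(25):
        q = rng.choice(universe, size=rng.integers(3, 15), replace=False).tolist()
        s = rng.choice(universe, size=rng.integers(3, 25), replace=False).tolist()
        res = mc.gene_set_enrichment(q, {"s": s}, universe)
        k = len(set(q) & set(s))
        assert res.loc[0, "overlap"] == k
        assert res.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail_oracle(k, 60, len(s), len(q)), rel=1e-9
        )


def test_enrichment_empty_overlap_large_p(rng):
    universe = [f"g{i}" for i in range(40)]
    res = mc.gene_set_enrichment(universe[:4], {"s": universe[30:34]}, universe)
    assert res.loc[0, "p_value"] >= 0.5
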