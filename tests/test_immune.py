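"""HLA-LOH calling, neoantigen filters, expression rule, HLA-corrected TMB."""

import numpy as np
import pandas as pd
import pytest

import metaclone as mc
from metaclone.immune import HLAAllelePair, add_expression_calls
from metaclone.simulate import simulate_hla_coverage


def _pair(logr1, logr2, purity=0.6):
    return HLAAllelePair("S1", "A", np.asarray(logr1), np.asarray(logr2), purity)


# ---------------------------------------------------------------- LOH rule


def test_loh_requires_both_conditions(rng):
    # strong allelic imbalance, minor CN ~0 -> LOH
    lost = simulate_hla_coverage(1.0, 0.0, 0.8, 20, 300, rng)
    call = mc.call_hla_loh(lost)
    assert call.minor_cn < 0.5 and call.p_value < 0.01 and call.is_loh
    assert call.lost_allele == lost.allele2


def test_no_loh_when_minor_cn_too_high():
    # alleles differ significantly but minor CN stays >= 0.5 (CN 2 vs 1)
    base1 = np.full(20, 1.0) + np.linspace(-0.01, 0.01, 20)
    base2 = np.full(20, 0.263)  # log2(0.6*1 + 0.4) = 0.263 -> CN 1
    call = mc.call_hla_loh(_pair(base1, base2))
    assert call.p_value < 0.01 and call.minor_cn >= 0.5
    assert not call.is_loh


def test_no_loh_when_difference_not_significant():
    rng = np.random.default_rng(1)
    noise = rng.normal(0, 0.5, 20)
    # same noisy bins shifted slightly: minor CN small but p large
    call = mc.call_hla_loh(_pair(-2.0 + noise, -2.0 + noise + rng.normal(0, 0.5, 20)))
    assert call.minor_cn < 0.5
    assert call.p_value >= 0.01
    assert not call.is_loh


def test_unequal_bin_counts_rejected():
    with pytest.raises(ValueError):
        _pair(np.zeros(10), np.zeros(12))


def test_too_few_bins_rejected():
    with pytest.raises(ValueError):
        mc.call_hla_loh(_pair(np.zeros(3), np.zeros(3)))


def test_loh_operating_characteristics(rng):
    """>= 95% detection of true LOH; <= 5% positives on balanced null."""
    n = 200
    detected = sum(
        mc.call_hla_loh(
            simulate_hla_coverage(1.0, 0.0, 0.5, 20, 150, rng, sample=f"s{i}")
        ).is_loh
        for i in range(n)
    )
    false_pos = sum(
        mc.call_hla_loh(
            simulate_hla_coverage(1.0, 1.0, 0.5, 20, 150, rng, sample=f"b{i}")
        ).is_loh
        for i in range(n)
    )
    assert detected / n >= 0.95
    assert false_pos / n <= 0.05


def test_loh_incidence_percentages():
    calls = pd.DataFrame(
        {
            "patient": [f"P{i}" for i in range(1, 16)],
            "is_loh": [True] * 4 + [False] * 11,
        }
    )
    pct, k, n = mc.loh_incidence(calls)
    assert (k, n) == (4, 15)
    assert pct == pytest.approx(100 * 4 / 15)
    with pytest.raises(ValueError):
        mc.loh_incidence(calls.iloc[0:0])


# ---------------------------------------------------------------- depth filters


def _records(rows):
    cols = [
        "dna_normal_depth", "dna_normal_vaf", "dna_tumor_depth", "dna_tumor_vaf",
        "rna_site_depth", "rna_alt_reads",
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.mark.parametrize(
    "row, kept",
    [
        ((4, 0.03, 50, 0.45, 10, 5), False),  # low normal depth + normal VAF >= 2%
        ((30, 0.03, 50, 0.45, 10, 5), True),  # normal deep enough
        ((4, 0.01, 50, 0.45, 10, 5), True),  # normal VAF below 2%
        ((30, 0.0, 8, 0.45, 10, 5), False),  # tumor depth < 10
        ((30, 0.0, 10, 0.40, 10, 5), True),  # tumor cutoffs inclusive
        ((30, 0.0, 50, 0.39, 10, 5), False),  # tumor VAF < 40%
        ((5, 0.02, 50, 0.45, 10, 5), False),  # both normal boundaries inclusive
        ((6, 0.02, 50, 0.45, 10, 5), True),  # normal depth just above cutoff
    ],
)
def test_depth_filter_boundaries(row, kept):
    out = mc.depth_filter_variants(_records([row]))
    assert (len(out) == 1) is kept


def test_depth_filter_strict_mode_uses_higher_cutoff():
    row = (15, 0.03, 50, 0.45, 10, 5)
    assert len(mc.depth_filter_variants(_records([row]))) == 1
    assert len(mc.depth_filter_variants(_records([row]), strict=True)) == 0


def test_depth_filter_idempotent(rng):
    rows = [
        (
            int(rng.integers(0, 40)),
            float(rng.uniform(0, 0.1)),
            int(rng.integers(0, 60)),
            float(rng.uniform(0, 1)),
            10,
            5,
        )
        for _ in range(50)
    ]
    once = mc.depth_filter_variants(_records(rows))
    twice = mc.depth_filter_variants(once)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------- expression


@pytest.mark.parametrize(
    "depth, alt, expected",
    [(5, 3, True), (4, 3, False), (20, 2, False), (5, 2, False), (100, 3, True)],
)
def test_call_expressed_boundaries(depth, alt, expected):
    assert mc.call_expressed(depth, alt) is expected


def test_call_expressed_missing_rna_is_unknown():
    assert mc.call_expressed(float("nan"), 0) is None


# ---------------------------------------------------------------- summary


def _neo(sample, n, n_nonexpr, clonal=True):
    rows = []
    for i in range(n):
        expressed = i >= n_nonexpr
        rows.append(
            {
                "sample": sample,
                "variant_key": f"{sample}:v{i}",
                "clonality": "clonal" if clonal else "subclonal",
                "rna_site_depth": 50 if expressed else 2,
                "rna_alt_reads": 10 if expressed else 0,
            }
        )
    return pd.DataFrame(rows)


def test_summary_perfect_correlation_when_nonexpressed_tracks_total():
    records = add_expression_calls(
        pd.concat([_neo("a", 10, 10), _neo("b", 20, 20), _neo("c", 5, 5)])
    )
    table, r = mc.neoantigen_summary(records)
    assert (table["n_non_expressed"] == table["n_total"]).all()
    assert r == pytest.approx(1.0)


def test_summary_correlation_undefined_for_constant_totals():
    records = add_expression_calls(
        pd.concat([_neo("a", 10, 4), _neo("b", 10, 7), _neo("c", 10, 2)])
    )
    _, r = mc.neoantigen_summary(records)
    assert r is None


def test_summary_correlation_matches_closed_form(rng):
    frames = []
    totals, nonexpr = [], []
    for i, n in enumerate([8, 15, 22, 30, 12]):
        k = int(rng.integers(0, n + 1))
        frames.append(_neo(f"s{i}", n, k))
        totals.append(n)
        nonexpr.append(k)
    table, r = mc.neoantigen_summary(add_expression_calls(pd.concat(frames)))
    expected = np.corrcoef(totals, nonexpr)[0, 1]
    assert r == pytest.approx(expected)


def test_summary_too_few_samples_no_correlation():
    records = add_expression_calls(pd.concat([_neo("a", 5, 2), _neo("b", 9, 3)]))
    _, r = mc.neoantigen_summary(records)
    assert r is None


# ---------------------------------------------------------------- corrected TMB


def _muts(n, sample="S1", clonal_frac=0.5):
    return pd.DataFrame(
        {
            "sample": sample,
            "variant_key": [f"k{i}" for i in range(n)],
            "clonality": ["clonal" if i < n * clonal_frac else "subclonal" for i in range(n)],
        }
    )


def _binder_rows(keys, allele, rank=0.5):
    return pd.DataFrame(
        {"variant_key": list(keys), "allele": allele, "binding_rank": rank}
    )


def test_corrected_tmb_no_loh_equals_total():
    report = mc.hla_corrected_tmb(_muts(10), _binder_rows([f"k{i}" for i in range(10)], "HLA-A*01"), [])
    assert report.tmb_hla_corrected == report.tmb_total == 10
    assert report.tmb_clonal + report.tmb_subclonal == report.tmb_total


def test_corrected_tmb_all_bind_only_lost_allele():
    loh = [
        mc.LOHCall("S1", "A", 1.0, 0.1, 0.1, 1e-4, True, "HLA-A*01"),
    ]
    report = mc.hla_corrected_tmb(
        _muts(10), _binder_rows([f"k{i}" for i in range(10)], "HLA-A*01"), loh
    )
    assert report.tmb_hla_corrected == 0


def test_corrected_tmb_mixed_enumeration():
    """10 mutations, 3 bind only the lost allele -> corrected = 7."""
    loh = [mc.LOHCall("S1", "A", 1.0, 0.1, 0.1, 1e-4, True, "HLA-A*01")]
    neo = pd.concat(
        [
            _binder_rows(["k0", "k1", "k2"], "HLA-A*01"),  # only lost allele
            _binder_rows(["k3", "k4"], "HLA-A*01"),
            _binder_rows(["k3", "k4"], "HLA-B*02"),  # also an intact binder
            _binder_rows(["k5"], "HLA-B*02"),
            _binder_rows(["k6"], "HLA-A*01", rank=10.0),  # too weak to bind
        ]
    )
    report = mc.hla_corrected_tmb(_muts(10), neo, loh)
    assert report.tmb_total == 10
    assert report.tmb_hla_corrected == 7


def test_tmb_invariants_on_synthetic_cohort(small_cohort):
    _, tables = small_cohort
    muts = mc.add_ccf_columns(tables["mutations"])
    muts["variant_key"] = (
        muts.chrom.astype(str) + ":" + muts.pos.astype(str) + ":" + muts.ref + ":" + muts.alt
    )
    for sample, grp in muts.groupby("sample"):
        neo = tables["neoantigens"]
        report = mc.hla_corrected_tmb(grp, neo[neo["sample"] == sample], [])
        assert report.tmb_clonal + report.tmb_subclonal == report.tmb_total
        assert report.tmb_hla_corrected <= report.tmb_total
        assert report.per_megabase() == pytest.approx(report.tmb_total / 53.0)
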