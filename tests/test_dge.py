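"""Differential-expression contracts: normalisation, dispersion, Wald test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import revertome as rv
from revertome.dge import (
    Contrast,
    bh_adjust,
    deg_set,
    estimate_dispersion,
    size_factors,
)
from revertome.dge import test_contrast as nb_wald_test
from conftest import bh_oracle


# ---------------------------------------------------------------- size factors


def test_size_factors_identical_columns():
    mat = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
    np.testing.assert_allclose(size_factors(mat), 1.0)


def test_size_factors_doubled_column():
    mat = pd.DataFrame({"a": [5, 10, 20], "b": [10, 20, 40]})
    sf = size_factors(mat)
    assert sf["b"] / sf["a"] == pytest.approx(2.0)
    assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)


def test_size_factors_median_of_ratios_oracle():
    mat = pd.DataFrame(
        {"a": [10, 20, 40, 100], "b": [20, 10, 80, 100], "c": [10, 20, 40, 50]}
    )
    # oracle: gene-wise geometric means, per-sample median ratio, gmean-1 scale
    gm = np.exp(np.log(mat.to_numpy()).mean(axis=1))
    raw = np.median(mat.to_numpy() / gm[:, None], axis=0)
    expected = raw / np.exp(np.mean(np.log(raw)))
    np.testing.assert_allclose(size_factors(mat), expected)


def test_size_factors_fallback_total_count():
    mat = pd.DataFrame({"a": [0, 10], "b": [5, 0]})
    with pytest.warns(UserWarning, match="total-count"):
        sf = size_factors(mat)
    assert sf["a"] == pytest.approx(np.sqrt(10 / 5) * np.sqrt(5 / 10) * np.sqrt(2))


# ------------------------------------------------------------------ dispersion


def _two_group_design(n):
    samples = [f"A_{i}" for i in range(n)] + [f"B_{i}" for i in range(n)]
    return pd.DataFrame(
        {"condition": ["A"] * n + ["B"] * n, "replicate": list(range(1, n + 1)) * 2},
        index=pd.Index(samples, name="sample_id"),
    )


def _nb_counts(rng, mu, alpha, n_genes, n_samples):
    if alpha == 0:
        x = rng.poisson(mu, size=(n_genes, n_samples))
    else:
        size = 1 / alpha
        x = rng.negative_binomial(size, size / (size + mu), size=(n_genes, n_samples))
    design = _two_group_design(n_samples // 2)
    return pd.DataFrame(x, columns=design.index), design


def test_dispersion_poisson_data_near_zero():
    rng = np.random.default_rng(0)
    counts, design = _nb_counts(rng, 100.0, 0.0, 2000, 4)
    alpha = estimate_dispersion(counts, design, ("A", "B"))
    assert np.median(alpha) < 0.05


def test_dispersion_recovers_common_alpha():
    rng = np.random.default_rng(1)
    counts, design = _nb_counts(rng, 100.0, 0.2, 2000, 4)
    alpha = estimate_dispersion(counts, design, ("A", "B"))
    assert 0.1 < np.median(alpha) < 0.4


def test_dispersion_all_zero_gene_gets_common():
    rng = np.random.default_rng(2)
    counts, design = _nb_counts(rng, 100.0, 0.1, 500, 4)
    counts.iloc[0] = 0
    alpha = estimate_dispersion(counts, design, ("A", "B"))
    others = estimate_dispersion(counts.iloc[1:], design, ("A", "B"))
    # the degenerate gene sits at the common value, inside the others' range
    assert others.min() - 1e-9 <= alpha.iloc[0] <= others.max() + 1e-9


# ----------------------------------------------------------------- wald test


def test_contrast_identical_groups_null():
    counts = pd.DataFrame(
        {"A_0": [10, 50], "A_1": [20, 40], "B_0": [10, 50], "B_1": [20, 40]}
    )
    design = _two_group_design(2)
    res = nb_wald_test(counts, design, Contrast("t", "A", "B"))
    np.testing.assert_allclose(res.table["log2fc"], 0, atol=1e-12)
    np.testing.assert_allclose(res.table["p"], 1.0)


def test_contrast_symmetry():
    rng = np.random.default_rng(3)
    counts, design = _nb_counts(rng, 200.0, 0.05, 300, 4)
    fwd = nb_wald_test(counts, design, Contrast("f", "A", "B"))
    rev = nb_wald_test(counts, design, Contrast("r", "B", "A"))
    np.testing.assert_allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-12)
    np.testing.assert_allclose(fwd.table["p"], rev.table["p"], atol=1e-12)


def test_contrast_unknown_condition_errors():
    counts, design = _nb_counts(np.random.default_rng(4), 100.0, 0.05, 10, 4)
    with pytest.raises(ValueError, match="not found"):
        nb_wald_test(counts, design, Contrast("bad", "A", "Z"))


def test_contrast_untested_zero_genes():
    counts = pd.DataFrame(
        {"A_0": [0, 10], "A_1": [0, 12], "B_0": [0, 9], "B_1": [0, 11]}
    )
    design = _two_group_design(2)
    res = nb_wald_test(counts, design, Contrast("t", "A", "B"))
    assert not res.table["tested"].iloc[0]
    assert np.isnan(res.table.loc[res.table.index[0], "p"])
    assert res.table["tested"].iloc[1]


def test_planted_effect_recovery_small():
    """Planted 2-log2 shift is recovered on average (small-scale check)."""
    cfg = rv.SimConfig(
        n_genes=2000,
        n_reps=6,
        seed=9,
        class_proportions={"null": 0.9, "up_not_reversed": 0.1},
        base_mean_range=(200, 200),
        effect_log2fc=2.0,
        dispersion=0.05,
    )
    cm, truth = rv.generate(cfg)
    res = nb_wald_test(cm.counts, cm.design, Contrast("A", "A", "control"))
    planted = truth["class_label"] == "up_not_reversed"
    assert res.table.loc[planted, "log2fc"].mean() == pytest.approx(2.0, abs=0.15)


def test_deg_set_nesting_and_recall(small_sim):
    _, cm, truth = small_sim
    res = nb_wald_test(cm.counts, cm.design, Contrast("A", "A", "control"))
    fdr1 = deg_set(res, 0.01)
    fdr5 = deg_set(res, 0.05)
    assert set(fdr1.index) <= set(fdr5.index)
    assert set(fdr5.index) == set(deg_set(res, 1.0).index) - set(
        res.table.index[res.table["log2fc"] == 0]
    ) or set(fdr5.index) <= set(res.table.index)
    planted_up = truth.index[truth["class_label"] == "up_reversed"]
    recall = len(set(fdr5.index) & set(planted_up)) / len(planted_up)
    assert recall >= 0.8
    assert (fdr5.loc[fdr5.index.intersection(planted_up)] == 1).mean() > 0.95


def test_deg_set_trivial_thresholds():
    counts, design = _nb_counts(np.random.default_rng(5), 100.0, 0.05, 50, 4)
    res = nb_wald_test(counts, design, Contrast("t", "A", "B"))
    all_set = deg_set(res, 1.0)
    assert set(all_set.index) == set(
        res.table.index[res.table["tested"] & (res.table["log2fc"] != 0)]
    )


# -------------------------------------------------------------------- BH FDR


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError, match="missing"):
        bh_adjust([0.5, np.nan])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
)
def test_bh_matches_brute_force_oracle(p):
    p = np.array(p)
    np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(6)
    p = rng.uniform(size=500)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_adjust(p), q, atol=1e-12)


def test_bh_monotone_in_sorted_order():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=100)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# ------------------------------------------------- independent DGE cross-check


def test_lfc_agrees_with_pydeseq2():
    """Cross-check fold changes against an independent NB GLM implementation."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = rv.SimConfig(
        n_genes=400,
        n_reps=4,
        seed=13,
        class_proportions={"null": 0.8, "up_reversed": 0.1, "down_reversed": 0.1},
        effect_log2fc=2.0,
        dispersion=0.05,
        base_mean_range=(50, 500),
    )
    cm, truth = rv.generate(cfg)
    cols = cm.samples_for("control") + cm.samples_for("A")
    meta = cm.design.loc[cols, ["condition"]]
    dds = DeseqDataSet(
        counts=cm.counts[cols].T, metadata=meta, design="~condition", quiet=True
    )
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "A", "control"], quiet=True)
    stats.summary()
    ours = nb_wald_test(cm.counts, cm.design, Contrast("A", "A", "control"))
    merged = pd.DataFrame(
        {"ours": ours.table["log2fc"], "ref": stats.results_df["log2FoldChange"]}
    ).dropna()
    r = np.corrcoef(merged["ours"], merged["ref"])[0, 1]
    assert r > 0.9
    planted = truth["class_label"] != "null"
    assert np.corrcoef(
        merged.loc[planted, "ours"], merged.loc[planted, "ref"]
    )[0, 1] > 0.98
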