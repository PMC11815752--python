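"""Compositional summaries, diversity, and exact nonparametric tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from residose.microbiota import (
    TaxaTable,
    bray_curtis,
    collapse_to_level,
    fb_ratio,
    group_composition,
    load_taxa_table,
    mann_whitney_u,
    observed,
    relative_abundance,
    shannon,
    beta_diversity_matrix,
    wilcoxon_signed_rank,
    write_taxa_table,
)


def make_table(counts, taxonomy=None, meta=None):
    counts = pd.DataFrame(counts).T if isinstance(counts, dict) else counts
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {lvl: list(counts.columns) for lvl in ("phylum", "class", "family", "genus")},
            index=counts.columns,
        )
    if meta is None:
        meta = pd.DataFrame(
            {"group": "g", "sex": "female", "time_point": "T0",
             "animal_id": list(counts.index)},
            index=counts.index,
        )
    return TaxaTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


# --------------------------------------------------------------- composition


def test_relative_abundance_closure():
    t = make_table({"s1": {"A": 60, "B": 40}, "s2": {"A": 1, "B": 0}})
    rel = relative_abundance(t)
    assert rel.loc["s1", "A"] == pytest.approx(0.6)
    assert rel.loc["s1", "B"] == pytest.approx(0.4)
    assert rel.loc["s2", "A"] == pytest.approx(1.0)
    assert rel.sum(axis=1).to_numpy() == pytest.approx(np.ones(2))


def test_relative_abundance_random_closure():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 100, (10, 6)),
                          index=[f"s{i}" for i in range(10)],
                          columns=list("ABCDEF"))
    counts.iloc[0] += 1  # guard against an all-zero row
    t = make_table(counts)
    rel = relative_abundance(t)
    assert np.allclose(rel.sum(axis=1), 1.0)


def test_zero_sum_sample_excluded_with_warning(caplog):
    t = make_table({"s1": {"A": 5, "B": 5}, "s2": {"A": 0, "B": 0}})
    with caplog.at_level("WARNING"):
        rel = relative_abundance(t)
    assert "s2" not in rel.index and "zero-sum" in caplog.text


def test_collapse_conserves_totals():
    counts = pd.DataFrame(
        [[10, 20, 5], [1, 2, 3]], index=["s1", "s2"], columns=["t1", "t2", "t3"]
    )
    tax = pd.DataFrame(
        {
            "phylum": ["Firmicutes", "Firmicutes", "Bacteroidota"],
            "class": ["Clostridia", "Clostridia", "Bacteroidia"],
            "family": ["Lachnospiraceae", "Lachnospiraceae", "Muribaculaceae"],
            "genus": ["Blautia", "Roseburia", "Muribaculum"],
        },
        index=["t1", "t2", "t3"],
    )
    t = make_table(counts, taxonomy=tax)
    ph = collapse_to_level(t, "phylum")
    assert set(ph.counts.columns) == {"Firmicutes", "Bacteroidota"}
    assert ph.counts.loc["s1", "Firmicutes"] == 30
    assert (ph.counts.sum(axis=1) == counts.sum(axis=1)).all()


def test_collapse_single_phylum_to_one_column():
    counts = pd.DataFrame([[3, 4]], index=["s1"], columns=["t1", "t2"])
    tax = pd.DataFrame(
        {"phylum": ["P", "P"], "class": ["c", "c"], "family": ["f", "f"],
         "genus": ["g1", "g2"]},
        index=["t1", "t2"],
    )
    ph = collapse_to_level(make_table(counts, taxonomy=tax), "phylum")
    assert list(ph.counts.columns) == ["P"]
    assert ph.counts.loc["s1", "P"] == 7


def test_unclassified_genera_collapse_to_family_label(tmp_path):
    """Two ASVs of one family without genus labels merge into a single
    'unclassified <family>' genus."""
    p = tmp_path / "taxa.tsv"
    p.write_text(
        "taxon_id\ts1\ttaxonomy\n"
        "asv1\t10\tFirmicutes;Clostridia;Lachnospiraceae;\n"
        "asv2\t5\tFirmicutes;Clostridia;Lachnospiraceae;\n"
        "asv3\t2\tFirmicutes;Clostridia;Lachnospiraceae;Blautia\n"
    )
    m = tmp_path / "meta.tsv"
    m.write_text("sample_id\tgroup\tsex\ttime_point\tanimal_id\ns1\tg\tfemale\tT0\ta1\n")
    t = load_taxa_table(p, m)
    g = collapse_to_level(t, "genus")
    assert g.counts.loc["s1", "unclassified Lachnospiraceae"] == 15
    assert g.counts.loc["s1", "Blautia"] == 2


def test_group_composition_identical_samples_sd_zero():
    counts = pd.DataFrame([[50, 50], [50, 50]], index=["s1", "s2"], columns=["A", "B"])
    cs = group_composition(make_table(counts), threshold=0.0)
    assert cs.means.loc["g", "A"] == pytest.approx(50.0)
    assert (cs.sds.to_numpy() == 0).all()


def test_group_composition_threshold_pools_rare_taxa():
    counts = pd.DataFrame([[98, 1, 1]], index=["s1"], columns=["A", "B", "C"])
    cs = group_composition(make_table(counts), threshold=1.0)
    assert "other" in cs.means.columns
    assert cs.means.loc["g", "other"] == pytest.approx(2.0)
    assert "B" not in cs.means.columns


def test_group_composition_no_threshold_sums_to_100():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(1, 100, (6, 5)),
                          index=[f"s{i}" for i in range(6)], columns=list("ABCDE"))
    cs = group_composition(make_table(counts), threshold=0.0)
    assert cs.means.sum(axis=1).to_numpy() == pytest.approx([100.0])


def test_group_of_one_warns_sd_zero(caplog):
    counts = pd.DataFrame([[60, 40]], index=["s1"], columns=["A", "B"])
    with caplog.at_level("WARNING"):
        cs = group_composition(make_table(counts), threshold=0.0)
    assert (cs.sds.to_numpy() == 0).all()
    assert "size 1" in caplog.text


# ------------------------------------------------------------------ F/B ratio


def test_fb_ratio_equal_proportions():
    assert fb_ratio({"Firmicutes": 0.5, "Bacteroidota": 0.5}) == pytest.approx(1.0)


def test_fb_ratio_published_control_means():
    assert fb_ratio({"Firmicutes": 48.1, "Bacteroidota": 47.28}) == pytest.approx(
        1.017, abs=5e-4
    )


def test_fb_ratio_synonyms_and_scale_invariance():
    r1 = fb_ratio({"Bacillota": 30, "Bacteroidetes": 20})
    r2 = fb_ratio({"Firmicutes": 0.3, "Bacteroidota": 0.2})
    assert r1 == pytest.approx(r2)


def test_fb_ratio_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        fb_ratio({"Firmicutes": 1.0, "Bacteroidota": 0.0})


def test_fb_ratio_missing_phylum():
    with pytest.raises(ValueError):
        fb_ratio({"Firmicutes": 1.0})


# ------------------------------------------------------------------ diversity


def test_shannon_uniform_closed_form():
    assert shannon([25, 25, 25, 25]) == pytest.approx(math.log(4))
    assert shannon([1.0]) == 0.0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=12))
def test_shannon_maximal_at_uniform(abundances):
    assert shannon(abundances) <= math.log(len(abundances)) + 1e-9


def test_observed_richness():
    assert observed([5, 0, 1, 0]) == 2
    assert observed([0, 0]) == 0


def test_bray_curtis_boundaries():
    assert bray_curtis([3, 4], [3, 4]) == pytest.approx(0.0)
    assert bray_curtis([5, 0], [0, 7]) == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        bray_curtis([0, 0], [0, 0])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
    st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
)
def test_bray_curtis_symmetric_and_bounded(a, b):
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    if sum(a) + sum(b) == 0:
        return
    d = bray_curtis(a, b)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(bray_curtis(b, a))


def test_beta_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(rng.integers(1, 50, (5, 4)),
                          index=[f"s{i}" for i in range(5)], columns=list("ABCD"))
    beta = beta_diversity_matrix(make_table(counts))
    arr = beta.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0.0)
    assert (arr >= 0).all() and (arr <= 1).all()


# ---------------------------------------------------- exact tests vs oracles


def oracle_wilcoxon(a, b):
    """Brute force: every sign assignment of the nonzero differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2
    dist = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product((1, -1), repeat=len(d))
    ]
    return np.mean([abs(w - center) >= abs(w_obs - center) - 1e-9 for w in dist])


def oracle_mwu(a, b):
    """Brute force: every labeling; U counted by pairwise wins (not rank sums)."""
    a, b = list(a), list(b)
    n = len(a)
    pooled = a + b

    def u_stat(x, y):
        return sum(
            (1.0 if xi > yi else 0.5 if xi == yi else 0.0) for xi in x for yi in y
        )

    u_obs = u_stat(a, b)
    center = n * len(b) / 2
    dists = []
    idx = set(range(len(pooled)))
    for comb in itertools.combinations(range(len(pooled)), n):
        x = [pooled[i] for i in comb]
        y = [pooled[i] for i in idx - set(comb)]
        dists.append(u_stat(x, y))
    return np.mean([abs(u - center) >= abs(u_obs - center) - 1e-9 for u in dists])


def test_mwu_textbook_example():
    """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1."""
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.mode == "exact"


def test_wilcoxon_symmetric_null_p_one():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = a[::-1]  # differences symmetric around zero
    res = wilcoxon_signed_rank(a, b)
    assert res.mode == "exact"
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_all_zero_differences_convention():
    res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(8))
def test_exact_tests_equal_enumeration_oracle(seed):
    """Exact p-values match brute-force enumeration for n <= 8, ties included."""
    rng = np.random.default_rng(seed)
    n, m = rng.integers(3, 9), rng.integers(3, 9)
    a = rng.integers(0, 6, n).astype(float)  # small ints force ties
    b = rng.integers(0, 6, m).astype(float)
    res = mann_whitney_u(a, b)
    assert res.mode == "exact"
    assert res.p_value == pytest.approx(oracle_mwu(a, b))

    k = int(rng.integers(3, 9))
    x = rng.integers(0, 6, k).astype(float)
    y = rng.integers(0, 6, k).astype(float)
    if np.any(x != y):
        resw = wilcoxon_signed_rank(x, y)
        assert resw.mode == "exact"
        assert resw.p_value == pytest.approx(oracle_wilcoxon(x, y))


@pytest.mark.parametrize("seed", range(4))
def test_exact_tests_match_scipy_on_tie_free_data(seed):
    """Independent cross-check: classical doubled-tail exact p (scipy)
    coincides with the enumeration on tie-free inputs."""
    rng = np.random.default_rng(100 + seed)
    a = rng.normal(0, 1, 6)
    b = rng.normal(0.5, 1, 7)
    res = mann_whitney_u(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert res.p_value == pytest.approx(ref.pvalue)

    x = rng.normal(0, 1, 7)
    y = rng.normal(0.3, 1, 7)
    resw = wilcoxon_signed_rank(x, y)
    refw = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
    assert resw.p_value == pytest.approx(refw.pvalue)


def test_exact_and_approximate_agree_for_moderate_n():
    rng = np.random.default_rng(11)
    a = rng.normal(0, 1, 20)
    b = rng.normal(0.4, 1, 20)
    exact = mann_whitney_u(a, b, exact_limit=20)
    approx = mann_whitney_u(a, b, exact_limit=5)
    assert exact.mode == "exact" and approx.mode == "approximate"
    assert abs(exact.p_value - approx.p_value) < 0.02

    x = rng.normal(0, 1, 20)
    y = x + rng.normal(0.3, 0.8, 20)
    we = wilcoxon_signed_rank(x, y, exact_limit=20)
    wa = wilcoxon_signed_rank(x, y, exact_limit=5)
    assert we.mode == "exact" and wa.mode == "approximate"
    assert abs(we.p_value - wa.p_value) < 0.02


# ----------------------------------------------------------------------- I/O


def test_taxa_table_round_trip(tmp_path):
    counts = pd.DataFrame([[10, 5], [2, 8]], index=["s1", "s2"], columns=["t1", "t2"])
    tax = pd.DataFrame(
        {"phylum": ["P1", "P2"], "class": ["c1", "c2"], "family": ["f1", "f2"],
         "genus": ["g1", "g2"]},
        index=["t1", "t2"],
    )
    meta = pd.DataFrame(
        {"group": ["a", "b"], "sex": ["male", "male"],
         "time_point": ["T0", "T0"], "animal_id": ["m1", "m2"]},
        index=["s1", "s2"],
    )
    t = TaxaTable(counts, tax, meta)
    write_taxa_table(t, tmp_path / "taxa.tsv", tmp_path / "meta.tsv")
    t2 = load_taxa_table(tmp_path / "taxa.tsv", tmp_path / "meta.tsv")
    pd.testing.assert_frame_equal(
        t2.counts.sort_index(axis=1), counts.sort_index(axis=1), check_dtype=False
    )
    assert t2.taxonomy.loc["t1", "genus"] == "g1"
    assert t2.sample_meta.loc["s2", "group"] == "b"


def test_taxa_without_taxonomy_rejected():
    counts = pd.DataFrame([[1, 2]], index=["s1"], columns=["t1", "t2"])
    tax = pd.DataFrame({"phylum": ["P"], "class": ["c"], "family": ["f"],
                        "genus": ["g"]}, index=["t1"])
    meta = pd.DataFrame({"group": ["g"], "sex": ["male"], "time_point": ["T0"],
                         "animal_id": ["a"]}, index=["s1"])
    with pytest.raises(ValueError, match="taxonomy"):
        TaxaTable(counts, tax, meta)
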