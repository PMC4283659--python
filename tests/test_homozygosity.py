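import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplohom import (
    GroupAssignment,
    PanelError,
    all_pairs,
    chromosome_correlation,
    expected_homozygosity,
    pair_homozygosity,
    summarize,
)
from haplohom.synthetic_data import build_panel, calibrate

from conftest import PANEL_SIZES, random_matrix


@pytest.mark.parametrize(
    "h1, h2, expected",
    [
        ([0, 1, 0, 1], [0, 1, 0, 1], 1.0),
        ([0, 1, 0, 1], [1, 0, 1, 0], 0.0),
        ([0, 1, 0, 1], [0, 1, 1, 1], 0.75),
    ],
)
def test_pair_homozygosity_examples(h1, h2, expected):
    assert pair_homozygosity(np.array(h1), np.array(h2)) == expected
    assert pair_homozygosity(np.array(h2), np.array(h1)) == expected


def test_pair_homozygosity_length_mismatch():
    with pytest.raises(PanelError):
        pair_homozygosity(np.zeros(3), np.zeros(4))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), L=st.integers(1, 100))
def test_homozygosity_is_one_minus_hamming(seed, L):
    """Oracle equivalence with naive per-site counting on random vectors."""
    rng = np.random.default_rng(seed)
    h1 = rng.integers(0, 2, L)
    h2 = rng.integers(0, 2, L)
    naive = sum(int(a == b) for a, b in zip(h1, h2)) / L
    hamming = np.count_nonzero(h1 != h2)
    assert pair_homozygosity(h1, h2) == pytest.approx(naive)
    assert pair_homozygosity(h1, h2) == pytest.approx(1 - hamming / L)


def test_pooling_over_site_blocks():
    """Homozygosity of concatenated blocks is the length-weighted mean."""
    rng = np.random.default_rng(5)
    a1, a2 = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
    b1, b2 = rng.integers(0, 2, 70), rng.integers(0, 2, 70)
    whole = pair_homozygosity(np.concatenate([a1, b1]), np.concatenate([a2, b2]))
    blockwise = 0.3 * pair_homozygosity(a1, a2) + 0.7 * pair_homozygosity(b1, b2)
    assert whole == pytest.approx(blockwise)


def _group_map(m, group="EuropeanWild"):
    return GroupAssignment.from_pairs({h: group for h in m.haplotype_ids})


def test_all_pairs_counts_within():
    m = random_matrix(np.random.default_rng(6), n_individuals=2, n_sites=20)
    ga = _group_map(m)
    t = all_pairs(m, ga, within="EuropeanWild")
    assert len(t) == 6  # C(4,2)
    t_excl = all_pairs(m, ga, within="EuropeanWild", include_within_individual=False)
    assert len(t_excl) == 4  # minus the 2 same-individual pairs
    assert (t_excl["individual_1"] != t_excl["individual_2"]).all()
    # each unordered pair once, canonical order
    assert (t["hap_id_1"] < t["hap_id_2"]).all()


def test_all_pairs_counts_between():
    m_full = random_matrix(np.random.default_rng(7), n_individuals=8, n_sites=20)
    ga = GroupAssignment.from_pairs(
        {
            h: ("EuropeanWild" if h[1] in "0123" else "AsianWild")
            for h in m_full.haplotype_ids
        }
    )
    # 3 wild and 5 asian haplotypes present in the panel
    m = m_full.subset_haplotypes(
        ["i0_A", "i0_B", "i1_A", "i4_A", "i4_B", "i5_A", "i5_B", "i6_A"]
    )
    t = all_pairs(m, ga, between=("EuropeanWild", "AsianWild"))
    assert len(t) == 15  # 3 x 5
    with pytest.raises(PanelError):
        all_pairs(m, ga, within="NoSuchGroup")


def test_summarize_basics():
    base = dict(
        hap_id_1="a_A", hap_id_2="b_A", individual_1="a", individual_2="b",
        group_1="EuropeanWild", group_2="EuropeanWild", chromosome="1", n_sites=10,
    )
    single = pd.DataFrame([{**base, "homozygosity": 0.9}])
    s = summarize(single)
    assert s.mean == s.median == s.min == s.max == 0.9
    assert s.n_pairs == 1 and s.bin_counts.sum() == 1
    two = pd.DataFrame([{**base, "homozygosity": 0.8}, {**base, "homozygosity": 1.0}])
    assert summarize(two).mean == pytest.approx(0.9)
    with pytest.raises(PanelError):
        summarize(two.iloc[:0])


def test_group_means_match_generator_expectation(calibrated_panel):
    """Pooled within-group mean sits on the generator's closed form."""
    config, m, ga, _ = calibrated_panel
    t = all_pairs(m, ga, within="EuropeanWild", include_within_individual=False)
    expected = expected_homozygosity(config, "EuropeanWild", "EuropeanWild")
    assert summarize(t).mean == pytest.approx(expected, abs=0.005)


def test_group_ordering_matches_demography(calibrated_panel):
    """Bottlenecked wild Europe > diverse Asia within groups; between-continent lowest."""
    _, m, ga, _ = calibrated_panel
    within_euw = all_pairs(m, ga, within="EuropeanWild")["homozygosity"].mean()
    within_asw = all_pairs(m, ga, within="AsianWild")["homozygosity"].mean()
    cross = all_pairs(m, ga, between=("EuropeanWild", "AsianWild"))["homozygosity"].mean()
    assert within_euw > within_asw > cross


def test_chromosome_correlation_identity(calibrated_panel):
    _, m, ga, _ = calibrated_panel
    t = all_pairs(m, ga, within="EuropeanWild")
    corr = chromosome_correlation(t, t)
    assert corr.r == pytest.approx(1.0)
    assert len(corr.outlier_pairs) == 0 and corr.flagged_individuals == []


def test_chromosome_correlation_flags_shifted_pair(calibrated_panel):
    _, m, ga, _ = calibrated_panel
    t = all_pairs(m, ga, within="EuropeanWild")
    shifted = t.copy()
    shifted.loc[0, "homozygosity"] -= 0.1
    corr = chromosome_correlation(t, shifted)
    flagged = corr.outlier_pairs
    assert len(flagged) == 1
    assert flagged.loc[0, "hap_id_1"] == t.loc[0, "hap_id_1"]
    assert flagged.loc[0, "hap_id_2"] == t.loc[0, "hap_id_2"]


def test_chromosome_correlation_flags_individual(calibrated_panel):
    """Shift every pair of one individual: the individual is flagged."""
    _, m, ga, _ = calibrated_panel
    t = all_pairs(m, ga)
    ind = "EUW01"
    shifted = t.copy()
    sel = (shifted["individual_1"] == ind) | (shifted["individual_2"] == ind)
    shifted.loc[sel, "homozygosity"] -= 0.08
    corr = chromosome_correlation(t, shifted)
    assert ind in corr.flagged_individuals


def test_two_chromosomes_shared_demography_correlate():
    """Same individuals, independent sites on two chromosomes: r > 0.95."""
    sizes = {"EuropeanWild": 12, "AsianCommercial": 12, "AsianWild": 8}
    tables = []
    for chrom in ("1", "2"):
        config = calibrate(
            seed=21, L=8_000, sample_sizes=dict(sizes), chromosome=chrom
        )
        m, ga, _ = build_panel(config)
        tables.append(all_pairs(m, ga))
    corr = chromosome_correlation(*tables)
    assert corr.n_pairs == len(tables[0])
    assert corr.r > 0.95


def test_chromosome_correlation_needs_matches():
    cols = ["hap_id_1", "hap_id_2", "individual_1", "individual_2", "homozygosity"]
    t = pd.DataFrame([["a_A", "b_A", "a", "b", 0.9]], columns=cols)
    with pytest.raises(PanelError):
        chromosome_correlation(t, t)
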