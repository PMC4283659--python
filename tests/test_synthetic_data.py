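import numpy as np
import pytest

from haplohom import (
    CalibrationTargets,
    GeneratorConfig,
    PanelError,
    all_pairs,
    build_panel,
    calibrate,
    expected_homozygosity,
    sample_haplotypes,
    sample_population_frequencies,
)
from haplohom.synthetic_data import (
    DEFAULT_TARGETS,
    drift_frequencies,
    sample_ancestral_frequencies,
)


def test_no_drift_limit_returns_ancestral_draws():
    rng = np.random.default_rng(0)
    p_bar = sample_ancestral_frequencies(0.0875, 1000, rng)
    np.testing.assert_array_equal(drift_frequencies(p_bar, 0.0, rng), p_bar)


def test_balding_nichols_heterozygosity_moment():
    """E[p(1-p)] = (1-F) * theta over many sites (closed-form moment)."""
    theta, F = 0.0875, 0.6
    p = sample_population_frequencies(theta, F, 100_000, seed=1)
    got = np.mean(p * (1 - p))
    assert got == pytest.approx((1 - F) * theta, rel=0.02)


def test_ancestral_moment_matches_theta():
    rng = np.random.default_rng(2)
    for theta in (0.05, 0.0875, 0.2):
        p = sample_ancestral_frequencies(theta, 200_000, rng)
        assert np.mean(p * (1 - p)) == pytest.approx(theta, rel=0.02)


def test_high_drift_concentrates_at_fixation():
    p = sample_population_frequencies(0.0875, 0.995, 20_000, seed=3)
    assert np.mean((p < 0.01) | (p > 0.99)) > 0.9
    with pytest.raises(PanelError):
        drift_frequencies(np.array([0.5]), 1.0, np.random.default_rng(0))


def test_haplotype_sampling_frequencies():
    rng = np.random.default_rng(4)
    freqs = rng.uniform(0.05, 0.95, 200)
    haps = sample_haplotypes(freqs, 10_000, seed=5)
    emp = haps.mean(axis=0)
    se = np.sqrt(freqs * (1 - freqs) / 10_000)
    assert np.all(np.abs(emp - freqs) < 4 * se + 1e-9)
    assert np.array_equal(sample_haplotypes(np.zeros(50), 4, seed=0), np.zeros((4, 50)))


def test_ld_blocks_induce_adjacent_correlation():
    rng = np.random.default_rng(6)
    freqs = rng.uniform(0.2, 0.8, 2_000)

    def adjacent_r2(haps):
        # mean squared correlation between neighboring sites (LD r^2);
        # the signed correlation averages to zero even under strong LD
        a = haps[:, :-1].astype(float)
        b = haps[:, 1:].astype(float)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        denom = (ac**2).sum(axis=0) * (bc**2).sum(axis=0)
        ok = denom > 0
        return np.mean((ac * bc).sum(axis=0)[ok] ** 2 / denom[ok])

    indep = sample_haplotypes(freqs, 200, ld_block_sites=0, seed=7)
    linked = sample_haplotypes(freqs, 200, ld_block_sites=50, seed=7)
    assert adjacent_r2(linked) > 5 * adjacent_r2(indep)
    # copying is unbiased: frequencies preserved in expectation (per-site
    # spread is wider than binomial because blocks share few founders)
    assert abs((linked.mean(axis=0) - freqs).mean()) < 0.01


@pytest.mark.parametrize(
    "target, kind, expected",
    [
        (0.825, "theta", 0.0875),
        (0.941, "F:EuropeanWild", 0.6629),
        (0.84, "F:AsianWild", 0.0857),
    ],
)
def test_calibration_inverts_printed_means(target, kind, expected):
    """Algebraic inversion of the closed forms hits the known coefficients."""
    config = calibrate(DEFAULT_TARGETS, seed=0)
    if kind == "theta":
        assert config.theta_anc == pytest.approx(expected, abs=1e-6)
    else:
        group = kind.split(":")[1]
        assert config.F_by_population[group] == pytest.approx(expected, abs=1e-4)


def test_calibrate_expected_homozygosity_roundtrip():
    config = calibrate(DEFAULT_TARGETS, seed=0)
    assert expected_homozygosity(config, "EuropeanWild", "AsianWild") == pytest.approx(
        DEFAULT_TARGETS.between_clade, abs=1e-12
    )
    for g, w in DEFAULT_TARGETS.within_group.items():
        assert expected_homozygosity(config, g, g) == pytest.approx(w, abs=1e-12)


def test_invalid_targets_rejected():
    with pytest.raises(PanelError):
        CalibrationTargets({"EuropeanWild": 0.7}, between_clade=0.825)
    with pytest.raises(PanelError):
        CalibrationTargets({"EuropeanWild": 1.2}, between_clade=0.825)
    with pytest.raises(PanelError):
        expected_homozygosity(calibrate(seed=0), "EuropeanWild", "Atlantis")


def test_admixed_expectations_are_mixtures():
    config = calibrate(seed=0, true_f=0.2)
    h_ww = expected_homozygosity(config, "EuropeanWild", "EuropeanWild")
    h_bc = DEFAULT_TARGETS.between_clade
    h_aa = expected_homozygosity(config, "AsianCommercial", "AsianCommercial")
    vs_wild = expected_homozygosity(config, "EuropeanCommercial", "EuropeanWild")
    assert vs_wild == pytest.approx(0.8 * h_ww + 0.2 * h_bc, abs=1e-12)
    vs_donor = expected_homozygosity(config, "EuropeanCommercial", "AsianCommercial")
    assert vs_donor == pytest.approx(0.8 * h_bc + 0.2 * h_aa, abs=1e-12)
    f0 = calibrate(seed=0, true_f=0.0)
    assert expected_homozygosity(f0, "EuropeanCommercial", "EuropeanWild") == (
        pytest.approx(h_ww, abs=1e-12)
    )


def test_single_group_panel():
    config = calibrate(seed=1, L=500, sample_sizes={"AsianWild": 6})
    m, ga, _ = build_panel(config)
    assert m.n_haplotypes == 6
    assert set(ga.group_by_haplotype.values()) == {"AsianWild"}


def test_empirical_means_match_closed_forms(calibrated_panel):
    """Every group-pair mean sits within a few 1e-3 of its closed form."""
    config, m, ga, _ = calibrated_panel
    checks = [
        ("EuropeanWild", "EuropeanWild"),
        ("AsianWild", "AsianWild"),
        ("AsianCommercial", "AsianCommercial"),
        ("EuropeanWild", "AsianWild"),
        ("EuropeanWild", "AsianCommercial"),
        ("EuropeanWild", "Outgroup"),
        ("EuropeanCommercial", "EuropeanWild"),
        ("EuropeanCommercial", "AsianCommercial"),
    ]
    for ga_name, gb_name in checks:
        if ga_name == gb_name:
            t = all_pairs(m, ga, within=ga_name)
        else:
            t = all_pairs(m, ga, between=(ga_name, gb_name))
        emp = t["homozygosity"].mean()
        exp = expected_homozygosity(config, ga_name, gb_name)
        assert emp == pytest.approx(exp, abs=0.006), (ga_name, gb_name)


def test_panel_reproducible_and_seed_sensitive():
    sizes = {"EuropeanWild": 4, "AsianWild": 4}
    a1, _, _ = build_panel(calibrate(seed=42, L=400, sample_sizes=dict(sizes)))
    a2, _, _ = build_panel(calibrate(seed=42, L=400, sample_sizes=dict(sizes)))
    b, _, _ = build_panel(calibrate(seed=43, L=400, sample_sizes=dict(sizes)))
    np.testing.assert_array_equal(a1.alleles, a2.alleles)
    assert not np.array_equal(a1.alleles, b.alleles)


def test_inbred_individual_shares_segment():
    config = calibrate(
        seed=9, L=2_000, sample_sizes={"EuropeanWild": 4},
        inbred_pairs=[("EuropeanWild", 0.5)],
    )
    m, ga, truth = build_panel(config)
    rec = truth["inbred"][0]
    a = m.row(rec["individual"] + "_A")
    b = m.row(rec["individual"] + "_B")
    start = rec["start"]
    n_shared = round(0.5 * config.L)
    assert np.array_equal(a[start : start + n_shared], b[start : start + n_shared])
    # within-individual homozygosity >= shared fraction plus background
    assert np.mean(a == b) >= 0.5


def test_odd_sample_size_rejected():
    with pytest.raises(PanelError):
        GeneratorConfig(seed=0, sample_sizes={"EuropeanWild": 5})
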