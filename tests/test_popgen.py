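"""Diversity statistics: analytic cases, brute-force fuzzing, bootstrap behaviour."""

import numpy as np
import pytest

from rangegen import popgen
from rangegen.popgen import (
    MISSING,
    NULL,
    BootstrapDistribution,
    GenotypeTable,
    basic_stats,
    ci_nonoverlap,
    effective_alleles,
    filter_individuals,
    rarefy_bootstrap,
)

from _oracles import brute_diversity, random_table
from conftest import make_table


# ---------------------------------------------------------------------------
# analytic cases
# ---------------------------------------------------------------------------

def test_fixed_populations_partition_all_diversity_among_them(two_pop_fixed):
    st = basic_stats(two_pop_fixed)
    row = st.per_locus.iloc[0]
    assert row["H_S"] == 0.0
    assert row["H_T"] == 0.5
    assert row["F_ST"] == 1.0
    assert st.overall["F_ST"] == 1.0


def test_all_heterozygotes_give_maximal_excess(all_het_one_pop):
    st = basic_stats(all_het_one_pop)
    row = st.per_locus.iloc[0]
    assert row["H_O"] == 1.0
    assert row["H_S"] == 0.5
    assert row["F_IS"] == -1.0
    assert row["F_IS_raw"] == -1.0
    # single population: partitioning statistics undefined
    assert np.isnan(row["H_T"])


def test_monomorphic_locus_has_zero_diversity_and_undefined_ratios():
    gt = make_table({"a": [[(1, 1)], [(1, 1)]], "b": [[(1, 1)], [(1, 1)]]})
    st = basic_stats(gt)
    row = st.per_locus.iloc[0]
    assert row[["H_O", "H_S", "H_T"]].tolist() == [0.0, 0.0, 0.0]
    assert np.isnan(row["F_ST"]) and np.isnan(row["F_IS"])


@pytest.mark.parametrize(
    "genos, expected",
    [
        # k equifrequent alleles -> A_e = k
        ([[(1, 2)], [(3, 4)]], 4.0),
        # fixed locus -> A_e = 1
        ([[(1, 1)], [(1, 1)]], 1.0),
        # frequencies (0.5, 0.25, 0.25) -> 1/0.375
        ([[(1, 2)], [(1, 3)], [(1, 1)], [(2, 3)]], 1.0 / 0.375),
    ],
)
def test_effective_allele_number(genos, expected):
    gt = make_table({"a": genos, "b": [[(1, 1)]] * 2})
    ae = effective_alleles(gt)
    assert ae.loc["L0", "a"] == pytest.approx(expected, abs=1e-12)


def test_null_alleles_are_a_scorable_class():
    # null/null homozygotes are homozygous; nulls enter frequencies
    gt = make_table({"a": [[(NULL, NULL)], [(1, NULL)], [(1, 1)], [(1, 1)]]})
    st = basic_stats(gt)
    row = st.per_locus.iloc[0]
    assert row["H_O"] == 0.25           # only the 1/null individual
    # freqs: null 3/8, allele1 5/8
    assert row["H_S"] == pytest.approx(1 - (3 / 8) ** 2 - (5 / 8) ** 2)
    assert row["A"] == 2


def test_missing_calls_excluded_locus_wise():
    gt = make_table({
        "a": [[(1, 2), (MISSING, MISSING)], [(1, 1), (1, 2)]],
        "b": [[(2, 2), (1, 1)], [(1, 2), (2, 2)]],
    })
    st = basic_stats(gt)
    # locus 2, pop a: only the second individual is scored
    assert st.per_locus.iloc[1]["pct_missing"] == pytest.approx(25.0)
    ora = brute_diversity(gt)
    np.testing.assert_allclose(st.per_locus["H_S"].to_numpy(), ora["H_S"])


# ---------------------------------------------------------------------------
# fuzzing against the counting oracle and exact identities
# ---------------------------------------------------------------------------

def test_plain_estimators_match_brute_force_on_fuzzed_tables():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        gt = random_table(rng)
        st = basic_stats(gt)
        ora = brute_diversity(gt)
        for k in ("H_O", "H_S", "H_T"):
            np.testing.assert_allclose(
                st.per_locus[k].to_numpy(), ora[k], atol=1e-12,
                err_msg=f"{k} mismatch",
            )


def test_plain_identities_hold_exactly():
    rng = np.random.default_rng(7)
    for _ in range(200):
        gt = random_table(rng)
        st = basic_stats(gt)
        pl = st.per_locus
        np.testing.assert_allclose(pl["D_ST"], pl["H_T"] - pl["H_S"], atol=1e-14)
        ok = np.isfinite(pl["F_ST"])
        np.testing.assert_allclose(
            (pl["F_ST"] * pl["H_T"])[ok], pl["D_ST"][ok], atol=1e-14)
        ok = np.isfinite(pl["F_IS_raw"])
        np.testing.assert_allclose(
            pl["F_IS_raw"][ok], 1 - pl["H_O"][ok] / pl["H_S"][ok], atol=1e-14)
        ov = st.overall
        assert ov["D_ST"] == pytest.approx(ov["H_T"] - ov["H_S"], abs=1e-14)


def test_statistics_invariant_to_individual_and_population_order():
    rng = np.random.default_rng(3)
    gt = random_table(rng)
    perm = rng.permutation(gt.n_individuals)
    gt2 = gt.subset(perm)
    a = basic_stats(gt).per_locus
    b = basic_stats(gt2).per_locus
    np.testing.assert_allclose(
        a[["H_O", "H_S", "H_T"]].to_numpy(),
        b[["H_O", "H_S", "H_T"]].to_numpy(), atol=1e-14)


def test_sample_corrected_converges_to_plain_for_large_samples():
    from rangegen import SimConfig, simulate_genotypes

    gt = simulate_genotypes(SimConfig(seed=11, inds_per_pop=400, n_pops=4,
                                      selfing_rate=0.0))
    plain = basic_stats(gt, "plain").overall
    corr = basic_stats(gt, "sample_corrected").overall
    assert corr["H_S"] == pytest.approx(plain["H_S"], abs=0.005)
    assert corr["H_T"] == pytest.approx(plain["H_T"], abs=0.005)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def test_genepop_round_trip(tmp_path):
    gt = make_table({
        "a": [[(1, 2), (NULL, NULL)], [(1, 1), (MISSING, MISSING)]],
        "b": [[(2, 2), (3, 1)]],
    })
    path = tmp_path / "toy.gen"
    gt.to_genepop(path)
    back = popgen.read_genotypes(path, "genepop")
    assert len(back.pop_names()) == 2
    np.testing.assert_array_equal(back.calls, gt.calls)
    assert int(np.sum(back.missing_mask())) == 1


def test_csv_round_trip(tmp_path):
    gt = make_table({"a": [[(1, 2)], [(3, MISSING)]], "b": [[(2, 2)]]})
    path = tmp_path / "toy.csv"
    gt.to_csv(path)
    back = popgen.read_genotypes(path, "csv")
    np.testing.assert_array_equal(back.calls, gt.calls)
    assert list(back.populations) == list(gt.populations)


def test_duplicate_individuals_rejected():
    with pytest.raises(ValueError, match="duplicated"):
        GenotypeTable(
            individuals=["x", "x"], populations=["a", "a"], loci=["L"],
            calls=np.ones((2, 1, 2), dtype=np.int32),
        )


# ---------------------------------------------------------------------------
# missing-data filter
# ---------------------------------------------------------------------------

def _table_with_missing(n_missing_per_ind, n_loci=15):
    genos = []
    for m in n_missing_per_ind:
        row = [(1, 2)] * (n_loci - m) + [(MISSING, MISSING)] * m
        genos.append(row)
    return make_table({"a": genos})


def test_filter_boundary_at_four_missing_loci():
    gt = _table_with_missing([5, 4, 0])
    kept = filter_individuals(gt)
    assert kept.n_individuals == 2          # >4 removed, ==4 retained
    assert "i0" not in list(kept.individuals)


def test_filter_matches_brute_force_enumeration():
    rng = np.random.default_rng(5)
    miss = rng.integers(0, 10, 40)
    gt = _table_with_missing(miss.tolist())
    expected = int(np.sum(miss <= 4))
    assert filter_individuals(gt).n_individuals == expected


def test_filter_error_when_everything_removed():
    gt = _table_with_missing([10, 12])
    with pytest.raises(ValueError, match="max_missing_loci=4"):
        filter_individuals(gt)


# ---------------------------------------------------------------------------
# rarefy-then-bootstrap
# ---------------------------------------------------------------------------

def _degenerate_table():
    # all populations identical, all individuals identical heterozygotes:
    # any resample reproduces the same statistics
    return make_table({
        "a": [[(1, 2)]] * 5, "b": [[(1, 2)]] * 5,
    })


def test_degenerate_table_gives_zero_width_ci():
    boots = rarefy_bootstrap(_degenerate_table(), n_boot=50, seed=0)
    for b in boots.values():
        assert np.ptp(b.replicates[np.isfinite(b.replicates)]) == 0.0
        assert b.ci_high - b.ci_low == pytest.approx(0.0, abs=1e-15)


def test_diagnostic_mode_reproduces_point_estimate():
    # rarefaction at the (equal) population size is the identity, and with
    # the resampling stage switched off every replicate must equal the
    # full-data point estimate
    eq = make_table({"a": [[(1, 2)], [(1, 1)], [(2, 2)]],
                     "b": [[(1, 1)], [(1, 2)], [(2, 2)]]})
    boots = rarefy_bootstrap(eq, n_boot=5, depth=3, seed=0, resample=False)
    point = basic_stats(eq).overall
    for k, b in boots.items():
        np.testing.assert_allclose(b.replicates, point[k], atol=1e-14)


def test_bootstrap_reproducible_with_same_seed():
    rng = np.random.default_rng(9)
    gt = random_table(rng)
    a = rarefy_bootstrap(gt, n_boot=30, seed=123)
    b = rarefy_bootstrap(gt, n_boot=30, seed=123)
    for k in a:
        np.testing.assert_array_equal(a[k].replicates, b[k].replicates)


def test_bootstrap_input_validation():
    gt = _degenerate_table()
    with pytest.raises(ValueError, match="depth"):
        rarefy_bootstrap(gt, n_boot=10, depth=50)
    with pytest.raises(ValueError, match="n_boot"):
        rarefy_bootstrap(gt, n_boot=1)


# ---------------------------------------------------------------------------
# CI non-overlap rule
# ---------------------------------------------------------------------------

def _dist(lo, hi, name="H_S"):
    reps = np.linspace(lo, hi, 101)
    return BootstrapDistribution(name=name, replicates=reps,
                                 point=(lo + hi) / 2, level=0.95,
                                 ci_low=lo, ci_high=hi, ci_method="percentile")


def test_disjoint_intervals_significant():
    assert ci_nonoverlap(_dist(0.1, 0.2), _dist(0.3, 0.4), level=1.0)


def test_shared_endpoint_counts_as_overlap():
    assert not ci_nonoverlap(_dist(0.1, 0.3), _dist(0.3, 0.4), level=1.0)


def test_identical_distributions_not_significant():
    assert not ci_nonoverlap(_dist(0.1, 0.3), _dist(0.1, 0.3))


def test_mismatched_names_rejected():
    with pytest.raises(ValueError, match="mismatched"):
        ci_nonoverlap(_dist(0, 1, "H_S"), _dist(0, 1, "F_ST"))
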