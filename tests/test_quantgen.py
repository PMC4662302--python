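"""Composite phenotype and variance components: oracles, identities, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from rangegen.quantgen import (
    PhenotypeTable,
    composite_phenotype,
    derive_traits,
    parametric_bootstrap_vc,
    variance_components,
)


def _phenotype_frame(n=12, seed=0, **overrides):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "individual": [f"i{k}" for k in range(n)],
        "population": ["a"] * (n // 2) + ["b"] * (n - n // 2),
        "family": [f"f{k // 3}" for k in range(n)],
        "height_d21": rng.uniform(10, 30, n),
        "leaf_area_d21": rng.uniform(100, 500, n),
        "leaf_number_d21": rng.integers(3, 9, n).astype(float),
        "height_d55": rng.uniform(30, 90, n),
        "leaf_area_d55": rng.uniform(500, 2000, n),
        "leaf_number_d55": rng.integers(6, 18, n).astype(float),
    })
    for k, v in overrides.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# derived traits
# ---------------------------------------------------------------------------

def test_ratio_traits_follow_printed_formulas():
    df = _phenotype_frame(n=2)
    df.loc[0, ["height_d55", "leaf_area_d55", "leaf_number_d55"]] = [50.0, 500.0, 10.0]
    pt = derive_traits(PhenotypeTable(df))
    assert pt.data.loc[0, "internode_d55"] == pytest.approx(10.0 / 50.0)
    assert pt.data.loc[0, "leaf_size_d55"] == pytest.approx(50.0)


def test_zero_leaf_number_is_flagged_and_excluded_from_pca():
    df = _phenotype_frame(n=10)
    df.loc[0, "leaf_number_d55"] = 0.0
    pt = derive_traits(PhenotypeTable(df))
    assert np.isnan(pt.data.loc[0, "leaf_size_d55"])
    comp = composite_phenotype(pt)
    assert comp.n_dropped == 1
    assert "i0" not in comp.scores.index


def test_inverted_internode_flag():
    df = _phenotype_frame(n=2)
    df.loc[0, ["height_d55", "leaf_number_d55"]] = [50.0, 10.0]
    pt = derive_traits(PhenotypeTable(df), invert_internode=True)
    assert pt.data.loc[0, "internode_d55"] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# composite phenotype
# ---------------------------------------------------------------------------

def test_single_trait_composite_is_the_standardized_trait():
    df = _phenotype_frame(n=30, seed=1)
    comp = composite_phenotype(PhenotypeTable(df), n_axes=1,
                               traits=["height_d21"])
    z = df["height_d21"]
    z = (z - z.mean()) / z.std(ddof=1)
    np.testing.assert_allclose(np.abs(comp.scores.to_numpy()),
                               np.abs(z.to_numpy()), atol=1e-10)
    assert comp.pct_variance[0] == pytest.approx(100.0)


def test_two_uncorrelated_traits_split_variance_evenly():
    rng = np.random.default_rng(2)
    n = 4000
    df = _phenotype_frame(n=n, seed=2,
                          height_d21=rng.normal(20, 3, n),
                          leaf_area_d21=rng.normal(300, 40, n))
    comp = composite_phenotype(PhenotypeTable(df), n_axes=2,
                               traits=["height_d21", "leaf_area_d21"])
    assert comp.pct_variance[0] == pytest.approx(50.0, abs=3.0)
    assert comp.pct_variance[1] == pytest.approx(50.0, abs=3.0)


def test_pct_variance_matches_eigendecomposition_oracle():
    from rangegen import SimConfig, simulate_phenotypes

    pt = derive_traits(simulate_phenotypes(SimConfig(seed=40)))
    comp = composite_phenotype(pt)
    traits = [c for c in pt.data.columns
              if c.endswith(("_d21", "_d55")) and c != "height_d28"]
    X = pt.data[traits].to_numpy(float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    eig = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))[::-1]
    np.testing.assert_allclose(comp.pct_variance,
                               100 * eig / eig.sum(), atol=1e-8)
    assert np.all(np.diff(comp.pct_variance) <= 1e-12)


def test_composite_requires_enough_complete_rows():
    df = _phenotype_frame(n=5)
    with pytest.raises(ValueError, match="complete rows"):
        composite_phenotype(PhenotypeTable(df))


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _balanced(n_pops=6, n_fams=4, n_sibs=3, v=(2.0, 1.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    pops = np.repeat([f"p{i}" for i in range(n_pops)], n_fams * n_sibs)
    fams = np.array([f"{p}_f{(k // n_sibs) % n_fams}"
                     for k, p in enumerate(pops)])
    P = dict(zip(np.unique(pops), rng.normal(0, np.sqrt(v[0]), n_pops)))
    F = dict(zip(np.unique(fams), rng.normal(0, np.sqrt(v[1]),
                                             n_pops * n_fams)))
    y = (np.array([P[p] for p in pops]) + np.array([F[f] for f in fams])
         + rng.normal(0, np.sqrt(v[2]), len(pops)))
    return y, pops, fams


def test_all_equal_observations_give_zero_components_and_undefined_ratios():
    _, pops, fams = _balanced()
    fit = variance_components(np.zeros(len(pops)), pops, fams)
    assert (fit.v_pop, fit.v_fam, fit.v_err) == (0.0, 0.0, 0.0)
    assert np.isnan(fit.q_st) and np.isnan(fit.h2)


def test_equal_population_means_give_zero_qst():
    # two populations constructed with identical family-mean layouts
    pops = np.repeat(["a", "b"], 6)
    fams = np.array(["a1"] * 3 + ["a2"] * 3 + ["b1"] * 3 + ["b2"] * 3)
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2)
    fit = variance_components(y, pops, fams)
    assert fit.v_pop == pytest.approx(0.0, abs=1e-10)
    assert fit.q_st == pytest.approx(0.0, abs=1e-8)


def test_reml_equals_anova_on_balanced_interior_designs():
    hits = 0
    for seed in range(12):
        y, pops, fams = _balanced(seed=seed)
        mom = variance_components(y, pops, fams, method="anova_mom")
        if min(mom.v_pop, mom.v_fam, mom.v_err) <= 1e-8:
            continue  # boundary solution: REML and MoM legitimately differ
        reml = variance_components(y, pops, fams, method="reml")
        for a, b in [(reml.v_pop, mom.v_pop), (reml.v_fam, mom.v_fam),
                     (reml.v_err, mom.v_err)]:
            assert a == pytest.approx(b, abs=1e-6)
        hits += 1
    assert hits >= 5


def test_reml_matches_statsmodels_mixedlm_on_unbalanced_data():
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(14)
    pops = np.repeat([f"p{i}" for i in range(8)], 20)
    fams = np.array([f"{p}_f{rng.integers(4)}" for p in pops])
    P = dict(zip(np.unique(pops), rng.normal(0, 1.1, 8)))
    F = dict(zip(np.unique(fams), rng.normal(0, 0.9, len(set(fams)))))
    y = (np.array([P[p] for p in pops]) + np.array([F[f] for f in fams])
         + rng.normal(0, 0.7, len(pops)))
    fit = variance_components(y, pops, fams)
    df = pd.DataFrame({"y": y, "pop": pops, "fam": fams})
    md = smf.mixedlm("y ~ 1", df, groups="pop", re_formula="1",
                     vc_formula={"fam": "0 + C(fam)"}).fit(reml=True)
    assert fit.v_pop == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=1e-3)
    assert fit.v_fam == pytest.approx(float(md.vcomp[0]), rel=1e-3)
    assert fit.v_err == pytest.approx(float(md.scale), rel=1e-3)


def test_qst_invariant_to_affine_transformation():
    y, pops, fams = _balanced(seed=3)
    a = variance_components(y, pops, fams)
    b = variance_components(3.5 * y - 7.0, pops, fams)
    assert a.q_st == pytest.approx(b.q_st, abs=1e-7)
    assert a.h2 == pytest.approx(b.h2, abs=1e-7)


def test_estimates_permutation_equivariant_and_nonnegative():
    y, pops, fams = _balanced(seed=4)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    a = variance_components(y, pops, fams)
    b = variance_components(y[perm], pops[perm], fams[perm])
    assert a.v_pop == pytest.approx(b.v_pop, abs=1e-7)
    assert min(a.v_pop, a.v_fam, a.v_err) >= 0.0


def test_h2_identity():
    y, pops, fams = _balanced(seed=5)
    fit = variance_components(y, pops, fams)
    assert fit.h2 + (fit.v_pop + fit.v_err) / fit.v_tot == pytest.approx(
        1.0, abs=1e-12)
    assert fit.v_tot == pytest.approx(fit.v_pop + fit.v_fam + fit.v_err,
                                      abs=1e-12)


def test_singular_design_rejected():
    with pytest.raises(ValueError, match="2 populations"):
        variance_components([1.0, 2.0], ["a", "a"], ["f1", "f1"])
    with pytest.raises(ValueError, match="famil"):
        variance_components([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"],
                            ["f1", "f1", "f2", "f2"])


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

def test_zero_variance_fit_bootstraps_to_zero_width():
    _, pops, fams = _balanced()
    fit = variance_components(np.zeros(len(pops)), pops, fams)
    boots = parametric_bootstrap_vc(fit, pops, fams, n_boot=20, seed=0)
    for k in ("V_POP", "V_FAM", "V_ERR", "V_TOT"):
        assert np.all(boots[k].replicates == 0.0)
        assert boots[k].ci_high - boots[k].ci_low == 0.0


def test_bootstrap_deterministic_given_seed():
    y, pops, fams = _balanced(seed=6)
    fit = variance_components(y, pops, fams, method="anova_mom")
    a = parametric_bootstrap_vc(fit, pops, fams, n_boot=25, seed=7,
                                method="anova_mom")
    b = parametric_bootstrap_vc(fit, pops, fams, n_boot=25, seed=7,
                                method="anova_mom")
    np.testing.assert_array_equal(a["Q_ST"].replicates, b["Q_ST"].replicates)
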