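"""Composite-phenotype construction and nested variance-component estimation.

The quantitative-genetic model is a two-level nested random-effects model

    y_ijk = mu + P_i + F_ij + e_ijk,
    P_i ~ N(0, V_POP),  F_ij ~ N(0, V_FAM),  e_ijk ~ N(0, V_ERR),

fit to a composite phenotype (the weighted mean of the leading principal
component scores of a standardized trait matrix).  From the estimated
components we derive

    Q_ST = V_POP / (V_POP + V_FAM)      (selfing-appropriate form: families
                                         are selfed sib groups, so V_FAM
                                         approximates total genetic variance
                                         within populations and is not
                                         multiplied by 2), and
    H^2  = V_FAM / V_TOT,  V_TOT = V_POP + V_FAM + V_ERR
                                        (broad-sense, among-family fraction
                                         of *total* variance, including
                                         V_POP in the denominator).

Two estimators are provided: ``reml`` (restricted maximum likelihood with
non-negativity constraints, the default) and ``anova_mom`` (closed-form
nested-ANOVA method of moments with negative solutions truncated at 0), used
as a cross-check — on balanced designs with interior solutions the two
coincide.  Uncertainty comes from a parametric bootstrap that simulates new
responses from the fitted model on the original design and refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular

from .popgen import BootstrapDistribution, _bootstrap_ci

logger = logging.getLogger(__name__)

#: Columns a raw phenotype table must provide (mm for heights, mm^2 for
#: areas, counts for leaf number; measurement days are postgermination).
PRIMARY_TRAITS = [
    "height_d21", "leaf_area_d21", "leaf_number_d21",
    "height_d55", "leaf_area_d55", "leaf_number_d55",
]
DERIVED_TRAITS = ["internode_d55", "leaf_size_d55"]
GROWTH_COLUMNS = ["height_d28", "leaf_area_d28", "height_d63", "leaf_area_d63"]
ALL_TRAITS = PRIMARY_TRAITS + DERIVED_TRAITS


@dataclass
class PhenotypeTable:
    """Individual phenotype records with population and family labels.

    ``data`` holds one row per individual with columns ``individual``,
    ``population``, ``family``, the six primary rosette traits, and height
    and leaf area at the two growth-rate timepoints (days 28 and 63).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        for col in ["individual", "population", "family"] + PRIMARY_TRAITS:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if df["individual"].duplicated().any():
            raise ValueError("duplicated individual ids")
        size_cols = [c for c in df.columns
                     if c.startswith(("height_", "leaf_area_"))]
        vals = df[size_cols].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("sizes must be strictly positive where present")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))


@dataclass
class CompositeScore:
    """Weighted-mean principal-component score per individual.

    ``scores`` is indexed by individual id; ``pct_variance`` gives the
    percent variance explained by each retained axis; ``weights`` are the
    (renormalized) axis weights actually applied.
    """

    scores: pd.Series
    pct_variance: np.ndarray
    weights: np.ndarray
    loadings: pd.DataFrame
    n_dropped: int = 0


@dataclass
class VarianceComponents:
    """Estimated variance components and the derived Q_ST and H^2."""

    v_pop: float
    v_fam: float
    v_err: float
    method: str
    converged: bool = True
    n_pops: int = 0
    n_families: int = 0
    n_obs: int = 0
    reml_neg2ll: float = np.nan

    @property
    def v_tot(self) -> float:
        return self.v_pop + self.v_fam + self.v_err

    @property
    def q_st(self) -> float:
        denom = self.v_pop + self.v_fam
        return self.v_pop / denom if denom > 0 else np.nan

    @property
    def h2(self) -> float:
        return self.v_fam / self.v_tot if self.v_tot > 0 else np.nan

    def as_dict(self) -> dict:
        return {
            "V_POP": self.v_pop, "V_FAM": self.v_fam, "V_ERR": self.v_err,
            "V_TOT": self.v_tot, "Q_ST": self.q_st, "H2": self.h2,
        }


# ---------------------------------------------------------------------------
# derived traits
# ---------------------------------------------------------------------------

def derive_traits(pt: PhenotypeTable, invert_internode: bool = False) -> PhenotypeTable:
    """Add the two day-55 ratio traits.

    internode distance = leaf number / height at day 55 (with
    ``invert_internode=True`` the dimensionally conventional height/leaf
    number is used instead); leaf size = leaf area / leaf number at day 55.
    Individuals with zero leaf number get NaN leaf size (and internode when
    inverted), are logged, and drop out of complete-case analyses.
    """
    df = pt.data.copy()
    h = df["height_d55"].to_numpy(dtype=float)
    la = df["leaf_area_d55"].to_numpy(dtype=float)
    ln = df["leaf_number_d55"].to_numpy(dtype=float)
    zero_leaf = ln == 0
    for i in np.flatnonzero(zero_leaf):
        logger.info("derive_traits: %s has zero leaf number; ratio traits NaN",
                    df["individual"].iloc[i])
    with np.errstate(invalid="ignore", divide="ignore"):
        if invert_internode:
            df["internode_d55"] = np.where(zero_leaf, np.nan, h / ln)
        else:
            df["internode_d55"] = ln / h
        df["leaf_size_d55"] = np.where(zero_leaf, np.nan, la / ln)
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# composite phenotype
# ---------------------------------------------------------------------------

def composite_phenotype(
    pt: PhenotypeTable,
    n_axes: int = 3,
    traits: list | None = None,
    scale: bool = True,
) -> CompositeScore:
    """Weighted mean of the first ``n_axes`` principal-component scores.

    Traits are centered and (by default) scaled to unit variance, so the
    decomposition is of the trait correlation structure; rows with any
    missing trait are dropped (complete-case) and logged.  The composite for
    individual i is ``sum_k w_k PC_ki / sum_k w_k`` with ``w_k`` the percent
    variance explained by axis k.  Axis signs are fixed so each loading
    vector has a non-negative sum, making scores reproducible.
    """
    df = pt.data
    if traits is None:
        traits = [t for t in ALL_TRAITS if t in df.columns]
    X = df[traits].to_numpy(dtype=float)
    complete = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("composite_phenotype: dropping %d incomplete rows", n_dropped)
    X = X[complete]
    if X.shape[0] <= len(traits):
        raise ValueError(
            f"only {X.shape[0]} complete rows for {len(traits)} traits"
        )
    if n_axes > len(traits):
        raise ValueError("n_axes exceeds the number of traits")

    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [t for t, s in zip(traits, sd) if s == 0]
            raise ValueError(f"constant trait(s): {bad}")
        Xc = Xc / sd
    # SVD of the standardized matrix == eigen-decomposition of the
    # correlation (or covariance) matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    pct = 100.0 * var / var.sum()
    signs = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    Vt = Vt * signs[:, None]
    scores_full = Xc @ Vt.T

    w = pct[:n_axes]
    composite = scores_full[:, :n_axes] @ (w / w.sum())
    ids = df.loc[complete, "individual"].to_numpy()
    loadings = pd.DataFrame(
        Vt[:n_axes].T, index=traits,
        columns=[f"PC{k+1}" for k in range(n_axes)],
    )
    return CompositeScore(
        scores=pd.Series(composite, index=pd.Index(ids, name="individual")),
        pct_variance=pct, weights=w / w.sum(), loadings=loadings,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# nested variance components
# ---------------------------------------------------------------------------

def _design(populations, families):
    pops = pd.Series(np.asarray(populations, dtype=object))
    fams = pd.Series(np.asarray(families, dtype=object))
    # families are nested within populations: disambiguate shared labels
    combo = pops.astype(str) + "//" + fams.astype(str)
    pop_codes, _ = pd.factorize(pops)
    fam_codes, _ = pd.factorize(combo)
    return pop_codes, fam_codes


def _anova_mom(y, pop_codes, fam_codes):
    """Nested ANOVA method-of-moments estimator (general, unbalanced).

    Expected mean squares (s = #pops, f = #families, N = #obs):
        E[MS_err] = V_ERR
        E[MS_fam] = V_ERR + c1 V_FAM
        E[MS_pop] = V_ERR + c2 V_FAM + c3 V_POP
    with the standard unbalanced-design coefficients
        c1 = (N - sum_i sum_j n_ij^2 / n_i) / df_fam
        c2 = (sum_i sum_j n_ij^2 / n_i - sum_ij n_ij^2 / N) / df_pop
        c3 = (N - sum_i n_i^2 / N) / df_pop.
    Negative solutions are truncated at zero.
    """
    df = pd.DataFrame({"y": y, "p": pop_codes, "f": fam_codes})
    N = len(df)
    gmean = df["y"].mean()
    pop_g = df.groupby("p")["y"]
    fam_g = df.groupby("f")["y"]
    pop_means, pop_sizes = pop_g.mean(), pop_g.size()
    fam_means, fam_sizes = fam_g.mean(), fam_g.size()
    fam_pop = df.drop_duplicates("f").set_index("f")["p"]
    s, f = len(pop_means), len(fam_means)
    df_pop, df_fam, df_err = s - 1, f - s, N - f
    if df_pop < 1 or df_fam < 1:
        raise ValueError(
            f"singular design: {s} population(s), {f} family(ies)"
        )

    ss_pop = float((pop_sizes * (pop_means - gmean) ** 2).sum())
    ss_fam = float((fam_sizes * (fam_means - pop_means.reindex(fam_pop).to_numpy()) ** 2).sum())
    resid = df["y"].to_numpy() - fam_means.reindex(fam_codes).to_numpy()
    ss_err = float((resid**2).sum())

    nij2_by_pop = (fam_sizes**2).groupby(fam_pop).sum()
    t1 = float((nij2_by_pop / pop_sizes).sum())
    c1 = (N - t1) / df_fam
    c2 = (t1 - float((fam_sizes**2).sum()) / N) / df_pop
    c3 = (N - float((pop_sizes**2).sum()) / N) / df_pop

    ms_pop, ms_fam = ss_pop / df_pop, ss_fam / df_fam
    v_err = ss_err / df_err if df_err > 0 else 0.0
    v_fam = max((ms_fam - v_err) / c1, 0.0)
    v_pop = max((ms_pop - v_err - c2 * v_fam) / c3, 0.0)
    return v_pop, v_fam, v_err


class _RemlProblem:
    """-2 restricted log-likelihood of the nested model, block by population.

    V is block diagonal over populations,
        V_i = V_ERR I + V_FAM blockdiag_j(J_{n_ij}) + V_POP J_{n_i},
    and the only fixed effect is the intercept, so
        -2 llr = sum_i log|V_i| + log(1' V^-1 1) + y' P y  (+ const).

    Each population block is reduced analytically: with
    D = V_ERR I + V_FAM blockdiag(J) (family-level Woodbury inverse) and
    the population effect a rank-one update ``V = D + V_POP 1 1'``, every
    term depends on the data only through family sizes m_j, family sums
    S_j and per-population sums of squares — an O(#families) evaluation:

        1'D^-1 1 = sum_j m_j / (V_ERR + m_j V_FAM)            =: a
        1'D^-1 y = sum_j S_j / (V_ERR + m_j V_FAM)            =: b
        y'D^-1 y = (sum y^2)/V_ERR
                   - sum_j V_FAM S_j^2 / (V_ERR (V_ERR + m_j V_FAM))  =: c
        log|D|   = sum_j [(m_j - 1) ln V_ERR + ln(V_ERR + m_j V_FAM)]
        log|V|   = log|D| + ln(1 + V_POP a)
        1'V^-1 1 = a - V_POP a^2 / (1 + V_POP a), etc.
    """

    def __init__(self, y, pop_codes, fam_codes):
        y = np.asarray(y, dtype=float)
        self.n = len(y)
        fam = pd.DataFrame({"y": y, "p": pop_codes, "f": fam_codes})
        g = fam.groupby("f", sort=True)
        self.m = g.size().to_numpy(dtype=float)              # family sizes
        self.S = g["y"].sum().to_numpy()                     # family sums
        self.fam_pop = g["p"].first().to_numpy()             # pop of family
        self.pops = np.unique(pop_codes)
        self.ss = np.array([np.sum(y[pop_codes == p] ** 2) for p in self.pops])
        self.pop_slot = {p: i for i, p in enumerate(self.pops)}
        self.fam_slot = np.array([self.pop_slot[p] for p in self.fam_pop])

    def neg2llr(self, theta):
        v_pop, v_fam, v_err = theta
        if v_err <= 0 or v_pop < 0 or v_fam < 0:
            return np.inf
        denom = v_err + self.m * v_fam
        P = len(self.pops)
        a = np.bincount(self.fam_slot, weights=self.m / denom, minlength=P)
        b = np.bincount(self.fam_slot, weights=self.S / denom, minlength=P)
        c = (self.ss / v_err
             - np.bincount(self.fam_slot,
                           weights=v_fam * self.S**2 / (v_err * denom),
                           minlength=P))
        logdet_d = ((self.m - 1.0) * np.log(v_err) + np.log(denom))
        logdet = float(np.bincount(self.fam_slot, weights=logdet_d,
                                   minlength=P).sum()
                       + np.log1p(v_pop * a).sum())
        shrink = v_pop / (1.0 + v_pop * a)
        xtvx = float((a - shrink * a**2).sum())
        xtvy = float((b - shrink * a * b).sum())
        ytvy = float((c - shrink * b**2).sum())
        if xtvx <= 0 or not np.isfinite(logdet):
            return np.inf
        ypy = ytvy - xtvy**2 / xtvx
        return logdet + np.log(xtvx) + ypy


def variance_components(
    values,
    populations,
    families,
    method: str = "reml",
) -> VarianceComponents:
    """Estimate (V_POP, V_FAM, V_ERR) for the nested random-effects model.

    ``values`` may be a :class:`CompositeScore` (its scores are used, with
    labels aligned by individual id when ``populations``/``families`` are
    mappings) or any 1-D array-like aligned with the label arrays.

    ``method="reml"`` maximizes the restricted likelihood under
    non-negativity constraints, multi-started from the ANOVA estimates;
    ``method="anova_mom"`` returns the closed-form nested-ANOVA estimator.
    """
    if isinstance(values, CompositeScore):
        y = values.scores.to_numpy(dtype=float)
        ids = values.scores.index
        if isinstance(populations, (dict, pd.Series)):
            populations = pd.Series(populations).reindex(ids).to_numpy()
            families = pd.Series(families).reindex(ids).to_numpy()
    else:
        y = np.asarray(values, dtype=float)
    populations = np.asarray(populations, dtype=object)
    families = np.asarray(families, dtype=object)
    if not (len(y) == len(populations) == len(families)):
        raise ValueError("values and labels have mismatched lengths")
    pop_codes, fam_codes = _design(populations, families)
    n_pops = pop_codes.max() + 1
    n_fams = fam_codes.max() + 1
    if n_pops < 2:
        raise ValueError("need >= 2 populations")
    fam_per_pop = pd.Series(fam_codes).groupby(pd.Series(pop_codes)).nunique()
    if (fam_per_pop < 2).all():
        raise ValueError("need >= 2 families in at least one population")

    if np.ptp(y) == 0.0:
        # all observations identical: every component is exactly zero and
        # the ratios are undefined
        return VarianceComponents(0.0, 0.0, 0.0, method, True,
                                  n_pops, n_fams, len(y))

    v_pop0, v_fam0, v_err0 = _anova_mom(y, pop_codes, fam_codes)
    if method == "anova_mom":
        return VarianceComponents(v_pop0, v_fam0, v_err0, method, True,
                                  n_pops, n_fams, len(y))
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    prob = _RemlProblem(y, pop_codes, fam_codes)
    vt = np.var(y, ddof=1)
    floor = 1e-12 * vt
    starts = [
        (max(v_pop0, floor), max(v_fam0, floor), max(v_err0, floor)),
        (vt / 3.0, vt / 3.0, vt / 3.0),
        (floor, floor, vt),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            prob.neg2llr, x0=np.asarray(x0), method="Nelder-Mead",
            options={"xatol": 1e-10 * max(vt, 1.0),
                     "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    v_pop, v_fam, v_err = np.maximum(best.x, 0.0)
    return VarianceComponents(
        float(v_pop), float(v_fam), float(v_err), "reml",
        bool(np.isfinite(best.fun)), n_pops, n_fams, len(y),
        reml_neg2ll=float(best.fun),
    )


def parametric_bootstrap_vc(
    fit: VarianceComponents,
    populations,
    families,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    method: str | None = None,
    ci_method: str = "percentile",
    max_failures: float = 0.05,
) -> dict:
    """Parametric bootstrap of the variance components on the original design.

    Each replicate simulates new responses from the fitted model (normal
    population, family and residual effects) on the same population/family
    layout, refits with the same estimator, and records V_POP, V_FAM, V_ERR,
    V_TOT, Q_ST and H^2.  Returns ``{name: BootstrapDistribution}``.  More
    than ``max_failures`` non-converged replicates raises.
    """
    populations = np.asarray(populations, dtype=object)
    families = np.asarray(families, dtype=object)
    pop_codes, fam_codes = _design(populations, families)
    method = method or fit.method
    rng = np.random.default_rng(seed)
    n = len(pop_codes)
    n_pops, n_fams = pop_codes.max() + 1, fam_codes.max() + 1
    names = ["V_POP", "V_FAM", "V_ERR", "V_TOT", "Q_ST", "H2"]
    reps = {k: np.empty(n_boot) for k in names}
    failures = 0
    for b in range(n_boot):
        y = (
            rng.normal(0.0, np.sqrt(fit.v_pop), n_pops)[pop_codes]
            + rng.normal(0.0, np.sqrt(fit.v_fam), n_fams)[fam_codes]
            + rng.normal(0.0, np.sqrt(fit.v_err), n)
        )
        try:
            bf = variance_components(y, populations, families, method=method)
            if not bf.converged:
                raise RuntimeError("non-converged replicate")
            d = bf.as_dict()
        except Exception:  # degenerate replicate
            failures += 1
            d = {k: np.nan for k in names}
        for k in names:
            reps[k][b] = d[k]
    if failures > max_failures * n_boot:
        raise RuntimeError(
            f"parametric bootstrap: {failures}/{n_boot} replicates failed "
            f"(> {max_failures:.0%})"
        )
    point = fit.as_dict()
    out = {}
    for k in names:
        lo, hi = _bootstrap_ci(reps[k], point[k], level, ci_method)
        out[k] = BootstrapDistribution(
            name=k, replicates=reps[k], point=float(point[k]), level=level,
            ci_low=lo, ci_high=hi, ci_method=ci_method, seed=seed,
        )
    return out
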