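"""Growth-rate plasticity: reaction norms across winter and spring conditions.

Growth rate is the relative (log-difference) rate

    GR = (ln size_t2 - ln size_t1) / (days_t2 - days_t1)    [per day]

applied to rosette height (stem elongation, GR_SE) and to leaf area (GR_LA).
The winter rate spans days 21 -> 28 postgermination and the spring rate days
55 -> 63, bracketing the vernalization and spring chamber phases.

The plasticity breeding value of a maternal family is the family-level mean
of the absolute growth-rate difference between the two environments,
``Plast = mean_sibs |GR_winter - GR_spring|`` — an acclimatization magnitude,
computed separately for leaf area and stem elongation.  Because the two
traits are on different per-day scales, the combined "mean plasticity" is by
default the average of the two family values after z-standardization within
the analysis set (``standardize=False`` gives the raw average).

Species are compared with a mixed model: plasticity ~ species (fixed) +
population (random intercept), fit by REML, with parametric-bootstrap CIs on
the species means and significance by CI non-overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .popgen import BootstrapDistribution, _bootstrap_ci, ci_nonoverlap

logger = logging.getLogger(__name__)

#: Growth-record environments and the measurement days they span.
GROWTH_WINDOWS = {"winter": (21, 28), "spring": (55, 63)}


def growth_rate(size_t1, size_t2, days_t1, days_t2):
    """Relative growth rate ``(ln s2 - ln s1) / (d2 - d1)`` per day.

    Vectorized; raises on non-positive sizes or non-increasing days.
    """
    s1 = np.asarray(size_t1, dtype=float)
    s2 = np.asarray(size_t2, dtype=float)
    d1 = np.asarray(days_t1, dtype=float)
    d2 = np.asarray(days_t2, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("sizes must be positive")
    if np.any(d2 <= d1):
        raise ValueError("days_t2 must exceed days_t1")
    out = (np.log(s2) - np.log(s1)) / (d2 - d1)
    return float(out) if out.ndim == 0 else out


def growth_records_from_phenotypes(pt) -> pd.DataFrame:
    """Build tidy growth records from a phenotype table.

    Returns one row per individual x environment x trait with columns
    individual, population, family, environment, trait (``SE``/``LA``),
    size_t1, size_t2, day_t1, day_t2.
    """
    df = pt.data
    cols = {"SE": "height", "LA": "leaf_area"}
    recs = []
    for env, (d1, d2) in GROWTH_WINDOWS.items():
        for trait, stem in cols.items():
            c1, c2 = f"{stem}_d{d1}", f"{stem}_d{d2}"
            if c1 not in df.columns or c2 not in df.columns:
                continue
            sub = df[["individual", "population", "family", c1, c2]].copy()
            sub.columns = ["individual", "population", "family", "size_t1", "size_t2"]
            sub["environment"] = env
            sub["trait"] = trait
            sub["day_t1"] = d1
            sub["day_t2"] = d2
            recs.append(sub)
    return pd.concat(recs, ignore_index=True)


def family_plasticity(records: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Family-level plasticity breeding values from growth records.

    Per individual and trait, ``delta = |GR_winter - GR_spring|``; per
    family, ``Plast`` is the mean of delta over sibs (per-individual-first
    averaging).  Individuals lacking one environment are excluded and
    logged.  Returns one row per family with columns population, family,
    Plast_LA, Plast_SE, n_sibs and — when both traits are present —
    mean_plast (z-standardized average by default).
    """
    rec = records.copy()
    rec["GR"] = growth_rate(rec["size_t1"], rec["size_t2"],
                            rec["day_t1"], rec["day_t2"])
    wide = rec.pivot_table(
        index=["individual", "population", "family", "trait"],
        columns="environment", values="GR", aggfunc="mean",
    )
    incomplete = wide[["winter", "spring"]].isna().any(axis=1) \
        if {"winter", "spring"} <= set(wide.columns) else pd.Series(True, index=wide.index)
    for idx in wide.index[incomplete]:
        logger.info("family_plasticity: %s/%s lacks one environment; excluded",
                    idx[0], idx[3])
    wide = wide[~incomplete]
    if wide.empty:
        raise ValueError("no individual has growth rates in both environments")
    wide = wide.reset_index()
    wide["delta"] = (wide["winter"] - wide["spring"]).abs()
    fam = (
        wide.groupby(["population", "family", "trait"])
        .agg(plast=("delta", "mean"), n_sibs=("delta", "size"))
        .reset_index()
        .pivot(index=["population", "family"], columns="trait",
               values=["plast", "n_sibs"])
    )
    out = pd.DataFrame(index=fam.index)
    for trait in ("LA", "SE"):
        if ("plast", trait) in fam.columns:
            out[f"Plast_{trait}"] = fam[("plast", trait)]
    out["n_sibs"] = fam["n_sibs"].max(axis=1)
    if {"Plast_LA", "Plast_SE"} <= set(out.columns):
        if standardize:
            z = out[["Plast_LA", "Plast_SE"]].apply(
                lambda c: (c - c.mean()) / (c.std(ddof=1) if c.std(ddof=1) > 0 else 1.0)
            )
            out["mean_plast"] = z.mean(axis=1)
        else:
            out["mean_plast"] = out[["Plast_LA", "Plast_SE"]].mean(axis=1)
    return out.reset_index()


# ---------------------------------------------------------------------------
# species-level mixed model
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPlasticityFit:
    """REML fit of plasticity ~ species (fixed) + population (random)."""

    species_means: pd.Series
    v_pop: float
    v_err: float
    bootstrap: dict | None = None  # species -> BootstrapDistribution

    def significant_pairs(self, level: float = 0.95) -> dict:
        """CI non-overlap verdict for every species pair."""
        if self.bootstrap is None:
            raise ValueError("fit has no bootstrap distributions")
        names = list(self.bootstrap)
        out = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                out[(a, b)] = ci_nonoverlap(
                    self.bootstrap[a], self.bootstrap[b], level=level
                )
        return out


def _reml_species(y, sp_codes, pop_codes, n_species):
    """Profile REML for the one-random-factor model with species means fixed.

    With populations nested in species, V is block diagonal per population
    (V_p = v_err (I + lam J)), so GLS species means are inverse-variance
    weighted population means with weights w_p = n_p / (1 + lam n_p); the
    1-D profiled criterion in lam = v_pop/v_err is minimized numerically.
    """
    y = np.asarray(y, dtype=float)
    pops = np.unique(pop_codes)
    n_p = np.array([np.sum(pop_codes == p) for p in pops])
    ybar = np.array([y[pop_codes == p].mean() for p in pops])
    ss_within = float(sum(((y[pop_codes == p] - ybar[i]) ** 2).sum()
                          for i, p in enumerate(pops)))
    sp_of_pop = np.array([sp_codes[pop_codes == p][0] for p in pops])
    N, q = len(y), n_species

    def profile(lam):
        w = n_p / (1.0 + lam * n_p)
        beta = np.array([
            np.average(ybar[sp_of_pop == s], weights=w[sp_of_pop == s])
            if np.any(sp_of_pop == s) else np.nan
            for s in range(q)
        ])
        rss = ss_within + float((w * (ybar - beta[sp_of_pop]) ** 2).sum())
        v_err = rss / (N - q)
        logdet = float(np.sum(np.log1p(lam * n_p)))  # |I + lam J| per block
        logxvx = float(np.sum(np.log([w[sp_of_pop == s].sum() for s in range(q)])))
        neg2 = (N - q) * np.log(max(v_err, 1e-300)) + logdet + logxvx + (N - q)
        return neg2, beta, v_err

    res = optimize.minimize_scalar(
        lambda t: profile(np.exp(t) - 1.0)[0],
        bounds=(np.log(1.0), np.log(1e8)), method="bounded",
        options={"xatol": 1e-12},
    )
    lam = np.exp(res.x) - 1.0
    # compare against the boundary lam = 0 explicitly
    if profile(0.0)[0] <= profile(lam)[0]:
        lam = 0.0
    _, beta, v_err = profile(lam)
    return beta, lam * v_err, v_err


def species_plasticity_model(
    values: pd.DataFrame,
    response: str = "mean_plast",
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> SpeciesPlasticityFit:
    """Fit and bootstrap the species comparison of family plasticity values.

    ``values`` needs columns ``species``, ``population`` and ``response``
    (one row per family).  Species means are REML/GLS estimates accounting
    for the population random intercept; their uncertainty comes from a
    parametric bootstrap (simulate population effects and residuals from the
    fitted model, refit, collect the fixed-effect estimates).
    """
    df = values.dropna(subset=[response])
    sp_codes, sp_names = pd.factorize(df["species"])
    combo = df["species"].astype(str) + "//" + df["population"].astype(str)
    pop_codes, _ = pd.factorize(combo)
    if len(sp_names) < 2:
        raise ValueError("need >= 2 species")
    pops_per_sp = pd.Series(pop_codes).groupby(pd.Series(sp_codes)).nunique()
    if (pops_per_sp < 2).any():
        logger.warning(
            "species with a single population: the population random effect "
            "is degenerate there"
        )
    y = df[response].to_numpy(dtype=float)
    beta, v_pop, v_err = _reml_species(y, sp_codes, pop_codes, len(sp_names))

    boot = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        n_pops = pop_codes.max() + 1
        reps = np.empty((n_boot, len(sp_names)))
        for b in range(n_boot):
            yb = (
                beta[sp_codes]
                + rng.normal(0.0, np.sqrt(v_pop), n_pops)[pop_codes]
                + rng.normal(0.0, np.sqrt(v_err), len(y))
            )
            reps[b], _, _ = _reml_species(yb, sp_codes, pop_codes, len(sp_names))
        boot = {}
        for j, name in enumerate(sp_names):
            lo, hi = _bootstrap_ci(reps[:, j], beta[j], level, "percentile")
            boot[name] = BootstrapDistribution(
                name=f"plasticity[{response}]", replicates=reps[:, j],
                point=float(beta[j]), level=level, ci_low=lo, ci_high=hi,
                ci_method="percentile", seed=seed,
            )
    return SpeciesPlasticityFit(
        species_means=pd.Series(beta, index=list(sp_names)),
        v_pop=float(v_pop), v_err=float(v_err), bootstrap=boot,
    )
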