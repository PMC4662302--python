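"""Synthetic genotype, phenotype and occurrence data generators.

The generators reproduce the statistical structure the downstream estimators
assume, so every stage of the pipeline can be exercised and validated
without field data:

* **Genotypes** follow the Balding-Nichols island model: ancestral allele
  frequencies are flat-Dirichlet, population frequencies are
  ``Dirichlet(p_anc (1 - F_ST)/F_ST)`` (variance ``F_ST p(1-p)`` around the
  ancestral frequencies; ``target_fst = 0`` short-circuits to identical
  frequencies everywhere).  Individuals are drawn at inbreeding equilibrium
  for a partially selfing mating system: the two alleles are identical
  copies with probability ``F_IS = s/(2 - s)`` and independent draws
  otherwise.  Null alleles are injected by relabelling one allele class as
  the null code at a configurable fraction of loci (nulls remain a scorable
  class); genotypes go missing completely at random at ``missing_rate``.

* **Phenotypes** follow a nested random-effects model on a small number of
  latent factors, ``g = P_i + F_ij + e_ijk`` with variances (v_pop, v_fam,
  v_err); observed log-sizes are linear combinations of the (unit-scaled)
  factors plus trait-specific noise, exponentiated so sizes are strictly
  positive.  Because every factor shares the same variance ratios, any
  linear composite of the traits has among-population fraction
  ``v_pop/(v_pop + v_fam)`` by construction — the property the Q_ST
  machinery is tested against.  Heights and leaf areas at days 28 and 63
  are grown from family-by-environment growth rates with a family-level
  plasticity contrast of standard deviation ``plasticity_sd``.

* **Occurrences** are points jittered around population centroids placed
  uniformly in a bounding box.

Defaults emulate a study of four selfing montane mustards scored at 15
microsatellite-like loci: ~10 populations of 8 selfed maternal families
with 4 sibs each, moderate differentiation (F_ST 0.2), near-complete
selfing (s = 0.95), nulls at a fifth of loci and ~2% missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .comparative import OccurrenceSet
from .popgen import MISSING, NULL, GenotypeTable
from .quantgen import PhenotypeTable

logger = logging.getLogger(__name__)

_DEFAULT_LOADINGS = np.array([
    [0.9, 0.2, 0.1],
    [0.8, -0.3, 0.2],
    [0.7, 0.4, -0.2],
    [0.3, 0.8, 0.3],
    [-0.2, 0.7, 0.4],
    [0.1, -0.2, 0.9],
])

#: log-scale base size and dispersion per simulated trait
_TRAIT_SCALES = {
    "height_d21": (20.0, 0.25),
    "leaf_area_d21": (300.0, 0.30),
    "leaf_number_d21": (6.0, 0.20),
    "height_d55": (60.0, 0.25),
    "leaf_area_d55": (1200.0, 0.30),
    "leaf_number_d55": (12.0, 0.20),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; ``seed`` fully determines output."""

    n_pops: int = 10
    n_families_per_pop: int = 8
    sibs_per_family: int = 4
    inds_per_pop: int | None = None       # default: families x sibs
    n_loci: int = 15
    alleles_per_locus: int = 5
    target_fst: float = 0.2
    selfing_rate: float = 0.95
    null_allele_rate: float = 0.2         # fraction of loci carrying a null class
    missing_rate: float = 0.02
    v_pop: float = 1.0
    v_fam: float = 4.0
    v_err: float = 1.0
    trait_loading_matrix: np.ndarray = field(
        default_factory=lambda: _DEFAULT_LOADINGS.copy())
    trait_noise_sd: float = 0.3
    plasticity_sd: float = 0.02
    env_mean_gr: dict = field(
        default_factory=lambda: {"winter": 0.02, "spring": 0.08})
    gr_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        self.trait_loading_matrix = np.asarray(self.trait_loading_matrix, float)
        self.validate()

    def validate(self):
        counts = {
            "n_pops": self.n_pops, "n_families_per_pop": self.n_families_per_pop,
            "sibs_per_family": self.sibs_per_family, "n_loci": self.n_loci,
            "alleles_per_locus": self.alleles_per_locus,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a count >= 1, got {v}")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1) (1 is degenerate)")
        for name in ("selfing_rate", "null_allele_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("v_pop", "v_fam", "v_err", "plasticity_sd",
                     "trait_noise_sd", "gr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trait_loading_matrix.ndim != 2:
            raise ValueError("trait_loading_matrix must be traits x factors")

    @property
    def fis_eq(self) -> float:
        """Equilibrium inbreeding coefficient F_IS = s / (2 - s)."""
        s = self.selfing_rate
        return s / (2.0 - s)

    def pop_size(self) -> int:
        return (self.inds_per_pop if self.inds_per_pop is not None
                else self.n_families_per_pop * self.sibs_per_family)

    # -- IO ------------------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["trait_loading_matrix"] = self.trait_loading_matrix.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GenotypeTruth:
    """Generating frequencies behind a simulated genotype table."""

    ancestral_freqs: np.ndarray   # (L, k)
    pop_freqs: np.ndarray         # (L, P, k)
    fis_eq: float

    def true_hs(self) -> float:
        """Generating-model within-population gene diversity (plain scale)."""
        hs = 1.0 - np.sum(self.pop_freqs**2, axis=2)   # (L, P)
        return float(hs.mean())

    def true_ht(self) -> float:
        pbar = self.pop_freqs.mean(axis=1)             # (L, k)
        return float((1.0 - np.sum(pbar**2, axis=1)).mean())

    def true_fst(self) -> float:
        ht = self.true_ht()
        return (ht - self.true_hs()) / ht if ht > 0 else np.nan


def _labels(config: SimConfig):
    n = config.pop_size()
    nf = config.n_families_per_pop
    pops, fams, inds = [], [], []
    for p in range(config.n_pops):
        pname = f"pop{p + 1:02d}"
        for i in range(n):
            f = min(i * nf // n, nf - 1)
            pops.append(pname)
            fams.append(f"{pname}_f{f + 1:02d}")
            inds.append(f"{pname}_f{f + 1:02d}_s{i - (f * n // nf) + 1}")
    # sib index above is cosmetic; guarantee uniqueness
    seen = {}
    uniq = []
    for name in inds:
        seen[name] = seen.get(name, 0) + 1
        uniq.append(name if seen[name] == 1 else f"{name}_{seen[name]}")
    return (np.array(inds if len(set(inds)) == len(inds) else uniq, dtype=object),
            np.array(pops, dtype=object), np.array(fams, dtype=object))


def simulate_genotypes(config: SimConfig, return_truth: bool = False):
    """Balding-Nichols genotypes at inbreeding equilibrium.

    Returns a :class:`~rangegen.popgen.GenotypeTable`; with
    ``return_truth=True`` also the :class:`GenotypeTruth` generating
    frequencies (null-allele relabelling does not alter them — the null is
    just another scorable class).
    """
    rng = np.random.default_rng([config.seed, 0])
    logger.info("simulate_genotypes: seed=%s", config.seed)
    L, P, k = config.n_loci, config.n_pops, config.alleles_per_locus
    n = config.pop_size()
    F = config.fis_eq

    anc = rng.dirichlet(np.ones(k), size=L)              # (L, k)
    if config.target_fst == 0.0:
        pop_freqs = np.repeat(anc[:, None, :], P, axis=1)
    else:
        a = anc * (1.0 - config.target_fst) / config.target_fst
        pop_freqs = np.empty((L, P, k))
        for l in range(L):
            alpha = np.maximum(a[l], 1e-9)
            pop_freqs[l] = rng.dirichlet(alpha, size=P)

    inds, pops, fams = _labels(config)
    calls = np.empty((P * n, L, 2), dtype=np.int32)
    for p in range(P):
        rows = slice(p * n, (p + 1) * n)
        for l in range(L):
            cum = np.cumsum(pop_freqs[l, p])
            a1 = np.searchsorted(cum, rng.random(n), side="right").clip(0, k - 1)
            a2 = np.searchsorted(cum, rng.random(n), side="right").clip(0, k - 1)
            ident = rng.random(n) < F
            a2 = np.where(ident, a1, a2)
            calls[rows, l, 0] = a1 + 1   # allele codes are 1-based
            calls[rows, l, 1] = a2 + 1

    # null alleles: relabel one class at a fraction of loci
    null_loci = rng.random(L) < config.null_allele_rate
    for l in np.flatnonzero(null_loci):
        cls = rng.integers(1, k + 1)
        calls[:, l, :][calls[:, l, :] == cls] = NULL

    # missing completely at random, whole genotypes
    miss = rng.random((P * n, L)) < config.missing_rate
    calls[miss] = MISSING

    gt = GenotypeTable(inds, pops, [f"loc{l + 1:02d}" for l in range(L)],
                       calls, families=fams)
    if return_truth:
        return gt, GenotypeTruth(anc, pop_freqs, F)
    return gt


@dataclass
class PhenotypeTruth:
    """Generating values behind a simulated phenotype table."""

    latent: np.ndarray        # (n,) first nested factor, raw variance scale
    pop_effects: np.ndarray   # (P, n_factors)
    fam_effects: np.ndarray   # (n_families, n_factors)
    gr_family: pd.DataFrame   # family x (trait, env) growth rates


def simulate_phenotypes(config: SimConfig, structure=None,
                        return_truth: bool = False):
    """Nested-model phenotypes plus two-environment growth trajectories.

    ``structure``, when given, is a ``(populations, families)`` pair of
    label arrays (e.g. from a simulated genotype table) that overrides the
    layout implied by the config.  Sizes are generated multiplicatively (on
    the log scale) so they are strictly positive and log-difference growth
    rates are exact.
    """
    rng = np.random.default_rng([config.seed, 1])
    logger.info("simulate_phenotypes: seed=%s", config.seed)
    if structure is None:
        inds, pops, fams = _labels(config)
    else:
        pops, fams = (np.asarray(structure[0], dtype=object),
                      np.asarray(structure[1], dtype=object))
        inds = np.array([f"ind{i + 1:04d}" for i in range(len(pops))],
                        dtype=object)
    n = len(pops)
    pop_codes, pop_names = pd.factorize(pops)
    fam_codes, fam_names = pd.factorize(fams)

    Lam = config.trait_loading_matrix
    n_traits, n_factors = Lam.shape
    if n_traits != len(_TRAIT_SCALES):
        raise ValueError(
            f"trait_loading_matrix has {n_traits} rows; "
            f"{len(_TRAIT_SCALES)} simulated traits expected"
        )

    v_tot = config.v_pop + config.v_fam + config.v_err
    if v_tot <= 0:
        raise ValueError("v_pop + v_fam + v_err must be > 0")
    P_eff = rng.normal(0.0, np.sqrt(config.v_pop), (len(pop_names), n_factors))
    F_eff = rng.normal(0.0, np.sqrt(config.v_fam), (len(fam_names), n_factors))
    e_eff = rng.normal(0.0, np.sqrt(config.v_err), (n, n_factors))
    g_raw = P_eff[pop_codes] + F_eff[fam_codes] + e_eff      # (n, factors)
    g = g_raw / np.sqrt(v_tot)                               # unit total variance

    z = g @ Lam.T + rng.normal(0.0, config.trait_noise_sd, (n, n_traits))

    data = {"individual": inds, "population": pops, "family": fams}
    for t, (name, (base, scale)) in enumerate(_TRAIT_SCALES.items()):
        data[name] = base * np.exp(scale * z[:, t])
    df = pd.DataFrame(data)

    # family-by-environment growth rates; plasticity contrast d per family
    # and trait-type, SD(|GR_w - GR_s|) ~ plasticity_sd when the environment
    # contrast dominates
    envs = list(config.env_mean_gr)
    gr_rows = []
    gr_fam = {}
    for trait in ("SE", "LA"):
        d = rng.normal(0.0, config.plasticity_sd, len(fam_names))
        for j, fam in enumerate(fam_names):
            gr_fam[(trait, "winter", fam)] = config.env_mean_gr["winter"] + d[j] / 2.0
            gr_fam[(trait, "spring", fam)] = config.env_mean_gr["spring"] - d[j] / 2.0
    for trait, stem, (c1, d1, c2, d2) in (
        ("SE", "height", ("height_d21", 21, "height_d28", 28)),
        ("SE", "height", ("height_d55", 55, "height_d63", 63)),
        ("LA", "leaf_area", ("leaf_area_d21", 21, "leaf_area_d28", 28)),
        ("LA", "leaf_area", ("leaf_area_d55", 55, "leaf_area_d63", 63)),
    ):
        env = "winter" if d1 == 21 else "spring"
        gr = np.array([gr_fam[(trait, env, fam)] for fam in fams])
        gr = gr + rng.normal(0.0, config.gr_noise_sd, n)
        df[c2] = df[c1].to_numpy() * np.exp(gr * (d2 - d1))

    pt = PhenotypeTable(df)
    if return_truth:
        gr_df = pd.DataFrame(
            [(t, e, f, v) for (t, e, f), v in gr_fam.items()],
            columns=["trait", "environment", "family", "gr"],
        )
        truth = PhenotypeTruth(latent=g_raw[:, 0], pop_effects=P_eff,
                               fam_effects=F_eff, gr_family=gr_df)
        return pt, truth
    return pt


def simulate_occurrences(
    n_pops: int,
    extent: tuple,
    points_per_pop: int = 10,
    seed: int | None = None,
    jitter_deg: float = 0.03,
    species: str = "sim",
) -> OccurrenceSet:
    """Occurrence points jittered around uniform population centroids.

    ``extent`` is ``(lon_min, lon_max, lat_min, lat_max)`` in decimal
    degrees; it must have strictly positive width and height.
    ``jitter_deg = 0`` puts every point exactly on its centroid.
    """
    lon0, lon1, lat0, lat1 = map(float, extent)
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError("extent must have positive width and height")
    if n_pops < 1 or points_per_pop < 1:
        raise ValueError("n_pops and points_per_pop must be >= 1")
    rng = np.random.default_rng([seed if seed is not None else 0, 2])
    logger.info("simulate_occurrences: seed=%s", seed)
    cx = rng.uniform(lon0, lon1, n_pops)
    cy = rng.uniform(lat0, lat1, n_pops)
    lon = np.repeat(cx, points_per_pop) + rng.normal(
        0.0, jitter_deg, n_pops * points_per_pop) * (jitter_deg > 0)
    lat = np.repeat(cy, points_per_pop) + rng.normal(
        0.0, jitter_deg, n_pops * points_per_pop) * (jitter_deg > 0)
    return OccurrenceSet(
        species=species,
        lon=np.clip(lon, -180.0, 180.0),
        lat=np.clip(lat, -90.0, 90.0),
        populations=np.repeat([f"pop{p + 1:02d}" for p in range(n_pops)],
                              points_per_pop),
    )
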