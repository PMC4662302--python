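"""Molecular diversity and structure statistics for codominant genotype tables.

Implements Nei's hierarchical gene-diversity partitioning for multiallelic
codominant markers (microsatellite-style data):

    H_O   observed heterozygosity (mean over populations of the fraction of
          heterozygous individuals),
    H_S   mean within-population gene diversity, ``mean_p(1 - sum_a p_a^2)``,
    H_T   total gene diversity, ``1 - sum_a pbar_a^2`` with ``pbar`` the
          *unweighted* mean of population allele frequencies,
    D_ST  = H_T - H_S, absolute among-population differentiation,
    F_ST  = D_ST / H_T, proportional among-population differentiation,
    F_IS  = 1 - H_O / H_S, within-population inbreeding coefficient,
    A_e   = 1 / sum_a p_a^2, effective number of alleles per population.

Two estimator families are provided.  The ``plain`` (plug-in) estimators
satisfy the above identities exactly and are the default for testing; the
``sample_corrected`` estimators apply the Nei & Chesser small-sample
corrections with harmonic-mean sample sizes (formulas in ``basic_stats``).

Null alleles are a first-class, scorable allele class (code ``NULL``);
missing genotypes (code ``MISSING``) are excluded locus-wise from all counts.

Uncertainty is quantified by a rarefy-then-bootstrap scheme: each replicate
first subsamples every population to a common depth without replacement
(removing sample-size imbalance) and then resamples with replacement.  By
default confidence intervals use the basic (reverse-percentile) construction,
which corrects the first-order small-sample bias of the plug-in estimators;
percentile intervals are available via ``ci_method="percentile"``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allele code for a missing (unscored) call.  A genotype with any MISSING
#: slot is treated as unscored at that locus.
MISSING = 0

#: Allele code for a null allele.  Nulls are scorable: they enter allele
#: frequencies as one additional codominant class, and null/null homozygotes
#: count as homozygous for H_O.
NULL = 999

_STAT_NAMES = ("H_O", "H_S", "H_T", "D_ST", "F_ST", "F_IS")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Individuals x loci codominant diploid calls with population labels.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; each entry is an
    integer allele code, ``MISSING`` (0) for unscored slots and ``NULL``
    (999) for null alleles.
    """

    individuals: np.ndarray
    populations: np.ndarray
    loci: list
    calls: np.ndarray
    families: np.ndarray | None = None

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls)
        self.loci = list(self.loci)
        n = len(self.individuals)
        if len(set(self.individuals)) != n:
            raise ValueError("duplicated individual ids")
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2 alleles"
            )
        if len(self.populations) != n:
            raise ValueError("population labels do not match individuals")
        if any(p is None or str(p) == "" for p in self.populations):
            raise ValueError("population labels must be non-empty")
        if self.families is not None:
            self.families = np.asarray(self.families, dtype=object)
            if len(self.families) != n:
                raise ValueError("family labels do not match individuals")

    # -- basic structure ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def pop_names(self) -> list:
        """Population labels in order of first appearance."""
        return list(pd.unique(self.populations))

    def pop_sizes(self) -> dict:
        return {p: int(np.sum(self.populations == p)) for p in self.pop_names()}

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): genotype unscored at that locus."""
        return np.any(self.calls == MISSING, axis=2)

    def subset(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeTable(
            individuals=self.individuals[idx],
            populations=self.populations[idx],
            loci=self.loci,
            calls=self.calls[idx],
            families=None if self.families is None else self.families[idx],
        )

    def subset_populations(self, pops) -> "GenotypeTable":
        keep = np.isin(self.populations.astype(str), [str(p) for p in pops])
        return self.subset(keep)

    # -- IO ------------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Tidy CSV: individual, population, family, locus, allele1, allele2."""
        recs = []
        fams = self.families if self.families is not None else [""] * self.n_individuals
        for i in range(self.n_individuals):
            for l, locus in enumerate(self.loci):
                recs.append(
                    (self.individuals[i], self.populations[i], fams[i], locus,
                     int(self.calls[i, l, 0]), int(self.calls[i, l, 1]))
                )
        pd.DataFrame(
            recs, columns=["individual", "population", "family", "locus",
                           "allele1", "allele2"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, keep_default_na=False)
        loci = list(pd.unique(df["locus"]))
        inds = list(pd.unique(df["individual"]))
        ind_idx = {v: i for i, v in enumerate(inds)}
        loc_idx = {v: l for l, v in enumerate(loci)}
        calls = np.zeros((len(inds), len(loci), 2), dtype=np.int32)
        pops = np.empty(len(inds), dtype=object)
        fams = np.empty(len(inds), dtype=object)
        for row in df.itertuples(index=False):
            i = ind_idx[row.individual]
            l = loc_idx[row.locus]
            calls[i, l, 0] = int(row.allele1)
            calls[i, l, 1] = int(row.allele2)
            pops[i] = row.population
            fams[i] = row.family
        counts = df.groupby("individual", sort=False).size()
        if counts.nunique() > 1:
            raise ValueError("locus count mismatch between individuals")
        families = None if all(f == "" for f in fams) else fams
        return cls(np.array(inds, dtype=object), pops, loci, calls, families)

    def to_genepop(self, path, title="rangegen genotypes") -> None:
        """GenePop v4, 3-digit allele codes, 000 = missing, one POP per block."""
        lines = [title]
        lines.extend(str(l) for l in self.loci)
        for pop in self.pop_names():
            lines.append("POP")
            for i in np.flatnonzero(self.populations == pop):
                codes = " ".join(
                    f"{int(self.calls[i, l, 0]):03d}{int(self.calls[i, l, 1]):03d}"
                    for l in range(self.n_loci)
                )
                lines.append(f"{self.individuals[i]} ,  {codes}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_genepop(cls, path) -> "GenotypeTable":
        with open(path) as fh:
            raw = [ln.rstrip("\n") for ln in fh]
        raw = [ln for ln in raw if ln.strip() != ""]
        # first line is a title; locus names follow until the first POP record
        body = raw[1:]
        loci: list = []
        i = 0
        while i < len(body) and body[i].strip().lower() != "pop":
            # locus names may be one per line or comma separated
            loci.extend(s.strip() for s in body[i].split(",") if s.strip())
            i += 1
        inds, pops, rows = [], [], []
        pop_counter = 0
        pop_label = None
        while i < len(body):
            line = body[i].strip()
            if line.lower() == "pop":
                pop_counter += 1
                pop_label = f"pop{pop_counter}"
                i += 1
                continue
            if "," not in line:
                raise ValueError(f"unparseable genepop line: {line!r}")
            name, codes = line.split(",", 1)
            codes = codes.split()
            if len(codes) != len(loci):
                raise ValueError(
                    f"locus count mismatch for {name.strip()!r}: "
                    f"{len(codes)} codes for {len(loci)} loci"
                )
            alleles = []
            for c in codes:
                if len(c) not in (4, 6):
                    raise ValueError(f"bad allele code {c!r}")
                h = len(c) // 2
                alleles.append((int(c[:h]), int(c[h:])))
            inds.append(name.strip())
            pops.append(pop_label)
            rows.append(alleles)
            i += 1
        calls = np.array(rows, dtype=np.int32)
        return cls(np.array(inds, dtype=object), np.array(pops, dtype=object),
                   loci, calls)


@dataclass
class DiversityStats:
    """Per-locus and across-loci gene-diversity statistics.

    ``per_locus`` is indexed by locus with columns H_O, H_S, H_T, D_ST, F_ST,
    F_IS, A, A_e, pct_missing; ``overall`` is a Series of across-loci values.
    Overall H statistics are means over scored loci; overall D_ST, F_ST and
    F_IS are derived from the overall H components so that the defining
    identities hold exactly.  F_IS is reported clamped to [-1, 1]; the raw
    value is kept in ``per_locus["F_IS_raw"]``.
    """

    per_locus: pd.DataFrame
    overall: pd.Series
    estimator: str


@dataclass
class BootstrapDistribution:
    """Replicate values of one statistic plus its point estimate and CI."""

    name: str
    replicates: np.ndarray
    point: float
    level: float
    ci_low: float
    ci_high: float
    ci_method: str = "basic"
    seed: int | None = None
    depth: int | None = None

    def __post_init__(self):
        self.replicates = np.asarray(self.replicates, dtype=float)

    @property
    def n_boot(self) -> int:
        return len(self.replicates)

    def ci(self, level=None, method=None):
        """(lo, hi) interval, optionally at a different level or method."""
        level = self.level if level is None else level
        method = self.ci_method if method is None else method
        return _bootstrap_ci(self.replicates, self.point, level, method)


def _bootstrap_ci(reps, point, level, method):
    reps = np.asarray(reps, dtype=float)
    ok = reps[np.isfinite(reps)]
    if len(ok) == 0:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    qlo, qhi = np.quantile(ok, [alpha / 2.0, 1.0 - alpha / 2.0])
    if method == "percentile":
        return (float(qlo), float(qhi))
    if method == "basic":
        return (float(2.0 * point - qhi), float(2.0 * point - qlo))
    raise ValueError(f"unknown ci method {method!r}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str) -> GenotypeTable:
    """Read a genotype table from ``genepop`` or tidy ``csv`` format."""
    if format == "genepop":
        return GenotypeTable.from_genepop(path)
    if format == "csv":
        return GenotypeTable.from_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_individuals(gt: GenotypeTable, max_missing_loci: int = 4) -> GenotypeTable:
    """Drop individuals with missing genotypes at more than ``max_missing_loci`` loci.

    The default threshold of 4 mirrors the screening rule used for
    15-locus microsatellite panels (keep an individual only if it amplified
    at 11+ loci).  Each removal is logged.
    """
    n_missing = gt.missing_mask().sum(axis=1)
    keep = n_missing <= max_missing_loci
    for i in np.flatnonzero(~keep):
        logger.info(
            "filter_individuals: removing %s (%d missing loci > %d)",
            gt.individuals[i], n_missing[i], max_missing_loci,
        )
    if not keep.any():
        raise ValueError(
            f"all individuals removed at max_missing_loci={max_missing_loci}"
        )
    return gt.subset(keep)


# ---------------------------------------------------------------------------
# statistic core
# ---------------------------------------------------------------------------

class _CompactTable:
    """Per-table precomputation shared by basic_stats and the bootstrap.

    Allele codes are recoded per locus to 0..k_l-1 (missing -> -1) so counts
    can be accumulated with a single bincount per population.
    """

    def __init__(self, gt: GenotypeTable):
        n, L, _ = gt.calls.shape
        self.n, self.L = n, L
        self.codes = np.full((n, L, 2), -1, dtype=np.int64)
        self.k = np.zeros(L, dtype=int)
        self.allele_codes: list = []
        for l in range(L):
            col = gt.calls[:, l, :]
            scored = ~np.any(col == MISSING, axis=1)
            uniq = np.unique(col[scored])
            uniq = uniq[uniq != MISSING]
            self.allele_codes.append(uniq)
            self.k[l] = max(len(uniq), 1)
            if len(uniq):
                lookup = {a: j for j, a in enumerate(uniq)}
                for s in (0, 1):
                    vals = col[scored, s]
                    self.codes[scored, l, s] = [lookup[v] for v in vals]
        self.K = int(self.k.max())
        self.offsets = (np.arange(L) * self.K)[None, :, None]
        self.het = (gt.calls[:, :, 0] != gt.calls[:, :, 1]) & (self.codes[:, :, 0] >= 0)
        self.scored = self.codes[:, :, 0] >= 0
        pops = gt.pop_names()
        self.pop_names = pops
        pop_idx = {p: j for j, p in enumerate(pops)}
        self.pop_of = np.array([pop_idx[p] for p in gt.populations])
        self.P = len(pops)
        self.rows_by_pop = [np.flatnonzero(self.pop_of == j) for j in range(self.P)]

    def counts(self, rows_by_pop=None):
        """Allele counts (P, L, K), het counts (P, L), scored counts (P, L)."""
        if rows_by_pop is None:
            rows_by_pop = self.rows_by_pop
        P, L, K = len(rows_by_pop), self.L, self.K
        counts = np.zeros((P, L, K), dtype=np.int64)
        het = np.zeros((P, L), dtype=np.int64)
        scored = np.zeros((P, L), dtype=np.int64)
        for j, rows in enumerate(rows_by_pop):
            sub = self.codes[rows]
            valid = sub[:, :, 0] >= 0
            het[j] = np.sum(self.het[rows], axis=0)
            scored[j] = valid.sum(axis=0)
            flat = (sub + self.offsets)[valid.nonzero()[0], valid.nonzero()[1], :]
            counts[j] = np.bincount(flat.ravel(), minlength=L * K).reshape(L, K)
        return counts, het, scored


def _per_locus_stats(counts, het, scored, estimator="plain"):
    """Per-locus H_O, H_S, H_T (and helpers) from per-population counts.

    plain:
        H_S per population is the plug-in ``1 - sum p^2``; H_T uses the
        unweighted mean of population frequency vectors.
    sample_corrected (Nei & Chesser 1983, harmonic-mean sample size n~):
        Hs_hat = n~/(n~-1) * (mean_p(1 - sum p^2) - H_O/(2 n~))
        Ht_hat = 1 - sum pbar^2 + Hs_hat/(n~ s) - H_O/(2 n~ s)
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / (2.0 * scored)[:, :, None]
        ho_pop = het / scored
        hs_pop = 1.0 - np.einsum("plk,plk->pl", freqs, freqs)
    pop_ok = scored > 0  # population scored at this locus
    n_ok = pop_ok.sum(axis=0).astype(float)
    n_ok[n_ok == 0] = np.nan

    def popmean(x):
        return np.nansum(np.where(pop_ok, x, 0.0), axis=0) / n_ok

    H_O = popmean(ho_pop)
    hs_plug = popmean(hs_pop)
    pbar = np.nansum(np.where(pop_ok[:, :, None], freqs, 0.0), axis=0) / n_ok[:, None]
    ht_plug = 1.0 - np.einsum("lk,lk->l", pbar, pbar)

    if estimator == "plain":
        H_S, H_T = hs_plug, ht_plug
    elif estimator == "sample_corrected":
        with np.errstate(invalid="ignore", divide="ignore"):
            nharm = n_ok / np.nansum(np.where(pop_ok, 1.0 / scored, 0.0), axis=0)
            H_S = nharm / (nharm - 1.0) * (hs_plug - H_O / (2.0 * nharm))
            H_T = ht_plug + H_S / (nharm * n_ok) - H_O / (2.0 * nharm * n_ok)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        ae_pop = 1.0 / np.einsum("plk,plk->pl", freqs, freqs)
    A_e = popmean(ae_pop)
    A = (counts.sum(axis=0) > 0).sum(axis=1).astype(float)

    # monomorphic loci: diversities are exactly 0, ratios undefined
    mono = ht_plug <= 0.0
    H_O = np.where(mono, 0.0, H_O)
    H_S = np.where(mono, 0.0, H_S)
    H_T = np.where(mono, 0.0, H_T)
    return H_O, H_S, H_T, A, A_e, freqs, pop_ok


def _derived(H_O, H_S, H_T):
    with np.errstate(invalid="ignore", divide="ignore"):
        D_ST = H_T - H_S
        F_ST = np.where(H_T > 0, D_ST / np.where(H_T > 0, H_T, 1.0), np.nan)
        F_IS_raw = np.where(H_S > 0, 1.0 - H_O / np.where(H_S > 0, H_S, 1.0), np.nan)
    return D_ST, F_ST, F_IS_raw


def _overall_from_locus(H_O, H_S, H_T):
    """Across-loci summary: means of defined H components, ratios re-derived."""
    ok = np.isfinite(H_T) & np.isfinite(H_S) & np.isfinite(H_O)
    if not ok.any():
        return {k: np.nan for k in _STAT_NAMES}
    ho, hs, ht = H_O[ok].mean(), H_S[ok].mean(), H_T[ok].mean()
    dst = ht - hs
    fst = dst / ht if ht > 0 else np.nan
    fis = 1.0 - ho / hs if hs > 0 else np.nan
    return {"H_O": ho, "H_S": hs, "H_T": ht, "D_ST": dst, "F_ST": fst, "F_IS": fis}


def basic_stats(gt: GenotypeTable, estimator: str = "plain") -> DiversityStats:
    """Nei gene-diversity statistics per locus and across loci.

    Individuals missing at a locus are excluded at that locus only.  With a
    single population the partitioning statistics (H_T, D_ST, F_ST) are
    reported as NaN.  Raises if some population is unscored at every locus.
    """
    comp = _CompactTable(gt)
    counts, het, scored = comp.counts()
    dead = np.flatnonzero((scored > 0).sum(axis=1) == 0)
    if len(dead):
        raise ValueError(
            f"population(s) with zero scored individuals at every locus: "
            f"{[comp.pop_names[j] for j in dead]}"
        )
    H_O, H_S, H_T, A, A_e, _, _ = _per_locus_stats(counts, het, scored, estimator)
    if comp.P < 2:
        H_T = np.full_like(H_T, np.nan)
    D_ST, F_ST, F_IS_raw = _derived(H_O, H_S, H_T)
    pct_missing = 100.0 * (~comp.scored).sum(axis=0) / comp.n

    per_locus = pd.DataFrame(
        {
            "H_O": H_O, "H_S": H_S, "H_T": H_T, "D_ST": D_ST, "F_ST": F_ST,
            "F_IS": np.clip(F_IS_raw, -1.0, 1.0), "F_IS_raw": F_IS_raw,
            "A": A, "A_e": A_e, "pct_missing": pct_missing,
        },
        index=pd.Index(gt.loci, name="locus"),
    )
    overall = _overall_from_locus(H_O, H_S, H_T)
    if overall["F_IS"] is not np.nan and np.isfinite(overall["F_IS"]):
        overall["F_IS"] = float(np.clip(overall["F_IS"], -1.0, 1.0))
    overall["A"] = float(np.nanmean(A))
    overall["A_e"] = float(np.nanmean(A_e))
    overall["pct_missing"] = float(np.mean(pct_missing))
    return DiversityStats(per_locus, pd.Series(overall), estimator)


def effective_alleles(gt: GenotypeTable) -> pd.DataFrame:
    """Per-locus, per-population effective allele number A_e = 1/sum(p^2).

    Unscored locus/population combinations are NaN.  The species-level A_e
    (mean over populations, per locus) is appended as column ``species``.
    """
    comp = _CompactTable(gt)
    counts, het, scored = comp.counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / (2.0 * scored)[:, :, None]
        ae = 1.0 / np.einsum("plk,plk->pl", freqs, freqs)
    ae = np.where(scored > 0, ae, np.nan)
    df = pd.DataFrame(ae.T, index=pd.Index(gt.loci, name="locus"),
                      columns=comp.pop_names)
    df["species"] = np.nanmean(ae, axis=0)
    return df


# ---------------------------------------------------------------------------
# rarefy-then-bootstrap
# ---------------------------------------------------------------------------

def rarefy_bootstrap(
    gt: GenotypeTable,
    n_boot: int = 1000,
    depth="auto",
    level: float = 0.95,
    seed: int | None = None,
    estimator: str = "plain",
    ci_method: str = "basic",
    rarefy: bool = True,
    resample: bool = True,
) -> dict:
    """Rarefy-then-bootstrap distributions of the across-loci statistics.

    Per replicate: (i) rarefy — draw ``depth`` individuals *without*
    replacement from every population (``depth="auto"`` uses the smallest
    population size); (ii) bootstrap — resample ``depth`` individuals *with*
    replacement from each rarefied population; (iii) recompute the overall
    diversity statistics.  Point estimates come from the full, unrarefied
    table.  Both stages can be switched off independently (``rarefy=False``
    / ``resample=False``) for diagnostics.

    Returns ``{statistic: BootstrapDistribution}`` for H_O, H_S, H_T, D_ST,
    F_ST and F_IS.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    comp = _CompactTable(gt)
    sizes = np.array([len(r) for r in comp.rows_by_pop])
    if depth == "auto":
        depth = int(sizes.min())
    depth = int(depth)
    if depth < 1 or depth > sizes.min():
        raise ValueError(
            f"rarefaction depth {depth} exceeds the smallest population "
            f"size {sizes.min()}"
        )
    rng = np.random.default_rng(seed)
    logger.info(
        "rarefy_bootstrap: n_boot=%d depth=%d rarefy=%s resample=%s seed=%s",
        n_boot, depth, rarefy, resample, seed,
    )

    point_stats = basic_stats(gt, estimator=estimator).overall

    reps = {k: np.empty(n_boot) for k in _STAT_NAMES}
    for b in range(n_boot):
        rows_by_pop = []
        for rows in comp.rows_by_pop:
            sub = rng.choice(rows, size=depth, replace=False) if rarefy else rows
            if resample:
                sub = rng.choice(sub, size=len(sub), replace=True)
            rows_by_pop.append(sub)
        counts, het, scored = comp.counts(rows_by_pop)
        H_O, H_S, H_T, _, _, _, _ = _per_locus_stats(counts, het, scored, estimator)
        ov = _overall_from_locus(H_O, H_S, H_T)
        for k in _STAT_NAMES:
            reps[k][b] = ov[k]

    out = {}
    for k in _STAT_NAMES:
        point = float(point_stats[k])
        lo, hi = _bootstrap_ci(reps[k], point, level, ci_method)
        out[k] = BootstrapDistribution(
            name=k, replicates=reps[k], point=point, level=level,
            ci_low=lo, ci_high=hi, ci_method=ci_method, seed=seed, depth=depth,
        )
    return out


def ci_nonoverlap(a: BootstrapDistribution, b: BootstrapDistribution,
                  level: float = 0.95) -> bool:
    """True iff the two CIs at ``level`` are disjoint (shared endpoints overlap).

    This is the between-group significance rule used throughout the package:
    a difference is called significant only when the bootstrap confidence
    intervals of the two groups do not touch.
    """
    if a.name != b.name:
        raise ValueError(f"mismatched statistic names: {a.name!r} vs {b.name!r}")
    a_lo, a_hi = a.ci(level=level)
    b_lo, b_hi = b.ci(level=level)
    return bool(a_hi < b_lo or b_hi < a_lo)
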