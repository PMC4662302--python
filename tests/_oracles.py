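"""Independent brute-force oracles used to validate the main implementations.

Everything here is written with plain loops and first-principles formulas,
deliberately sharing no code with the package internals.
"""

import itertools
import math

import numpy as np

from rangegen.popgen import MISSING


# ---------------------------------------------------------------------------
# diversity statistics by direct counting
# ---------------------------------------------------------------------------

def brute_diversity(gt):
    """Per-locus H_O, H_S, H_T by direct counting over raw calls."""
    pops = list(dict.fromkeys(gt.populations))
    out = {"H_O": [], "H_S": [], "H_T": []}
    for l in range(gt.n_loci):
        ho_pops, hs_pops, freq_pops = [], [], []
        for p in pops:
            rows = [i for i in range(gt.n_individuals) if gt.populations[i] == p]
            genos = []
            for i in rows:
                a, b = int(gt.calls[i, l, 0]), int(gt.calls[i, l, 1])
                if a != MISSING and b != MISSING:
                    genos.append((a, b))
            if not genos:
                continue
            ho_pops.append(sum(a != b for a, b in genos) / len(genos))
            counts = {}
            for a, b in genos:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            tot = 2 * len(genos)
            freqs = {a: c / tot for a, c in counts.items()}
            hs_pops.append(1.0 - sum(f * f for f in freqs.values()))
            freq_pops.append(freqs)
        if not ho_pops:
            out["H_O"].append(np.nan)
            out["H_S"].append(np.nan)
            out["H_T"].append(np.nan)
            continue
        alleles = sorted({a for f in freq_pops for a in f})
        pbar = {a: sum(f.get(a, 0.0) for f in freq_pops) / len(freq_pops)
                for a in alleles}
        ht = 1.0 - sum(v * v for v in pbar.values())
        if ht <= 0:
            out["H_O"].append(0.0)
            out["H_S"].append(0.0)
            out["H_T"].append(0.0)
        else:
            out["H_O"].append(sum(ho_pops) / len(ho_pops))
            out["H_S"].append(sum(hs_pops) / len(hs_pops))
            out["H_T"].append(ht)
    return {k: np.array(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# modularity by exhaustive partition enumeration
# ---------------------------------------------------------------------------

def _set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def newman_girvan_q(graph, partition):
    """Q = sum_c (e_c - a_c^2) computed straight from the definition."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        cset = set(comm)
        within = sum(1 for u, v in graph.edges if u in cset and v in cset)
        ends = sum(graph.degree(v) for v in cset)
        q += within / m - (ends / (2.0 * m)) ** 2
    return q


def max_modularity_exhaustive(graph):
    """Maximum Q over all set partitions of the nodes (feasible for <= 7)."""
    nodes = list(graph.nodes)
    return max(newman_girvan_q(graph, part) for part in _set_partitions(nodes))


# ---------------------------------------------------------------------------
# partial correlation by regression residuals
# ---------------------------------------------------------------------------

def partial_corr_residual(X, i, j):
    """Partial correlation of rows i, j of X given all other rows.

    X is variables x observations; residuals from least-squares regression
    of each variable on the remaining ones are correlated.
    """
    others = [k for k in range(X.shape[0]) if k not in (i, j)]
    Z = np.column_stack([X[others].T, np.ones(X.shape[1])])
    ri = X[i] - Z @ np.linalg.lstsq(Z, X[i], rcond=None)[0]
    rj = X[j] - Z @ np.linalg.lstsq(Z, X[j], rcond=None)[0]
    return float(np.dot(ri, rj) / math.sqrt(np.dot(ri, ri) * np.dot(rj, rj)))


# ---------------------------------------------------------------------------
# closed-form simple OLS
# ---------------------------------------------------------------------------

def ols_closed_form(x, y):
    """Slope, intercept, r^2 and two-sided P (df = n - 2) from first principles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = sxy**2 / (sxx * syy)
    from scipy import stats as sps
    se = math.sqrt((syy - slope * sxy) / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


# ---------------------------------------------------------------------------
# random genotype tables for fuzzing
# ---------------------------------------------------------------------------

def random_table(rng, max_pops=5, max_loci=3):
    """Small random genotype table with missing calls and ragged pops."""
    from rangegen.popgen import GenotypeTable

    P = rng.integers(2, max_pops + 1)
    L = rng.integers(1, max_loci + 1)
    sizes = rng.integers(2, 8, P)
    n = int(sizes.sum())
    pops = np.repeat([f"p{j}" for j in range(P)], sizes)
    k = int(rng.integers(1, 5))
    calls = rng.integers(1, k + 1, size=(n, L, 2)).astype(np.int32)
    miss = rng.random((n, L)) < 0.1
    calls[miss] = MISSING
    # ensure every population keeps at least one scored locus
    for j in range(P):
        rows = np.flatnonzero(pops == f"p{j}")
        if np.all(calls[rows] == MISSING):
            calls[rows[0], 0] = (1, 1)
    inds = np.array([f"i{t}" for t in range(n)], dtype=object)
    return GenotypeTable(inds, pops, [f"L{l}" for l in range(L)], calls)
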