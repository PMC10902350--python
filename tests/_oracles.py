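"""Independent naive oracles used by the test suite.

Everything here is written symbol-by-symbol from the printed definitions,
with plain loops and no reuse of the package's optimised code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sd(xs, ddof=1):
    xs = list(map(float, xs))
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - ddof))


def mean(xs):
    xs = list(xs)
    return sum(map(float, xs)) / len(xs)


def pearson(a, b):
    a, b = list(map(float, a)), list(map(float, b))
    ma, mb = mean(a), mean(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


# --- site level: abundance matrix as T x S nested lists ---------------------


def alpha_stability(abund):
    totals = [sum(row) for row in abund]
    return mean(totals) / sd(totals)


def species_stability(abund):
    t = len(abund)
    s = len(abund[0])
    mu_i = mean([sum(row) for row in abund])
    acc = 0.0
    for j in range(s):
        col = [abund[k][j] for k in range(t)]
        mu_j = mean(col)
        acc += (mu_j / mu_i) * (sd(col) / mu_j)
    return 1.0 / acc


def gross_asynchrony(abund):
    t = len(abund)
    s = len(abund[0])
    mu_i = mean([sum(row) for row in abund])
    eta = 0.0
    for j in range(s):
        col = [abund[k][j] for k in range(t)]
        rest = [sum(abund[k]) - abund[k][j] for k in range(t)]
        eta -= (mean(col) / mu_i) * pearson(col, rest)
    return eta


def ldm_phi(abund):
    t = len(abund)
    s = len(abund[0])
    totals = [sum(row) for row in abund]
    sd_sum = sum(sd([abund[k][j] for k in range(t)]) for j in range(s))
    return (sd(totals) ** 2) / sd_sum**2


# --- metacommunity level: abundance as N x S x T nested lists ---------------


def _site_totals(t):
    n, s, tt = len(t), len(t[0]), len(t[0][0])
    return [[sum(t[i][j][k] for j in range(s)) for k in range(tt)] for i in range(n)]


def _metapop(t):
    n, s, tt = len(t), len(t[0]), len(t[0][0])
    return [[sum(t[i][j][k] for i in range(n)) for k in range(tt)] for j in range(s)]


def gamma_stability(t):
    tot = _site_totals(t)
    meta = [sum(col) for col in zip(*tot)]
    return mean(meta) / sd(meta)


def average_alpha_stability(t):
    """Inverse of the site-abundance-weighted mean site CV."""
    tot = _site_totals(t)
    mu_m = mean([sum(col) for col in zip(*tot)])
    acc = 0.0
    for series in tot:
        acc += (mean(series) / mu_m) * (sd(series) / mean(series))
    return 1.0 / acc


def average_species_stability(t):
    """Inverse of the abundance-weighted mean species CV across sites.

    The site-weighted sum of the per-site weighted species variabilities
    (the inverse of each site's species stability), inverted.
    """
    n, s, tt = len(t), len(t[0]), len(t[0][0])
    tot = _site_totals(t)
    mu_m = mean([sum(col) for col in zip(*tot)])
    acc = 0.0
    for i in range(n):
        mu_i = mean(tot[i])
        inner = 0.0
        for j in range(s):
            col = t[i][j]
            mu_j = mean(col)
            if mu_j > 0:
                inner += (mu_j / mu_i) * (sd(col) / mu_j)
        acc += (mu_i / mu_m) * inner
    return 1.0 / acc


def ass_literal_printed(t):
    """Average species stability with the inverse wrapped around a weighted
    sum of the (already inverted) per-site species stabilities — the other
    possible literal reading, kept to document its inconsistency."""
    n = len(t)
    tot = _site_totals(t)
    mu_m = mean([sum(col) for col in zip(*tot)])
    acc = 0.0
    for i in range(n):
        mu_i = mean(tot[i])
        s_i = len(t[i])
        tt = len(t[i][0])
        sp = species_stability([[t[i][j][k] for j in range(s_i)] for k in range(tt)])
        acc += (mu_i / mu_m) * sp
    return 1.0 / acc


def metapopulation_stability(t):
    pops = _metapop(t)
    tot = _site_totals(t)
    mu_m = mean([sum(col) for col in zip(*tot)])
    acc = 0.0
    for series in pops:
        mu_j = mean(series)
        if mu_j > 0:
            acc += (mu_j / mu_m) * (sd(series) / mu_j)
    return 1.0 / acc


def spatial_community_asynchrony(t):
    tot = _site_totals(t)
    mu = mean([sum(col) for col in zip(*tot)])
    val = 0.0
    for i, series in enumerate(tot):
        rest = [sum(x) - series[k] for k, x in enumerate(zip(*tot))]
        val -= (mean(series) / mu) * pearson(series, rest)
    return val


def spatial_species_asynchrony(t):
    n, s, tt = len(t), len(t[0]), len(t[0][0])
    tot = _site_totals(t)
    mu = mean([sum(col) for col in zip(*tot)])
    pops = _metapop(t)
    val, wsum = 0.0, 0.0
    terms = []
    for i in range(n):
        for j in range(s):
            col = t[i][j]
            rest = [pops[j][k] - col[k] for k in range(tt)]
            if sd(col) == 0 or sd(rest) == 0:
                continue
            w = mean(col) / mu
            terms.append((w, pearson(col, rest)))
            wsum += w
    for w, r in terms:
        val -= (w / wsum) * r
    return val


def average_species_asynchrony(t):
    n, s, tt = len(t), len(t[0]), len(t[0][0])
    tot = _site_totals(t)
    mu = mean([sum(col) for col in zip(*tot)])
    val = 0.0
    for i in range(n):
        site = [[t[i][j][k] for j in range(s)] for k in range(tt)]
        val += (mean(tot[i]) / mu) * gross_asynchrony(site)
    return val


def metapopulation_asynchrony(t):
    pops = _metapop(t)
    tot = _site_totals(t)
    mu = mean([sum(col) for col in zip(*tot)])
    val = 0.0
    for j, series in enumerate(pops):
        rest = [sum(x) - series[k] for k, x in enumerate(zip(*pops))]
        val -= (mean(series) / mu) * pearson(series, rest)
    return val


# --- graphs -----------------------------------------------------------------


def brute_force_mst_weight(d: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive search over edge subsets."""
    n = d.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(d[i, j] for i, j in combo))
    return best


# --- climatology ------------------------------------------------------------


def pooled_window_percentile(values_by_doy, doy, half_width, q):
    """Direct percentile of all values within the day-of-year window."""
    pool = []
    for off in range(-half_width, half_width + 1):
        d = (doy - 1 + off) % 366 + 1
        pool.extend(values_by_doy.get(d, []))
    return float(np.percentile(pool, q))
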