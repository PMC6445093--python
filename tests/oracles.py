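"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (exhaustive enumeration,
Floyd-Warshall, union-find, row-by-row rule application) and shares no
code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# graph oracles
# ---------------------------------------------------------------------------

def floyd_warshall(nodes, edges):
    """All-pairs shortest path lengths; dict[(u, v)] -> int or inf."""
    nodes = list(nodes)
    dist = {(u, v): (0 if u == v else math.inf)
            for u in nodes for v in nodes}
    for u, v in edges:
        dist[(u, v)] = dist[(v, u)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def clustering_by_triangles(nodes, edges):
    """Mean local clustering, degree-<2 nodes counted as 0."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    total = 0.0
    for n in nodes:
        nbrs = sorted(adj[n])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        total += 2.0 * links / (k * (k - 1))
    return total / len(nodes)


def path_length_mean(nodes, edges):
    """Mean shortest-path length over ordered connected pairs; None if none."""
    dist = floyd_warshall(nodes, edges)
    finite = [d for (u, v), d in dist.items() if u != v and math.isfinite(d)]
    return (sum(finite) / len(finite)) if finite else None


def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


def bfs_distance(nodes, edges, source):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


# ---------------------------------------------------------------------------
# selection-rule oracles
# ---------------------------------------------------------------------------

def per_cohort_rules(cohort: pd.DataFrame, fc_cutoff=1.25, p_cutoff=0.05,
                     score_cutoff=6.0):
    """Row-by-row re-application of the per-cohort candidate rules.

    Returns dict protein -> (fc, candidate) computed with its own t-test.
    """
    from scipy import stats

    out = {}
    for symbol in sorted(cohort["protein_symbol"].unique()):
        grp = cohort[cohort["protein_symbol"] == symbol]
        m = grp["abundance_M"].to_numpy(float)
        nm = grp["abundance_nonM"].to_numpy(float)
        fc = m.mean() / nm.mean()
        fc_ok = fc > fc_cutoff or fc < 1.0 / fc_cutoff
        if len(grp) == 1:
            row = grp.iloc[0]
            usable = (int(row["n_mapped_proteins"]) == 1
                      and float(row["peptide_score"]) >= score_cutoff)
            out[symbol] = (fc, bool(usable and fc_ok))
        else:
            d = np.log2(m) - np.log2(nm)
            if d.std(ddof=1) == 0:
                p_ok = not np.all(d == 0)   # degenerate nonzero mean: significant
            else:
                p_ok = stats.ttest_rel(np.log2(m), np.log2(nm)).pvalue < p_cutoff
            out[symbol] = (fc, bool(p_ok and fc_ok))
    return out


def concordance_rules(log2_table: pd.DataFrame, cohort_ids, fc_cutoff=1.25,
                      min_cohorts=3, combined_p_cutoff=0.1):
    """Row-by-row concordance rule on a log2 (cohort, channel) table.

    Returns dict protein -> direction ('up'/'down'/'none').
    """
    from scipy import stats

    out = {}
    for symbol in log2_table.index:
        fcs, diffs = [], []
        for c in cohort_ids:
            m = log2_table.loc[symbol, (c, "M")]
            nm = log2_table.loc[symbol, (c, "nonM")]
            if pd.isna(m) or pd.isna(nm):
                continue
            diffs.append(m - nm)
            fcs.append(2.0 ** (m - nm))
        n_up = sum(f > fc_cutoff for f in fcs)
        n_down = sum(f < 1.0 / fc_cutoff for f in fcs)
        d = np.array(diffs)
        if len(d) < 2:
            p_ok = False
        elif d.std(ddof=1) == 0:
            p_ok = not np.all(d == 0)
        else:
            t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
            p_ok = 2 * stats.t.sf(abs(t), len(d) - 1) < combined_p_cutoff
        if n_up >= min_cohorts and n_down == 0 and p_ok:
            out[symbol] = "up"
        elif n_down >= min_cohorts and n_up == 0 and p_ok:
            out[symbol] = "down"
        else:
            out[symbol] = "none"
    return out


# ---------------------------------------------------------------------------
# survival oracle
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta, times, events, x):
    """Negative log partial likelihood, single covariate, no ties."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return -ll
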