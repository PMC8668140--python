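"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written from first principles — explicit
loops, the t density integrated numerically — and never calls the code
paths it is used to check (no scipy.stats.t, no networkx).
"""

from __future__ import annotations

import math

from scipy.integrate import quad


def t_pdf(x: float, df: int) -> float:
    """Student t density from the closed-form normalizing constant."""
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))
    return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)


def t_two_tailed_p(t: float, df: int) -> float:
    """2 * P(T > |t|) by numerical integration of the density."""
    if math.isinf(t):
        return 0.0
    tail, _ = quad(t_pdf, abs(t), math.inf, args=(df,), epsabs=1e-14, epsrel=1e-12)
    return min(1.0, 2.0 * tail)


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value by bisection on the integrated tail."""
    lo, hi = 0.0, 1e3
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if t_two_tailed_p(mid, df) > alpha:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def pearson_loop(x, y) -> tuple[float, int]:
    """Pearson r via the definitional sums, pairwise-complete."""
    pairs = [
        (a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))
    ]
    n = len(pairs)
    if n < 3:
        return math.nan, n
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    if sxx == 0 or syy == 0:
        return math.nan, n
    return sxy / math.sqrt(sxx * syy), n


def pearson_p_loop(x, y) -> tuple[float, float, int]:
    r, n = pearson_loop(x, y)
    if math.isnan(r):
        return r, math.nan, n
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return r, t_two_tailed_p(t, n - 2), n


def significant_pairs(data, alpha: float = 0.05):
    """Brute-force thresholded edge set for a subjects x regions list of lists.

    Returns {(i, j): (r, p, n)} over index pairs i < j with defined r and
    p < alpha.
    """
    k = len(data[0])
    cols = [[row[j] for row in data] for j in range(k)]
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            r, p, n = pearson_p_loop(cols[i], cols[j])
            if not math.isnan(r) and p < alpha:
                out[(i, j)] = (r, p, n)
    return out


def all_pairs(data):
    """{(i, j): (r, p, n)} for every pair, NaNs preserved."""
    k = len(data[0])
    cols = [[row[j] for row in data] for j in range(k)]
    return {
        (i, j): pearson_p_loop(cols[i], cols[j])
        for i in range(k)
        for j in range(i + 1, k)
    }


def fisher_loop(r: float) -> float:
    r = max(-(1 - 1e-12), min(1 - 1e-12, r))
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def differential_pairs(task_data, control_data, alpha: float = 0.05, n_rule: str = "task_n"):
    """Brute-force subtraction network over index pairs.

    Returns (rows, retained): rows maps (i, j) -> (r_diff, t, df, p);
    retained is the subset with p < alpha. Pairs undefined in either
    condition are skipped.
    """
    t_pairs = all_pairs(task_data)
    c_pairs = all_pairs(control_data)
    rows, retained = {}, {}
    for key in t_pairs:
        r_t, _, n_t = t_pairs[key]
        r_c, _, n_c = c_pairs[key]
        if math.isnan(r_t) or math.isnan(r_c):
            continue
        n_used = {"task_n": n_t, "control_n": n_c, "min_n": min(n_t, n_c)}[n_rule]
        if n_used < 3:
            continue
        z = fisher_loop(r_t) - fisher_loop(r_c)
        r_d = math.tanh(z)
        df = n_used - 2
        if abs(r_d) >= 1.0:
            t, p = math.inf, 0.0
        else:
            t = r_d * math.sqrt(df) / math.sqrt(1.0 - r_d * r_d)
            p = t_two_tailed_p(t, df)
        rows[key] = (r_d, t, df, p)
        if p < alpha:
            retained[key] = (r_d, t, df, p)
    return rows, retained


def connected_components(nodes, edges):
    """Components by breadth-first search over an explicit adjacency list."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for v in nodes:
        if v in seen or not adj[v]:
            continue
        frontier, comp = [v], set()
        while frontier:
            u = frontier.pop()
            if u in comp:
                continue
            comp.add(u)
            frontier.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
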