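"""Independent brute-force oracles: explicit double/triple loops written
directly from the statistic definitions, kept free of any code shared
with the package implementations they check."""

import numpy as np


def alaam_statistics_loops(y, adj, covariates=None, include_degrees=True):
    """All ALAAM statistics by naive loops over pairs and triples."""
    n = len(y)
    xplus = [[int(adj[i][j] or adj[j][i]) for j in range(n)] for i in range(n)]
    out = {}
    out["intercept"] = sum(int(v) for v in y)
    if include_degrees:
        out["activity"] = sum(int(y[i]) * sum(int(adj[i][j]) for j in range(n))
                              for i in range(n))
        out["popularity"] = sum(int(y[i]) * sum(int(adj[j][i]) for j in range(n))
                                for i in range(n))
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        for k in range(covariates.shape[1]):
            out[f"cov{k}"] = sum(float(y[i]) * covariates[i, k] for i in range(n))
    direct = reciprocal = indirect = closed = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not (y[i] and y[j]):
                continue
            two_path = any(xplus[i][k] and xplus[k][j]
                           for k in range(n) if k not in (i, j))
            if xplus[i][j]:
                direct += 1
                if two_path:
                    closed += 1
            elif two_path:
                indirect += 1
            if adj[i][j] and adj[j][i]:
                reciprocal += 1
    transitive = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if (y[i] and y[j] and y[k] and xplus[i][j] and xplus[j][k]
                        and xplus[i][k]):
                    transitive += 1
    out.update(contagion_direct=direct, contagion_reciprocal=reciprocal,
               contagion_indirect=indirect, contagion_closed_indirect=closed,
               contagion_transitive=transitive)
    return out


def network_summary_loops(adj, n):
    """Ties, density, reciprocity, transitivity, isolates by counting."""
    ties = sum(int(adj[i][j]) for i in range(n) for j in range(n) if i != j)
    density = ties / (n * (n - 1))
    recip = (sum(1 for i in range(n) for j in range(n)
                 if i != j and adj[i][j] and adj[j][i]) / ties
             if ties else float("nan"))
    xp = [[int(i != j and (adj[i][j] or adj[j][i])) for j in range(n)]
          for i in range(n)]
    two_paths = closed = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i != j and j != k and i != k and xp[i][j] and xp[j][k]:
                    two_paths += 1
                    if xp[i][k]:
                        closed += 1
    transitivity = closed / two_paths if two_paths else float("nan")
    isolates = sum(1 for i in range(n)
                   if all(not adj[i][j] and not adj[j][i]
                          for j in range(n) if j != i))
    return {"ties": ties, "density": density, "reciprocity": recip,
            "transitivity": transitivity, "isolates": isolates}


def shortest_paths_floyd(adj, n):
    """All-pairs directed shortest-path lengths (inf if unreachable)."""
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def harmonic_centrality_loops(adj, n):
    """Sum over sources u of 1 / d(u, v); unreachable contributes 0."""
    d = shortest_paths_floyd(adj, n)
    return [sum(1.0 / d[u][v] for u in range(n)
                if u != v and d[u][v] != float("inf")) for v in range(n)]


def betweenness_loops(adj, n):
    """Directed shortest-path betweenness by explicit path enumeration."""
    inf = float("inf")
    d = shortest_paths_floyd(adj, n)

    def count_paths(s, t):
        # number of shortest s->t paths, by recursion on distance
        if s == t:
            return 1
        if d[s][t] == inf:
            return 0
        return sum(count_paths(s, u) for u in range(n)
                   if adj[u][t] and d[s][u] + 1 == d[s][t])

    def count_through(s, t, v):
        if d[s][t] == inf or d[s][v] + d[v][t] != d[s][t]:
            return 0
        return count_paths(s, v) * count_paths(v, t)

    bet = []
    for v in range(n):
        total = 0.0
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) == 3 and d[s][t] != inf:
                    total += count_through(s, t, v) / count_paths(s, t)
        bet.append(total)
    return bet


def latent_posterior_enumeration(k_mat, m_mat, lam1, lam0, alpha, beta):
    """Exact posterior tie probabilities for a tiny roster by summing over
    all 2^(n(n-1)) latent directed networks."""
    n = k_mat.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    npairs = len(pairs)
    lam1 = min(max(lam1, 1e-12), 1 - 1e-12)
    lam0 = min(max(lam0, 1e-12), 1 - 1e-12)
    post = np.zeros((n, n))
    total = 0.0
    for code in range(2 ** npairs):
        yvals = {}
        for b, (i, j) in enumerate(pairs):
            yvals[(i, j)] = (code >> b) & 1
        logp = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                a, bb = yvals[(i, j)], yvals[(j, i)]
                logp += alpha * (a + bb) + beta * a * bb
        for (i, j) in pairs:
            k, m = int(k_mat[i, j]), int(m_mat[i, j])
            lam = lam1 if yvals[(i, j)] else lam0
            logp += k * np.log(lam) + (m - k) * np.log(1 - lam)
        w = np.exp(logp)
        total += w
        for (i, j) in pairs:
            if yvals[(i, j)]:
                post[i, j] += w
    return post / total
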