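"""Independent reference implementations used only as test oracles.

These deliberately avoid the library's code paths: the D' oracle counts
the 2x2 haplotype contingency table directly, the clustering oracle
rebuilds the full adjacent-distance list from scratch at every step, and
the REML oracle maximizes the untransformed restricted likelihood with a
general-purpose optimizer.
"""
from __future__ import annotations

import numpy as np
from scipy import optimize

from haploblup.ld import cluster_distance


def dprime_contingency(a, b):
    """D' from explicit 2x2 haplotype counts (pairwise-complete)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n = len(a)
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = n - n11 - n10 - n01
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    pAB = n11 / n
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = max(-pA * pB, -(1 - pA) * (1 - pB))
    else:
        dmax = 0.0
    return D / dmax if dmax != 0 else 0.0


def reference_ld_clustering(g, targets: dict):
    """Quadratic-time adjacency-constrained complete-linkage clustering.

    Rebuilds the complete adjacent-cluster distance list by direct
    ``cluster_distance`` calls at every iteration; merges the leftmost
    minimum until each chromosome holds its target count.  Returns the
    partition as a list of index lists plus the merge-distance log.
    """
    chroms = g.snp_map["chrom"].to_numpy()
    partitions = []
    distances = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            chrom = chroms[start]
            clusters = [[j] for j in range(start, i)]
            while len(clusters) > targets[chrom]:
                dists = [
                    cluster_distance(clusters[j], clusters[j + 1], g)
                    for j in range(len(clusters) - 1)
                ]
                j = int(np.argmin(dists))
                distances.append(dists[j])
                clusters[j: j + 2] = [clusters[j] + clusters[j + 1]]
            partitions.extend(clusters)
            start = i
    return partitions, distances


def reml_direct(y, X, G, n_starts: int = 4):
    """REML by Nelder-Mead on the untransformed restricted likelihood.

    Maximizes -1/2 [log|V| + log|X'V^-1 X| + r' V^-1 r] over
    (log sigma_g^2, log sigma_e^2) with V = G sg2 + I se2 and r the GLS
    residual.  Returns (sg2, se2, h2).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float)
    n = len(y)

    def negll(theta):
        sg2, se2 = np.exp(theta)
        V = sg2 * G + se2 * np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        _, logdetXVX = np.linalg.slogdet(XtViX)
        return 0.5 * (logdetV + logdetXVX + quad)

    vy = np.var(y)
    best = None
    for f in np.linspace(0.1, 0.9, n_starts):
        res = optimize.minimize(
            negll,
            x0=np.log([max(f * vy, 1e-8), max((1 - f) * vy, 1e-8)]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    sg2, se2 = np.exp(best.x)
    return sg2, se2, sg2 / (sg2 + se2)
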