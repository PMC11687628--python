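"""Independent oracles used by the test suite.

These deliberately avoid the closed forms used by the package: OU means and
covariances are obtained by numerically integrating the piecewise moment
ODEs (m' = alpha (theta - m), v' = -2 alpha v + sigma^2) with an adaptive
Runge-Kutta solver; the Brownian rate comes from GLS on the full covariance
matrix; minimal regime-change counts come from exhaustive enumeration.
"""

import itertools

import numpy as np
from scipy.integrate import solve_ivp

from drivephy.phylo import Phylogeny, RegimeMap


def root_path(tree: Phylogeny, node: int) -> list[int]:
    """Branch-subtending nodes from the root down to ``node`` inclusive."""
    path = []
    while node != tree.root:
        path.append(node)
        node = int(tree.parent[node])
    return path[::-1]


def _segments(tree, regimes: RegimeMap, node):
    ridx = regimes.regime_index()
    return [(float(tree.blen[b]), ridx[regimes.branch_regime[b]]) for b in root_path(tree, node)]


def _integrate(rhs, y0, length):
    sol = solve_ivp(rhs, (0.0, length), y0, rtol=1e-11, atol=1e-14, method="DOP853")
    return sol.y[:, -1]


def ode_weights(tree, regimes, alphas, tip) -> np.ndarray:
    """Regime weight row for one tip: solve m' = alpha (1_r - m) per regime,
    plus the residual root weight appended to the root regime's column."""
    R = len(regimes.alphabet)
    segs = _segments(tree, regimes, tip)
    W = np.zeros(R)
    for r in range(R):
        m = np.array([0.0])
        for length, sr in segs:
            a = alphas[sr]
            theta = 1.0 if sr == r else 0.0
            m = _integrate(lambda t, y, a=a, th=theta: a * (th - y), m, length)
        W[r] = m[0]
    m = np.array([1.0])  # root contribution decays multiplicatively
    for length, sr in segs:
        a = alphas[sr]
        m = _integrate(lambda t, y, a=a: -a * y, m, length)
    ridx = regimes.regime_index()[regimes.root_regime]
    W[ridx] += m[0]
    return W


def ode_covariance(tree, regimes, alphas, sigmas) -> np.ndarray:
    """Tip covariance by integrating v' = -2 alpha v + sigma^2 along the
    shared path and attenuating along each tail (fixed root, v(0) = 0)."""
    M = tree.mrca_matrix()
    tips = tree.tip_ids
    nt = len(tips)
    paths = {t: _segments(tree, regimes, t) for t in tips}
    node_paths = {}
    V = np.zeros((nt, nt))
    for i in range(nt):
        for j in range(i, nt):
            m = int(M[i, j])
            shared = _segments(tree, regimes, m) if m != tree.root else []
            v = np.array([0.0])
            for length, sr in shared:
                a, s2 = alphas[sr], sigmas[sr]
                v = _integrate(lambda t, y, a=a, s2=s2: -2 * a * y + s2, v, length)
            cov = v[0]
            for tip in ((tips[i], tips[j]) if i != j else ()):
                tail = paths[tip][len(shared):]
                att = np.array([1.0])
                for length, sr in tail:
                    a = alphas[sr]
                    att = _integrate(lambda t, y, a=a: -a * y, att, length)
                cov *= att[0]
            if i == j:
                tail = paths[tips[i]][len(shared):]
                assert not tail
            V[i, j] = V[j, i] = cov
    return V


def gls_brownian_rate(tree, tip_values) -> float:
    """REML Brownian rate from the full covariance: (y-mu)' C^-1 (y-mu)/(n-1)
    with mu the GLS mean under C_ij = shared root-to-MRCA path length."""
    d = tree.depths()
    M = tree.mrca_matrix()
    C = d[M].copy()
    np.fill_diagonal(C, [d[i] for i in tree.tip_ids])
    y = np.array([float(tip_values[l]) for l in tree.tip_labels])
    Ci = np.linalg.inv(C)
    one = np.ones_like(y)
    mu = (one @ Ci @ y) / (one @ Ci @ one)
    r = y - mu
    return float(r @ Ci @ r / (len(y) - 1))


def gls_root_estimate(tree, tip_values) -> float:
    d = tree.depths()
    M = tree.mrca_matrix()
    C = d[M].copy()
    np.fill_diagonal(C, [d[i] for i in tree.tip_ids])
    y = np.array([float(tip_values[l]) for l in tree.tip_labels])
    Ci = np.linalg.inv(C)
    one = np.ones_like(y)
    return float((one @ Ci @ y) / (one @ Ci @ one))


def fitch_min_changes(tree, tip_regimes, alphabet) -> int:
    """Exhaustive minimum number of branches whose state differs from the
    parent's, over all internal-node labelings (root state free)."""
    internals = [n for n in range(tree.n_nodes) if not tree.is_tip(n)]
    tips = {n: tip_regimes[tree.labels[n]] for n in tree.tip_ids}
    best = np.inf
    for combo in itertools.product(alphabet, repeat=len(internals)):
        state = dict(zip(internals, combo))
        state.update(tips)
        changes = sum(
            1
            for n in range(tree.n_nodes)
            if n != tree.root and state[n] != state[int(tree.parent[n])]
        )
        best = min(best, changes)
    return int(best)
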