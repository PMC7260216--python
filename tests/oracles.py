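"""Independent oracle implementations used only by the test suite.

These deliberately avoid the package's own propagation kernels: the Mk
likelihood uses matrix exponentials, the birth-death likelihood a closed
form, and the SSE oracle a fixed-step Euler grid.
"""

import numpy as np
from scipy.linalg import expm


def mk_loglik(tree, states, Q, flat_root=True):
    """Pruning likelihood of a pure character (Mk) model via expm."""
    k = Q.shape[0]
    L = np.zeros((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        if tree.left[v] < 0:
            for s in states[tree.labels[v]]:
                L[v, s - 1] = 1.0
    for v in range(tree.n_nodes):
        if tree.left[v] >= 0:
            l, r = int(tree.left[v]), int(tree.right[v])
            Pl, Pr = expm(Q * tree.blen[l]), expm(Q * tree.blen[r])
            L[v] = (Pl @ L[l]) * (Pr @ L[r])
    root = L[tree.root]
    return float(np.log(root.mean() if flat_root else root.sum()))


def bd_loglik(tree, lam, mu):
    """Constant-rate birth-death log-likelihood on an ultrametric tree.

    Closed form for the single-lineage propagation with complete sampling:
    D(t) = D(0) * phi(t2)/phi(t1) with phi(t) = e^{rt} / (lam e^{rt} - mu)^2,
    one log(lam) per internal node (root merge included), no conditioning,
    matching a flat/any root weighting of a state-independent model.
    """
    r = lam - mu

    def logphi(t):
        return r * t - 2.0 * np.log(lam * np.exp(r * t) - mu)

    h = tree.node_heights()
    ll = np.log(lam) * (tree.n_nodes - tree.n_tips)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        ll += logphi(h[v] + tree.blen[v]) - logphi(h[v])
    return float(ll)


def euler_sse_loglik(tree, states, params, options, h=2e-5):
    """Fixed-grid forward-Euler SSE likelihood (independent integrator)."""
    k = params.k
    lam, mu, Q = params.lam, params.mu, params.Q
    Et = np.zeros((tree.n_nodes, k))
    Dt = np.zeros((tree.n_nodes, k))
    logs = 0.0
    for v in range(tree.n_nodes):
        if tree.left[v] < 0:
            e = np.zeros(k)
            d = np.zeros(k)
            for s in states[tree.labels[v]]:
                d[s - 1] = 1.0
        else:
            l, r = int(tree.left[v]), int(tree.right[v])
            e = 0.5 * (Et[l] + Et[r])
            d = lam * Dt[l] * Dt[r]
        s0 = d.sum()
        d = d / s0
        logs += np.log(s0)
        if v == tree.root:
            e_root, d_root = e, d
            break
        t = tree.blen[v]
        n = max(1, int(t / h))
        step = t / n
        for _ in range(n):
            de = mu - (lam + mu) * e + lam * e * e + Q @ e
            dd = -(lam + mu) * d + 2 * lam * e * d + Q @ d
            e = e + step * de
            d = d + step * dd
        sn = d.sum()
        d /= sn
        logs += np.log(sn)
        Et[v], Dt[v] = e, d
    if options.root_mode == "flat":
        pi = np.full(k, 1.0 / k)
    else:
        pi = d_root / d_root.sum()
    d = d_root
    if options.condition_survival:
        d = d / (pi * lam * (1 - e_root) ** 2).sum()
    return float(np.log((pi * d).sum()) + logs)


def brute_clamped_marginals(tree, states, params, options, rtol=1e-10):
    """Fix each node's state, recompute the FULL likelihood with scipy's
    own integrator, and normalize — the definitional marginal ASR."""
    from scipy.integrate import solve_ivp

    k = params.k
    lam, mu, Q = params.lam, params.mu, params.Q

    def ode(t, y):
        E, D = y[:k], y[k:]
        return np.concatenate([mu - (lam + mu) * E + lam * E * E + Q @ E,
                               -(lam + mu) * D + 2 * lam * E * D + Q @ D])

    def full_lik(clamp_node, clamp_state):
        Et = np.zeros((tree.n_nodes, k))
        Dt = np.zeros((tree.n_nodes, k))
        for v in range(tree.n_nodes):
            if tree.left[v] < 0:
                e = np.zeros(k)
                d = np.zeros(k)
                for s in states[tree.labels[v]]:
                    d[s - 1] = 1.0
            else:
                l, r = int(tree.left[v]), int(tree.right[v])
                e = 0.5 * (Et[l] + Et[r])
                d = lam * Dt[l] * Dt[r]
            if v == clamp_node:
                mask = np.zeros(k)
                mask[clamp_state] = 1.0
                d = d * mask
            if v == tree.root:
                e_root, d_root = e, d
                break
            if tree.blen[v] > 0:
                sol = solve_ivp(ode, (0, tree.blen[v]), np.concatenate([e, d]),
                                rtol=rtol, atol=1e-14)
                y = sol.y[:, -1]
                Et[v], Dt[v] = y[:k], y[k:]
            else:
                Et[v], Dt[v] = e, d
        if options.root_mode == "flat":
            pi = np.full(k, 1.0 / k)
        else:
            tot = d_root.sum()
            pi = d_root / tot if tot > 0 else np.full(k, 1.0 / k)
        d = d_root
        if options.condition_survival:
            d = d / (pi * lam * (1 - e_root) ** 2).sum()
        return float((pi * d).sum())

    out = np.zeros((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        ls = np.array([full_lik(v, j) for j in range(k)])
        out[v] = ls / ls.sum()
    return out
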