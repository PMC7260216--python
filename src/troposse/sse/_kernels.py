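"""Numerical kernels for SSE likelihood propagation.

The coupled per-branch system integrates, toward the root, the extinction
probabilities ``E_i(t)`` and data partial likelihoods ``D_i(t)``::

    dE_i/dt = mu_i - (lam_i + mu_i) E_i + lam_i E_i^2 + (Q E)_i
    dD_i/dt = -(lam_i + mu_i) D_i + 2 lam_i E_i D_i + (Q D)_i

with ``Q`` a zero-row-sum rate matrix.  Integration uses an embedded
Dormand-Prince 5(4) pair with standard proportional step control; the
system is smooth and non-stiff at diversification-rate scales, and an
allocation-free hand-rolled stepper keeps the per-branch cost low enough
for MCMC over hundreds of branches.  Kernels are jitted with numba when
available (a pure-NumPy fallback keeps the package functional without it).

``D`` is renormalized to unit sum at every node and branch top, with the
log-scaler accumulated, so large trees never underflow.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


STATUS_OK = 0
STATUS_NEGATIVE_D = 1
STATUS_STEP_FAILURE = 2

_MAX_STEPS = 100_000

# Dormand-Prince 5(4) coefficients (a-matrix rows, 5th-order weights b,
# and the embedded 4th-order error weights e = b - b_hat)
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_DP_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_E = _DP_B - np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                          -92097 / 339200, 187 / 2100, 1 / 40])


@njit(cache=True)
def _deriv_into(y, lam, mu, Q, k, out):
    for i in range(k):
        qe = 0.0
        qd = 0.0
        for j in range(k):
            qe += Q[i, j] * y[j]
            qd += Q[i, j] * y[k + j]
        E = y[i]
        D = y[k + i]
        out[i] = mu[i] - (lam[i] + mu[i]) * E + lam[i] * E * E + qe
        out[k + i] = -(lam[i] + mu[i]) * D + 2.0 * lam[i] * E * D + qd


@njit(cache=True)
def _rk45(y, t_total, lam, mu, Q, rtol, atol, F, ys):
    """Advance ``y = (E, D)`` over ``t_total``; returns a status code.

    Mutates ``y`` in place; ``F`` (7 x 2k) and ``ys`` (2k) are caller-owned
    scratch so repeated calls allocate nothing.
    """
    k = lam.size
    n2 = 2 * k
    if t_total <= 0.0:
        return STATUS_OK
    t = 0.0
    h = t_total
    _deriv_into(y, lam, mu, Q, k, F[0])
    for _ in range(_MAX_STEPS):
        if t >= t_total:
            return STATUS_OK
        if h > t_total - t:
            h = t_total - t
        for s in range(1, 6):
            for i in range(n2):
                acc = 0.0
                for m in range(s):
                    acc += _DP_A[s, m] * F[m, i]
                ys[i] = y[i] + h * acc
            _deriv_into(ys, lam, mu, Q, k, F[s])
        for i in range(n2):                      # 5th-order solution
            acc = 0.0
            for m in range(6):
                acc += _DP_B[m] * F[m, i]
            ys[i] = y[i] + h * acc
        _deriv_into(ys, lam, mu, Q, k, F[6])
        err = 0.0
        for i in range(n2):
            ei = 0.0
            for m in range(7):
                ei += _DP_E[m] * F[m, i]
            ei *= h
            sc = atol + rtol * max(abs(y[i]), abs(ys[i]))
            err += (ei / sc) * (ei / sc)
        err = np.sqrt(err / n2)
        if err <= 1.0:
            t += h
            for i in range(n2):
                y[i] = ys[i]
            for i in range(n2):                  # FSAL
                F[0, i] = F[6, i]
            for i in range(k):                   # clamp round-off excursions
                if y[i] < 0.0:
                    if y[i] < -1e-8:
                        return STATUS_STEP_FAILURE
                    y[i] = 0.0
                elif y[i] > 1.0:
                    if y[i] > 1.0 + 1e-8:
                        return STATUS_STEP_FAILURE
                    y[i] = 1.0
                if y[k + i] < 0.0:
                    if y[k + i] < -1e-6:
                        return STATUS_NEGATIVE_D
                    y[k + i] = 0.0
        if err == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
        h *= fac
        if h < 1e-14 * t_total:
            return STATUS_STEP_FAILURE
    return STATUS_STEP_FAILURE


@njit(cache=True)
def _postorder_pass(left, right, blen, D0, lam, mu, Q, rtol, atol):
    """Full tip-to-root pass.

    Returns ``(status, bad_node, E_node, D_node, E_top, D_top, logscale)``:
    per-node quantities at the node itself (post-merge, ``D`` normalized)
    and at the rootward top of its branch.  ``logscale`` accumulates every
    normalization so ``log L = log(root combination) + logscale``.
    """
    n = left.size
    k = lam.size
    E_node = np.zeros((n, k))
    D_node = np.zeros((n, k))
    E_top = np.zeros((n, k))
    D_top = np.zeros((n, k))
    F = np.empty((7, 2 * k))
    ys = np.empty(2 * k)
    y = np.empty(2 * k)
    logscale = 0.0
    root = n - 1
    for v in range(n):
        if left[v] < 0:
            for i in range(k):
                y[i] = 0.0            # E at the present: complete sampling
                y[k + i] = D0[v, i]
        else:
            l, r = left[v], right[v]
            for i in range(k):
                y[i] = 0.5 * (E_top[l, i] + E_top[r, i])
                y[k + i] = lam[i] * D_top[l, i] * D_top[r, i]
        s = 0.0
        for i in range(k):
            s += y[k + i]
        if s <= 0.0 or not np.isfinite(s):
            return STATUS_NEGATIVE_D, v, E_node, D_node, E_top, D_top, logscale
        for i in range(k):
            y[k + i] /= s
        logscale += np.log(s)
        for i in range(k):
            E_node[v, i] = y[i]
            D_node[v, i] = y[k + i]
        if v == root:
            break
        if blen[v] > 0.0:
            status = _rk45(y, blen[v], lam, mu, Q, rtol, atol, F, ys)
            if status != STATUS_OK:
                return status, v, E_node, D_node, E_top, D_top, logscale
            s2 = 0.0
            for i in range(k):
                s2 += y[k + i]
            if s2 <= 0.0 or not np.isfinite(s2):
                return STATUS_NEGATIVE_D, v, E_node, D_node, E_top, D_top, logscale
            for i in range(k):
                E_top[v, i] = y[i]
                D_top[v, i] = y[k + i] / s2
            logscale += np.log(s2)
        else:
            for i in range(k):
                E_top[v, i] = E_node[v, i]
                D_top[v, i] = D_node[v, i]
    return STATUS_OK, -1, E_node, D_node, E_top, D_top, logscale


def propagate_branch(E0, D0, t, lam, mu, Q, rtol=1e-8, atol=1e-10):
    """Python-facing single-branch propagation (used by ancestral-state
    machinery).  Returns ``(E1, D1_normalized, log_scale)``."""
    lam = np.asarray(lam, float)
    mu = np.asarray(mu, float)
    Q = np.asarray(Q, float)
    k = lam.size
    y = np.empty(2 * k)
    y[:k] = E0
    y[k:] = D0
    F = np.empty((7, 2 * k))
    ys = np.empty(2 * k)
    status = _rk45(y, float(t), lam, mu, Q, rtol, atol, F, ys)
    if status != STATUS_OK:
        raise ArithmeticError(f"branch integration failed (status {status})")
    s = y[k:].sum()
    if s <= 0.0:
        return y[:k], y[k:], -np.inf
    return y[:k], y[k:] / s, float(np.log(s))
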