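"""Fused inner-loop kernels for the primal-dual solver.

Optional acceleration: the numpy implementation in :mod:`hmfsolver` is
the reference; these kernels perform the identical update with far less
memory traffic.  Import is guarded — when numba is unavailable the
solver transparently falls back to numpy.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def pd_iteration(u, u_bar, f, p, A, bounds, sigma, tau):  # pragma: no cover - numba
    """One primal-dual iteration in place.

    Updates ``p`` (dual ascent + box projection), then ``u`` and ``u_bar``
    (primal descent + simplex projection).  Returns
    ``(sum |du|, sum |dp|/bound)`` for the convergence test.
    """
    N = A.shape[0]
    K = A.shape[1]
    X, Y, Z = u.shape[1], u.shape[2], u.shape[3]

    dp_sum = 0.0
    for n in range(N):
        b0, b1, b2 = bounds[n, 0], bounds[n, 1], bounds[n, 2]
        if b0 <= 0.0 and b1 <= 0.0 and b2 <= 0.0:
            continue
        agg = np.zeros((X, Y, Z), dtype=np.float32)
        for l in range(K):
            if A[n, l] != 0.0:
                for x in range(X):
                    for y in range(Y):
                        for z in range(Z):
                            agg[x, y, z] += u_bar[l, x, y, z]
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    a = agg[x, y, z]
                    if x < X - 1:
                        g = agg[x + 1, y, z] - a
                    else:
                        g = 0.0
                    old = p[n, 0, x, y, z]
                    v = old + sigma * g
                    if v > b0:
                        v = b0
                    elif v < -b0:
                        v = -b0
                    if b0 > 0.0:
                        dp_sum += abs(v - old) / b0
                    p[n, 0, x, y, z] = v

                    if y < Y - 1:
                        g = agg[x, y + 1, z] - a
                    else:
                        g = 0.0
                    old = p[n, 1, x, y, z]
                    v = old + sigma * g
                    if v > b1:
                        v = b1
                    elif v < -b1:
                        v = -b1
                    if b1 > 0.0:
                        dp_sum += abs(v - old) / b1
                    p[n, 1, x, y, z] = v

                    if z < Z - 1:
                        g = agg[x, y, z + 1] - a
                    else:
                        g = 0.0
                    old = p[n, 2, x, y, z]
                    v = old + sigma * g
                    if v > b2:
                        v = b2
                    elif v < -b2:
                        v = -b2
                    if b2 > 0.0:
                        dp_sum += abs(v - old) / b2
                    p[n, 2, x, y, z] = v

    du_sum = 0.0
    vloc = np.empty(K, dtype=np.float32)
    sloc = np.empty(K, dtype=np.float32)
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                for l in range(K):
                    g = f[l, x, y, z]
                    for n in range(N):
                        if A[n, l] != 0.0:
                            for ax in range(3):
                                cur = p[n, ax, x, y, z]
                                if ax == 0:
                                    prev = p[n, 0, x - 1, y, z] if x > 0 else 0.0
                                elif ax == 1:
                                    prev = p[n, 1, x, y - 1, z] if y > 0 else 0.0
                                else:
                                    prev = p[n, 2, x, y, z - 1] if z > 0 else 0.0
                                g -= cur - prev
                    vloc[l] = u[l, x, y, z] - tau * g
                # simplex projection of vloc (sort descending)
                for l in range(K):
                    sloc[l] = vloc[l]
                for i in range(1, K):
                    key = sloc[i]
                    j = i - 1
                    while j >= 0 and sloc[j] < key:
                        sloc[j + 1] = sloc[j]
                        j -= 1
                    sloc[j + 1] = key
                css = np.float32(0.0)
                theta = np.float32(0.0)
                for k in range(K):
                    css += sloc[k]
                    t = (css - 1.0) / (k + 1.0)
                    if sloc[k] - t > 0.0:
                        theta = t
                for l in range(K):
                    nv = vloc[l] - theta
                    if nv < 0.0:
                        nv = 0.0
                    old = u[l, x, y, z]
                    du_sum += abs(nv - old)
                    u_bar[l, x, y, z] = 2.0 * nv - old
                    u[l, x, y, z] = nv
    return du_sum, dp_sum
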