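"""Numba kernels for the per-direction upwind DG transport sweeps.

A sweep solves, for every discrete direction, the advection--attenuation
operator (omega . grad + mua + mus) exactly by marching elements in upwind
order and solving one 3x3 system per element (linear basis per triangle).
The scattering integral enters only through the lagged nodal source ``f``.
"""

import numpy as np
from numba import njit

# Treat |omega . n| below this as a non-coupling (tangential) edge; must match
# the tolerance used when building the upwind element order.
DEG_TOL = 1e-12


@njit(cache=True)
def sweep_all(order, ainv, an, elen, neigh, nb_a, nb_b, bedge, bmom, f, areas):
    """One exact transport sweep for every direction.

    Parameters (shapes): order (P,T); ainv (P,T,3,3); an (P,T,3); elen (T,3);
    neigh/nb_a/nb_b/bedge (T,3); bmom (P,B,2); f (P,T,3) nodal source values;
    areas (T,).  Returns u (P,T,3).
    """
    P, T = order.shape
    u = np.zeros((P, T, 3))
    for p in range(P):
        for idx in range(T):
            k = order[p, idx]
            a12 = areas[k] / 12.0
            f0 = f[p, k, 0]
            f1 = f[p, k, 1]
            f2 = f[p, k, 2]
            r0 = a12 * (2.0 * f0 + f1 + f2)
            r1 = a12 * (f0 + 2.0 * f1 + f2)
            r2 = a12 * (f0 + f1 + 2.0 * f2)
            rhs = np.empty(3)
            rhs[0] = r0
            rhs[1] = r1
            rhs[2] = r2
            for l in range(3):
                s = an[p, k, l]
                if s < -DEG_TOL:
                    a = l
                    b = (l + 1) % 3
                    t2 = neigh[k, l]
                    if t2 >= 0:
                        ta = u[p, t2, nb_a[k, l]]
                        tb = u[p, t2, nb_b[k, l]]
                        c = s * elen[k, l] / 6.0
                        rhs[a] -= c * (2.0 * ta + tb)
                        rhs[b] -= c * (ta + 2.0 * tb)
                    else:
                        be = bedge[k, l]
                        rhs[a] -= s * bmom[p, be, 0]
                        rhs[b] -= s * bmom[p, be, 1]
            for i in range(3):
                u[p, k, i] = (ainv[p, k, i, 0] * rhs[0]
                              + ainv[p, k, i, 1] * rhs[1]
                              + ainv[p, k, i, 2] * rhs[2])
    return u
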