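"""Independent plain TV Split Bregman solver used as a test oracle.

Deliberately written from scratch (own gradient code, own CG loop, no
support variable) so it shares nothing with the package's SCoLD
implementation except the projection operator, whose correctness is
established separately by adjoint and chord-length tests.
"""

import numpy as np


def grad2d(u):
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1] = u[1:] - u[:-1]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def div2d(gx, gy):
    d = np.zeros_like(gx)
    d[0] = gx[0]
    d[1:-1] = gx[1:-1] - gx[:-2]
    d[-1] = -gx[-2]
    d2 = np.zeros_like(gy)
    d2[:, 0] = gy[:, 0]
    d2[:, 1:-1] = gy[:, 1:-1] - gy[:, :-2]
    d2[:, -1] = -gy[:, -2]
    return d + d2


def shrink_iso(gx, gy, t):
    m = np.sqrt(gx * gx + gy * gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(m > 0, np.maximum(m - t, 0.0) / np.where(m > 0, m, 1.0),
                     0.0)
    return gx * s, gy * s


def tv_split_bregman(op, f, mu, lam, n_outer, n_cg=12):
    """Plain TV-L2 Split Bregman with data Bregman updates."""
    shape = op.shape
    u = np.zeros(shape, np.float64)
    dx = np.zeros(shape)
    dy = np.zeros(shape)
    bx = np.zeros(shape)
    by = np.zeros(shape)
    fk = f.astype(np.float64).copy()
    for _ in range(n_outer):
        rhs = mu * op.back(fk.astype(np.float64)).data \
            - lam * div2d(dx - bx, dy - by)

        def matvec(x):
            atax = op.back(op.forward(x.astype(np.float64)).data).data
            gx, gy = grad2d(x)
            return mu * atax - lam * div2d(gx, gy)

        # hand-rolled conjugate gradients
        r = rhs - matvec(u)
        p = r.copy()
        rs = np.sum(r * r)
        for _ in range(n_cg):
            ap = matvec(p)
            alpha = rs / max(np.sum(p * ap), 1e-30)
            u = u + alpha * p
            r = r - alpha * ap
            rs_new = np.sum(r * r)
            if np.sqrt(rs_new) < 1e-10:
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
        gx, gy = grad2d(u)
        dx, dy = shrink_iso(gx + bx, gy + by, 1.0 / lam)
        bx = bx + gx - dx
        by = by + gy - dy
        fk = fk + f - op.forward(u).data
    return u
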