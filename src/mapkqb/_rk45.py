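"""Compiled Dormand-Prince 5(4) integrator for the four-state cascade.

The right-hand side is inlined in scalar form so that a single likelihood
evaluation (eight ODE solves) costs a few milliseconds.  The kernel mirrors
:func:`mapkqb.model.rhs` exactly; their agreement is enforced by the test
suite.  Output values at requested times are obtained by cubic Hermite
interpolation on accepted steps, which at the default tolerances contributes
an error far below the step-error control.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["integrate_cascade"]


@numba.njit(cache=True, inline="always")
def _u_of_t(t, K, ku, t_off):
    if t < 0.0 or t >= t_off:
        return 0.0
    t3 = t * t * t
    return ku * (1.0 - t3 / (t3 + K * K * K))


@numba.njit(cache=True, inline="always")
def _f(t, x1, x2, x3, x4, th, fp, fn, mek, s1, s2, s3, ku, t_off):
    # th order: k1p k2p k3p k4p k1m k2m k3m k4m kFn kFp g K
    u = _u_of_t(t, th[11], ku, t_off)
    h = 0.0
    if fp == 1.0 and x4 > 0.0:
        yg = x4 ** th[10]
        h = yg / (1.0 + yg)
    a = th[0] * u + fp * th[9] * h
    b = th[4] + fn * th[8] * x4
    k2 = th[1] * (1.0 - mek)
    d1 = a * (s1 - x1) - b * x1
    d2 = k2 * x1 * (s2 - x2) - th[5] * x2
    d3 = th[2] * x2 * (s3 - x3 - x4) - th[6] * x3 - th[3] * x2 * x3 + th[7] * x4
    d4 = th[3] * x2 * x3 - th[7] * x4
    return d1, d2, d3, d4


@numba.njit(cache=True)
def _integrate(t_out, x0, th, fp, fn, mek, s1, s2, s3, ku, t_off, rtol, atol,
               max_steps):
    n_out = t_out.shape[0]
    Y = np.zeros((n_out, 4))
    x1, x2, x3, x4 = x0[0], x0[1], x0[2], x0[3]
    t = 0.0
    io = 0
    while io < n_out and t_out[io] <= 0.0:
        Y[io, 0], Y[io, 1], Y[io, 2], Y[io, 3] = x1, x2, x3, x4
        io += 1
    T = t_out[n_out - 1]
    f1, f2, f3, f4 = _f(t, x1, x2, x3, x4, th, fp, fn, mek, s1, s2, s3, ku, t_off)
    h = 1e-3
    nstep = 0
    status = 0
    while t < T:
        if h > T - t:
            h = T - t
        # never step across the input-termination discontinuity
        if t < t_off and t + h > t_off and t_off < T:
            h = t_off - t
        k11, k12, k13, k14 = f1, f2, f3, f4
        a = 0.2 * h
        k21, k22, k23, k24 = _f(t + 0.2 * h, x1 + a * k11, x2 + a * k12,
                                x3 + a * k13, x4 + a * k14,
                                th, fp, fn, mek, s1, s2, s3, ku, t_off)
        b1 = h * 3.0 / 40.0
        b2 = h * 9.0 / 40.0
        k31, k32, k33, k34 = _f(t + 0.3 * h,
                                x1 + b1 * k11 + b2 * k21,
                                x2 + b1 * k12 + b2 * k22,
                                x3 + b1 * k13 + b2 * k23,
                                x4 + b1 * k14 + b2 * k24,
                                th, fp, fn, mek, s1, s2, s3, ku, t_off)
        c1 = h * 44.0 / 45.0
        c2 = -h * 56.0 / 15.0
        c3 = h * 32.0 / 9.0
        k41, k42, k43, k44 = _f(t + 0.8 * h,
                                x1 + c1 * k11 + c2 * k21 + c3 * k31,
                                x2 + c1 * k12 + c2 * k22 + c3 * k32,
                                x3 + c1 * k13 + c2 * k23 + c3 * k33,
                                x4 + c1 * k14 + c2 * k24 + c3 * k34,
                                th, fp, fn, mek, s1, s2, s3, ku, t_off)
        d1 = h * 19372.0 / 6561.0
        d2 = -h * 25360.0 / 2187.0
        d3 = h * 64448.0 / 6561.0
        d4 = -h * 212.0 / 729.0
        k51, k52, k53, k54 = _f(t + 8.0 / 9.0 * h,
                                x1 + d1 * k11 + d2 * k21 + d3 * k31 + d4 * k41,
                                x2 + d1 * k12 + d2 * k22 + d3 * k32 + d4 * k42,
                                x3 + d1 * k13 + d2 * k23 + d3 * k33 + d4 * k43,
                                x4 + d1 * k14 + d2 * k24 + d3 * k34 + d4 * k44,
                                th, fp, fn, mek, s1, s2, s3, ku, t_off)
        e1 = h * 9017.0 / 3168.0
        e2 = -h * 355.0 / 33.0
        e3 = h * 46732.0 / 5247.0
        e4 = h * 49.0 / 176.0
        e5 = -h * 5103.0 / 18656.0
        k61, k62, k63, k64 = _f(t + h,
                                x1 + e1 * k11 + e2 * k21 + e3 * k31 + e4 * k41 + e5 * k51,
                                x2 + e1 * k12 + e2 * k22 + e3 * k32 + e4 * k42 + e5 * k52,
                                x3 + e1 * k13 + e2 * k23 + e3 * k33 + e4 * k43 + e5 * k53,
                                x4 + e1 * k14 + e2 * k24 + e3 * k34 + e4 * k44 + e5 * k54,
                                th, fp, fn, mek, s1, s2, s3, ku, t_off)
        w1 = h * 35.0 / 384.0
        w3 = h * 500.0 / 1113.0
        w4 = h * 125.0 / 192.0
        w5 = -h * 2187.0 / 6784.0
        w6 = h * 11.0 / 84.0
        xn1 = x1 + w1 * k11 + w3 * k31 + w4 * k41 + w5 * k51 + w6 * k61
        xn2 = x2 + w1 * k12 + w3 * k32 + w4 * k42 + w5 * k52 + w6 * k62
        xn3 = x3 + w1 * k13 + w3 * k33 + w4 * k43 + w5 * k53 + w6 * k63
        xn4 = x4 + w1 * k14 + w3 * k34 + w4 * k44 + w5 * k54 + w6 * k64
        g1, g2, g3, g4 = _f(t + h, xn1, xn2, xn3, xn4,
                            th, fp, fn, mek, s1, s2, s3, ku, t_off)
        q1 = 71.0 / 57600.0
        q3 = -71.0 / 16695.0
        q4 = 71.0 / 1920.0
        q5 = -17253.0 / 339200.0
        q6 = 22.0 / 525.0
        q7 = -1.0 / 40.0
        er1 = h * (q1 * k11 + q3 * k31 + q4 * k41 + q5 * k51 + q6 * k61 + q7 * g1)
        er2 = h * (q1 * k12 + q3 * k32 + q4 * k42 + q5 * k52 + q6 * k62 + q7 * g2)
        er3 = h * (q1 * k13 + q3 * k33 + q4 * k43 + q5 * k53 + q6 * k63 + q7 * g3)
        er4 = h * (q1 * k14 + q3 * k34 + q4 * k44 + q5 * k54 + q6 * k64 + q7 * g4)
        sc1 = atol + rtol * max(abs(x1), abs(xn1))
        sc2 = atol + rtol * max(abs(x2), abs(xn2))
        sc3 = atol + rtol * max(abs(x3), abs(xn3))
        sc4 = atol + rtol * max(abs(x4), abs(xn4))
        err = np.sqrt(((er1 / sc1) ** 2 + (er2 / sc2) ** 2
                       + (er3 / sc3) ** 2 + (er4 / sc4) ** 2) / 4.0)
        nstep += 1
        if err <= 1.0:
            while io < n_out and t_out[io] <= t + h + 1e-14:
                s = (t_out[io] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                h10 = s * (1.0 - s) ** 2 * h
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0) * h
                Y[io, 0] = h00 * x1 + h10 * f1 + h01 * xn1 + h11 * g1
                Y[io, 1] = h00 * x2 + h10 * f2 + h01 * xn2 + h11 * g2
                Y[io, 2] = h00 * x3 + h10 * f3 + h01 * xn3 + h11 * g3
                Y[io, 3] = h00 * x4 + h10 * f4 + h01 * xn4 + h11 * g4
                io += 1
            t += h
            x1, x2, x3, x4 = xn1, xn2, xn3, xn4
            f1, f2, f3, f4 = g1, g2, g3, g4
        if err > 1e-30:
            fac = 0.9 * err ** (-0.2)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-13:
            h = 1e-13
        if not np.isfinite(x1 + x2 + x3 + x4):
            status = 2
            break
        if nstep > max_steps:
            status = 1
            break
    while io < n_out:
        Y[io, 0], Y[io, 1], Y[io, 2], Y[io, 3] = x1, x2, x3, x4
        io += 1
    return Y, status


def integrate_cascade(t_out, x0, theta_arr, fp, fn, mek_inhibited,
                      s, ku, t_off, rtol, atol, max_steps=5_000_000):
    """Integrate the cascade from ``x0`` at ``t=0``; returns ``(Y, status)``.

    ``status`` is 0 on success, 1 if the step budget was exhausted and 2 if
    the state became non-finite.
    """
    return _integrate(
        np.ascontiguousarray(t_out, dtype=np.float64),
        np.ascontiguousarray(x0, dtype=np.float64),
        np.ascontiguousarray(theta_arr, dtype=np.float64),
        1.0 if fp else 0.0, 1.0 if fn else 0.0,
        1.0 if mek_inhibited else 0.0,
        float(s[0]), float(s[1]), float(s[2]),
        float(ku), float(t_off) if t_off is not None else 1e300,
        float(rtol), float(atol), max_steps,
    )
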