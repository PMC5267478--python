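"""Independent numerical oracles used by the test suite.

Everything here re-derives model quantities from scratch (term-by-term RHS,
analytic Jacobian, fixed-step RK4, batched damped Newton) so the package
implementation is checked against code paths it does not share.
"""

import numpy as np


def rhs_terms(x, u, p, fp, fn, s=(1.0, 1.0, 1.0), mek_inhibited=False,
              feedback_removed=False):
    """Term-by-term re-evaluation of the cascade vector field.

    ``p`` is a dict of the twelve constants.  Each reaction term is written
    out separately and summed at the end.
    """
    x1, x2, x3, x4 = x
    s1, s2, s3 = s
    kFp = 0.0 if feedback_removed else p["kFp"]
    kFn = 0.0 if feedback_removed else p["kFn"]
    k2p = 0.0 if mek_inhibited else p["k2p"]

    h = x4 ** p["g"] / (1.0 + x4 ** p["g"]) if x4 > 0 else 0.0
    raf_phos_input = p["k1p"] * u * (s1 - x1)
    raf_phos_feedback = (kFp * h * (s1 - x1)) if fp else 0.0
    raf_dephos_basal = -p["k1m"] * x1
    raf_dephos_feedback = (-kFn * x4 * x1) if fn else 0.0
    d1 = raf_phos_input + raf_phos_feedback + raf_dephos_basal + raf_dephos_feedback

    mek_phos = k2p * x1 * (s2 - x2)
    mek_dephos = -p["k2m"] * x2
    d2 = mek_phos + mek_dephos

    erk_first_phos = p["k3p"] * x2 * (s3 - x3 - x4)
    erk_first_dephos = -p["k3m"] * x3
    erk_second_phos = -p["k4p"] * x2 * x3
    erk_second_dephos = p["k4m"] * x4
    d3 = erk_first_phos + erk_first_dephos + erk_second_phos + erk_second_dephos

    d4 = p["k4p"] * x2 * x3 - p["k4m"] * x4
    return np.array([d1, d2, d3, d4])


def rk4_fixed(f, x0, t_grid, h):
    """Classic fixed-step RK4 between the requested output times."""
    x = np.asarray(x0, dtype=float)
    out = [x.copy()]
    t = t_grid[0]
    for t_next in t_grid[1:]:
        n = max(1, int(np.ceil((t_next - t) / h)))
        hh = (t_next - t) / n
        for _ in range(n):
            k1 = f(x, t)
            k2 = f(x + 0.5 * hh * k1, t + 0.5 * hh)
            k3 = f(x + 0.5 * hh * k2, t + 0.5 * hh)
            k4 = f(x + hh * k3, t + hh)
            x = x + hh / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += hh
        out.append(x.copy())
        t = t_next
    return np.array(out)


def batch_rhs(X, u, p, fp, fn, s=(1.0, 1.0, 1.0)):
    """Vectorized cascade RHS for an (n, 4) batch of states."""
    x1, x2, x3, x4 = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
    s1, s2, s3 = s
    x4p = np.maximum(x4, 0.0)
    h = np.where(x4p > 0, x4p ** p["g"] / (1.0 + x4p ** p["g"]), 0.0)
    a = p["k1p"] * u + (p["kFp"] * h if fp else 0.0)
    b = p["k1m"] + (p["kFn"] * x4 if fn else 0.0)
    F = np.empty_like(X)
    F[:, 0] = a * (s1 - x1) - b * x1
    F[:, 1] = p["k2p"] * x1 * (s2 - x2) - p["k2m"] * x2
    F[:, 2] = (p["k3p"] * x2 * (s3 - x3 - x4) - p["k3m"] * x3
               - p["k4p"] * x2 * x3 + p["k4m"] * x4)
    F[:, 3] = p["k4p"] * x2 * x3 - p["k4m"] * x4
    return F


def batch_jacobian(X, u, p, fp, fn, s=(1.0, 1.0, 1.0)):
    """Analytic Jacobians for an (n, 4) batch of states: (n, 4, 4)."""
    n = X.shape[0]
    x1, x2, x3, x4 = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
    s1, s2, s3 = s
    g = p["g"]
    x4p = np.maximum(x4, 1e-300)
    hval = x4p ** g / (1.0 + x4p ** g)
    hprime = g * x4p ** (g - 1.0) / (1.0 + x4p ** g) ** 2
    a = p["k1p"] * u + (p["kFp"] * hval if fp else 0.0)
    b = p["k1m"] + (p["kFn"] * x4 if fn else 0.0)
    J = np.zeros((n, 4, 4))
    J[:, 0, 0] = -(a + b)
    J[:, 0, 3] = (p["kFp"] * hprime * (s1 - x1) if fp else 0.0) \
        - (p["kFn"] * x1 if fn else 0.0)
    J[:, 1, 0] = p["k2p"] * (s2 - x2)
    J[:, 1, 1] = -(p["k2p"] * x1 + p["k2m"])
    J[:, 2, 1] = p["k3p"] * (s3 - x3 - x4) - p["k4p"] * x3
    J[:, 2, 2] = -(p["k3p"] * x2 + p["k3m"] + p["k4p"] * x2)
    J[:, 2, 3] = -p["k3p"] * x2 + p["k4m"]
    J[:, 3, 1] = p["k4p"] * x3
    J[:, 3, 2] = p["k4p"] * x2
    J[:, 3, 3] = -p["k4m"]
    return J


def newton_steady_states(p, u, fp, fn, s=(1.0, 1.0, 1.0), n_starts=200,
                         seed=0, tol=1e-11, max_iter=80):
    """Multi-start damped Newton on the full 4-D system.

    Returns ``(states, n_stable)`` where states is a list of distinct
    converged roots (clustered at 1e-7) inside the conservation box and
    stability is judged from the analytic Jacobian eigenvalues.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3 = s
    X = np.empty((n_starts, 4))
    X[:, 0] = rng.uniform(0, s1, n_starts)
    X[:, 1] = rng.uniform(0, s2, n_starts)
    w = rng.uniform(0, 1, (n_starts, 2))
    w.sort(axis=1)
    X[:, 2] = w[:, 0] * s3
    X[:, 3] = (w[:, 1] - w[:, 0]) * s3
    X[0] = 0.0  # always include the origin as a start

    active = np.ones(n_starts, dtype=bool)
    for _ in range(max_iter):
        F = batch_rhs(X, u, p, fp, fn, s)
        nrm = np.linalg.norm(F, axis=1)
        active = nrm > tol
        if not active.any():
            break
        J = batch_jacobian(X[active], u, p, fp, fn, s)
        try:
            step = np.linalg.solve(J, F[active][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # singular Jacobian at some start: fall back to gradient descent
            step = 0.1 * F[active]
        # damped update: backtrack until the residual decreases
        Xa = X[active]
        na = nrm[active]
        lam = np.ones(len(Xa))
        for _ in range(12):
            Xn = Xa - lam[:, None] * step
            nn = np.linalg.norm(batch_rhs(Xn, u, p, fp, fn, s), axis=1)
            worse = nn > na
            if not worse.any():
                break
            lam[worse] *= 0.5
        X[active] = Xa - lam[:, None] * step

    F = batch_rhs(X, u, p, fp, fn, s)
    ok = np.linalg.norm(F, axis=1) < 1e-9
    # keep roots inside (a slightly padded) conservation box
    pad = 1e-7
    box = ((X[:, 0] > -pad) & (X[:, 0] < s1 + pad)
           & (X[:, 1] > -pad) & (X[:, 1] < s2 + pad)
           & (X[:, 2] > -pad) & (X[:, 3] > -pad)
           & (X[:, 2] + X[:, 3] < s3 + pad))
    roots = X[ok & box]
    clusters = []
    for r in roots:
        if not any(np.max(np.abs(r - c)) < 1e-7 for c in clusters):
            clusters.append(r)
    n_stable = 0
    stable_flags = []
    for c in clusters:
        J = batch_jacobian(np.array([c]), u, p, fp, fn, s)[0]
        ev = np.linalg.eigvals(J)
        stable = bool(np.all(ev.real < -1e-9))
        stable_flags.append(stable)
        n_stable += stable
    return clusters, stable_flags
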