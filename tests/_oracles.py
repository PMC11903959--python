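"""Naive, independent reference implementations used to check the package.

Everything here is deliberately written the slow, obvious way (explicit
Python loops, no shared code with the package internals).
"""

import numpy as np


def df_naive(ca_coords):
    """Population variance and mean of every pairwise distance, double loop."""
    f, n, _ = ca_coords.shape
    df = np.zeros((n, n))
    meand = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.array([np.linalg.norm(ca_coords[k, i] - ca_coords[k, j])
                          for k in range(f)])
            m = d.mean()
            v = np.mean((d - m) ** 2)
            df[i, j] = df[j, i] = v
            meand[i, j] = meand[j, i] = m
    return df, meand


def lf_naive(df, residues, mode="window"):
    """Per-residue local fluctuation honoring terminus clipping."""
    offsets = (-2, -1, 1, 2) if mode == "window" else (-2, 2)
    serial = {key: i for i, key in enumerate(residues)}
    lf_i = []
    for i, (chain, resid) in enumerate(residues):
        vals = []
        for o in offsets:
            key = (chain, resid + o)
            if key in serial:
                vals.append(df[i, serial[key]])
        lf_i.append(sum(vals) / len(vals))
    lf_i = np.array(lf_i)
    return lf_i.mean(), lf_i


def eta_naive(df, meand, lf, gate=5.0):
    n = df.shape[0]
    eta = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and meand[i, j] > gate and df[i, j] < lf:
                eta[i] += 1
    return eta


def pct_naive(df_mut, df_wt, floor=1e-6):
    n = df_wt.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j and df_wt[i, j] >= floor:
                out[i, j] = 100.0 * (df_mut[i, j] - df_wt[i, j]) / df_wt[i, j]
    return out


def frame_filter_naive(times_ps, discard_ps, stride):
    """Frame-by-frame retention: keep times > discard, then every stride-th."""
    kept = [i for i, t in enumerate(times_ps) if t > discard_ps]
    return kept[::stride]


def brute_force_min_rmsd(x, y, n_rot=60000, seed=0):
    """Minimum RMSD over random rigid motions (after centering both sets)."""
    rng = np.random.default_rng(seed)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    q = rng.standard_normal((n_rot, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, a, b, c = q.T
    rots = np.empty((n_rot, 3, 3))
    rots[:, 0, 0] = 1 - 2 * (b * b + c * c)
    rots[:, 0, 1] = 2 * (a * b - c * w)
    rots[:, 0, 2] = 2 * (a * c + b * w)
    rots[:, 1, 0] = 2 * (a * b + c * w)
    rots[:, 1, 1] = 1 - 2 * (a * a + c * c)
    rots[:, 1, 2] = 2 * (b * c - a * w)
    rots[:, 2, 0] = 2 * (a * c - b * w)
    rots[:, 2, 1] = 2 * (b * c + a * w)
    rots[:, 2, 2] = 1 - 2 * (a * a + b * b)
    moved = np.einsum("rij,nj->rni", rots, xc)
    rmsds = np.sqrt(np.mean(np.sum((moved - yc) ** 2, axis=2), axis=1))
    best = int(np.argmin(rmsds))
    best_rot, best_rmsd = rots[best], float(rmsds[best])
    # local random refinement with shrinking perturbation angle
    scale = 0.05
    for _ in range(40):
        axes = rng.standard_normal((500, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.uniform(0, scale, 500)
        k = axes * angles[:, None]
        # Rodrigues via small-rotation matrices
        kx = np.zeros((500, 3, 3))
        kx[:, 0, 1], kx[:, 0, 2] = -k[:, 2], k[:, 1]
        kx[:, 1, 0], kx[:, 1, 2] = k[:, 2], -k[:, 0]
        kx[:, 2, 0], kx[:, 2, 1] = -k[:, 1], k[:, 0]
        theta = np.linalg.norm(k, axis=1, keepdims=True)[:, :, None]
        safe = np.where(theta == 0, 1.0, theta)
        perturb = (np.eye(3) + np.sin(safe) / safe * kx
                   + (1 - np.cos(safe)) / safe ** 2 * (kx @ kx))
        cand = perturb @ best_rot
        moved = np.einsum("rij,nj->rni", cand, xc)
        rmsds = np.sqrt(np.mean(np.sum((moved - yc) ** 2, axis=2), axis=1))
        i = int(np.argmin(rmsds))
        if rmsds[i] < best_rmsd:
            best_rmsd, best_rot = float(rmsds[i]), cand[i]
        else:
            scale *= 0.7
    return best_rmsd
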