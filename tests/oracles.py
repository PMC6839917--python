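"""Independent brute-force oracles used by the test suite.

Each oracle solves the same problem as a library routine by a different,
slower route (grid enumeration, closed form, O(n^2) scan), so agreement
is a genuine cross-check rather than a tautology.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist


def fibonacci_axes(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _axis_angle_matrices(axes: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """(n_axes * n_angles, 3, 3) rotation matrices via Rodrigues."""
    mats = []
    for k in axes:
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        K2 = K @ K
        for a in np.radians(angles_deg):
            mats.append(np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K2)
    return np.asarray(mats)


def grid_search_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[float, np.ndarray]:
    """Best-RMSD rotation by exhaustive rotation-space search.

    Coarse pass: ~600 axes x 2 deg angles; refinement: axes within ~6 deg
    of the winner at 0.25 deg angular steps (finer than the 0.5 deg
    agreement the library superposition is checked to).  The translation
    is optimal in closed form for every trial rotation.  Returns
    (rmsd, rotation).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def score(mats: np.ndarray) -> np.ndarray:
        rot = np.einsum("nij,kj->nki", mats, P0)
        return np.sqrt(np.mean(np.sum((rot - Q0) ** 2, axis=2), axis=1))

    axes = fibonacci_axes(600)
    angles = np.arange(0.0, 360.0, 2.0)
    mats = _axis_angle_matrices(axes, angles)
    r = score(mats)
    best = int(np.argmin(r))
    best_axis = axes[best // len(angles)]
    best_angle = angles[best % len(angles)]
    # refine: nearby axes and fine angles
    local = fibonacci_axes(4000)
    near = local[local @ best_axis > np.cos(np.radians(8.0))]
    near = np.vstack([near, best_axis])
    fine = np.arange(best_angle - 3.0, best_angle + 3.01, 0.25)
    mats2 = _axis_angle_matrices(near, fine)
    r2 = score(mats2)
    b2 = int(np.argmin(r2))
    if r2[b2] < r[best]:
        return float(r2[b2]), mats2[b2]
    return float(r[best]), mats[best]


def simplex_grid_weights(
    i_exp: np.ndarray,
    sigma: np.ndarray,
    member_curves: np.ndarray,
    step: float = 0.001,
) -> tuple[np.ndarray, float]:
    """Best mixture weights by exhaustive simplex enumeration.

    ``member_curves`` is (n_q, m).  The overall scale is fitted in closed
    form per grid point, so only the weight *shape* is enumerated.
    Returns (weights, chi2*(N-1)).
    """
    A = member_curves / sigma[:, None]
    b = i_exp / sigma
    G = A.T @ A
    h = A.T @ b
    btb = float(b @ b)
    m = A.shape[1]
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 9)
    if m == 1:
        grids = np.array([[1.0]])
    elif m == 2:
        grids = np.column_stack([ticks, 1.0 - ticks])
    elif m == 3:
        w1, w2 = np.meshgrid(ticks, ticks, indexing="ij")
        keep = w1 + w2 <= 1.0 + 1e-12
        grids = np.column_stack(
            [w1[keep], w2[keep], 1.0 - w1[keep] - w2[keep]]
        )
    elif m == 4:
        w1, w2, w3 = np.meshgrid(ticks, ticks, ticks, indexing="ij")
        keep = w1 + w2 + w3 <= 1.0 + 1e-12
        grids = np.column_stack(
            [w1[keep], w2[keep], w3[keep], 1.0 - w1[keep] - w2[keep] - w3[keep]]
        )
    else:
        raise ValueError("simplex grid oracle supports at most 4 members")
    best_w, best_r2 = None, np.inf
    chunk = 2_000_000
    for lo in range(0, len(grids), chunk):
        W = grids[lo : lo + chunk]
        num = W @ h
        den = np.einsum("bi,ij,bj->b", W, G, W)
        den = np.where(den > 0, den, np.inf)
        r2 = btb - num**2 / den
        k = int(np.argmin(r2))
        if r2[k] < best_r2:
            best_r2, best_w = float(r2[k]), W[k].copy()
    return best_w, best_r2


def brute_force_clashes(
    coords: np.ndarray,
    chain_ids: np.ndarray,
    residue_numbers: np.ndarray,
    cutoff: float,
) -> list[tuple[int, int]]:
    """All-pairs O(n^2) scan for non-adjacent contacts below the cutoff."""
    n = len(coords)
    d = cdist(coords, coords)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if chain_ids[i] == chain_ids[j] and abs(
                int(residue_numbers[i]) - int(residue_numbers[j])
            ) <= 2:
                continue
            if d[i, j] < cutoff:
                out.append((i, j))
    return out


def sphere_intensity(q: np.ndarray, radius: float) -> np.ndarray:
    """Analytic scattering of a uniform solid sphere, I(0) = 1."""
    x = q * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Analytic distance distribution of a uniform solid sphere (unnormalized)."""
    s = r / (2.0 * radius)
    p = r**2 * (1.0 - 1.5 * s + 0.5 * s**3)
    return np.where((r >= 0) & (r <= 2 * radius), p, 0.0)


def distance_histogram_pr(
    coords: np.ndarray, r_grid: np.ndarray, bandwidth: float = 2.0
) -> np.ndarray:
    """Gaussian-smoothed weighted pair-distance histogram on a given grid."""
    d = pdist(coords)
    p = np.zeros_like(r_grid, dtype=float)
    chunk = 50_000
    for lo in range(0, len(d), chunk):
        block = d[lo : lo + chunk]
        p += np.exp(
            -0.5 * ((r_grid[:, None] - block[None, :]) / bandwidth) ** 2
        ).sum(axis=1)
    return p / (bandwidth * np.sqrt(2 * np.pi))
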