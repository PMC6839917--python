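"""Experimental SAXS curve analysis.

Implements the standard one-dimensional analyses of a solution scattering
curve:

* Guinier fit — low-q law I(q) = I(0) exp(-q^2 Rg^2 / 3), fitted as a
  weighted linear regression of ln I on q^2 over the largest low-q window
  satisfying q_max * Rg <= 1.3 (self-consistent window selection).
* Kratky transform — q^2 I(q), or the dimensionless form
  (q Rg)^2 I / I(0) vs q Rg, sensitive to compactness and flexibility.
* Pair-distance distribution P(r) — regularized indirect Fourier
  transform of I(q) with endpoint constraints P(0) = P(Dmax) = 0,
  non-negativity, and a second-difference (Tikhonov) smoothness penalty
  whose weight is chosen by an L-curve corner unless fixed by the user.
* Dmax estimation — scan of candidate maximal dimensions scored by the
  back-transform fit.
* Volume of correlation — Vc = I(0) / int q I(q) dq, with the protein
  molecular-weight calibration MW(kDa) = (Vc^2 / Rg) / 0.1231.  The
  constant is the published protein calibration of the Vc method and is
  adopted here unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .errors import DataError, FitError, InversionError
from .profiles import SaxsProfile

__all__ = [
    "GuinierFit",
    "KratkyCurve",
    "PairDistribution",
    "VcResult",
    "guinier_fit",
    "kratky",
    "pair_distribution",
    "estimate_dmax",
    "volume_of_correlation",
]

#: Protein calibration constant of the volume-of-correlation mass estimate.
VC_PROTEIN_CONSTANT = 0.1231


@dataclass(frozen=True)
class GuinierFit:
    """Result of a self-consistent Guinier fit."""

    rg: float  # Angstrom
    i0: float  # intensity units
    q_window: tuple[float, float]
    n_points: int
    fit_quality: float  # coefficient of determination of ln I vs q^2
    degenerate: bool = False  # flat profile: Rg indistinguishable from 0


@dataclass(frozen=True)
class KratkyCurve:
    """Kratky transform; x = qRg and y = (qRg)^2 I/I0 when normalized."""

    x: np.ndarray
    y: np.ndarray
    normalized: bool
    peak_x: float
    peak_y: float


@dataclass(frozen=True)
class PairDistribution:
    """Real-space pair-distance distribution on [0, dmax]."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    regularization: float
    chi2: float  # back-transform residual (reduced)
    fit: np.ndarray | None = None  # back-transformed intensity on the input grid

    def total(self) -> float:
        """Trapezoid integral of P(r)."""
        return float(np.trapezoid(self.p, self.r))

    def normalized_to(self, area: float) -> "PairDistribution":
        """Copy rescaled so that the integral of P equals ``area``.

        Used e.g. to normalize P(r) curves to SAXS-determined molecular
        weights before comparing states.
        """
        tot = self.total()
        if tot <= 0:
            raise InversionError("cannot normalize a P(r) with non-positive area")
        scale = area / tot
        return PairDistribution(
            r=self.r, p=self.p * scale, dmax=self.dmax,
            regularization=self.regularization, chi2=self.chi2, fit=self.fit,
        )


@dataclass(frozen=True)
class VcResult:
    """Volume of correlation and derived mass estimate."""

    vc: float  # A^2
    qr: float  # A^3, Vc^2 / Rg
    mw_kda: float
    q_range: tuple[float, float]
    truncated: bool = False  # q-range ended short of 0.3 1/A


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns (a, b, r_squared)."""
    W = w / w.sum()
    xm, ym = W @ x, W @ y
    cov = W @ ((x - xm) * (y - ym))
    var = W @ ((x - xm) ** 2)
    if var <= 0:
        raise FitError("degenerate abscissa in linear fit")
    b = cov / var
    a = ym - b * xm
    resid = y - (a + b * x)
    ss_res = W @ resid**2
    ss_tot = W @ ((y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(a), float(b), float(r2)


def guinier_fit(
    profile: SaxsProfile,
    qrg_limit: float = 1.3,
    min_points: int = 5,
    min_quality: float = 0.9,
) -> GuinierFit:
    """Self-consistent Guinier fit of the low-q region.

    ln I is regressed on q^2 (weighted by (I/sigma)^2 when sigma is
    present) over a window starting at the lowest usable q.  The window
    size is iterated to the fixed point of the condition
    q_max * Rg_fit <= qrg_limit, then shrunk if needed until the
    coefficient of determination reaches ``min_quality``.

    A flat profile (slope ~ 0) returns rg = 0 flagged ``degenerate``;
    a positive slope (Rg^2 < 0) raises :class:`FitError`.
    """
    usable = profile.intensity > 0
    q = profile.q[usable]
    i = profile.intensity[usable]
    if len(q) < min_points:
        raise FitError(f"fewer than {min_points} usable low-q points")
    sig = profile.sigma[usable] if profile.sigma is not None else None
    x = q**2
    y = np.log(i)
    w_all = (i / sig) ** 2 if sig is not None else np.ones_like(y)

    def fit(m: int):
        return _weighted_linfit(x[:m], y[:m], w_all[:m])

    m = min_points
    seen: set[int] = set()
    for _ in range(100):
        a, b, r2 = fit(m)
        if b > 1e-12 * max(1.0, abs(a)):
            # intensity rising with q at low q
            if m > min_points:
                m -= 1
                continue
            raise FitError("Guinier slope is positive (Rg^2 < 0)")
        rg = float(np.sqrt(max(-3.0 * b, 0.0)))
        if rg == 0.0:
            return GuinierFit(
                rg=0.0, i0=float(np.exp(a)), q_window=(float(q[0]), float(q[m - 1])),
                n_points=m, fit_quality=r2, degenerate=True,
            )
        m_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        m_new = max(min_points, min(m_new, len(q)))
        if m_new == m:
            break
        if m_new in seen:  # two-cycle: settle on the smaller window
            m = min(m, m_new)
            break
        seen.add(m)
        m = m_new
    else:
        raise FitError("Guinier window selection did not converge")
    a, b, r2 = fit(m)
    while r2 < min_quality and m > min_points:
        m -= 1
        a, b, r2 = fit(m)
    if b > 0:
        raise FitError("Guinier slope is positive (Rg^2 < 0)")
    rg = float(np.sqrt(-3.0 * b))
    if q[m - 1] * rg > qrg_limit * (1 + 1e-9):
        raise FitError(
            f"no self-consistent Guinier window: q_max*Rg = {q[m-1]*rg:.2f} "
            f"> {qrg_limit} even at {m} points"
        )
    return GuinierFit(
        rg=rg, i0=float(np.exp(a)), q_window=(float(q[0]), float(q[m - 1])),
        n_points=m, fit_quality=r2,
    )


def kratky(
    profile: SaxsProfile,
    guinier: GuinierFit | None = None,
    normalized: bool = True,
) -> KratkyCurve:
    """Kratky transform of a profile.

    Normalized form requires a valid Guinier fit and returns
    x = q Rg, y = (q Rg)^2 I / I(0); the un-normalized form returns
    x = q, y = q^2 I.  The peak position is reported.
    """
    if normalized:
        if guinier is None or guinier.rg <= 0 or guinier.i0 <= 0:
            raise FitError("normalized Kratky needs a valid Guinier fit")
        x = profile.q * guinier.rg
        y = x**2 * profile.intensity / guinier.i0
    else:
        x = profile.q
        y = profile.q**2 * profile.intensity
    k = int(np.argmax(y)) if np.any(y != 0) else 0
    return KratkyCurve(
        x=x, y=y, normalized=normalized, peak_x=float(x[k]), peak_y=float(y[k])
    )


def _transform_matrix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Discretized indirect transform: I(q) = 4 pi int P(r) sinc(qr) dr."""
    dr = r[1] - r[0]
    w = np.full(len(r), dr)
    w[0] = w[-1] = dr / 2.0  # trapezoid end weights
    return 4.0 * np.pi * np.sinc(np.outer(q, r) / np.pi) * w


def _second_difference(n: int) -> np.ndarray:
    """Second-difference operator on the full grid (endpoints included as zeros)."""
    D = np.zeros((n - 2, n))
    for j in range(1, n - 1):
        D[j - 1, j - 1 : j + 2] = (1.0, -2.0, 1.0)
    return D


def _solve_pr(
    q, i_exp, sigma, dmax, n_bins, lam_rel
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Solve the non-negative regularized inversion at one smoothness value."""
    r = np.linspace(0.0, dmax, n_bins)
    A = _transform_matrix(q, r)
    # interior unknowns only: P(0) = P(dmax) = 0 as hard constraints
    A_int = A[:, 1:-1]
    W = 1.0 / sigma
    Aw = A_int * W[:, None]
    bw = i_exp * W
    D = _second_difference(n_bins)[:, 1:-1]
    scale = np.linalg.norm(Aw) / max(np.linalg.norm(D), 1e-300)
    lam = lam_rel * scale
    M = np.vstack([Aw, lam * D])
    rhs = np.concatenate([bw, np.zeros(D.shape[0])])
    res = lsq_linear(M, rhs, bounds=(0.0, np.inf), method="bvls", tol=1e-12)
    if not np.all(np.isfinite(res.x)):
        raise InversionError("indirect transform solver returned non-finite values")
    p = np.zeros(n_bins)
    p[1:-1] = res.x
    fit = A @ p
    ndof = max(len(q) - 1, 1)
    chi2 = float(np.sum(((i_exp - fit) / sigma) ** 2) / ndof)
    return r, p, chi2, fit


_LCURVE_GRID = np.logspace(-7.0, 1.0, 13)


def _lcurve_corner(q, i_exp, sigma, dmax, n_bins) -> float:
    """Choose the smoothness weight at the L-curve corner.

    The corner is the grid point with maximal distance from the straight
    line joining the endpoints of the (log residual, log seminorm) curve
    (triangle method).
    """
    pts = []
    D = _second_difference(n_bins)
    for lam_rel in _LCURVE_GRID:
        r, p, chi2, _ = _solve_pr(q, i_exp, sigma, dmax, n_bins, lam_rel)
        seminorm = float(np.linalg.norm(D @ p))
        pts.append((np.log10(max(chi2, 1e-300)), np.log10(max(seminorm, 1e-300))))
    pts_arr = np.asarray(pts)
    a, b = pts_arr[0], pts_arr[-1]
    ab = b - a
    nab = np.linalg.norm(ab)
    if nab == 0:
        return float(_LCURVE_GRID[len(_LCURVE_GRID) // 2])
    # signed distance; the corner bulges toward low residual + low seminorm
    cross = (pts_arr - a) @ np.array([-ab[1], ab[0]]) / nab
    return float(_LCURVE_GRID[int(np.argmin(cross))])


def pair_distribution(
    profile: SaxsProfile,
    dmax: float,
    n_bins: int = 101,
    smoothness: float | None = None,
) -> PairDistribution:
    """P(r) by regularized indirect Fourier transform.

    Solves I(q) = 4 pi int_0^dmax P(r) sin(qr)/(qr) dr on an n_bins grid
    with P(0) = P(dmax) = 0, P >= 0, and a second-difference smoothness
    penalty.  ``smoothness`` is a dimensionless relative weight; None
    selects it by the L-curve corner.  The reduced chi^2 of the
    back-transform against the input curve is reported; when the profile
    carries no sigma a nominal 1% relative uncertainty is assumed.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if n_bins < 5:
        raise ValueError("n_bins must be at least 5")
    sigma = profile.effective_sigma()
    if smoothness is None:
        smoothness = _lcurve_corner(profile.q, profile.intensity, sigma, dmax, n_bins)
    r, p, chi2, fit = _solve_pr(
        profile.q, profile.intensity, sigma, dmax, n_bins, smoothness
    )
    if not np.isfinite(chi2):
        raise InversionError("indirect transform produced a non-finite residual")
    return PairDistribution(
        r=r, p=p, dmax=float(dmax), regularization=float(smoothness),
        chi2=chi2, fit=fit,
    )


def estimate_dmax(
    profile: SaxsProfile,
    dmax_grid: Sequence[float] | np.ndarray,
    n_bins: int = 101,
    smoothness: float | None = None,
    rel_tol: float = 0.05,
) -> float:
    """Maximal particle dimension by scanning candidate Dmax values.

    Each candidate is scored by the back-transform chi^2 of its P(r)
    inversion.  Because chi^2 flattens once the true dimension is reached
    (larger supports fit equally well), the smallest candidate whose
    chi^2 is within ``rel_tol`` of the minimum is returned — a parsimony
    rule equivalent to penalizing excess support.

    The smoothness weight is chosen once (L-curve at the median
    candidate) and reused across the scan unless given explicitly.
    """
    grid = np.sort(np.asarray(dmax_grid, dtype=np.float64))
    if len(grid) == 0 or np.any(grid <= 0):
        raise ValueError("dmax_grid must contain positive candidates")
    sigma = profile.effective_sigma()
    if smoothness is None:
        mid = float(grid[len(grid) // 2])
        smoothness = _lcurve_corner(profile.q, profile.intensity, sigma, mid, n_bins)
    chi2s = np.empty(len(grid))
    for k, d in enumerate(grid):
        try:
            _, _, chi2s[k], _ = _solve_pr(
                profile.q, profile.intensity, sigma, d, n_bins, smoothness
            )
        except InversionError:
            chi2s[k] = np.inf
    if not np.any(np.isfinite(chi2s)):
        raise InversionError("no Dmax candidate produced an acceptable inversion")
    best = float(np.min(chi2s))
    ok = chi2s <= best * (1.0 + rel_tol)
    return float(grid[int(np.argmax(ok))])


def volume_of_correlation(
    profile: SaxsProfile,
    guinier: GuinierFit,
    qmax_expected: float = 0.3,
) -> VcResult:
    """Volume of correlation and the derived protein mass estimate.

    Vc = I(0) / int q I(q) dq (trapezoid on the measured range),
    QR = Vc^2 / Rg, MW(kDa) = QR / 0.1231.  The estimate is invariant
    under rescaling of I(q).  When the measured range ends short of
    ``qmax_expected`` the integral is truncated; the result is returned
    with ``truncated=True`` and a warning rather than extrapolated.
    """
    if guinier.rg <= 0 or guinier.i0 <= 0:
        raise FitError("volume of correlation needs a valid Guinier fit")
    integral = float(np.trapezoid(profile.q * profile.intensity, profile.q))
    if integral <= 0:
        raise DataError("integral of q*I(q) is non-positive")
    truncated = profile.q[-1] < qmax_expected
    if truncated:
        warnings.warn(
            f"q-range ends at {profile.q[-1]:.3g} < {qmax_expected} 1/A; "
            "Vc integral is truncated (no extrapolation performed)",
            stacklevel=2,
        )
    vc = guinier.i0 / integral
    qr = vc**2 / guinier.rg
    return VcResult(
        vc=float(vc),
        qr=float(qr),
        # QR / 0.1231 gives the protein mass in Da; report kDa
        mw_kda=float(qr / VC_PROTEIN_CONSTANT / 1000.0),
        q_range=(float(profile.q[0]), float(profile.q[-1])),
        truncated=truncated,
    )
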