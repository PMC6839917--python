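"""Ensemble fitting of SAXS profiles: chi-square, weights, minimal search.

An experimental curve is compared with theoretical member curves through
the reduced chi-square with an analytically fitted global scale,

    chi^2 = 1/(N-1) * sum_i ( (I_exp(q_i) - c * I_mod(q_i)) / sigma_i )^2,

with theoretical curves interpolated onto the experimental grid (never
the reverse, so experimental uncertainties are preserved).  Mixtures are
fitted by non-negative least squares over member intensities; the minimal
ensemble search finds, for each ensemble size n, the best-fitting member
subset, exhaustively when the subset count is tractable and by a seeded
stochastic search otherwise.  The conformational equilibrium constant is
the weight ratio of extended-state to compact-state members.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import ConfigError, DataError, FitError, GridError
from .profiles import SaxsProfile
from .sampling import ConformerPool
from .scattering import FormFactorModel, debye_profile

__all__ = [
    "EnsembleFit",
    "MesResult",
    "chi_square",
    "fit_weights",
    "minimal_ensemble_search",
    "classify_members",
    "equilibrium_constant",
    "relative_activity",
]

#: Largest subset count that is enumerated exhaustively.
ENUMERATION_LIMIT = 100_000
#: Relative chi^2 improvement below which adding a state is not justified.
IMPROVEMENT_THRESHOLD = 0.10


@dataclass(frozen=True)
class EnsembleFit:
    """A weighted conformer subset fitted to an experimental curve.

    Weights are non-negative, sum to 1 and are sorted descending with
    matching ``member_ids``; ``scale`` absorbs the overall magnitude.
    """

    member_ids: tuple[str, ...]
    weights: np.ndarray
    scale: float
    chi2: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if len(w) != len(self.member_ids):
            raise FitError("weights and member_ids lengths differ")
        if np.any(w < -1e-12):
            raise FitError("ensemble weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise FitError("ensemble weights must sum to 1")

    def weight_of(self, member_id: str) -> float:
        """Weight of a member, 0.0 when absent from the fit."""
        for mid, w in zip(self.member_ids, self.weights):
            if mid == member_id:
                return float(w)
        return 0.0


@dataclass(frozen=True)
class MesResult:
    """Best ensemble per size plus the selected parsimonious size."""

    per_n: dict[int, EnsembleFit]
    selected_n: int

    @property
    def selected(self) -> EnsembleFit:
        return self.per_n[self.selected_n]


def _common_arrays(
    experimental: SaxsProfile, theoretical: SaxsProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if experimental.sigma is None:
        raise DataError("experimental profile needs per-point sigma")
    sigma = experimental.sigma
    if np.any(sigma <= 0):
        raise DataError("experimental sigma must be positive everywhere")
    i_mod = theoretical.interpolated(experimental.q)
    return experimental.intensity, i_mod, sigma


def chi_square(
    experimental: SaxsProfile, theoretical: SaxsProfile
) -> tuple[float, float]:
    """Reduced chi-square and the analytically fitted scale factor.

    The scale c minimizing sum((I_e - c I_m)/sigma)^2 is computed in
    closed form; chi^2 uses an N-1 denominator.
    """
    i_exp, i_mod, sigma = _common_arrays(experimental, theoretical)
    w = 1.0 / sigma**2
    denom = np.sum(w * i_mod**2)
    if denom <= 0:
        raise FitError("theoretical intensity is zero on the experimental grid")
    c = float(np.sum(w * i_exp * i_mod) / denom)
    resid = (i_exp - c * i_mod) / sigma
    chi2 = float(np.sum(resid**2) / max(len(i_exp) - 1, 1))
    return chi2, c


def _design_matrix(
    experimental: SaxsProfile, members: Sequence[SaxsProfile]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not members:
        raise FitError("need at least one ensemble member")
    if experimental.sigma is None:
        raise DataError("experimental profile needs per-point sigma")
    sigma = experimental.sigma
    if np.any(sigma <= 0):
        raise DataError("experimental sigma must be positive everywhere")
    M = np.column_stack([m.interpolated(experimental.q) for m in members])
    return M, experimental.intensity, sigma


def _fit_from_coeffs(
    coeffs: np.ndarray,
    member_ids: Sequence[str],
    chi2: float,
) -> EnsembleFit:
    total = float(coeffs.sum())
    if total <= 0:
        raise FitError("degenerate fit: all member coefficients are zero")
    weights = coeffs / total
    order = np.argsort(-weights, kind="stable")
    return EnsembleFit(
        member_ids=tuple(member_ids[k] for k in order),
        weights=weights[order],
        scale=total,
        chi2=float(chi2),
    )


def fit_weights(
    experimental: SaxsProfile,
    members: Sequence[SaxsProfile],
    member_ids: Sequence[str] | None = None,
) -> EnsembleFit:
    """Non-negative least-squares mixture weights for a member set.

    Deterministic.  The global scale is absorbed into ``scale`` and the
    weights are renormalized to the simplex.  With duplicated members the
    split between duplicates is degenerate; the summed weight is
    well-defined and the active-set solver concentrates it on the first
    duplicate encountered.
    """
    M, i_exp, sigma = _design_matrix(experimental, members)
    if member_ids is None:
        member_ids = [
            m.label if m.label else f"member_{k}" for k, m in enumerate(members)
        ]
    A = M / sigma[:, None]
    b = i_exp / sigma
    coeffs, _rnorm = nnls(A, b)
    resid = b - A @ coeffs
    chi2 = float(np.sum(resid**2) / max(len(b) - 1, 1))
    return _fit_from_coeffs(coeffs, list(member_ids), chi2)


def _best_subsets_exhaustive(
    A: np.ndarray, b: np.ndarray, n: int, chunk: int = 4096
) -> tuple[float, tuple[int, ...], np.ndarray]:
    """Best residual over all size-n supports of the NNLS problem.

    Uses the KKT identity that the NNLS optimum over a support either is
    the unconstrained solution on that support (when it is non-negative)
    or coincides with the optimum of a strictly smaller support, which a
    previous (smaller n) pass has already covered.  Supports are solved
    in batches via the Gram matrix, so the cost per subset is O(n^2).
    """
    m = A.shape[1]
    G = A.T @ A
    h = A.T @ b
    btb = float(b @ b)
    best = (np.inf, None, None)
    combos = combinations(range(m), n)
    while True:
        batch = list(_take(combos, chunk))
        if not batch:
            break
        S = np.asarray(batch, dtype=np.intp)  # (B, n)
        GS = G[S[:, :, None], S[:, None, :]]  # (B, n, n)
        hS = h[S]  # (B, n)
        try:
            w = np.linalg.solve(GS, hS[..., None])[..., 0]
        except np.linalg.LinAlgError:
            w = np.full_like(hS, np.nan)
            for kk in range(len(S)):
                try:
                    w[kk] = np.linalg.solve(GS[kk], hS[kk])
                except np.linalg.LinAlgError:
                    pass  # singular support (duplicates): covered by smaller n
        feasible = np.all(w >= 0, axis=1) & np.all(np.isfinite(w), axis=1)
        if not np.any(feasible):
            continue
        resid2 = btb - np.einsum("bi,bi->b", w, hS)
        resid2 = np.where(feasible, resid2, np.inf)
        k = int(np.argmin(resid2))
        if resid2[k] < best[0]:
            best = (float(resid2[k]), tuple(int(x) for x in S[k]), w[k].copy())
    return best


def _take(it, k):
    for _, v in zip(range(k), it):
        yield v


def _member_profiles(
    pool: ConformerPool | Sequence[SaxsProfile],
    q: np.ndarray,
    form_factors: FormFactorModel | None,
) -> tuple[list[SaxsProfile], list[str]]:
    if isinstance(pool, ConformerPool):
        profiles = [
            debye_profile(c.model, q, form_factors, label=c.member_id) for c in pool
        ]
        ids = pool.ids()
    else:
        profiles = list(pool)
        ids = [
            p.label if p.label else f"member_{k}" for k, p in enumerate(profiles)
        ]
        if len(set(ids)) != len(ids):
            ids = [f"member_{k}" for k in range(len(profiles))]
    return profiles, ids


def minimal_ensemble_search(
    experimental: SaxsProfile,
    pool: ConformerPool | Sequence[SaxsProfile],
    max_states: int = 3,
    form_factors: FormFactorModel | None = None,
    seed: int | None = None,
    n_restarts: int = 2000,
) -> MesResult:
    """Minimal ensemble search over a conformer pool.

    Theoretical curves are computed once per member (directly on the
    experimental grid when the pool holds models).  For each ensemble
    size n = 1..max_states the best weight-fitted subset is found —
    exhaustively while the subset count stays below
    :data:`ENUMERATION_LIMIT`, otherwise by a seeded stochastic subset
    search (``seed`` is then required) with greedy one-member exchange.
    chi^2 is non-increasing in n by construction; ``selected_n`` is the
    smallest n whose chi^2 the next size fails to improve by more than
    10%.
    """
    if max_states < 1:
        raise ConfigError("max_states must be at least 1")
    profiles, ids = _member_profiles(pool, experimental.q, form_factors)
    if not profiles:
        raise FitError("empty conformer pool")
    M, i_exp, sigma = _design_matrix(experimental, profiles)
    A = M / sigma[:, None]
    b = i_exp / sigma
    ndof = max(len(b) - 1, 1)
    m = M.shape[1]
    per_n: dict[int, EnsembleFit] = {}
    prev: tuple[float, tuple[int, ...], np.ndarray] | None = None
    rng = None
    for n in range(1, min(max_states, m) + 1):
        if math.comb(m, n) <= ENUMERATION_LIMIT:
            resid2, support, w = _best_subsets_exhaustive(A, b, n)
        else:
            if seed is None:
                raise ConfigError(
                    f"subset count C({m},{n}) exceeds the enumeration limit; "
                    "a seed for the stochastic search is required"
                )
            if rng is None:
                rng = np.random.default_rng(seed)
            resid2, support, w = _stochastic_subset_search(
                A, b, n, rng, n_restarts, prev
            )
        if support is None or (prev is not None and prev[0] < resid2):
            # smaller support already fits at least as well; pad it
            resid2, support, w = prev  # type: ignore[misc]
        coeffs = np.zeros(m)
        coeffs[list(support)] = np.maximum(w, 0.0)
        chi2 = resid2 / ndof
        per_n[n] = _fit_from_coeffs(
            coeffs[list(support)], [ids[k] for k in support], chi2
        )
        prev = (resid2, support, w)
    ns = sorted(per_n)
    selected = ns[-1]
    for n in ns[:-1]:
        c_now, c_next = per_n[n].chi2, per_n[n + 1].chi2
        # a numerically exact fit cannot be meaningfully improved
        if c_now <= 1e-10 or (c_now - c_next) / c_now <= IMPROVEMENT_THRESHOLD:
            selected = n
            break
    return MesResult(per_n=per_n, selected_n=selected)


def _stochastic_subset_search(
    A: np.ndarray,
    b: np.ndarray,
    n: int,
    rng: np.random.Generator,
    n_restarts: int,
    prev: tuple[float, tuple[int, ...], np.ndarray] | None,
) -> tuple[float, tuple[int, ...], np.ndarray]:
    """Random-restart + greedy-exchange subset search (NNLS per subset)."""
    m = A.shape[1]

    def score(support: tuple[int, ...]) -> tuple[float, np.ndarray]:
        coeffs, rnorm = nnls(A[:, list(support)], b)
        return float(rnorm**2), coeffs

    candidates: list[tuple[int, ...]] = []
    if prev is not None and prev[1] is not None:
        base = set(prev[1])
        for j in range(m):
            if j not in base and len(base) < n:
                candidates.append(tuple(sorted(base | {j})))
    for _ in range(n_restarts):
        candidates.append(tuple(sorted(rng.choice(m, size=n, replace=False))))
    best: tuple[float, tuple[int, ...] | None, np.ndarray | None] = (np.inf, None, None)
    for supp in candidates:
        r2, w = score(supp)
        if r2 < best[0]:
            best = (r2, supp, w)
    # greedy one-member exchange until no improvement
    improved = True
    while improved and best[1] is not None:
        improved = False
        supp = best[1]
        for pos in range(n):
            for j in range(m):
                if j in supp:
                    continue
                trial = tuple(sorted(supp[:pos] + (j,) + supp[pos + 1 :]))
                r2, w = score(trial)
                if r2 < best[0] - 1e-15:
                    best = (r2, trial, w)
                    improved = True
        if improved:
            continue
    return best  # type: ignore[return-value]


def classify_members(
    members: dict[str, "CalphaModel"], references: dict[str, "CalphaModel"]
) -> dict[str, str]:
    """Assign each member the state of its nearest reference model.

    Nearness is the Calpha RMSD after optimal superposition (shape, not
    pose), with residues paired by (chain, residue_number).  Typical use:
    partition a fitted ensemble into compact vs. extended states before
    computing the equilibrium constant.
    """
    from .geometry import paired_rmsd

    if not references:
        raise ConfigError("need at least one reference model")
    out: dict[str, str] = {}
    for mid, model in members.items():
        best_state, best_rmsd = None, np.inf
        for state, ref in references.items():
            r = paired_rmsd(model, ref)
            if r < best_rmsd:
                best_state, best_rmsd = state, r
        out[mid] = best_state  # type: ignore[assignment]
    return out


def equilibrium_constant(
    fit: EnsembleFit, extended_ids: Iterable[str]
) -> float:
    """Conformational equilibrium constant K_eq = extended / compact.

    ``extended_ids`` names the members counted as the extended (active)
    state; all remaining members count as compact.  When the compact
    weight is zero the result is ``inf`` (flagging an all-extended fit)
    rather than an exception.
    """
    ext = set(extended_ids)
    w_ext = float(sum(w for mid, w in zip(fit.member_ids, fit.weights) if mid in ext))
    w_comp = float(
        sum(w for mid, w in zip(fit.member_ids, fit.weights) if mid not in ext)
    )
    if w_comp <= 0.0:
        return float("inf")
    return w_ext / w_comp


def relative_activity(rate: float, rate_max: float) -> float:
    """Activity as a percentage of the maximal rate (100 * rate / rate_max)."""
    if rate_max <= 0:
        raise DataError("rate_max must be positive")
    return 100.0 * rate / rate_max
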