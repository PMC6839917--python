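"""Theoretical scattering from coarse-grained models via the Debye equation.

The orientationally averaged intensity of a point-scatterer model is

    I(q) = sum_i sum_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij)

evaluated as an exact double sum over all bead pairs.  Beads are Calpha
positions with a uniform (or per-residue) form factor; an optional
Gaussian q-dependence models the finite bead size.  There is no hydration
layer or excluded-volume term: profiles computed here are meant for
relative, self-consistent comparisons (model vs. model, model vs. the
synthetic experiments in :mod:`saxstate.synthetic`), not for absolute
matching of atomistic predictions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .errors import EmptyModelError, GridError
from .models import CalphaModel
from .profiles import SaxsProfile

__all__ = ["FormFactorModel", "debye_profile", "coordinate_rg", "default_q_grid"]

#: Default instrument-like grid: 101 points on 0.01-0.4 1/A.
DEFAULT_QMIN = 0.01
DEFAULT_QMAX = 0.40
DEFAULT_NQ = 101


def default_q_grid(
    qmin: float = DEFAULT_QMIN, qmax: float = DEFAULT_QMAX, n: int = DEFAULT_NQ
) -> np.ndarray:
    return np.linspace(qmin, qmax, n)


@dataclass(frozen=True)
class FormFactorModel:
    """Coarse-grained bead form factors.

    mode 'uniform' assigns every bead the same zero-angle factor
    (``values`` is a scalar, electron equivalents); mode 'per_residue'
    looks factors up by 3-letter residue name with a default for unlisted
    names.  ``gaussian_width`` (Angstrom) adds a q-dependent attenuation
    f(q) = f0 exp(-(q w)^2 / 2) shared by all beads; 0 means q-independent
    dummy-residue factors.
    """

    mode: str = "uniform"
    values: float | dict[str, float] = 1.0
    default: float = 1.0
    gaussian_width: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "per_residue"):
            raise ValueError("mode must be 'uniform' or 'per_residue'")
        if self.mode == "uniform":
            if not np.isscalar(self.values) or float(self.values) <= 0:
                raise ValueError("uniform form factor must be a positive scalar")
        else:
            if not isinstance(self.values, dict) or any(
                v <= 0 for v in self.values.values()
            ):
                raise ValueError("per-residue form factors must be positive")
        if self.gaussian_width < 0:
            raise ValueError("gaussian_width must be >= 0")

    def zero_angle(self, model: CalphaModel) -> np.ndarray:
        """Per-bead f(0) array."""
        if self.mode == "uniform":
            return np.full(len(model), float(self.values))
        return np.asarray(
            [self.values.get(str(rn), self.default) for rn in model.residue_names],
            dtype=np.float64,
        )

    def attenuation(self, q: np.ndarray) -> np.ndarray:
        """Shared q-dependent factor exp(-(q w)^2 / 2)."""
        if self.gaussian_width == 0.0:
            return np.ones_like(q)
        return np.exp(-0.5 * (q * self.gaussian_width) ** 2)


#: Distance-histogram bin width for the accelerated Debye sum (Angstrom).
#: At the instrument qmax of 0.4 1/A the phase error q*dr/2 is ~2e-3 rad,
#: keeping the histogram evaluation within 0.01% of the exact double sum.
HISTOGRAM_BIN = 0.01
#: Bead counts up to this size use the exact pair sum directly.
EXACT_LIMIT = 400


def _pair_terms(coords: np.ndarray, f0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pair distances and form-factor products (condensed upper triangle)."""
    n = len(coords)
    d = pdist(coords)
    iu, ju = np.triu_indices(n, k=1)
    return d, f0[iu] * f0[ju]


def debye_profile(
    model: CalphaModel,
    q_grid: np.ndarray | None = None,
    form_factors: FormFactorModel | None = None,
    label: str | None = None,
    method: str = "auto",
) -> SaxsProfile:
    """Debye-sum intensity of a Calpha model.

    ``method='exact'`` evaluates the O(n^2) double sum directly.
    ``method='histogram'`` bins the pair distances on a 0.01 A grid
    (weighted mean distance per bin) before summing, which agrees with
    the exact sum to much better than 0.1% relative on the default
    instrument range while scaling with the number of occupied bins
    instead of the number of pairs.  ``'auto'`` picks the exact sum for
    small models and the histogram for large ones.

    ``I(0+)`` equals ``(sum f)^2`` and the curve is invariant under rigid
    transformation of the model.  Raises :class:`GridError` for
    non-positive q entries and :class:`EmptyModelError` for an empty
    model.
    """
    if method not in ("auto", "exact", "histogram"):
        raise ValueError("method must be 'auto', 'exact' or 'histogram'")
    if len(model) == 0:
        raise EmptyModelError("cannot scatter an empty model")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=np.float64)
    if np.any(q <= 0):
        raise GridError("q grid entries must be positive")
    ff = form_factors or FormFactorModel()
    f0 = ff.zero_angle(model)
    n = len(model)
    self_term = float(np.sum(f0**2))
    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "histogram"
    if n == 1:
        intensity = np.full_like(q, self_term)
    else:
        d, w = _pair_terms(model.coords, f0)
        if method == "histogram":
            bins = np.floor(d / HISTOGRAM_BIN).astype(np.intp)
            nb = int(bins.max()) + 1
            wsum = np.bincount(bins, weights=w, minlength=nb)
            dsum = np.bincount(bins, weights=w * d, minlength=nb)
            occ = wsum > 0
            d, w = dsum[occ] / wsum[occ], wsum[occ]
        # sin(q d)/(q d) == sinc(q d / pi)
        if len(d) * len(q) <= 20_000_000:
            intensity = self_term + 2.0 * np.sinc(np.outer(q, d) / np.pi) @ w
        else:
            intensity = np.empty_like(q)
            for k, qk in enumerate(q):
                intensity[k] = self_term + 2.0 * np.dot(w, np.sinc(qk * d / np.pi))
    intensity *= ff.attenuation(q) ** 2
    return SaxsProfile(
        q=q,
        intensity=intensity,
        sigma=None,
        label=label if label is not None else (model.model_id or "debye"),
    )


def coordinate_rg(
    model: CalphaModel, weights: np.ndarray | FormFactorModel | None = None
) -> float:
    """Real-space radius of gyration of the bead model.

    Rg = sqrt( sum w_i |r_i - rbar|^2 / sum w_i ) with rbar the weighted
    centroid.  ``weights`` may be a per-bead array, a
    :class:`FormFactorModel` (its zero-angle factors are used), or None
    for unit weights.
    """
    if len(model) == 0:
        raise EmptyModelError("cannot compute Rg of an empty model")
    if weights is None:
        w = np.ones(len(model))
    elif isinstance(weights, FormFactorModel):
        w = weights.zero_angle(model)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if len(w) != len(model):
            raise ValueError("weights length mismatch")
    w = w / w.sum()
    centroid = w @ model.coords
    return float(np.sqrt(np.sum(w * np.sum((model.coords - centroid) ** 2, axis=1))))
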