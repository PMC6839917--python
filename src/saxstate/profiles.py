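"""SAXS profile container and 3-column text I/O.

A profile is a triplet (q, I, sigma) on a strictly ascending q-grid in
inverse Angstrom, with sigma optional for theoretical curves.  Files are
whitespace-delimited text with 2 or 3 numeric columns; lines starting
with '#' (and any non-numeric header lines) are ignored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError, GridError

__all__ = ["SaxsProfile", "read_dat", "write_dat"]


@dataclass
class SaxsProfile:
    """(q, I, sigma) triplets on an ascending q-grid.

    Intensities are in arbitrary (relative) units.  ``sigma`` is the
    per-point uncertainty and may be None for theoretical curves.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64).ravel()
        self.intensity = np.asarray(self.intensity, dtype=np.float64).ravel()
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=np.float64).ravel()
        if len(self.q) != len(self.intensity):
            raise GridError("q and intensity lengths differ")
        if self.sigma is not None and len(self.sigma) != len(self.q):
            raise GridError("sigma length differs from q")
        if len(self.q) == 0:
            raise GridError("empty profile")
        if np.any(self.q <= 0):
            raise GridError("q values must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise GridError("q grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.q)

    def interpolated(self, q: np.ndarray) -> np.ndarray:
        """Linear interpolation of the intensity onto another grid.

        Extrapolation is forbidden: the target grid must lie within the
        profile's q-range.
        """
        q = np.asarray(q, dtype=np.float64)
        if q.min() < self.q[0] - 1e-12 or q.max() > self.q[-1] + 1e-12:
            raise GridError(
                f"target grid [{q.min():g}, {q.max():g}] extends beyond the "
                f"profile range [{self.q[0]:g}, {self.q[-1]:g}]"
            )
        return np.interp(q, self.q, self.intensity)

    def effective_sigma(self, relative: float = 0.01, floor_frac: float = 1e-4) -> np.ndarray:
        """Declared sigma, or a nominal fallback when none was measured.

        The fallback assigns ``relative`` of the local intensity plus a
        small floor (``floor_frac`` of the maximum intensity), which keeps
        weights finite near intensity zeros of oscillatory curves.
        """
        if self.sigma is not None:
            if np.any(self.sigma <= 0):
                raise DataError("profile sigma must be positive everywhere")
            return self.sigma
        imax = float(np.max(np.abs(self.intensity)))
        return relative * np.abs(self.intensity) + floor_frac * imax


def read_dat(path: str | Path) -> SaxsProfile:
    """Read a 3-column (or 2-column) whitespace-delimited SAXS profile."""
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                continue  # header line
            if len(vals) < 2:
                continue
            if ncol is None:
                ncol = min(len(vals), 3)
            rows.append(vals[:ncol])
    if not rows:
        raise FormatError(f"{path}: no numeric data rows")
    arr = np.asarray([r + [np.nan] * (3 - len(r)) for r in rows])
    sigma = arr[:, 2] if ncol == 3 and np.all(np.isfinite(arr[:, 2])) else None
    return SaxsProfile(
        q=arr[:, 0], intensity=arr[:, 1], sigma=sigma, label=Path(str(path)).stem
    )


def write_dat(profile: SaxsProfile, path: str | Path, header: str | None = None) -> None:
    """Write a profile as 3-column text (sigma column omitted when absent)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q(A^-1) I(q)" + (" sigma\n" if profile.sigma is not None else "\n"))
        for i in range(len(profile)):
            if profile.sigma is not None:
                fh.write(
                    f"{profile.q[i]:.6e} {profile.intensity[i]:.8e} {profile.sigma[i]:.8e}\n"
                )
            else:
                fh.write(f"{profile.q[i]:.6e} {profile.intensity[i]:.8e}\n")
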