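"""Angular discretization of the unit circle and the Henyey-Greenstein scattering operator.

The transport equation couples directions only through the scattering integral
``mu_s(x) * Integral_Omega k(w . w') u(x, w') dw'``.  On the unit circle we use
equispaced direction nodes with mass-lumped (midpoint) quadrature weights
``2*pi/n_dir``; for equispaced nodes this collocation coincides with a lumped
linear angular FEM and keeps the discrete kernel circulant.

The discrete kernel rows are renormalized to sum to one so that conservative
scattering preserves total intensity exactly (the continuous kernel is
normalized; raw quadrature would break photon conservation at the 1e-3 level
for strongly peaked kernels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AngularGrid", "build_angular_grid", "hg_phase", "build_scatter_matrix"]


@dataclass
class AngularGrid:
    """Discrete direction set on the unit circle.

    Attributes
    ----------
    n_dir : int
        Number of directions (>= 4).
    angles : (n_dir,) ndarray
        Direction angles in [0, 2*pi), measured counterclockwise from the
        positive first axis.
    directions : (n_dir, 2) ndarray
        Unit vectors (cos, sin) of each angle.
    weights : (n_dir,) ndarray
        Quadrature weights in radians; they sum to 2*pi.
    scatter_matrix : (n_dir, n_dir) ndarray or None
        Row-normalized discrete scattering kernel: row p maps a radiance
        vector over directions to the (weighted) scattering integral at
        direction p.  ``None`` until :func:`build_scatter_matrix` is called.
    g : float or None
        Anisotropy factor used to fill ``scatter_matrix``.
    """

    n_dir: int
    angles: np.ndarray
    directions: np.ndarray
    weights: np.ndarray
    scatter_matrix: np.ndarray | None = None
    g: float | None = field(default=None)

    def reversed_index(self) -> np.ndarray:
        """Index map p -> q with omega_q = -omega_p (requires even n_dir)."""
        if self.n_dir % 2 != 0:
            raise ValueError("direction reversal requires an even number of directions")
        return (np.arange(self.n_dir) + self.n_dir // 2) % self.n_dir


def build_angular_grid(n_dir: int, g: float | None = None) -> AngularGrid:
    """Equispaced angular grid with midpoint weights 2*pi/n_dir.

    Parameters
    ----------
    n_dir : int
        Number of directions, at least 4.
    g : float, optional
        If given, the Henyey-Greenstein scatter matrix is filled immediately.
    """
    if n_dir < 4:
        raise ValueError(f"n_dir must be >= 4, got {n_dir}")
    angles = 2.0 * np.pi * np.arange(n_dir) / n_dir
    directions = np.column_stack([np.cos(angles), np.sin(angles)])
    weights = np.full(n_dir, 2.0 * np.pi / n_dir)
    grid = AngularGrid(n_dir, angles, directions, weights)
    if g is not None:
        build_scatter_matrix(grid, g)
    return grid


def hg_phase(g: float, c):
    """2D Henyey-Greenstein phase function k(c), c = cosine of the scattering angle.

    k(c) = (1 - g^2) / (2*pi * (1 + g^2 - 2*g*c)); normalized so that the
    integral over the circle of k(cos(theta)) d(theta) equals 1 for every
    anisotropy g in (-1, 1).
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must lie in (-1, 1), got {g}")
    c = np.asarray(c, dtype=float)
    if np.any(np.abs(c) > 1.0 + 1e-12):
        raise ValueError("cosine argument outside [-1, 1]")
    val = (1.0 - g * g) / (2.0 * np.pi * (1.0 + g * g - 2.0 * g * c))
    return val if val.ndim else float(val)


def build_scatter_matrix(grid: AngularGrid, g: float) -> AngularGrid:
    """Fill ``grid.scatter_matrix`` with the discretized HG kernel.

    Entry (p, q) approximates k(omega_p . omega_q) * w_q, then each row is
    rescaled to sum exactly to 1, so the matrix applied to a constant vector
    returns the same constant (conservative scattering).
    """
    cosdiff = np.cos(grid.angles[:, None] - grid.angles[None, :])
    k = hg_phase(g, np.clip(cosdiff, -1.0, 1.0))
    mat = k * grid.weights[None, :]
    mat /= mat.sum(axis=1, keepdims=True)
    grid.scatter_matrix = mat
    grid.g = float(g)
    return grid
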