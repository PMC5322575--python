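"""Piecewise-constant optical phantoms: background plus circular inclusions.

The reconstruction problem treats tissue optical properties as piecewise
constant per mesh element; a phantom is the continuous description (background
absorption/scattering plus circular inclusions) and :func:`rasterize` samples
it onto a mesh by element-centroid membership, which keeps the true field
exactly representable in the piecewise-constant coefficient basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh

logger = logging.getLogger(__name__)

__all__ = ["Inclusion", "Phantom", "OpticalCoefficients", "rasterize",
           "preset_phantom", "PRESET_NAMES"]


@dataclass
class Inclusion:
    """Circular inclusion; mua/mus default to the background value if None."""

    center: tuple[float, float]
    radius: float  # mm
    mua: float | None = None  # mm^-1
    mus: float | None = None  # mm^-1


@dataclass
class Phantom:
    """Background medium plus circular inclusions inside a disk domain.

    All coefficients must be strictly positive and bounded (the transport
    problem is well-posed only for uniformly positive, bounded mua and mus);
    inclusions must lie inside the disk of ``domain_radius``.
    Later inclusions override earlier ones where they overlap.
    """

    background_mua: float  # mm^-1
    background_mus: float  # mm^-1
    inclusions: list[Inclusion] = field(default_factory=list)
    domain_radius: float = 10.0  # mm

    def __post_init__(self):
        vals = [self.background_mua, self.background_mus]
        for inc in self.inclusions:
            if inc.mua is None:
                inc.mua = self.background_mua
            if inc.mus is None:
                inc.mus = self.background_mus
            vals += [inc.mua, inc.mus]
            r_c = float(np.hypot(*inc.center))
            if r_c + inc.radius > self.domain_radius + 1e-12:
                raise ValueError(
                    f"inclusion at {inc.center} with radius {inc.radius} "
                    f"extends outside the disk of radius {self.domain_radius}")
            if inc.radius <= 0:
                raise ValueError("inclusion radius must be positive")
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("all optical coefficients must be positive and finite")
        for a, b in zip(self.inclusions, self.inclusions[1:]):
            da = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if da < a.radius + b.radius:
                logger.warning("overlapping inclusions at %s and %s; the later "
                               "one wins on overlap", a.center, b.center)


@dataclass
class OpticalCoefficients:
    """Per-element absorption/scattering values on a mesh (mm^-1)."""

    mua: np.ndarray
    mus: np.ndarray
    mesh: TriMesh

    def __post_init__(self):
        n = self.mesh.n_elements
        if len(self.mua) != n or len(self.mus) != n:
            raise ValueError("coefficient length does not match mesh element count")
        if np.any(self.mua <= 0) or np.any(self.mus <= 0):
            raise ValueError("optical coefficients must be strictly positive")

    def with_mua(self, mua: np.ndarray) -> "OpticalCoefficients":
        return OpticalCoefficients(np.asarray(mua, float), self.mus, self.mesh)


def _subtriangle_barycentrics(k: int) -> np.ndarray:
    """Centroid barycentric coordinates of the 4^k congruent subtriangles of
    a reference triangle (uniform k-fold midpoint refinement)."""
    n = 2 ** k
    bc = []
    for i in range(n):
        for j in range(n - i):
            bc.append(((i + 1 / 3) / n, (j + 1 / 3) / n))
            if j < n - i - 1:
                bc.append(((i + 2 / 3) / n, (j + 2 / 3) / n))
    return np.array(bc)


def _circle_fraction(mesh: TriMesh, inc: Inclusion, subdiv: int) -> np.ndarray:
    """Per-element area fraction inside the inclusion circle (resolution
    4^-subdiv), evaluated only on elements that straddle the circle."""
    pts = mesh.nodes[mesh.triangles]
    cx, cy = inc.center
    d = np.sqrt((pts[..., 0] - cx) ** 2 + (pts[..., 1] - cy) ** 2)
    h = mesh.edge_len.max(axis=1)
    frac = np.zeros(mesh.n_elements)
    frac[np.all(d < inc.radius, axis=1)] = 1.0  # all vertices inside
    cross = ~np.all(d < inc.radius, axis=1) & (d.min(axis=1) < inc.radius + h)
    if cross.any():
        bc = _subtriangle_barycentrics(subdiv)
        l0 = 1.0 - bc.sum(axis=1)
        p = pts[cross]
        sub = (l0[:, None, None] * p[None, :, 0]
               + bc[:, 0][:, None, None] * p[None, :, 1]
               + bc[:, 1][:, None, None] * p[None, :, 2])
        inside = (sub[..., 0] - cx) ** 2 + (sub[..., 1] - cy) ** 2 < inc.radius ** 2
        frac[cross] = inside.mean(axis=0)
    return frac


def rasterize(phantom: Phantom, mesh: TriMesh, mode: str = "centroid",
              subdiv: int = 4) -> OpticalCoefficients:
    """Sample a phantom onto a mesh.

    mode="centroid": element value = inclusion value if the element centroid
    lies strictly inside the inclusion circle, else background — the strict
    piecewise-constant model (the true field is exactly representable in the
    per-element basis, the right choice for same-mesh studies).

    mode="exact": partial-volume blending by the element's area fraction
    inside each circle (midpoint refinement to 4^-subdiv resolution).  This
    makes the inclusions' integrated optical mass mesh-independent; centroid
    rasterization quantizes small inclusions (an r = 0.5 mm circle covers
    only 2-3 elements) so coarsely that data synthesized on two different
    meshes disagree on the inclusion signal itself.  Used on the data side of
    the dual-mesh experiments.
    """
    mua = np.full(mesh.n_elements, phantom.background_mua)
    mus = np.full(mesh.n_elements, phantom.background_mus)
    if mode == "centroid":
        c = mesh.centroids()
        for inc in phantom.inclusions:
            inside = (c[:, 0] - inc.center[0]) ** 2 \
                + (c[:, 1] - inc.center[1]) ** 2 < inc.radius ** 2
            mua[inside] = inc.mua
            mus[inside] = inc.mus
    elif mode == "exact":
        for inc in phantom.inclusions:
            f = _circle_fraction(mesh, inc, subdiv)
            mua = (1.0 - f) * mua + f * inc.mua
            mus = (1.0 - f) * mus + f * inc.mus
    else:
        raise ValueError(f"unknown rasterization mode {mode!r}")
    return OpticalCoefficients(mua, mus, mesh)


def _sim2(*incl) -> Phantom:
    return Phantom(0.01, 10.0, [Inclusion(c, r, 0.02, 20.0) for c, r in incl])


_PRESETS = {
    "sim1_small": lambda: _sim2(((7.0, 0.0), 0.5)),
    "sim2_small": lambda: _sim2(((7.0, 0.0), 0.5)),
    "sim2_middle": lambda: _sim2(((5.0, 0.0), 2.0)),
    "sim2_big": lambda: _sim2(((3.0, 0.0), 4.0)),
    "sim2_two_small": lambda: _sim2(((7.0, 0.0), 0.5), ((0.0, 0.0), 0.5)),
    "sim2_three_small": lambda: _sim2(((7.0, 0.0), 0.5), ((0.0, -7.0), 0.5),
                                      ((0.0, 0.0), 0.5)),
    "sim2_big_two_small": lambda: _sim2(((-5.0, 2.0), 2.0), ((0.0, -7.0), 0.5),
                                        ((7.0, 0.0), 0.5)),
    "sim3_abs_scat": lambda: Phantom(0.05, 5.0, [
        Inclusion((3.5, 3.5), 2.0, mua=0.1),
        Inclusion((0.0, -5.0), 2.0, mus=10.0),
    ]),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_phantom(name: str) -> Phantom:
    """Named phantom presets for the three simulation studies.

    ``sim1_small``/``sim2_small``: one r=0.5 mm circle at (7, 0) with
    mua=0.02, mus=20 on a 0.01/10 background; ``sim2_middle``/``sim2_big``:
    larger single circles; ``sim2_two_small``/``sim2_three_small``/
    ``sim2_big_two_small``: the multi-inclusion cases; ``sim3_abs_scat``:
    0.05/5 background with a purely absorbing and a purely scattering
    inclusion (r=2 mm each).
    """
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown phantom preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
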