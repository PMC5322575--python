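"""End-to-end experiment presets: data synthesis, inversion, and comparison.

Each experiment synthesizes boundary data on a *finer* forward mesh,
optionally adds multiplicative Gaussian noise, and reconstructs the
absorption map on a coarser inverse mesh — two genuinely different
discretizations, so the inversion never sees its own forward model's data
(the "inverse crime" guard).  Sources and detectors sit at boundary nodes
shared exactly by both meshes.

The presets mirror the three simulation studies: a single small inclusion
with varying anisotropy, the single/multi-inclusion comparisons of TV-L1
against pure TV and pure L1 regularization, and the high-absorption /
low-scattering phantom under measurement noise.  ``scale`` reduces the mesh
element counts (and optionally the direction count) for desk-scale runs.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .angular import build_angular_grid
from .forward import MeasurementSet, add_noise, forward_map
from .mesh import mesh_disk, place_boundary_units
from .phantom import Phantom, preset_phantom, rasterize
from .recon import RegParams, error_metrics, reconstruct

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "preset_experiment", "run_experiment",
           "run_regularization_variant", "run_comparison",
           "EXPERIMENT_PRESETS"]


@dataclass
class ExperimentConfig:
    """Full description of one synthetic tomography experiment."""

    phantom: str | Phantom
    forward_elements: int
    inverse_elements: int
    params: RegParams
    n_dir: int = 32
    g: float = 0.9
    n_src: int = 12
    n_det: int = 12
    radius: float = 10.0
    noise_delta: float = 0.0
    noise_seed: int = 0
    mesh_seed_forward: int = 11
    mesh_seed_inverse: int = 7
    solver_tol: float = 1e-7
    solver_max_iter: int = 2000
    outdir: str | None = None

    def __post_init__(self):
        if self.forward_elements <= self.inverse_elements:
            raise ValueError("the forward (data) mesh must be finer than the "
                             "inverse mesh to avoid the inverse crime")
        if self.noise_delta < 0:
            raise ValueError("noise level must be nonnegative")

    @property
    def boundary_multiple(self) -> int:
        # boundary nodes must include source angles i/n_src and detector
        # angles (2j+1)/(2 n_det) of the full circle
        return math.lcm(self.n_src, 2 * self.n_det)

    def resolve_phantom(self) -> Phantom:
        return preset_phantom(self.phantom) if isinstance(self.phantom, str) \
            else self.phantom


# (alpha, beta, eta) per regularization and study case; eps is
# 1e-6 throughout.  sim1/sim2 single-inclusion cases list TV-L1 and TV;
# the multi-inclusion cases additionally list L1.
EXPERIMENT_PRESETS: dict[str, dict] = {
    "sim1_small": dict(phantom="sim1_small", fwd=2440, inv=1484,
                       tvl1=(1e-4, 1e-3, 1e-5), tv=(3e-4, 0.0, 0.0)),
    "sim2_small": dict(phantom="sim2_small", fwd=2440, inv=1484,
                       tvl1=(3e-4, 3e-3, 3e-4), tv=(3e-4, 0.0, 0.0)),
    "sim2_middle": dict(phantom="sim2_middle", fwd=2642, inv=1080,
                        tvl1=(3e-3, 3e-3, 3e-4), tv=(3e-4, 0.0, 0.0)),
    "sim2_big": dict(phantom="sim2_big", fwd=3124, inv=1096,
                     tvl1=(3e-3, 3e-4, 3e-4), tv=(3e-4, 0.0, 0.0)),
    "sim2_two_small": dict(phantom="sim2_two_small", fwd=3616, inv=2488,
                           tvl1=(1e-4, 1e-3, 1e-5), tv=(1e-4, 0.0, 0.0),
                           l1=(0.0, 1e-3, 1e-5)),
    "sim2_three_small": dict(phantom="sim2_three_small", fwd=4176, inv=3264,
                             tvl1=(1e-4, 1e-3, 1e-5), tv=(1e-3, 0.0, 0.0),
                             l1=(0.0, 1e-3, 1e-5)),
    "sim2_big_two_small": dict(phantom="sim2_big_two_small", fwd=3512, inv=2568,
                               tvl1=(1e-3, 1e-3, 1e-5), tv=(1e-3, 0.0, 0.0),
                               l1=(0.0, 1e-4, 1e-6)),
    "sim3": dict(phantom="sim3_abs_scat", fwd=1288, inv=856,
                 tvl1=(5e-4, 5e-4, 1e-6), tvl1_noisy=(5e-3, 5e-4, 1e-6)),
}


def preset_experiment(name: str, variant: str = "tvl1", scale: float = 1.0,
                      n_dir: int | None = None, noise_delta: float = 0.0,
                      noise_seed: int = 0, max_outer: int = 30,
                      stop_tol: float = 1e-4, **overrides) -> ExperimentConfig:
    """Build the configuration for a named preset experiment.

    ``variant`` selects the regularization column (``tvl1``, ``tv``, ``l1``;
    ``sim3`` also has ``tvl1_noisy`` for the 1%-noise parameters).  ``scale``
    multiplies both mesh element targets for reduced-resolution runs; the
    direction count stays at the experiment's value unless ``n_dir`` is given.
    """
    try:
        preset = EXPERIMENT_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown experiment preset {name!r}; valid: "
                         f"{', '.join(sorted(EXPERIMENT_PRESETS))}") from None
    if variant not in preset and variant not in ("tvl1", "tv", "l1"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant not in preset:
        raise ValueError(f"preset {name!r} has no parameters for variant "
                         f"{variant!r}")
    a, b, e = preset[variant]
    # Dual-mesh experiments stop fitting once the calibrated residual has
    # dropped to 10% of its initial size (discrepancy principle: beyond that
    # the iteration fits cross-mesh discretization misfit or noise).
    params = RegParams(alpha=a, beta=b, eta=e, eps=1e-6, max_outer=max_outer,
                       stop_tol=stop_tol, resi_stop_ratio=0.1)
    cfg = ExperimentConfig(
        phantom=preset["phantom"],
        forward_elements=max(64, round(preset["fwd"] * scale)),
        inverse_elements=max(32, round(preset["inv"] * scale)),
        params=params,
        n_dir=n_dir if n_dir is not None else 32,
        noise_delta=noise_delta,
        noise_seed=noise_seed,
        **overrides,
    )
    return cfg


def synthesize_data(config: ExperimentConfig):
    """Forward data on the fine mesh (noise applied if configured); returns
    (MeasurementSet, forward mesh, angular grid)."""
    grid = build_angular_grid(config.n_dir, config.g)
    mesh_f = mesh_disk(config.radius, config.forward_elements,
                       seed=config.mesh_seed_forward,
                       boundary_multiple=config.boundary_multiple)
    phantom = config.resolve_phantom()
    coeffs = rasterize(phantom, mesh_f, mode="exact")
    src, det = place_boundary_units(mesh_f, config.n_src, config.n_det, grid)
    data = forward_map(coeffs, src, det, mesh_f, grid, tol=config.solver_tol,
                       max_iter=config.solver_max_iter)
    if config.noise_delta > 0:
        data = add_noise(data, config.noise_delta, config.noise_seed)
    return data, mesh_f, grid


def _invert(config: ExperimentConfig, data: MeasurementSet, grid):
    mesh_i = mesh_disk(config.radius, config.inverse_elements,
                       seed=config.mesh_seed_inverse,
                       boundary_multiple=config.boundary_multiple)
    phantom = config.resolve_phantom()
    truth = rasterize(phantom, mesh_i, mode="exact")
    src, det = place_boundary_units(mesh_i, config.n_src, config.n_det, grid)
    data_i = MeasurementSet(data.M, src, det, delta=data.delta, seed=data.seed)
    init = np.full(mesh_i.n_elements, phantom.background_mua)
    mua, state = reconstruct(data_i, mesh_i, grid, truth.mus, init,
                             config.params, truth_mua=truth.mua,
                             tol=config.solver_tol,
                             max_iter=config.solver_max_iter)
    # state.pred holds the forward prediction at the final iterate
    e_resi, e_mua = error_metrics(mua, truth.mua, state.pred, data.M)
    return mesh_i, truth, mua, state, e_resi, e_mua


def run_experiment(config: ExperimentConfig,
                   data: MeasurementSet | None = None, grid=None,
                   mesh_f=None, label: str = "experiment") -> dict:
    """Run one experiment end to end; returns the result bundle (and writes
    summary/history/field files when ``config.outdir`` is set)."""
    try:
        if data is None:
            data, mesh_f, grid = synthesize_data(config)
    except Exception:
        logger.exception("stage 'synthesize' failed")
        raise
    try:
        mesh_i, truth, mua, state, e_resi, e_mua = _invert(config, data, grid)
    except Exception:
        logger.exception("stage 'invert' failed")
        raise
    p = config.params
    bundle = {
        "label": label,
        "phantom": config.phantom if isinstance(config.phantom, str) else "inline",
        "alpha": p.alpha, "beta": p.beta, "eta": p.eta, "eps": p.eps,
        "n_dir": config.n_dir, "g": config.g,
        "n_src": config.n_src, "n_det": config.n_det,
        "noise_delta": config.noise_delta, "noise_seed": config.noise_seed,
        "forward_elements": mesh_f.n_elements if mesh_f is not None
        else config.forward_elements,
        "inverse_elements": mesh_i.n_elements,
        "inverse_nodes": mesh_i.n_nodes,
        "iterations": state.iter,
        "status": state.status,
        "E_resi": e_resi,
        "E_mua": e_mua,
        "mua": mua,
        "truth_mua": truth.mua,
        "history": state.history,
        "mesh_inverse": mesh_i,
    }
    if config.outdir:
        _write_bundle(config, bundle)
    return bundle


def run_regularization_variant(config: ExperimentConfig, variant: str,
                               data: MeasurementSet | None = None, grid=None,
                               mesh_f=None) -> dict:
    """Run the experiment with the TV-L1 parameters degraded to a pure-TV
    (beta = eta = 0) or pure-L1 (alpha = 0) variant; ``tvl1`` runs as is."""
    p = config.params
    if variant == "tvl1":
        cfg = config
    elif variant == "tv":
        cfg = replace(config, params=replace(p, beta=0.0, eta=0.0))
    elif variant == "l1":
        cfg = replace(config, params=replace(p, alpha=0.0))
    else:
        raise ValueError(f"unknown variant {variant!r} (tvl1, tv, l1)")
    return run_experiment(cfg, data=data, grid=grid, mesh_f=mesh_f,
                          label=variant)


def run_comparison(configs: dict[str, ExperimentConfig]) -> dict[str, dict]:
    """Run several parameterizations (e.g. the tvl1/tv/l1 columns) against
    the *same* synthesized data set; configs must share the data geometry.

    Keys of ``configs`` label the rows of the returned bundle dict.
    """
    first = next(iter(configs.values()))
    data, mesh_f, grid = synthesize_data(first)
    out = {}
    for name, cfg in configs.items():
        if (cfg.forward_elements, cfg.n_dir, cfg.noise_delta, cfg.noise_seed) \
                != (first.forward_elements, first.n_dir, first.noise_delta,
                    first.noise_seed):
            raise ValueError("comparison configs must share the data geometry")
        out[name] = run_experiment(cfg, data=data, grid=grid, mesh_f=mesh_f,
                                   label=name)
    return out


def _write_bundle(config: ExperimentConfig, bundle: dict) -> None:
    from .io import write_field_csv, write_vtk

    os.makedirs(config.outdir, exist_ok=True)
    base = os.path.join(config.outdir, bundle["label"])
    with open(base + "_summary.txt", "w") as fh:
        for k in ("label", "phantom", "alpha", "beta", "eta", "eps", "n_dir",
                  "g", "n_src", "n_det", "noise_delta", "noise_seed",
                  "forward_elements", "inverse_elements", "inverse_nodes",
                  "iterations", "status", "E_resi", "E_mua"):
            fh.write(f"{k} = {bundle[k]}\n")
    with open(base + "_history.csv", "w") as fh:
        cols = ["iter", "E_resi", "E_mua", "objective", "data_fidelity",
                "tv", "l1", "step_norm"]
        fh.write(",".join(cols) + "\n")
        for rec in bundle["history"]:
            fh.write(",".join(str(rec.get(c, "")) for c in cols) + "\n")
    write_field_csv(base + "_mua.csv", mua=bundle["mua"],
                    mua_true=bundle["truth_mua"])
    write_vtk(base + "_mua.vtk", bundle["mesh_inverse"],
              {"mua": bundle["mua"], "mua_true": bundle["truth_mua"]})
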