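"""White-box recovery of an absorbing inclusion (same-mesh, noise-free).

A single r = 2 mm inclusion (mua twice background) is reconstructed from
6 x 6 boundary measurements by split Bregman TV-L1.  Because data synthesis
and inversion share the mesh and the data are exact, this isolates the
inverse solver: the relative L2 error should drop well below 10%.
"""

import numpy as np

from rtetomo import (Inclusion, Phantom, RegParams, build_angular_grid,
                     forward_map, mesh_disk, place_boundary_units, rasterize,
                     reconstruct)

grid = build_angular_grid(16, g=0.9)
mesh = mesh_disk(10.0, 400, seed=2)
phantom = Phantom(0.01, 2.0, [Inclusion((5.0, 0.0), 2.0, mua=0.02)])
coeffs = rasterize(phantom, mesh)
sources, detectors = place_boundary_units(mesh, 6, 6, grid)
data = forward_map(coeffs, sources, detectors, mesh, grid, tol=1e-8)

params = RegParams(alpha=1e-5, beta=1e-4, eta=1e-5, eps=1e-6,
                   max_outer=25, stop_tol=1e-4)
init = np.full(mesh.n_elements, 0.01)   # start from the background value
mua, state = reconstruct(data, mesh, grid, coeffs.mus, init, params,
                         truth_mua=coeffs.mua, tol=1e-8)

print("iter  E_mua   E_resi")
for h in state.history[::4]:
    print(f"{h['iter']:4d}  {h['E_mua']:.4f}  {h['E_resi']:.2e}")
e_final = np.linalg.norm(mua - coeffs.mua) / np.linalg.norm(coeffs.mua)
print(f"\nfinal relative L2 error E_mua = {100 * e_final:.2f}%  "
      f"({state.iter} iterations, {state.status})")
print(f"recovered inclusion peak mua = {mua.max():.4f} (truth 0.02, "
      f"background 0.01)")
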