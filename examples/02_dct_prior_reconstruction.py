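"""Reconstruct a uniform-ventilation frame with the DCT contour prior.

Simulates the uniform lung-ventilation pattern (lung conductivity 0.5 ->
0.25) with 25% measurement noise on a fine forward mesh, reconstructs on an
independent coarse mesh in the lung-masked cosine subspace, and prints the
calibrated hyperparameter, the achieved noise figure, and where the
reconstructed change lives.
"""

import numpy as np

from eitdct import (
    DctPipeline,
    ReconConfig,
    adjacent_protocol,
    apply_pattern,
    build_dct_basis,
    build_mesh,
    make_contour_prior,
    make_thorax_scene,
    normalized_jacobian,
    simulate_measurement,
    solve_forward,
)

scene0 = make_thorax_scene(128, 128, seed=0)
scene = apply_pattern(scene0, "a")
protocol = adjacent_protocol(16)

fwd = build_mesh(scene.thorax_polygon, 16, 12000)
inv = build_mesh(scene.thorax_polygon, 16, 3000)
v_target = solve_forward(
    fwd.with_conductivity(scene.element_conductivity(fwd, "target")), protocol
).values
v_base = solve_forward(
    fwd.with_conductivity(scene.element_conductivity(fwd, "baseline")), protocol
).values
y = simulate_measurement(None, None, protocol, noise_fraction=0.25, seed=7,
                         v_target=v_target, v_baseline=v_base)

J, _ = normalized_jacobian(inv, scene.element_conductivity(inv, "baseline"),
                           protocol)
prior = make_contour_prior(scene.lung_mask, scene.extent)
pipe = DctPipeline(inv, prior, J, build_dct_basis(128, 128, 15, 15),
                   scene.extent, ReconConfig(target_noise_figure=0.5))
result = pipe.reconstruct(y)

H = result.restored_image.values
lung = scene.lung_mask
print(f"lambda = {result.lambda_used:.4f}, "
      f"noise figure = {result.achieved_noise_figure:.4f} (target 0.5)")
print(f"mean change in lung:  {H[lung].mean():+.3f} AU "
      "(true change is -0.25: conductivity fell with inflation)")
print(f"max |change| outside lung: {np.abs(H[~lung]).max():.1f} "
      "(exactly 0 - the prior confines the reconstruction)")
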