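"""Detail prior vs contour prior on a 30% dorsal-atelectasis phantom.

The detail prior (CT Hounsfield weights) is zero over the collapsed slab, so
the reconstruction is inhibited exactly there; the contour prior spreads the
ventilation signal over the whole lung. Prints the restored amplitude inside
the atelectatic slab for both priors and the image errors vs ground truth.
"""

import numpy as np

from eitdct import (
    DctPipeline,
    ReconConfig,
    adjacent_protocol,
    apply_atelectasis,
    build_dct_basis,
    build_mesh,
    l2_image_difference,
    make_contour_prior,
    make_detail_prior,
    make_thorax_scene,
    normalize_image,
    normalized_jacobian,
    simulate_measurement,
    solve_forward,
)

scene0 = make_thorax_scene(128, 128, seed=0)
scene = apply_atelectasis(scene0, fraction=0.30)
atel = scene.meta["atelectasis_mask"]
protocol = adjacent_protocol(16)

fwd = build_mesh(scene.thorax_polygon, 16, 12000)
inv = build_mesh(scene.thorax_polygon, 16, 3000)
vt = solve_forward(
    fwd.with_conductivity(scene.element_conductivity(fwd, "target")), protocol
).values
vb = solve_forward(
    fwd.with_conductivity(scene.element_conductivity(fwd, "baseline")), protocol
).values
y = simulate_measurement(None, None, protocol, 0.25, seed=11,
                         v_target=vt, v_baseline=vb)

J, _ = normalized_jacobian(inv, scene.element_conductivity(inv, "baseline"),
                           protocol)
basis = build_dct_basis(128, 128, 15, 15)
cfg = ReconConfig(target_noise_figure=0.5)
gt = normalize_image(scene.ground_truth)

for name, prior in (
    ("contour", make_contour_prior(scene.lung_mask, scene.extent)),
    ("detail ", make_detail_prior(scene.ct_surrogate, scene.lung_mask)),
):
    pipe = DctPipeline(inv, prior, J, basis, scene.extent, cfg)
    H = pipe.reconstruct(y).restored_image
    err = l2_image_difference(normalize_image(H), gt)
    amp = np.abs(H.values[atel]).max()
    print(f"{name} prior: max |H| in atelectatic slab = {amp:.4f}, "
          f"l2 image difference vs truth = {err:.2f}")
print("the contour prior paints spurious ventilation into the collapsed "
      "slab; the detail prior suppresses it exactly (single noisy frames - "
      "the image errors fluctuate seed to seed, the zero is structural)")
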