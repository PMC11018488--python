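"""Generate a synthetic panicle scene and build its training labels.

Prints the exact ground-truth count, the density-map integral (which
must equal that count — the property that makes density-map counting
work), and the label shapes at the network's output stride.
"""

import flowernet as fn

spec = fn.SceneSpec(height=256, width=256, n_flowers=120,
                    flower_spacing_min=6.0, seed=42)
scene = fn.generate_scene(spec)
print(f"scene: {scene.image.shape[0]}x{scene.image.shape[1]} px, "
      f"{len(scene.points)} annotated flowers")

density, mask = fn.make_targets(scene.points, scene.image.shape,
                                sigma=4.0, dilation=3, stride=8)
print(f"density-map integral: {density.count:.9f} "
      f"(equals the flower count — counting is summing the map)")
print(f"labels at stride 8: density {density.values.shape}, "
      f"mask {mask.values.shape}, foreground cells {int(mask.values.sum())}")
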